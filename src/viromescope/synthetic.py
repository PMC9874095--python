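"""Synthetic gut-virome community generator with known ground truth.

Everything the pipeline consumes can be generated here: viral and host
genomes with planted prophages and CRISPR arrays, bulk/VLP contig pools
with detector-evidence records, and case-control abundance tables with
planted group effects and planted virus-bacterium correlations.  Every
generator is a pure function of (parameters, seed), so all downstream
recovery tests have an exact oracle (:class:`StudyTruth`).

Models
------
* Sequences are i.i.d. uniform over ACGT, so spurious alignment hits are
  quantifiably rare (an exact shared 20-mer between unrelated 10 kb
  sequences has probability ~ L^2/4^20).
* Prophages are verbatim substrings of a viral genome spliced into a host
  backbone; CRISPR arrays follow the detector's model (repeat length
  23-47 nt, spacers 26-50 nt cut verbatim from a viral genome, >= 2
  repeats).  Consecutive planted spacers are rejection-sampled to differ
  in their first and last base, which makes repeat/spacer boundaries
  exactly identifiable by an exact-repeat detector.
* Detector evidence separates viral from non-viral contigs stochastically:
  DeepVirFinder-like scores are Beta(8,2) for viral and Beta(2,8) for
  non-viral contigs with p = (1 - score)^2, and the noise ``level``
  interpolates between that model (level=1) and a deterministic,
  perfectly separated limit (level=0).
* Abundances are log-normal (per-feature mean, sigma=1 on the natural-log
  scale) then closed to relative abundances; planted differential features
  receive a group-mean log2 ratio of ``effect_log2`` before noise;
  planted virus-bacterium pairs share a Gaussian latent factor whose
  loading is chosen to induce a target Spearman correlation.

The default study design is 16 cases ("SLE") versus 31 controls.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .annotate import ProteinHit
from .profiling import AbundanceProfile, normalize_counts
from .triage import ContigRecord, ViralEvidence

_ALPHABET = np.frombuffer(b"ACGT", dtype=np.uint8)

VIRAL_FAMILIES = (
    "Siphoviridae",
    "Myoviridae",
    "Microviridae",
    "Podoviridae",
    "crAss-like",
    "Quimbyviridae",
    "Autographiviridae",
    "Inoviridae",
)

HOST_GENERA = (
    ("Bacteroides", "Bacteroidota"),
    ("Prevotella", "Bacteroidota"),
    ("Ruminococcus_E", "Firmicutes"),
    ("Parabacteroides", "Bacteroidota"),
    ("Lachnospirales_CAG-274", "Firmicutes"),
    ("Hungatella_A", "Firmicutes"),
)


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ViralGenome:
    id: str
    sequence: str
    family: str
    protein_coords: tuple[tuple[int, int], ...]


@dataclass(frozen=True)
class PlantedProphage:
    virus_id: str
    host_start: int
    host_end: int
    virus_start: int
    virus_end: int


@dataclass(frozen=True)
class PlantedArray:
    repeat: str
    spacers: tuple[str, ...]
    spacer_sources: tuple[tuple[str, int, int], ...]  # (virus_id, start, end)
    host_start: int


@dataclass(frozen=True)
class HostGenome:
    id: str
    sequence: str
    genus: str
    phylum: str
    prophages: tuple[PlantedProphage, ...]
    crispr_arrays: tuple[PlantedArray, ...]
    backbone_intervals: tuple[tuple[int, int], ...]  # purely non-viral spans


@dataclass
class GenomeSet:
    viral_genomes: list[ViralGenome]
    host_genomes: list[HostGenome]

    def viral_by_id(self) -> dict[str, ViralGenome]:
        return {v.id: v for v in self.viral_genomes}

    def host_taxonomy(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "host_id": [h.id for h in self.host_genomes],
                "genus": [h.genus for h in self.host_genomes],
                "phylum": [h.phylum for h in self.host_genomes],
            }
        ).set_index("host_id")


@dataclass(frozen=True)
class StudyDesign:
    sample_ids: tuple[str, ...]
    labels: tuple[str, ...]
    case_label: str = "SLE"
    control_label: str = "Control"

    def __post_init__(self) -> None:
        groups = set(self.labels)
        if groups != {self.case_label, self.control_label}:
            raise ValueError(f"labels must be exactly two groups, got {groups}")
        if self.n_case < 2 or self.n_control < 2:
            raise ValueError("each group needs at least 2 samples")
        if len(self.sample_ids) != len(self.labels):
            raise ValueError("sample_ids and labels length mismatch")

    @property
    def n_case(self) -> int:
        return sum(1 for l in self.labels if l == self.case_label)

    @property
    def n_control(self) -> int:
        return sum(1 for l in self.labels if l == self.control_label)

    @property
    def case_ids(self) -> list[str]:
        return [s for s, l in zip(self.sample_ids, self.labels) if l == self.case_label]

    @property
    def control_ids(self) -> list[str]:
        return [
            s for s, l in zip(self.sample_ids, self.labels) if l == self.control_label
        ]

    def label_series(self) -> pd.Series:
        return pd.Series(list(self.labels), index=list(self.sample_ids), name="group")

    @classmethod
    def balanced(cls, n_case: int = 16, n_control: int = 31) -> "StudyDesign":
        """The study's 16-patient / 31-control layout by default."""
        samples = [f"SLE{i + 1:02d}" for i in range(n_case)] + [
            f"HC{i + 1:02d}" for i in range(n_control)
        ]
        labels = ["SLE"] * n_case + ["Control"] * n_control
        return cls(tuple(samples), tuple(labels))


@dataclass
class StudyTruth:
    """Planted signals used as recovery-test oracles."""

    viral_labels: dict[str, str] = field(default_factory=dict)  # contig -> viral|nonviral
    contig_sources: dict[str, str] = field(default_factory=dict)  # contig -> genome id
    differential_features: list[tuple[str, str, float]] = field(default_factory=list)
    correlated_pairs: list[tuple[str, str, int]] = field(default_factory=list)
    spacer_links: list[tuple[str, str]] = field(default_factory=list)  # (virus, host)
    prophage_links: list[tuple[str, str]] = field(default_factory=list)


@dataclass(frozen=True)
class EvidenceNoise:
    """Evidence-noise level in [0, 1]; 0 = perfectly separated detectors."""

    level: float = 1.0

    def __post_init__(self) -> None:
        if not (0.0 <= self.level <= 1.0):
            raise ValueError(f"noise level {self.level} outside [0, 1]")


# ---------------------------------------------------------------------------
# sequence helpers
# ---------------------------------------------------------------------------

def _random_sequence(rng: np.random.Generator, length: int) -> str:
    return _ALPHABET[rng.integers(0, 4, size=length)].tobytes().decode("ascii")


def mutate_sequence(
    sequence: str, rate: float, rng: np.random.Generator
) -> str:
    """Substitute a fraction ``rate`` of positions with a different base."""
    arr = np.frombuffer(sequence.encode("ascii"), dtype=np.uint8).copy()
    n_mut = int(round(rate * len(arr)))
    if n_mut == 0:
        return sequence
    pos = rng.choice(len(arr), size=n_mut, replace=False)
    shift = rng.integers(1, 4, size=n_mut)
    lookup = {c: i for i, c in enumerate(_ALPHABET)}
    idx = np.array([lookup[c] for c in arr[pos]])
    arr[pos] = _ALPHABET[(idx + shift) % 4]
    return arr.tobytes().decode("ascii")


def _protein_coords(
    rng: np.random.Generator, length: int
) -> tuple[tuple[int, int], ...]:
    coords = []
    pos = 0
    while pos + 300 <= length:
        end = min(pos + int(rng.integers(600, 1200)), length)
        coords.append((pos, end))
        pos = end
    return tuple(coords)


# ---------------------------------------------------------------------------
# genome generation
# ---------------------------------------------------------------------------

def generate_genomes(
    n_viral: int = 8,
    n_host: int = 4,
    *,
    viral_length: tuple[int, int] = (6000, 12000),
    host_length: tuple[int, int] = (20000, 35000),
    prophage_rate: float = 0.5,
    spacer_count: int = 3,
    seed: int = 0,
) -> GenomeSet:
    """Generate viral and host genomes with planted prophages and CRISPRs.

    ``host_length`` sizes the random backbone; planted inserts extend it.
    Every host carries one CRISPR array of ``spacer_count`` spacers (each a
    verbatim substring of a viral genome) and, with probability
    ``prophage_rate``, one prophage (a verbatim viral substring covering
    50-100% of its source genome).
    """
    if n_viral < 1 or n_host < 1:
        raise ValueError("n_viral and n_host must be positive")
    if min(*viral_length, *host_length) <= 0:
        raise ValueError("length ranges must be positive")
    if spacer_count < 0:
        raise ValueError("spacer_count must be >= 0")
    rng = np.random.default_rng(seed)

    viral = []
    for i in range(n_viral):
        length = int(rng.integers(viral_length[0], viral_length[1] + 1))
        seq = _random_sequence(rng, length)
        viral.append(
            ViralGenome(
                id=f"virus_{i + 1:03d}",
                sequence=seq,
                family=VIRAL_FAMILIES[i % len(VIRAL_FAMILIES)],
                protein_coords=_protein_coords(rng, length),
            )
        )

    hosts = []
    for i in range(n_host):
        genus, phylum = HOST_GENERA[i % len(HOST_GENERA)]
        host_id = f"host_{i + 1:03d}"
        backbone = int(rng.integers(host_length[0], host_length[1] + 1))
        backbone = max(backbone, 9000)
        extra = backbone - 9000
        cuts = np.sort(rng.integers(0, extra + 1, size=2)) if extra else np.zeros(2, int)
        parts = [3000 + int(cuts[0]), 3000 + int(cuts[1] - cuts[0]), 3000 + int(extra - cuts[1])]

        prophage = None
        if rng.random() < prophage_rate and n_viral > 0:
            v = viral[int(rng.integers(0, n_viral))]
            frac = rng.uniform(0.5, 1.0)
            plen = int(frac * len(v.sequence))
            vstart = int(rng.integers(0, len(v.sequence) - plen + 1))
            prophage = (v.id, vstart, vstart + plen, v.sequence[vstart : vstart + plen])

        array = None
        if spacer_count >= 1:
            array = _plant_array(rng, viral, spacer_count)

        pieces: list[str] = []
        backbone_intervals: list[tuple[int, int]] = []
        prophages: list[PlantedProphage] = []
        arrays: list[PlantedArray] = []
        pos = 0

        def _add_backbone(length: int) -> None:
            nonlocal pos
            pieces.append(_random_sequence(rng, length))
            backbone_intervals.append((pos, pos + length))
            pos += length

        _add_backbone(parts[0])
        if prophage is not None:
            vid, vs, ve, pseq = prophage
            prophages.append(PlantedProphage(vid, pos, pos + len(pseq), vs, ve))
            pieces.append(pseq)
            pos += len(pseq)
        _add_backbone(parts[1])
        if array is not None:
            repeat, spacers, sources = array
            # keep the array's left boundary identifiable: the backbone base
            # preceding the first repeat must differ from the base preceding
            # the second repeat (= last base of the first spacer)
            prev = pieces[-1]
            if prev[-1] == spacers[0][-1]:
                replacement = next(c for c in "ACGT" if c != spacers[0][-1])
                pieces[-1] = prev[:-1] + replacement
            text = repeat + "".join(sp + repeat for sp in spacers)
            arrays.append(
                PlantedArray(
                    repeat=repeat,
                    spacers=tuple(spacers),
                    spacer_sources=tuple(sources),
                    host_start=pos,
                )
            )
            pieces.append(text)
            pos += len(text)
        _add_backbone(parts[2])

        hosts.append(
            HostGenome(
                id=host_id,
                sequence="".join(pieces),
                genus=genus,
                phylum=phylum,
                prophages=tuple(prophages),
                crispr_arrays=tuple(arrays),
                backbone_intervals=tuple(backbone_intervals),
            )
        )
    return GenomeSet(viral_genomes=viral, host_genomes=hosts)


def _plant_array(
    rng: np.random.Generator, viral: list[ViralGenome], spacer_count: int
) -> tuple[str, list[str], list[tuple[str, int, int]]]:
    """One CRISPR array: exact repeats, spacers cut verbatim from viruses.

    Consecutive spacers are rejection-sampled to differ in first and last
    base so that an exact-repeat detector can place boundaries exactly.
    """
    repeat_len = int(rng.integers(23, 48))
    repeat = _random_sequence(rng, repeat_len)
    spacers: list[str] = []
    sources: list[tuple[str, int, int]] = []
    for _ in range(spacer_count):
        for _attempt in range(500):
            v = viral[int(rng.integers(0, len(viral)))]
            slen = int(rng.integers(26, 51))
            start = int(rng.integers(0, len(v.sequence) - slen + 1))
            cand = v.sequence[start : start + slen]
            if spacers and (cand[0] == spacers[-1][0] or cand[-1] == spacers[-1][-1]):
                continue
            spacers.append(cand)
            sources.append((v.id, start, start + slen))
            break
        else:  # pragma: no cover - probability ~ (7/16)^500
            raise RuntimeError("could not sample a boundary-distinct spacer")
    return repeat, spacers, sources


# ---------------------------------------------------------------------------
# contig pools with detector evidence
# ---------------------------------------------------------------------------

_VIRAL_TIER_P = np.array([0.16, 0.33, 0.36, 0.10, 0.05])
_NONVIRAL_TIER_P = np.array([0.01, 0.02, 0.07, 0.45, 0.45])
_TIERS = ("complete", "high", "medium", "low", "not-determined")


def _viral_evidence(
    rng: np.random.Generator, contig_id: str, length: int, level: float
) -> ViralEvidence:
    total = max(3, length // 500)
    if level == 0.0:
        return ViralEvidence(contig_id, total, 0, 0.99, (1 - 0.99) ** 2, True,
                             "high", 0, total)
    score = float((1 - level) * 0.99 + level * rng.beta(8, 2))
    vg = int(rng.binomial(total, 1 - 0.25 * level))
    tier_p = (1 - level) * np.array([0, 1, 0, 0, 0]) + level * _VIRAL_TIER_P
    return ViralEvidence(
        contig_id=contig_id,
        viral_gene_count=vg,
        microbial_gene_count=total - vg,
        dvf_score=score,
        dvf_pvalue=(1 - score) ** 2,
        vibrant_viral=bool(rng.random() >= 0.10 * level),
        checkv_quality=_TIERS[int(rng.choice(5, p=tier_p / tier_p.sum()))],
        busco_hits=int(rng.binomial(total, 0.01 * level)),
        total_genes=total,
    )


def _nonviral_evidence(
    rng: np.random.Generator, contig_id: str, length: int, level: float
) -> ViralEvidence:
    total = max(3, length // 500)
    if level == 0.0:
        return ViralEvidence(contig_id, 0, total, 0.20, (1 - 0.20) ** 2, False,
                             "not-determined", max(1, round(0.25 * total)), total)
    score = float((1 - level) * 0.20 + level * rng.beta(2, 8))
    vg = int(rng.binomial(total, 0.10 * level))
    tier_p = (1 - level) * np.array([0, 0, 0, 0, 1]) + level * _NONVIRAL_TIER_P
    return ViralEvidence(
        contig_id=contig_id,
        viral_gene_count=vg,
        microbial_gene_count=total - vg,
        dvf_score=score,
        dvf_pvalue=(1 - score) ** 2,
        vibrant_viral=bool(rng.random() < 0.05 * level),
        checkv_quality=_TIERS[int(rng.choice(5, p=tier_p / tier_p.sum()))],
        busco_hits=int(rng.binomial(total, 0.25)),
        total_genes=total,
    )


def generate_contig_pool(
    genomes: GenomeSet,
    design: StudyDesign,
    mode: str,
    *,
    noise: EvidenceNoise = EvidenceNoise(),
    n_contigs_per_sample: int = 10,
    viral_fraction: float | None = None,
    length_range: tuple[int, int] = (2000, 6000),
    seed: int = 0,
) -> tuple[list[ContigRecord], list[ViralEvidence], StudyTruth]:
    """Sample a per-sample contig pool with truth labels and evidence.

    VLP pools default to a much higher viral fraction (0.8) than bulk pools
    (0.3), mirroring the enrichment asymmetry between the two library
    types.  Contig lengths respect the 2 kb triage floor; a requested lower
    bound below 2000 is clamped with a warning.
    """
    if mode not in ("bulk", "vlp"):
        raise ValueError(f"unknown mode {mode!r}; legal: bulk, vlp")
    if not genomes.viral_genomes or not genomes.host_genomes:
        raise ValueError("genome set must contain viral and host genomes")
    lo, hi = length_range
    if lo < 2000:
        warnings.warn(
            f"contig length lower bound {lo} below the 2 kb floor; clamped to 2000",
            stacklevel=2,
        )
        lo = 2000
    if viral_fraction is None:
        viral_fraction = 0.8 if mode == "vlp" else 0.3
    rng = np.random.default_rng(seed)

    contigs: list[ContigRecord] = []
    evidence: list[ViralEvidence] = []
    truth = StudyTruth()
    n_viral = int(round(n_contigs_per_sample * viral_fraction))
    for sample in design.sample_ids:
        for k in range(n_contigs_per_sample):
            cid = f"{sample}_{mode}_c{k + 1:03d}"
            is_viral = k < n_viral
            if is_viral:
                g = genomes.viral_genomes[int(rng.integers(len(genomes.viral_genomes)))]
                max_len = min(hi, len(g.sequence))
                length = int(rng.integers(lo, max_len + 1)) if max_len > lo else max_len
                start = int(rng.integers(0, len(g.sequence) - length + 1))
                seq = g.sequence[start : start + length]
                ev = _viral_evidence(rng, cid, length, noise.level)
                truth.viral_labels[cid] = "viral"
            else:
                h = genomes.host_genomes[int(rng.integers(len(genomes.host_genomes)))]
                spans = [iv for iv in h.backbone_intervals if iv[1] - iv[0] >= lo]
                s0, s1 = spans[int(rng.integers(len(spans)))]
                max_len = min(hi, s1 - s0)
                length = int(rng.integers(lo, max_len + 1)) if max_len > lo else max_len
                start = s0 + int(rng.integers(0, (s1 - s0) - length + 1))
                seq = h.sequence[start : start + length]
                ev = _nonviral_evidence(rng, cid, length, noise.level)
                truth.viral_labels[cid] = "nonviral"
                g = h
            contigs.append(
                ContigRecord(id=cid, sample_id=sample, mode=mode, length=len(seq),
                             sequence=seq)
            )
            evidence.append(ev)
            truth.contig_sources[cid] = g.id
    return contigs, evidence, truth


# ---------------------------------------------------------------------------
# abundance study
# ---------------------------------------------------------------------------

def generate_abundance_study(
    design: StudyDesign,
    *,
    n_votus: int = 120,
    n_genera: int = 40,
    n_differential: int = 16,
    effect_log2: float = 2.0,
    n_corr_pairs: int = 6,
    rho_target: float = 0.9,
    sigma: float = 1.0,
    seed: int = 0,
) -> tuple[AbundanceProfile, AbundanceProfile, StudyTruth]:
    """Log-normal virome and bacteriome profiles with planted signals.

    Returns (virome profile, bacteriome profile, truth).  Differential
    vOTUs alternate direction (case-enriched / control-enriched) and carry
    a pre-noise group-mean log2 ratio of ``effect_log2``; correlated
    (vOTU, genus) pairs share a latent Gaussian factor inducing
    sign(rho_target) rank correlation of magnitude ~|rho_target|.
    """
    if n_differential > n_votus:
        raise ValueError("n_differential exceeds n_votus")
    if not abs(rho_target) < 1:
        raise ValueError("|rho_target| must be < 1")
    if n_corr_pairs > min(n_votus, n_genera):
        raise ValueError("n_corr_pairs exceeds available features")
    rng = np.random.default_rng(seed)
    n = len(design.sample_ids)
    case_mask = np.array([l == design.case_label for l in design.labels], dtype=float)

    votus = [f"vOTU_{i + 1:04d}" for i in range(n_votus)]
    genera = [f"genus_{i + 1:03d}" for i in range(n_genera)]

    truth = StudyTruth()
    ln2 = np.log(2.0)

    # per-feature log-normal model: mean + planted group effect + noise
    mu_v = rng.normal(0.0, 1.5, size=n_votus)
    mu_b = rng.normal(0.0, 1.5, size=n_genera)
    noise_v = rng.normal(0.0, 1.0, size=(n, n_votus))
    noise_b = rng.normal(0.0, 1.0, size=(n, n_genera))
    effect_v = np.zeros((n, n_votus))

    diff_idx = rng.choice(n_votus, size=n_differential, replace=False)
    for j, fi in enumerate(sorted(int(i) for i in diff_idx)):
        direction = design.case_label if j % 2 == 0 else design.control_label
        group = case_mask if direction == design.case_label else 1.0 - case_mask
        effect_v[:, fi] = effect_log2 * ln2 * group
        truth.differential_features.append((votus[fi], direction, float(effect_log2)))

    # Correlated pairs sit on the differential (study-associated) vOTUs when
    # available — the network is built over study-associated features — and
    # spill over to free vOTUs otherwise.  The shared Gaussian factor is a
    # *component* of the per-feature noise with weight rho_p (the Pearson
    # correlation matching the target Spearman rho for bivariate normals),
    # so marginal variances are unchanged and closure stays well behaved.
    diff_set = {int(i) for i in diff_idx}
    candidates = sorted(diff_set) + [i for i in range(n_votus) if i not in diff_set]
    pair_votus = candidates[:n_corr_pairs]
    pair_g = rng.choice(n_genera, size=n_corr_pairs, replace=False)
    rho_p = 2.0 * np.sin(np.pi * abs(rho_target) / 6.0)
    sign = 1 if rho_target >= 0 else -1
    effect_b = np.zeros((n, n_genera))
    for fv, gi in zip(pair_votus, pair_g):
        fg = int(gi)
        z = rng.normal(0.0, 1.0, size=n)
        noise_v[:, fv] = np.sqrt(rho_p) * z + np.sqrt(1 - rho_p) * rng.normal(0, 1, n)
        noise_b[:, fg] = sign * np.sqrt(rho_p) * z + np.sqrt(1 - rho_p) * rng.normal(
            0, 1, n
        )
        # a phage correlated with a disease-associated vOTU tracks a host
        # genus that shares the disease shift; without this the group effect
        # is noise w.r.t. the pair and attenuates the planted correlation
        effect_b[:, fg] = sign * effect_v[:, fv]
        truth.correlated_pairs.append((votus[fv], genera[fg], sign))

    log_v = mu_v[None, :] + effect_v + sigma * noise_v
    log_b = mu_b[None, :] + effect_b + sigma * noise_b

    families = [
        VIRAL_FAMILIES[i % len(VIRAL_FAMILIES)] if i % 3 != 2 else None
        for i in range(n_votus)
    ]
    host_genus = [HOST_GENERA[i % len(HOST_GENERA)][0] for i in range(n_votus)]
    v_meta = pd.DataFrame(
        {"family": families, "host_genus": host_genus}, index=pd.Index(votus)
    )
    b_meta = pd.DataFrame(
        {"phylum": [HOST_GENERA[i % len(HOST_GENERA)][1] for i in range(n_genera)]},
        index=pd.Index(genera),
    )

    samples = pd.Index(design.sample_ids)
    virome = normalize_counts(
        pd.DataFrame(np.exp(log_v), index=samples, columns=votus), v_meta
    )
    bacteriome = normalize_counts(
        pd.DataFrame(np.exp(log_b), index=samples, columns=genera), b_meta
    )
    return virome, bacteriome, truth


# ---------------------------------------------------------------------------
# protein-hit tables (DIAMOND-style surrogate)
# ---------------------------------------------------------------------------

def generate_protein_hits(
    viruses: list[ViralGenome],
    *,
    classified_fraction: float = 0.75,
    vote_share: float = 0.40,
    seed: int = 0,
) -> list[ProteinHit]:
    """Surrogate protein-alignment hits for family-vote taxonomy.

    For a ``classified_fraction`` share of viruses, a ``vote_share``
    fraction of proteins hits the genome's true family (above the one
    quarter vote threshold); the remainder receive too few same-family
    hits to be classified.  A sprinkle of off-family noise hits on other
    proteins exercises the plurality logic without outvoting the truth.
    """
    rng = np.random.default_rng(seed)
    hits: list[ProteinHit] = []
    for vi, v in enumerate(viruses):
        n_prot = len(v.protein_coords)
        if n_prot == 0:
            continue
        classified = rng.random() < classified_fraction
        share = vote_share if classified else 0.15
        n_true = int(np.floor(share * n_prot)) if not classified else max(
            int(np.ceil(share * n_prot)), int(np.floor(0.25 * n_prot)) + 1
        )
        n_true = min(n_true, n_prot)
        order = rng.permutation(n_prot)
        true_proteins = order[:n_true]
        other_family = VIRAL_FAMILIES[(vi + 3) % len(VIRAL_FAMILIES)]
        n_noise = min(max(0, int(np.floor(0.25 * n_prot)) - 1), n_prot - n_true)
        noise_proteins = order[n_true : n_true + n_noise]
        for p in true_proteins:
            hits.append(
                ProteinHit(
                    virus_id=v.id,
                    protein_id=f"{v.id}_p{p + 1:03d}",
                    family_label=v.family,
                    percent_identity=float(rng.uniform(40, 95)),
                    query_coverage=float(rng.uniform(60, 100)),
                    subject_coverage=float(rng.uniform(60, 100)),
                    bit_score=float(rng.uniform(80, 400)),
                )
            )
        for p in noise_proteins:
            hits.append(
                ProteinHit(
                    virus_id=v.id,
                    protein_id=f"{v.id}_p{p + 1:03d}",
                    family_label=other_family,
                    percent_identity=float(rng.uniform(30, 60)),
                    query_coverage=float(rng.uniform(50, 90)),
                    subject_coverage=float(rng.uniform(50, 90)),
                    bit_score=float(rng.uniform(50, 120)),
                )
            )
    return hits
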