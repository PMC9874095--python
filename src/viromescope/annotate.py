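"""Viral taxonomy and host prediction.

Three evidence channels are implemented:

* **Family vote** — protein hits (DIAMOND-style rows) are filtered at
  query cover >= 50, subject cover >= 50, identity >= 30 and bit-score
  >= 50, reduced to the single best hit per protein, and the virus is
  assigned the family matched by strictly more than a quarter of its
  proteins.  Plurality ties or insufficient support yield
  ``unclassified``.
* **Prophage matches** — the viral sequence is locally aligned against
  each host genome (word size 20); a host is assigned at >= 90% merged
  nucleotide identity covering >= 30% of the *viral* sequence.
* **CRISPR-spacer matches** — CRISPR arrays are detected in host genomes
  (exact tandem repeats of 23-47 nt separated by 26-50 nt spacers, at
  least 2 repeat copies, in the style of MinCED), and each spacer is
  aligned to the virus with the short-query scoring scheme (word size 8,
  reward +2 / penalty -3); an assignment requires a bit-score >= 45 with
  blastn-short Karlin-Altschul constants (lambda = 0.625, K = 0.41).
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass

import pandas as pd

from .alignment import best_local_score, bitscore, local_align


@dataclass(frozen=True)
class ProteinHit:
    virus_id: str
    protein_id: str
    family_label: str
    percent_identity: float
    query_coverage: float
    subject_coverage: float
    bit_score: float

    def __post_init__(self) -> None:
        for name in ("query_coverage", "subject_coverage"):
            v = getattr(self, name)
            if not (0.0 <= v <= 100.0):
                raise ValueError(f"{self.protein_id}: {name}={v} outside [0, 100]")


@dataclass(frozen=True)
class CrisprArray:
    genome_id: str
    repeat_sequence: str
    spacers: tuple[str, ...]
    positions: tuple[tuple[int, int], ...]  # repeat intervals, half-open

    @property
    def n_repeats(self) -> int:
        return len(self.positions)


@dataclass(frozen=True)
class HostAssignment:
    virus_id: str
    host_id: str
    host_genus: str
    host_phylum: str
    evidence: str  # "prophage" | "crispr"
    score: float   # percent identity (prophage) or bit-score (crispr)


UNCLASSIFIED = "unclassified"


def assign_family(
    hits: list[ProteinHit],
    n_proteins: int,
    *,
    vote_fraction: float = 0.25,
    min_identity: float = 30.0,
    min_query_cover: float = 50.0,
    min_subject_cover: float = 50.0,
    min_bitscore: float = 50.0,
) -> str:
    """Family-level plurality vote over a virus's protein hits.

    Counts proteins, not hits: only the best (bit-score) retained hit per
    protein votes.  The winning family must cover strictly more than
    ``vote_fraction`` of all ``n_proteins``; a tied plurality returns
    :data:`UNCLASSIFIED` because the vote presumes a unique family.
    """
    if n_proteins < 1:
        raise ValueError("n_proteins must be >= 1")
    if len({h.virus_id for h in hits}) > 1:
        raise ValueError("hits must belong to a single virus")
    kept = [
        h
        for h in hits
        if h.query_coverage >= min_query_cover
        and h.subject_coverage >= min_subject_cover
        and h.percent_identity >= min_identity
        and h.bit_score >= min_bitscore
    ]
    best_per_protein: dict[str, ProteinHit] = {}
    # deterministic best-hit choice: bit-score desc, then family asc
    for h in sorted(kept, key=lambda h: (-h.bit_score, h.family_label)):
        best_per_protein.setdefault(h.protein_id, h)
    votes = Counter(h.family_label for h in best_per_protein.values())
    if not votes:
        return UNCLASSIFIED
    top = votes.most_common()
    if len(top) > 1 and top[0][1] == top[1][1]:
        return UNCLASSIFIED
    family, count = top[0]
    return family if count / n_proteins > vote_fraction else UNCLASSIFIED


# ---------------------------------------------------------------------------
# CRISPR-array detection
# ---------------------------------------------------------------------------

def _agree(g: str, positions: list[int], offset: int, max_mismatches: int) -> bool:
    """Do all repeat copies agree at ``offset`` (within the mismatch budget)?

    With ``max_mismatches=0`` this is exact agreement of consecutive copies.
    """
    chars = []
    for p in positions:
        idx = p + offset
        if idx < 0 or idx >= len(g):
            return False
        chars.append(g[idx])
    if max_mismatches == 0:
        return all(c == chars[0] for c in chars)
    return sum(1 for c in chars if c != chars[0]) <= max_mismatches


def detect_crispr_arrays(
    genome: str,
    *,
    min_repeats: int = 2,
    repeat_length: tuple[int, int] = (23, 47),
    spacer_length: tuple[int, int] = (26, 50),
    max_mismatches: int = 0,
    genome_id: str = "genome",
) -> list[CrisprArray]:
    """Find tandem repeat-spacer-repeat arrays with exact repeat copies.

    The scan anchors on the minimal repeat length (23-mers), chains
    occurrences at spacings compatible with the repeat/spacer length
    model, then extends the repeat boundary rightwards while *all* copies
    agree, subject to every spacer staying within 26-50 nt.  Arrays with
    at least ``min_repeats`` repeat copies are reported left to right and
    their footprints consumed, so nested sub-arrays are not re-reported.
    ``max_mismatches`` (0 or 1) relaxes the copy-agreement test for
    degenerate repeats.
    """
    g = genome.upper()
    length = len(g)
    if length < 100:
        raise ValueError("genome shorter than 100 bp")
    if min_repeats < 2:
        raise ValueError("min_repeats must be >= 2")
    rmin, rmax = repeat_length
    smin, smax = spacer_length

    anchor_positions: dict[str, list[int]] = {}
    for i in range(length - rmin + 1):
        anchor_positions.setdefault(g[i : i + rmin], []).append(i)

    arrays: list[CrisprArray] = []
    consumed_until = -1
    i = 0
    while i <= length - rmin:
        if i <= consumed_until:
            i += 1
            continue
        anchor = g[i : i + rmin]
        occ = anchor_positions[anchor]
        # greedy chain of anchor occurrences at valid spacings; with a
        # mismatch budget, degenerate copies are found by window scan
        starts = [i]
        while True:
            lo = starts[-1] + rmin + smin
            hi = starts[-1] + rmax + smax
            nxt = None
            for j in occ:
                if lo <= j <= hi:
                    nxt = j
                    break
            if nxt is None and max_mismatches > 0:
                for t in range(lo, min(hi, length - rmin) + 1):
                    diffs = sum(
                        1 for x, y in zip(anchor, g[t : t + rmin]) if x != y
                    )
                    if diffs <= max_mismatches:
                        nxt = t
                        break
            if nxt is None:
                break
            starts.append(nxt)
        if len(starts) < max(2, min_repeats):
            i += 1
            continue
        gaps = [b - a for a, b in zip(starts, starts[1:])]
        rl_low = max(rmin, max(gaps) - smax)
        rl_high = min(rmax, min(gaps) - smin, length - starts[-1])
        if rl_low > rl_high:
            i += 1
            continue
        # extend the repeat rightwards while all copies agree
        rl = rmin
        while rl < rl_high and _agree(g, starts, rl, max_mismatches):
            rl += 1
        if rl < rl_low:
            i += 1
            continue
        repeat = g[i : i + rl]
        spacers = tuple(
            g[starts[k] + rl : starts[k + 1]] for k in range(len(starts) - 1)
        )
        arrays.append(
            CrisprArray(
                genome_id=genome_id,
                repeat_sequence=repeat,
                spacers=spacers,
                positions=tuple((s, s + rl) for s in starts),
            )
        )
        consumed_until = starts[-1] + rl - 1
        i = starts[-1] + rl
    return arrays


# ---------------------------------------------------------------------------
# host assignment
# ---------------------------------------------------------------------------

def match_spacers(
    arrays: list[CrisprArray],
    virus_id: str,
    virus_sequence: str,
    host_taxonomy: pd.DataFrame,
    *,
    bit_threshold: float = 45.0,
    word_size: int = 8,
) -> list[HostAssignment]:
    """CRISPR-spacer host assignment at bit-score >= ``bit_threshold``.

    Each spacer is aligned to the virus with blastn-short scoring; raw
    scores convert to bits via (lambda*S - ln K)/ln 2.  Duplicate
    (virus, host) pairs collapse to the maximal score.
    """
    best: dict[str, float] = {}
    for arr in arrays:
        for spacer in arr.spacers:
            raw = best_local_score(
                spacer, virus_sequence, word_size=word_size, match=2, mismatch=-3
            )
            if raw <= 0:
                continue
            bits = bitscore(raw)
            if bits >= bit_threshold:
                prev = best.get(arr.genome_id)
                if prev is None or bits > prev:
                    best[arr.genome_id] = bits
    out = []
    for host_id in sorted(best):
        if host_id not in host_taxonomy.index:
            raise ValueError(f"unknown host id {host_id!r} in taxonomy table")
        row = host_taxonomy.loc[host_id]
        out.append(
            HostAssignment(
                virus_id=virus_id,
                host_id=host_id,
                host_genus=str(row["genus"]),
                host_phylum=str(row["phylum"]),
                evidence="crispr",
                score=float(best[host_id]),
            )
        )
    return out


def predict_host_prophage(
    virus_id: str,
    virus_sequence: str,
    hosts: list,
    host_taxonomy: pd.DataFrame,
    *,
    id_threshold: float = 90.0,
    cov_threshold: float = 0.30,
    word_size: int = 20,
) -> list[HostAssignment]:
    """Prophage host assignment: >= 90% identity over >= 30% of the virus.

    ``hosts`` is a list of objects with ``id`` and ``sequence`` attributes
    (e.g. :class:`viromescope.synthetic.HostGenome`).  Coverage is always
    measured on the viral sequence, per the assignment rule.
    """
    out = []
    for host in hosts:
        summary = local_align(
            virus_sequence,
            host.sequence,
            word_size=word_size,
            query_id=virus_id,
            subject_id=host.id,
        )
        if (
            summary.aligned
            and summary.merged_identity >= id_threshold
            and summary.aligned_fraction_query >= cov_threshold
        ):
            row = host_taxonomy.loc[host.id]
            out.append(
                HostAssignment(
                    virus_id=virus_id,
                    host_id=host.id,
                    host_genus=str(row["genus"]),
                    host_phylum=str(row["phylum"]),
                    evidence="prophage",
                    score=float(summary.merged_identity),
                )
            )
    return out


def host_census(
    assignments: list[HostAssignment],
    host_taxonomy: pd.DataFrame,
    *,
    multi_label: str = "multi-host",
) -> dict[str, int]:
    """Per-phylum vOTU counts with a separate multi-host category.

    Each virus is counted exactly once: under its host's phylum when all
    its assignments agree on one host genus, otherwise under
    ``multi_label``.
    """
    for a in assignments:
        if a.host_id not in host_taxonomy.index:
            raise ValueError(f"unknown host id {a.host_id!r}")
    by_virus: dict[str, list[HostAssignment]] = {}
    for a in assignments:
        by_virus.setdefault(a.virus_id, []).append(a)
    census: dict[str, int] = {}
    for virus in sorted(by_virus):
        genera = {a.host_genus for a in by_virus[virus]}
        if len(genera) > 1:
            key = multi_label
        else:
            key = by_virus[virus][0].host_phylum
        census[key] = census.get(key, 0) + 1
    return census
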