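"""Viral-contig triage: bulk-mode and VLP-mode decision rules plus the
BUSCO contamination filter.

Contigs (length >= 2 kbp) arrive with per-contig evidence summarising the
upstream detectors: CheckV-style viral/microbial gene counts and quality
tier, a DeepVirFinder-style score and p-value, a VIBRANT verdict, and a
BUSCO tally (bacterial universal single-copy orthologs found among the
contig's genes).  The two sequencing modes use different rules:

* **bulk** (total fecal DNA): a contig is viral iff it passes *all* gates —
  the gene-count screen (removed only when viral genes are strictly fewer
  than microbial genes), then (DVF p < 0.01 AND score > 0.90) OR VIBRANT,
  then a CheckV quality tier in {complete, high, medium} (low and
  not-determined contigs are removed to avoid contamination).
* **vlp** (virus-like-particle enriched): the rule is disjunctive — viral
  gene count strictly greater than microbial, OR the DVF thresholds, OR
  VIBRANT; no quality-tier removal.

The bulk rule is therefore strictly stricter than the VLP rule.  After
triage, retained viral contigs with a BUSCO ratio (BUSCO hits / total
genes) >= 5% are removed as probable bacterial contamination; the boundary
is inclusive.
"""

from __future__ import annotations

from dataclasses import dataclass, field

QUALITY_TIERS = ("complete", "high", "medium", "low", "not-determined")
_GOOD_TIERS = frozenset({"complete", "high", "medium"})

EVIDENCE_COLUMNS = (
    "contig_id",
    "viral_genes",
    "microbial_genes",
    "dvf_score",
    "dvf_pvalue",
    "vibrant",
    "checkv_quality",
    "busco_hits",
    "total_genes",
)


@dataclass(frozen=True)
class ContigRecord:
    id: str
    sample_id: str
    mode: str  # "bulk" | "vlp"
    length: int
    sequence: str | None = None

    def __post_init__(self) -> None:
        if self.mode not in ("bulk", "vlp"):
            raise ValueError(f"contig {self.id}: unknown mode {self.mode!r}")
        if self.length < 2000:
            raise ValueError(
                f"contig {self.id}: length {self.length} < 2000 bp triage floor"
            )


@dataclass(frozen=True)
class ViralEvidence:
    contig_id: str
    viral_gene_count: int
    microbial_gene_count: int
    dvf_score: float
    dvf_pvalue: float
    vibrant_viral: bool
    checkv_quality: str
    busco_hits: int
    total_genes: int

    def __post_init__(self) -> None:
        if self.checkv_quality not in QUALITY_TIERS:
            raise ValueError(
                f"{self.contig_id}: unknown CheckV tier {self.checkv_quality!r}"
            )
        if min(
            self.viral_gene_count,
            self.microbial_gene_count,
            self.busco_hits,
            self.total_genes,
        ) < 0:
            raise ValueError(f"{self.contig_id}: negative count in evidence")
        if self.busco_hits > self.total_genes:
            raise ValueError(
                f"{self.contig_id}: busco_hits {self.busco_hits} exceeds "
                f"total_genes {self.total_genes}"
            )


@dataclass(frozen=True)
class TriageDecision:
    contig_id: str
    verdict: str  # "viral" | "nonviral"
    reasons: tuple[str, ...]


def _check_pair(contig: ContigRecord, ev: ViralEvidence, mode: str) -> None:
    if contig.mode != mode:
        raise ValueError(
            f"contig {contig.id} has mode {contig.mode!r}; expected {mode!r}"
        )
    if ev.contig_id != contig.id:
        raise ValueError(
            f"evidence for {ev.contig_id!r} does not match contig {contig.id!r}"
        )


def triage_bulk(
    contig: ContigRecord,
    ev: ViralEvidence,
    *,
    dvf_p: float = 0.01,
    dvf_score: float = 0.90,
) -> TriageDecision:
    """Conjunctive bulk-metagenome rule; see module docstring.

    ``reasons`` lists the satisfied gates for a viral verdict, or the first
    failed gate for a nonviral one.
    """
    _check_pair(contig, ev, "bulk")
    if ev.viral_gene_count < ev.microbial_gene_count:
        return TriageDecision(contig.id, "nonviral", ("checkv_gene_screen",))
    reasons = ["checkv_gene_screen"]
    dvf_ok = ev.dvf_pvalue < dvf_p and ev.dvf_score > dvf_score
    if dvf_ok:
        reasons.append("dvf")
    if ev.vibrant_viral:
        reasons.append("vibrant")
    if not (dvf_ok or ev.vibrant_viral):
        return TriageDecision(contig.id, "nonviral", ("dvf",))
    if ev.checkv_quality not in _GOOD_TIERS:
        return TriageDecision(contig.id, "nonviral", ("checkv_quality",))
    reasons.append("checkv_quality")
    return TriageDecision(contig.id, "viral", tuple(reasons))


def triage_vlp(
    contig: ContigRecord,
    ev: ViralEvidence,
    *,
    dvf_p: float = 0.01,
    dvf_score: float = 0.90,
) -> TriageDecision:
    """Disjunctive VLP-metagenome rule; no quality-tier removal."""
    _check_pair(contig, ev, "vlp")
    reasons = []
    if ev.viral_gene_count > ev.microbial_gene_count:
        reasons.append("checkv_gene_screen")
    if ev.dvf_pvalue < dvf_p and ev.dvf_score > dvf_score:
        reasons.append("dvf")
    if ev.vibrant_viral:
        reasons.append("vibrant")
    if reasons:
        return TriageDecision(contig.id, "viral", tuple(reasons))
    return TriageDecision(contig.id, "nonviral", ("checkv_gene_screen",))


def triage(contig: ContigRecord, ev: ViralEvidence, **kwargs) -> TriageDecision:
    """Dispatch to the mode-appropriate rule."""
    if contig.mode == "bulk":
        return triage_bulk(contig, ev, **kwargs)
    return triage_vlp(contig, ev, **kwargs)


def busco_filter(ev: ViralEvidence, *, busco_ratio: float = 0.05) -> str:
    """Return ``"keep"`` or ``"remove"``; removal when hits/genes >= ratio.

    The boundary is inclusive: 1 BUSCO among 20 genes (exactly 5%) is
    removed, 1 among 21 (4.76%) is kept.
    """
    if ev.total_genes < 1:
        raise ValueError(
            f"{ev.contig_id}: BUSCO ratio undefined for total_genes=0"
        )
    return "remove" if ev.busco_hits / ev.total_genes >= busco_ratio else "keep"


def quality_census(
    decisions: list[TriageDecision],
    evidence: dict[str, ViralEvidence],
) -> dict:
    """Per-CheckV-tier counts and fractions over retained viral contigs.

    Returns ``{"total": n, "counts": {tier: n}, "fractions": {tier: f}}``;
    an empty retained set yields total 0 and empty maps.
    """
    if not decisions:
        raise ValueError("quality_census requires at least one decision")
    retained = [d.contig_id for d in decisions if d.verdict == "viral"]
    counts: dict[str, int] = {}
    for cid in retained:
        tier = evidence[cid].checkv_quality
        counts[tier] = counts.get(tier, 0) + 1
    total = len(retained)
    fractions = {t: c / total for t, c in counts.items()} if total else {}
    return {"total": total, "counts": counts, "fractions": fractions}


def triage_pool(
    contigs: list[ContigRecord],
    evidence: dict[str, ViralEvidence],
    *,
    dvf_p: float = 0.01,
    dvf_score: float = 0.90,
    busco_ratio: float = 0.05,
) -> tuple[list[TriageDecision], list[str]]:
    """Triage a pool of contigs, then apply the BUSCO filter to survivors.

    Returns (decisions, retained contig ids).  Decisions for contigs removed
    by the BUSCO filter carry verdict ``nonviral`` with reason ``busco``
    appended; a missing evidence row raises rather than imputing.
    """
    decisions: list[TriageDecision] = []
    retained: list[str] = []
    for contig in contigs:
        if contig.id not in evidence:
            raise ValueError(f"no evidence row for contig {contig.id}")
        dec = triage(contig, evidence[contig.id], dvf_p=dvf_p, dvf_score=dvf_score)
        if dec.verdict == "viral":
            if busco_filter(evidence[contig.id], busco_ratio=busco_ratio) == "remove":
                dec = TriageDecision(contig.id, "nonviral", dec.reasons + ("busco",))
            else:
                retained.append(contig.id)
        decisions.append(dec)
    return decisions, retained
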