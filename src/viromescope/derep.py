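"""vOTU dereplication: greedy clustering at 95% identity / 75% coverage.

Viral sequences are sorted by (length descending, id ascending) and each
joins the first existing cluster whose *representative* it matches at
``identity_threshold`` percent merged nucleotide identity over
``coverage_threshold`` aligned fraction; otherwise it founds a new
cluster.  The representative is the founding (longest) member, with
length ties broken by lexicographically smallest id, so the procedure is
fully deterministic.

"75% of the sequence" is interpreted as the aligned fraction of the
*shorter* sequence by default (the common convention for viral
dereplication); the denominator is configurable (``shorter`` | ``query``
| ``subject``, query = the candidate member).
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .alignment import AlignmentSummary, local_align


@dataclass
class VOTU:
    votu_id: str
    representative_id: str
    member_ids: list[str]
    representative_length: int
    # per-member (identity, coverage) against the representative
    member_stats: dict[str, tuple[float, float]] = field(default_factory=dict)


def select_representative(lengths: dict[str, int]) -> str:
    """Longest member; ties broken by lexicographically smallest id."""
    if not lengths:
        raise ValueError("empty cluster")
    return min(lengths, key=lambda k: (-lengths[k], k))


def _coverage(summary: AlignmentSummary, denominator: str) -> float:
    if denominator == "shorter":
        return summary.aligned_fraction_shorter
    if denominator == "query":
        return summary.aligned_fraction_query
    if denominator == "subject":
        return summary.aligned_fraction_subject
    raise ValueError(
        f"unknown coverage denominator {denominator!r}; "
        "legal tokens: shorter, query, subject"
    )


def cluster_votus(
    sequences: dict[str, str],
    *,
    identity_threshold: float = 95.0,
    coverage_threshold: float = 0.75,
    coverage_denominator: str = "shorter",
    word_size: int = 20,
    align=local_align,
) -> list[VOTU]:
    """Greedy representative-based clustering of ``sequences`` into vOTUs.

    ``align`` is injectable so an oracle aligner can drive the identical
    clustering rule in tests.  Clusters are returned in founding order and
    named ``vOTU_0001`` onwards.
    """
    if not (0.0 <= identity_threshold <= 100.0):
        raise ValueError("identity_threshold outside [0, 100]")
    if not (0.0 <= coverage_threshold <= 1.0):
        raise ValueError("coverage_threshold outside [0, 1]")
    _coverage(AlignmentSummary("", "", 1, 1), coverage_denominator)  # validate token
    ids = list(sequences)
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate sequence ids")

    order = sorted(ids, key=lambda k: (-len(sequences[k]), k))
    clusters: list[VOTU] = []
    for sid in order:
        placed = False
        for cl in clusters:
            summary = align(
                sequences[sid],
                sequences[cl.representative_id],
                word_size=word_size,
                query_id=sid,
                subject_id=cl.representative_id,
            )
            if not summary.aligned:
                continue
            cov = _coverage(summary, coverage_denominator)
            if summary.merged_identity >= identity_threshold and cov >= coverage_threshold:
                cl.member_ids.append(sid)
                cl.member_stats[sid] = (summary.merged_identity, cov)
                placed = True
                break
        if not placed:
            clusters.append(
                VOTU(
                    votu_id=f"vOTU_{len(clusters) + 1:04d}",
                    representative_id=sid,
                    member_ids=[sid],
                    representative_length=len(sequences[sid]),
                    member_stats={sid: (100.0, 1.0)},
                )
            )
    return clusters


def membership_table(clusters: list[VOTU]) -> list[tuple[str, str, float, float]]:
    """Rows of (votu_id, member_id, identity, coverage) for TSV export."""
    rows = []
    for cl in clusters:
        for member in cl.member_ids:
            ident, cov = cl.member_stats[member]
            rows.append((cl.votu_id, member, ident, cov))
    return rows
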