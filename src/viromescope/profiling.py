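"""Relative-abundance profiles and taxon aggregation.

An :class:`AbundanceProfile` is a samples x features matrix of relative
abundances (rows closed to 1) with per-feature metadata (viral family, host
genus, bacterial genus/phylum).  Profiles are built from non-negative count
tables by per-sample normalisation; all-zero samples are preserved as
all-zero rows and flagged rather than dropped.  Aggregation to a higher
taxonomic level sums feature abundances within each taxon per sample, with
features lacking an assignment pooled into an ``unclassified`` bucket, and
commutes with normalisation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

UNCLASSIFIED = "unclassified"


@dataclass
class AbundanceProfile:
    """Samples x features relative abundances plus feature metadata.

    ``data``: DataFrame, index = sample ids, columns = feature ids.
    ``feature_meta``: DataFrame indexed by feature id; typical columns are
    ``family``, ``host_genus`` (virome) or ``genus``, ``phylum``
    (bacteriome).  ``zero_samples`` flags samples whose row was all-zero.
    """

    data: pd.DataFrame
    feature_meta: pd.DataFrame = field(default_factory=pd.DataFrame)
    zero_samples: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.data.index.has_duplicates:
            raise ValueError("duplicate sample ids in profile")
        if self.data.columns.has_duplicates:
            raise ValueError("duplicate feature ids in profile")
        values = self.data.to_numpy(dtype=float)
        if (values < 0).any():
            raise ValueError("negative abundance in profile")
        sums = values.sum(axis=1)
        nonzero = sums > 0
        if nonzero.any() and not np.allclose(sums[nonzero], 1.0, atol=1e-9):
            raise ValueError("profile rows must sum to 1 (or be all-zero)")

    @property
    def samples(self) -> list[str]:
        return list(self.data.index)

    @property
    def features(self) -> list[str]:
        return list(self.data.columns)

    def to_tsv(self, path: str | Path) -> None:
        self.data.to_csv(path, sep="\t", index_label="sample", float_format="%.10g")

    @classmethod
    def from_tsv(
        cls, path: str | Path, feature_meta: pd.DataFrame | None = None
    ) -> "AbundanceProfile":
        data = pd.read_csv(path, sep="\t", index_col="sample")
        data.index.name = None
        zero = tuple(data.index[data.sum(axis=1) == 0])
        return cls(
            data=data,
            feature_meta=feature_meta if feature_meta is not None else pd.DataFrame(),
            zero_samples=zero,
        )


def normalize_counts(
    counts: pd.DataFrame, feature_meta: pd.DataFrame | None = None
) -> AbundanceProfile:
    """Close each sample's counts to relative abundances.

    Rows are divided by their sum; all-zero rows are kept as zeros and the
    sample ids recorded in ``zero_samples``.  Negative entries raise.
    """
    values = counts.to_numpy(dtype=float)
    if (values < 0).any():
        raise ValueError("count table contains negative entries")
    sums = values.sum(axis=1)
    zero_rows = sums == 0
    safe = np.where(zero_rows, 1.0, sums)
    rel = values / safe[:, None]
    rel[zero_rows] = 0.0
    return AbundanceProfile(
        data=pd.DataFrame(rel, index=counts.index, columns=counts.columns),
        feature_meta=feature_meta if feature_meta is not None else pd.DataFrame(),
        zero_samples=tuple(counts.index[zero_rows]),
    )


def aggregate_taxa(profile: AbundanceProfile, level: str) -> AbundanceProfile:
    """Sum feature abundances within each taxon at ``level`` per sample.

    ``level`` must be a column of ``feature_meta`` (e.g. ``family``,
    ``genus``, ``phylum``, ``host_genus``); features with a missing or NA
    assignment are pooled into :data:`UNCLASSIFIED`.  Row sums are
    preserved exactly.
    """
    if level not in profile.feature_meta.columns:
        raise ValueError(
            f"feature_meta has no {level!r} column; "
            f"available: {list(profile.feature_meta.columns)}"
        )
    assignment = profile.feature_meta[level].reindex(profile.features)
    assignment = assignment.fillna(UNCLASSIFIED).replace("", UNCLASSIFIED)
    grouped = profile.data.T.groupby(assignment.to_numpy()).sum().T
    grouped = grouped[sorted(grouped.columns)]
    meta = pd.DataFrame(index=grouped.columns)
    return AbundanceProfile(
        data=grouped, feature_meta=meta, zero_samples=profile.zero_samples
    )


def mean_sem(profile: AbundanceProfile, *, dispersion: str = "sem") -> pd.DataFrame:
    """Per-feature mean relative abundance with SEM (default) or SD.

    Mirrors "mean +/- value" summaries of family compositions; the
    dispersion convention is configurable because published tables rarely
    say which was used.
    """
    if dispersion not in ("sem", "sd"):
        raise ValueError("dispersion must be 'sem' or 'sd'")
    mean = profile.data.mean(axis=0)
    sd = profile.data.std(axis=0, ddof=1)
    disp = sd / np.sqrt(len(profile.samples)) if dispersion == "sem" else sd
    return pd.DataFrame({"mean": mean, dispersion: disp})


def quantify_by_kmers(
    queries: dict[str, str],
    representatives: dict[str, str],
    *,
    k: int = 31,
) -> pd.Series:
    """Assign each query sequence to the representative sharing most k-mers.

    A deterministic, exact 31-mer containment counter for end-to-end demos
    (read-mapping quantification is out of scope).  Ties and zero-overlap
    queries are left unassigned (NaN); counts are returned per
    representative.
    """
    rep_kmers = {
        rid: frozenset(seq[i : i + k] for i in range(len(seq) - k + 1))
        for rid, seq in representatives.items()
    }
    counts = {rid: 0 for rid in representatives}
    for _, seq in sorted(queries.items()):
        qk = set(seq[i : i + k] for i in range(len(seq) - k + 1))
        best_rid, best_n, tie = None, 0, False
        for rid in sorted(rep_kmers):
            n = len(qk & rep_kmers[rid])
            if n > best_n:
                best_rid, best_n, tie = rid, n, False
            elif n == best_n and n > 0:
                tie = True
        if best_rid is not None and not tie:
            counts[best_rid] += 1
    return pd.Series(counts).sort_index()
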