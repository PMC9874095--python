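"""Community statistics for case-control virome/bacteriome profiles.

Contents: alpha diversity (observed richness, Shannon in natural log),
rarefaction over samples, Bray-Curtis distances, PERMANOVA with label
permutations (supporting both a two-group factor and a single continuous
constraint, which is how per-feature effect sizes are computed),
distance-based redundancy analysis (dbRDA), Wilcoxon rank-sum
differential abundance with Benjamini-Hochberg FDR and fold-change
classes, and the Spearman virus-bacterium correlation network.

Conventions: permutation p-values use the +1/+1 (never-zero) convention;
the BH family is all features tested at a given taxonomic level, or all
vOTU x genus pairs for the network; Wilcoxon uses exact enumeration when
both groups have fewer than 8 samples and no ties, otherwise the normal
approximation with tie correction; the fold-change pseudocount defaults
to half the smallest nonzero relative abundance in the table.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from .profiling import AbundanceProfile


# ---------------------------------------------------------------------------
# result types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PermanovaResult:
    pseudo_F: float
    R2: float
    p_value: float
    n_permutations: int


@dataclass
class DbrdaResult:
    site_scores: pd.DataFrame  # columns: CAP1 (constrained), MDS1 (residual)
    constrained_fraction: float
    n_positive_eigenvalues: int


# ---------------------------------------------------------------------------
# helpers
# ---------------------------------------------------------------------------

def _frame(profile) -> pd.DataFrame:
    return profile.data if isinstance(profile, AbundanceProfile) else profile


def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (q-values)."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p
    return multipletests(p, method="fdr_bh")[1]


def significance_stars(q: float) -> str:
    """Star tiers for adjusted p: * <0.05, ** <0.01, *** <0.001 (strict)."""
    if q < 0.001:
        return "***"
    if q < 0.01:
        return "**"
    if q < 0.05:
        return "*"
    return ""


# ---------------------------------------------------------------------------
# alpha diversity and rarefaction
# ---------------------------------------------------------------------------

def alpha_diversity(profile) -> pd.DataFrame:
    """Observed feature count and Shannon index (nats) per sample.

    Shannon H = -sum p_i ln p_i over nonzero p_i.  All-zero samples get
    observed 0, H = 0 and are flagged.
    """
    data = _frame(profile)
    values = data.to_numpy(dtype=float)
    observed = (values > 0).sum(axis=1)
    shannon = np.zeros(len(data))
    for i, row in enumerate(values):
        p = row[row > 0]
        if p.size:
            shannon[i] = float(-(p * np.log(p)).sum())
    return pd.DataFrame(
        {
            "observed_features": observed,
            "shannon": shannon,
            "flagged": observed == 0,
        },
        index=data.index,
    )


def rarefaction_over_samples(
    presence: pd.DataFrame,
    labels,
    *,
    n_reps: int = 10,
    seed: int = 0,
) -> pd.DataFrame:
    """Cumulative feature richness versus number of samples, per group.

    For each group and each subset size s = 1..group size, ``n_reps``
    random subsets of s samples are drawn without replacement; the
    statistic is the number of features present in at least one selected
    sample.  Median, Q1 and Q3 over replicates are reported.
    """
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    rng = np.random.default_rng(seed)
    labels = pd.Series(list(labels), index=presence.index)
    mat = presence.to_numpy() > 0
    rows = []
    for group in sorted(labels.unique()):
        idx = np.flatnonzero((labels == group).to_numpy())
        if len(idx) < 1:
            continue
        for s in range(1, len(idx) + 1):
            richness = np.empty(n_reps)
            for r in range(n_reps):
                chosen = rng.choice(idx, size=s, replace=False)
                richness[r] = mat[chosen].any(axis=0).sum()
            q1, med, q3 = np.percentile(richness, [25, 50, 75])
            rows.append((group, s, med, q1, q3))
    return pd.DataFrame(
        rows, columns=["group", "sample_size", "median", "q1", "q3"]
    )


# ---------------------------------------------------------------------------
# Bray-Curtis and PERMANOVA
# ---------------------------------------------------------------------------

def bray_curtis(profile) -> pd.DataFrame:
    """Symmetric Bray-Curtis distance matrix, d = sum|x-y| / sum(x+y)."""
    data = _frame(profile)
    values = data.to_numpy(dtype=float)
    zero_rows = values.sum(axis=1) == 0
    if zero_rows.sum() >= 2:
        raise ValueError(
            "Bray-Curtis undefined between all-zero samples: "
            f"{list(data.index[zero_rows])}"
        )
    from scipy.spatial.distance import pdist, squareform

    d = squareform(pdist(values, metric="braycurtis"))
    if np.isnan(d).any():
        raise ValueError("Bray-Curtis produced undefined distances")
    return pd.DataFrame(d, index=data.index, columns=data.index)


def _gower_center(d2: np.ndarray) -> np.ndarray:
    n = d2.shape[0]
    J = np.eye(n) - np.ones((n, n)) / n
    return -0.5 * J @ d2 @ J


def _design_matrix(constraint, index) -> np.ndarray:
    """Centered design matrix from a factor or a continuous vector."""
    c = pd.Series(list(constraint), index=index)
    if c.dtype.kind in "ifu":
        X = c.to_numpy(dtype=float)[:, None]
    else:
        levels = sorted(c.unique())
        if len(levels) < 2:
            raise ValueError("constraint has a single level")
        X = np.column_stack(
            [(c == lv).to_numpy(dtype=float) for lv in levels[1:]]
        )
    return X - X.mean(axis=0)


def permanova_stat(dist: pd.DataFrame, constraint) -> tuple[float, float]:
    """Observed pseudo-F and R2 of a PERMANOVA partition (no permutations).

    Uses the hat-matrix trace form of the distance-based linear model:
    SS_model = tr(H G H) with G the Gower-centered matrix of squared
    distances, which reduces to the classic two-group pseudo-F and also
    accepts a continuous constraint.  Exposed separately so exhaustive
    permutation oracles can reuse the identical statistic.
    """
    d = np.asarray(dist, dtype=float)
    G = _gower_center(d**2)
    X = _design_matrix(constraint, dist.index if hasattr(dist, "index") else None)
    n = d.shape[0]
    df1 = np.linalg.matrix_rank(X)
    df2 = n - df1 - 1
    if df2 < 1:
        raise ValueError("not enough residual degrees of freedom")
    H = X @ np.linalg.pinv(X.T @ X) @ X.T
    ss_total = float(np.trace(G))
    ss_model = float(np.sum(H * G))  # tr(HG), H symmetric idempotent
    ss_res = ss_total - ss_model
    F = (ss_model / df1) / (ss_res / df2)
    return F, ss_model / ss_total


def permanova(
    dist: pd.DataFrame,
    constraint,
    *,
    n_permutations: int = 1000,
    seed: int = 0,
) -> PermanovaResult:
    """Permutational multivariate ANOVA of a distance matrix.

    ``constraint`` is either a two-group (or multi-level) label vector or
    a continuous per-sample variable.  The p-value permutes sample
    identities and uses (1 + #{F_perm >= F_obs}) / (n_permutations + 1).
    Every group must contain at least 2 samples for a factor constraint.
    """
    d = np.asarray(dist, dtype=float)
    n = d.shape[0]
    index = dist.index if hasattr(dist, "index") else range(n)
    c = pd.Series(list(constraint), index=index)
    if c.dtype.kind not in "ifu":
        counts = c.value_counts()
        if (counts < 2).any():
            raise ValueError(f"singleton group in constraint: {counts.to_dict()}")
    G = _gower_center(d**2)
    X = _design_matrix(c, index)
    df1 = np.linalg.matrix_rank(X)
    df2 = n - df1 - 1
    if df2 < 1:
        raise ValueError("not enough residual degrees of freedom")
    H = X @ np.linalg.pinv(X.T @ X) @ X.T
    ss_total = float(np.trace(G))
    ss_model = float(np.sum(H * G))
    F = (ss_model / df1) / ((ss_total - ss_model) / df2)

    rng = np.random.default_rng(seed)
    perms = np.array([rng.permutation(n) for _ in range(n_permutations)])
    Gp = G[perms[:, :, None], perms[:, None, :]]  # (P, n, n)
    ss_model_p = np.einsum("ij,pij->p", H, Gp)
    # F is monotone in SS_model because SS_total is permutation-invariant
    exceed = int((ss_model_p >= ss_model - 1e-12).sum())
    p = (1 + exceed) / (n_permutations + 1)
    return PermanovaResult(
        pseudo_F=F,
        R2=ss_model / ss_total,
        p_value=p,
        n_permutations=n_permutations,
    )


# ---------------------------------------------------------------------------
# dbRDA
# ---------------------------------------------------------------------------

def dbrda(dist: pd.DataFrame, constraint) -> DbrdaResult:
    """Distance-based redundancy analysis constrained on a grouping.

    Principal coordinates of the distance matrix are computed first
    (negative eigenvalues are discarded with a warning; no Lingoes/Cailliez
    correction), then the coordinates are regressed on the centered
    constraint indicator.  Returns the first constrained axis (CAP1), the
    first residual axis (MDS1), and the constrained variance fraction.
    """
    d = np.asarray(dist, dtype=float)
    index = dist.index if hasattr(dist, "index") else pd.RangeIndex(d.shape[0])
    G = _gower_center(d**2)
    eigval, eigvec = np.linalg.eigh(G)
    order = np.argsort(eigval)[::-1]
    eigval, eigvec = eigval[order], eigvec[:, order]
    tol = 1e-8 * max(abs(eigval[0]), 1.0)
    positive = eigval > tol
    if positive.sum() < 2:
        raise ValueError("fewer than 2 positive eigenvalues; embedding degenerate")
    if (eigval < -tol).any():
        warnings.warn(
            f"discarding {int((eigval < -tol).sum())} negative eigenvalues "
            "in the principal-coordinate embedding",
            stacklevel=2,
        )
    Y = eigvec[:, positive] * np.sqrt(eigval[positive])

    X = _design_matrix(constraint, index)
    H = X @ np.linalg.pinv(X.T @ X) @ X.T
    fitted = H @ Y
    resid = Y - fitted
    u, s, _ = np.linalg.svd(fitted, full_matrices=False)
    cap1 = u[:, 0] * s[0]
    ur, sr, _ = np.linalg.svd(resid, full_matrices=False)
    mds1 = ur[:, 0] * sr[0]
    frac = float((fitted**2).sum() / (Y**2).sum())
    scores = pd.DataFrame({"CAP1": cap1, "MDS1": mds1}, index=index)
    return DbrdaResult(
        site_scores=scores,
        constrained_fraction=frac,
        n_positive_eigenvalues=int(positive.sum()),
    )


# ---------------------------------------------------------------------------
# differential abundance
# ---------------------------------------------------------------------------

def _wilcoxon_rank_sum(x: np.ndarray, y: np.ndarray) -> float:
    """Two-sided rank-sum p: exact below 8 per group (no ties), else
    normal approximation with tie correction."""
    pooled = np.concatenate([x, y])
    has_ties = len(np.unique(pooled)) < len(pooled)
    exact = min(len(x), len(y)) < 8 and not has_ties
    method = "exact" if exact else "asymptotic"
    return float(
        sps.mannwhitneyu(x, y, alternative="two-sided", method=method).pvalue
    )


def differential_abundance(
    profile,
    design,
    *,
    alpha: float = 0.05,
    fold_pseudo: float | None = None,
) -> pd.DataFrame:
    """Per-feature Wilcoxon rank-sum with BH FDR and log2 fold changes.

    ``design`` is a :class:`viromescope.synthetic.StudyDesign` (or any
    object with ``case_ids``/``control_ids``/``case_label``/
    ``control_label``).  Features constant across all samples get p = 1
    and a flag.  ``enriched_in`` is set for q < alpha by fold sign
    (positive = case-enriched).
    """
    data = _frame(profile)
    case = data.loc[design.case_ids].to_numpy(dtype=float)
    control = data.loc[design.control_ids].to_numpy(dtype=float)
    if case.shape[0] < 2 or control.shape[0] < 2:
        raise ValueError("each group needs at least 2 samples")
    if fold_pseudo is None:
        nonzero = data.to_numpy()[data.to_numpy() > 0]
        fold_pseudo = float(nonzero.min()) / 2.0 if nonzero.size else 1e-12

    rows = []
    for j, feature in enumerate(data.columns):
        x, y = case[:, j], control[:, j]
        constant = np.unique(np.concatenate([x, y])).size == 1
        p = 1.0 if constant else _wilcoxon_rank_sum(x, y)
        mc, mh = float(x.mean()), float(y.mean())
        fold = float(np.log2((mc + fold_pseudo) / (mh + fold_pseudo)))
        rows.append((feature, mc, mh, fold, p, constant))
    out = pd.DataFrame(
        rows,
        columns=["feature", "mean_case", "mean_control", "log2_fold", "p_value",
                 "flagged_constant"],
    ).set_index("feature")
    out["q_value"] = bh_adjust(out["p_value"].to_numpy())
    out["enriched_in"] = "none"
    sig = out["q_value"] < alpha
    out.loc[sig & (out["log2_fold"] > 0), "enriched_in"] = design.case_label
    out.loc[sig & (out["log2_fold"] <= 0), "enriched_in"] = design.control_label
    return out


def family_fold_panel(profile, design, *, alpha: float = 0.05) -> pd.DataFrame:
    """Family-level fold changes with significance stars from q tiers."""
    out = differential_abundance(profile, design, alpha=alpha)
    out["stars"] = [significance_stars(q) for q in out["q_value"]]
    return out


def volcano_classes(
    diff: pd.DataFrame, *, alpha: float = 0.05, fold_line: float = 2.0
) -> pd.Series:
    """Volcano classification: enriched direction when q < alpha AND
    |log2 fold| > fold_line, else 'ns' (mirrors the +/-2 dotted lines)."""
    cls = pd.Series("ns", index=diff.index)
    hit = (diff["q_value"] < alpha) & (diff["log2_fold"].abs() > fold_line)
    cls[hit & (diff["log2_fold"] > 0)] = "case"
    cls[hit & (diff["log2_fold"] < 0)] = "control"
    return cls


# ---------------------------------------------------------------------------
# effect sizes and correlation network
# ---------------------------------------------------------------------------

def feature_effect_sizes(
    source_profile,
    target_dist: pd.DataFrame,
    *,
    n_permutations: int = 1000,
    seed: int = 0,
) -> pd.DataFrame:
    """Variance of a target community explained by each source feature.

    Each source feature's abundance vector is used as a single continuous
    PERMANOVA constraint against the target distance matrix; R2 and the
    permutation p are reported with BH adjustment across features.
    Constant features are skipped with a flag.
    """
    data = _frame(source_profile).loc[target_dist.index]
    rows = []
    rng = np.random.default_rng(seed)
    for feature in data.columns:
        x = data[feature].to_numpy(dtype=float)
        if np.unique(x).size == 1:
            rows.append((feature, np.nan, np.nan, True))
            continue
        res = permanova(
            target_dist,
            x,
            n_permutations=n_permutations,
            seed=int(rng.integers(2**31)),
        )
        rows.append((feature, res.R2, res.p_value, False))
    out = pd.DataFrame(
        rows, columns=["feature", "R2", "p_value", "flagged_constant"]
    ).set_index("feature")
    tested = ~out["flagged_constant"]
    q = np.full(len(out), np.nan)
    q[tested.to_numpy()] = bh_adjust(out.loc[tested, "p_value"].to_numpy())
    out["q_value"] = q
    return out


def correlation_network(
    votu_profile,
    genus_profile,
    *,
    rho_threshold: float = 0.6,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Spearman vOTU x genus edges at |rho| > threshold and BH q < alpha.

    All pairs are tested (tie-corrected ranks, t-approximation p-values),
    BH runs across the full pair family, and surviving edges are returned
    sorted by (votu, genus) with their correlation sign.  The network is
    bipartite by construction.
    """
    v = _frame(votu_profile)
    b = _frame(genus_profile)
    if list(v.index) != list(b.index):
        raise ValueError("profiles must share an identical sample order")
    n = len(v.index)
    if n < 4:
        raise ValueError("need at least 4 shared samples for Spearman p-values")
    rv = np.apply_along_axis(sps.rankdata, 0, v.to_numpy(dtype=float))
    rb = np.apply_along_axis(sps.rankdata, 0, b.to_numpy(dtype=float))
    # constant columns (zero rank variance) get rho = 0 rather than NaN
    sv = rv.std(axis=0, ddof=0)
    sb = rb.std(axis=0, ddof=0)
    sv[sv == 0] = np.inf
    sb[sb == 0] = np.inf
    rv = (rv - rv.mean(axis=0)) / sv
    rb = (rb - rb.mean(axis=0)) / sb
    rho = rv.T @ rb / n  # (n_votus, n_genera)
    rho = np.clip(rho, -1.0, 1.0)
    with np.errstate(divide="ignore"):
        t = rho * np.sqrt((n - 2) / np.maximum(1.0 - rho**2, 1e-300))
    p = 2.0 * sps.t.sf(np.abs(t), df=n - 2)
    q = bh_adjust(p.ravel()).reshape(p.shape)

    rows = []
    for i, votu in enumerate(v.columns):
        for j, genus in enumerate(b.columns):
            if abs(rho[i, j]) > rho_threshold and q[i, j] < alpha:
                rows.append(
                    (votu, genus, float(rho[i, j]), float(p[i, j]),
                     float(q[i, j]), "+" if rho[i, j] > 0 else "-")
                )
    return pd.DataFrame(
        rows, columns=["votu", "genus", "rho", "p_value", "q_value", "sign"]
    ).sort_values(["votu", "genus"]).reset_index(drop=True)
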