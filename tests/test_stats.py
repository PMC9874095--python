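import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from viromescope import (
    StudyDesign,
    alpha_diversity,
    bh_adjust,
    bray_curtis,
    correlation_network,
    dbrda,
    differential_abundance,
    family_fold_panel,
    feature_effect_sizes,
    generate_abundance_study,
    permanova,
    permanova_stat,
    rarefaction_over_samples,
    significance_stars,
    volcano_classes,
)


def _profile(rows, samples=None, features=None):
    rows = np.asarray(rows, dtype=float)
    return pd.DataFrame(
        rows,
        index=samples or [f"s{i}" for i in range(rows.shape[0])],
        columns=features or [f"f{i}" for i in range(rows.shape[1])],
    )


# ---------------------------------------------------------------- diversity

class TestAlphaDiversity:
    def test_closed_forms(self):
        prof = _profile([[0.25] * 4, [1, 0, 0, 0], [0.5, 0.25, 0.25, 0]])
        div = alpha_diversity(prof)
        assert div["shannon"].iloc[0] == pytest.approx(np.log(4))
        assert div["shannon"].iloc[1] == 0.0
        assert div["shannon"].iloc[2] == pytest.approx(1.0397, abs=1e-4)
        assert list(div["observed_features"]) == [4, 1, 3]

    def test_all_zero_sample_flagged(self):
        div = alpha_diversity(_profile([[0, 0, 0]]))
        assert div["flagged"].iloc[0]
        assert div["shannon"].iloc[0] == 0.0

    def test_invariance_to_relabeling_and_zero_features(self, rng):
        p = rng.dirichlet(np.ones(6), size=3)
        base = alpha_diversity(_profile(p))["shannon"]
        shuffled = alpha_diversity(_profile(p[:, ::-1]))["shannon"]
        padded = alpha_diversity(_profile(np.hstack([p, np.zeros((3, 2))])))["shannon"]
        assert np.allclose(base, shuffled)
        assert np.allclose(base, padded)


class TestRarefaction:
    def test_full_group_size_equals_union_richness(self):
        presence = _profile([[1, 1, 0], [0, 1, 1], [1, 0, 0]])
        curve = rarefaction_over_samples(presence > 0, ["g", "g", "g"], n_reps=5)
        full = curve[curve["sample_size"] == 3].iloc[0]
        assert full["median"] == 3 and full["q1"] == 3 and full["q3"] == 3

    def test_identical_samples_give_a_flat_curve(self):
        presence = _profile([[1, 1, 0]] * 4)
        curve = rarefaction_over_samples(presence > 0, ["g"] * 4, n_reps=5)
        assert (curve["median"] == 2).all()
        assert (curve["q1"] == 2).all() and (curve["q3"] == 2).all()

    def test_nested_sets_match_exhaustive_enumeration(self):
        # nested supports: sample k has features 0..k
        presence = _profile(np.tril(np.ones((5, 5))))
        curve = rarefaction_over_samples(
            presence > 0, ["g"] * 5, n_reps=2000, seed=0
        )
        for s in range(1, 6):
            richness = [
                max(subset) + 1
                for subset in itertools.combinations(range(5), s)
            ]
            q1, med, q3 = np.percentile(richness, [25, 50, 75])
            row = curve[curve["sample_size"] == s].iloc[0]
            assert row["median"] == pytest.approx(med, abs=0.5)
            assert row["q1"] == pytest.approx(q1, abs=0.5)
            assert row["q3"] == pytest.approx(q3, abs=0.5)


# ------------------------------------------------------------- Bray-Curtis

class TestBrayCurtis:
    def test_worked_examples(self):
        prof = _profile([[0.6, 0.4, 0], [0.2, 0.4, 0.4], [0.6, 0.4, 0]])
        d = bray_curtis(prof)
        assert d.iloc[0, 1] == pytest.approx(0.4)
        assert d.iloc[0, 2] == pytest.approx(0.0)
        assert np.allclose(d, d.T)

    def test_disjoint_supports_are_at_distance_one(self):
        d = bray_curtis(_profile([[1, 0], [0, 1]]))
        assert d.iloc[0, 1] == pytest.approx(1.0)

    def test_two_all_zero_samples_are_an_error(self):
        with pytest.raises(ValueError, match="all-zero"):
            bray_curtis(_profile([[0, 0], [0, 0], [1, 0]]))


# --------------------------------------------------------------- PERMANOVA

def _toy_distance(rng, n=6):
    pts = rng.normal(size=(n, 2))
    d = np.sqrt(((pts[:, None] - pts[None, :]) ** 2).sum(-1))
    return pd.DataFrame(d, index=[f"s{i}" for i in range(n)],
                        columns=[f"s{i}" for i in range(n)])


def _classic_two_group_F(d, labels):
    """Independent oracle: Anderson's within-group sum-of-squares formula."""
    d = np.asarray(d, dtype=float)
    labels = np.asarray(labels)
    n = len(labels)
    ss_total = (d[np.triu_indices(n, 1)] ** 2).sum() / n
    ss_within = 0.0
    for g in np.unique(labels):
        idx = np.flatnonzero(labels == g)
        sub = d[np.ix_(idx, idx)]
        ss_within += (sub[np.triu_indices(len(idx), 1)] ** 2).sum() / len(idx)
    a = len(np.unique(labels))
    ss_between = ss_total - ss_within
    return (ss_between / (a - 1)) / (ss_within / (n - a))


class TestPermanova:
    def test_pseudo_F_matches_classic_formula(self, make_rng):
        for seed in range(5):
            d = _toy_distance(make_rng(seed), n=8)
            labels = ["A"] * 4 + ["B"] * 4
            F, R2 = permanova_stat(d, labels)
            assert F == pytest.approx(_classic_two_group_F(d, labels), rel=1e-10)
            assert 0 <= R2 <= 1

    def test_pseudo_F_matches_scikit_bio(self, make_rng):
        skbio = pytest.importorskip("skbio")
        d = _toy_distance(make_rng(3), n=10)
        labels = ["A"] * 5 + ["B"] * 5
        dm = skbio.DistanceMatrix(d.to_numpy(), ids=list(d.index))
        expected = skbio.stats.distance.permanova(dm, labels, permutations=0)
        F, _ = permanova_stat(d, labels)
        assert F == pytest.approx(float(expected["test statistic"]), rel=1e-8)

    def test_p_value_matches_exhaustive_permutation_oracle(self, make_rng):
        d = _toy_distance(make_rng(1), n=6)
        labels = np.array(["A", "A", "A", "B", "B", "B"])
        F_obs, _ = permanova_stat(d, labels)
        stats = []
        for combo in itertools.combinations(range(6), 3):
            perm = np.array(["B"] * 6)
            perm[list(combo)] = "A"
            stats.append(permanova_stat(d, perm)[0])
        p_exact = np.mean(np.array(stats) >= F_obs - 1e-12)
        res = permanova(d, labels, n_permutations=4000, seed=0)
        assert res.pseudo_F == pytest.approx(F_obs)
        assert res.p_value == pytest.approx(p_exact, abs=0.03)

    def test_no_signal_limit(self):
        # both groups occupy identical coordinates
        base = np.array([[0.0, 0], [1, 0], [0, 1], [1, 1]])
        pts = np.vstack([base, base])
        d = np.sqrt(((pts[:, None] - pts[None, :]) ** 2).sum(-1))
        d = pd.DataFrame(d)
        labels = ["A"] * 4 + ["B"] * 4
        res = permanova(d, labels, n_permutations=500, seed=1)
        assert res.R2 < 0.02
        assert res.p_value > 0.9

    def test_singleton_group_rejected(self, make_rng):
        d = _toy_distance(make_rng(0), n=5)
        with pytest.raises(ValueError, match="singleton"):
            permanova(d, ["A", "B", "B", "B", "B"])

    def test_p_never_below_phipson_smyth_floor(self, make_rng):
        d = _toy_distance(make_rng(5), n=8)
        res = permanova(d, ["A"] * 4 + ["B"] * 4, n_permutations=99, seed=0)
        assert res.p_value >= 1 / 100


class TestDbrda:
    def test_separated_clusters_load_on_the_constrained_axis(self, make_rng):
        r = make_rng(2)
        pts = np.vstack([r.normal(0, 0.3, (6, 3)), r.normal(4, 0.3, (6, 3))])
        d = pd.DataFrame(np.sqrt(((pts[:, None] - pts[None, :]) ** 2).sum(-1)))
        labels = ["A"] * 6 + ["B"] * 6
        res = dbrda(d, labels)
        assert res.constrained_fraction > 0.5
        cap1 = res.site_scores["CAP1"].to_numpy()
        assert max(cap1[:6]) < min(cap1[6:]) or min(cap1[:6]) > max(cap1[6:])

    def test_constrained_fraction_equals_permanova_R2(self, make_rng):
        # for a euclidean-embeddable distance the identities coincide
        r = make_rng(4)
        pts = r.normal(size=(10, 4))
        d = pd.DataFrame(np.sqrt(((pts[:, None] - pts[None, :]) ** 2).sum(-1)))
        labels = list(r.permutation(["A"] * 5 + ["B"] * 5))
        _, R2 = permanova_stat(d, labels)
        assert dbrda(d, labels).constrained_fraction == pytest.approx(R2, abs=0.02)

    def test_duplicated_samples_duplicate_scores(self, make_rng):
        r = make_rng(6)
        pts = r.normal(size=(5, 2))
        pts = np.vstack([pts, pts])
        d = pd.DataFrame(np.sqrt(((pts[:, None] - pts[None, :]) ** 2).sum(-1)))
        labels = (["A", "A", "A", "B", "B"]) * 2
        scores = dbrda(d, labels).site_scores.to_numpy()
        assert np.allclose(scores[:5], scores[5:], atol=1e-8)


# ------------------------------------------------- differential abundance

def _rank_sum_enumeration_p(x, y):
    """Exact two-sided rank-sum p by enumerating all group assignments."""
    pooled = np.concatenate([x, y])
    n = len(pooled)
    obs = np.sum(np.argsort(np.argsort(pooled))[: len(x)] + 1)
    stats = []
    for combo in itertools.combinations(range(n), len(x)):
        ranks = np.argsort(np.argsort(pooled)) + 1
        stats.append(ranks[list(combo)].sum())
    stats = np.asarray(stats)
    mean = stats.mean()
    return np.mean(np.abs(stats - mean) >= abs(obs - mean) - 1e-12)


class TestDifferentialAbundance:
    def test_wilcoxon_matches_enumeration_oracle(self):
        design = StudyDesign(
            tuple(f"s{i}" for i in range(6)),
            ("SLE",) * 3 + ("Control",) * 3,
        )
        counts = pd.DataFrame(
            {"f": [1, 2, 3, 4, 5, 6], "g": [9, 8, 7, 6, 5, 4]},
            index=[f"s{i}" for i in range(6)], dtype=float,
        )
        prof = counts.div(counts.sum(axis=1), axis=0)
        out = differential_abundance(prof, design)
        expected = _rank_sum_enumeration_p(np.array([1, 2, 3]), np.array([4, 5, 6]))
        assert expected == pytest.approx(0.1)
        assert out.loc["f", "p_value"] == pytest.approx(0.1)

    def test_bh_step_up_arithmetic(self):
        assert bh_adjust([0.01, 0.02, 0.03, 0.04]) == pytest.approx([0.04] * 4)

    def test_constant_feature_flagged_with_p_one(self):
        design = StudyDesign(
            tuple(f"s{i}" for i in range(6)), ("SLE",) * 3 + ("Control",) * 3
        )
        prof = _profile(
            [[0.5, 0.5]] * 6, samples=[f"s{i}" for i in range(6)]
        )
        out = differential_abundance(prof, design)
        assert out["flagged_constant"].all()
        assert (out["p_value"] == 1.0).all()
        assert (out["enriched_in"] == "none").all()

    def test_enrichment_direction_follows_fold_sign(self):
        design = StudyDesign.balanced(8, 8)
        rng = np.random.default_rng(0)
        up = np.concatenate([rng.uniform(0.6, 0.9, 8), rng.uniform(0.1, 0.4, 8)])
        data = pd.DataFrame({"f": up, "g": 1 - up}, index=design.sample_ids)
        out = differential_abundance(data, design)
        assert out.loc["f", "enriched_in"] == "SLE"
        assert out.loc["g", "enriched_in"] == "Control"

    def test_null_study_controls_the_fdr(self):
        design = StudyDesign.balanced(8, 8)
        clean = 0
        for seed in range(10):
            v, _, _ = generate_abundance_study(
                design, n_votus=200, n_genera=5, n_differential=0,
                effect_log2=0.0, n_corr_pairs=0, seed=seed,
            )
            out = differential_abundance(v, design)
            clean += int((out["q_value"] < 0.05).sum() == 0)
        assert clean >= 9

    def test_stars_and_volcano_boundaries(self):
        assert significance_stars(0.04) == "*"
        assert significance_stars(0.009) == "**"
        assert significance_stars(0.0009) == "***"
        assert significance_stars(0.05) == ""
        diff = pd.DataFrame(
            {"q_value": [0.01, 0.01, 0.2, 0.01],
             "log2_fold": [3.0, -3.0, 5.0, 1.0]},
            index=list("abcd"),
        )
        assert list(volcano_classes(diff)) == ["case", "control", "ns", "ns"]

    def test_family_panel_power_on_planted_shift(self):
        # a 4-fold family-level shift at n=16/31 is detected (q < 0.05)
        from viromescope import aggregate_taxa, normalize_counts

        design = StudyDesign.balanced()
        case_mask = np.array([l == "SLE" for l in design.labels])
        families = [f"F{i % 6}" for i in range(24)]
        meta = pd.DataFrame({"family": families},
                            index=[f"f{i}" for i in range(24)])
        detected = 0
        for seed in range(10):
            rng = np.random.default_rng(seed)
            counts = np.exp(rng.normal(0, 1, (47, 24)))
            counts[np.ix_(case_mask, [i for i, f in enumerate(families)
                                      if f == "F0"])] *= 4.0
            prof = normalize_counts(
                pd.DataFrame(counts, index=design.sample_ids, columns=meta.index),
                meta,
            )
            panel = family_fold_panel(aggregate_taxa(prof, "family"), design)
            detected += int(panel.loc["F0", "q_value"] < 0.05)
        assert detected >= 9


@settings(max_examples=100, derandomize=True)
@given(st.lists(st.floats(1e-6, 1.0), min_size=1, max_size=30))
def test_bh_is_a_monotone_step_up_transform(pvals):
    p = np.asarray(pvals)
    q = bh_adjust(p)
    assert (q >= p - 1e-12).all()
    order = np.argsort(p, kind="stable")
    assert (np.diff(q[order]) >= -1e-12).all()
    assert (q <= 1.0 + 1e-12).all()


# --------------------------------------------- effect sizes and network

class TestEffectSizes:
    def test_self_explanation_limit(self, make_rng):
        r = make_rng(0)
        x = r.normal(size=12)
        d = pd.DataFrame(np.abs(x[:, None] - x[None, :]),
                         index=[f"s{i}" for i in range(12)],
                         columns=[f"s{i}" for i in range(12)])
        src = pd.DataFrame({"self": x}, index=d.index)
        out = feature_effect_sizes(src, d, n_permutations=200, seed=1)
        assert out.loc["self", "R2"] > 0.8
        assert out.loc["self", "p_value"] < 0.05

    def test_constant_feature_skipped(self, make_rng):
        d = _toy_distance(make_rng(2), n=6)
        src = pd.DataFrame({"const": np.ones(6)}, index=d.index)
        out = feature_effect_sizes(src, d, n_permutations=50)
        assert out.loc["const", "flagged_constant"]
        assert np.isnan(out.loc["const", "R2"])

    def test_continuous_constraint_matches_exhaustive_oracle(self, make_rng):
        d = _toy_distance(make_rng(9), n=6)
        x = np.array([0.1, 0.9, 0.3, 0.7, 0.2, 0.8])
        F_obs, _ = permanova_stat(d, x)
        stats = [
            permanova_stat(d, x[list(perm)])[0]
            for perm in itertools.permutations(range(6))
        ]
        p_exact = np.mean(np.array(stats) >= F_obs - 1e-12)
        res = permanova(d, x, n_permutations=4000, seed=3)
        assert res.p_value == pytest.approx(p_exact, abs=0.03)


class TestCorrelationNetwork:
    def test_perfect_monotone_pair_is_an_edge(self):
        n = 10
        x = np.arange(1, n + 1, dtype=float)
        v = pd.DataFrame({"v1": x / x.sum()}, index=[f"s{i}" for i in range(n)])
        b = pd.DataFrame({"g1": (x**2) / (x**2).sum()}, index=v.index)
        edges = correlation_network(v, b)
        assert len(edges) == 1
        assert edges.loc[0, "rho"] == pytest.approx(1.0)
        assert edges.loc[0, "sign"] == "+"
        assert edges.loc[0, "q_value"] < 0.05

    def test_requires_at_least_four_samples(self):
        v = pd.DataFrame({"v": [0.1, 0.2, 0.7]}, index=list("abc"))
        with pytest.raises(ValueError, match="4"):
            correlation_network(v, v)

    def test_sample_order_must_match(self):
        v = pd.DataFrame({"v": np.arange(5.0)}, index=list("abcde"))
        b = v.iloc[::-1]
        with pytest.raises(ValueError, match="sample order"):
            correlation_network(v, b)

    def test_edges_are_bipartite_and_thresholded(self):
        design = StudyDesign.balanced()
        v, b, truth = generate_abundance_study(
            design, n_differential=0, n_corr_pairs=4, seed=3
        )
        edges = correlation_network(v, b)
        votus = set(v.features)
        genera = set(b.features)
        for _, e in edges.iterrows():
            assert e["votu"] in votus and e["genus"] in genera
            assert abs(e["rho"]) > 0.6 and e["q_value"] < 0.05
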