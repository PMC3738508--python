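"""Group statistics: PCA, MANOVA/Mahalanobis, single linkage, ANOVA/Tukey, TUNEL."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from oirpipe.stats import (
    AnovaTukeyResult,
    GroupDesign,
    anova_tukey,
    distances_relative_to_control,
    manova_mahalanobis,
    oneway_f_statistic,
    pca_scores,
    single_linkage,
    tunel_summary,
)


def toy_design(ns, names=None):
    names = names or [f"g{i}" for i in range(len(ns))]
    sample_ids, groups = [], []
    for name, n in zip(names, ns):
        for i in range(n):
            sample_ids.append(f"{name}_{i}")
            groups.append(name)
    return GroupDesign.from_lists(sample_ids, groups)


class TestPCA:
    def test_line_data_explained_fully_by_pc1(self):
        t = np.linspace(-1, 1, 30)
        X = np.c_[t, 2 * t]
        scores, explained = pca_scores(X, 1, standardize=False)
        assert explained[0] == pytest.approx(1.0)
        assert scores.shape == (30, 1)

    def test_duplicated_samples_have_identical_scores(self):
        rng = np.random.default_rng(0)
        X = rng.random((10, 4))
        X[3] = X[7]
        scores, _ = pca_scores(X, 2)
        assert np.allclose(scores[3], scores[7])

    def test_isotropic_data_spreads_variance_evenly(self):
        """Identity covariance at n=10000, p=6: each PC explains ~1/6."""
        rng = np.random.default_rng(42)
        X = rng.standard_normal((10_000, 6))
        _, explained = pca_scores(X, 6)
        assert np.allclose(explained, 1 / 6, atol=0.01)

    def test_rank_deficient_reduces_m_with_warning(self):
        t = np.linspace(0, 1, 20)
        X = np.c_[t, t, t]
        with pytest.warns(UserWarning, match="rank"):
            scores, _ = pca_scores(X, 3)
        assert scores.shape[1] == 1

    def test_sign_convention_deterministic(self):
        rng = np.random.default_rng(5)
        X = rng.random((15, 3))
        s1, _ = pca_scores(X, 2)
        s2, _ = pca_scores(X.copy(), 2)
        assert np.array_equal(s1, s2)


def mahalanobis_brute_force(scores, design):
    """Independent oracle: pooled covariance + quadratic form, looped."""
    groups = design.group_names
    n, p = scores.shape
    W = np.zeros((p, p))
    for g in groups:
        xg = scores[design.indices(g)]
        for row in xg:
            d = (row - xg.mean(axis=0))[:, None]
            W += d @ d.T
    W /= n - len(groups)
    Winv = np.linalg.inv(W)
    D = np.zeros((len(groups), len(groups)))
    for i, g in enumerate(groups):
        for j, h in enumerate(groups):
            d = scores[design.indices(g)].mean(0) - scores[design.indices(h)].mean(0)
            D[i, j] = np.sqrt(d @ Winv @ d)
    return D


class TestMahalanobis:
    def test_identical_means_give_zero_distance(self):
        rng = np.random.default_rng(1)
        base = rng.random((6, 2))
        scores = np.vstack([base, base])
        design = toy_design([6, 6], ["a", "b"])
        cl = manova_mahalanobis(scores, design)
        assert cl.distance_matrix[0, 1] == pytest.approx(0.0, abs=1e-10)
        assert cl.wilks_lambda == pytest.approx(1.0)

    def test_1d_unit_variance_standardised_difference(self):
        """With pooled variance 1 and means 0 / 1.96, D = 1.96."""
        a = np.array([-1.5, -0.5, 0.5, 1.5])  # mean 0
        scale = 1.0 / a.std(ddof=1)
        a = a * scale
        b = a + 1.96
        scores = np.r_[a, b][:, None]
        design = toy_design([4, 4], ["a", "b"])
        cl = manova_mahalanobis(scores, design)
        assert cl.distance_matrix[0, 1] == pytest.approx(1.96, rel=1e-12)

    def test_matches_brute_force_oracle_three_groups(self):
        rng = np.random.default_rng(11)
        scores = rng.standard_normal((15, 2)) + np.repeat(
            [[0, 0], [1.0, -0.5], [0.3, 2.0]], 5, axis=0
        )
        design = toy_design([5, 5, 5])
        cl = manova_mahalanobis(scores, design)
        D = mahalanobis_brute_force(scores, design)
        assert np.allclose(cl.distance_matrix, D, atol=1e-8)

    def test_affine_invariance(self):
        """D is invariant under any invertible affine map of the scores."""
        rng = np.random.default_rng(21)
        scores = rng.standard_normal((18, 3)) + np.repeat(
            [[0, 0, 0], [1, 0, 1], [0, 2, 0]], 6, axis=0
        )
        design = toy_design([6, 6, 6])
        A = np.array([[2.0, 0.3, 0], [-0.5, 1.0, 0.2], [0.1, 0, 3.0]])
        b = np.array([5.0, -2.0, 0.7])
        cl0 = manova_mahalanobis(scores, design)
        cl1 = manova_mahalanobis(scores @ A.T + b, design)
        assert np.allclose(cl0.distance_matrix, cl1.distance_matrix, atol=1e-8)

    def test_wilks_lambda_significant_for_separated_groups(self):
        rng = np.random.default_rng(3)
        scores = rng.standard_normal((30, 2)) + np.repeat(
            [[0, 0], [3, 3], [-3, 3]], 10, axis=0
        )
        cl = manova_mahalanobis(scores, toy_design([10, 10, 10]))
        assert cl.wilks_lambda < 0.2
        assert cl.p_value < 1e-6

    def test_small_group_rejected(self):
        scores = np.random.default_rng(0).random((3, 2))
        design = GroupDesign.from_lists(["a0", "a1", "b0"], ["a", "a", "b"])
        with pytest.raises(ValueError):
            manova_mahalanobis(scores, design)


def single_linkage_brute_force(dist):
    """O(n³) reference: recompute the full min-pair scan each merge."""
    n = dist.shape[0]
    clusters = [frozenset([i]) for i in range(n)]
    heights = []
    while len(clusters) > 1:
        best = None
        for a in range(len(clusters)):
            for b in range(a + 1, len(clusters)):
                d = min(dist[i, j] for i in clusters[a] for j in clusters[b])
                if best is None or d < best[0]:
                    best = (d, a, b)
        d, a, b = best
        heights.append(d)
        merged = clusters[a] | clusters[b]
        clusters = [c for k, c in enumerate(clusters) if k not in (a, b)]
        clusters.append(merged)
    return heights


class TestSingleLinkage:
    def test_three_point_chain(self):
        dist = np.array([[0, 1, 3], [1, 0, 2], [3, 2, 0]], float)
        d = single_linkage(dist, ["A", "B", "C"])
        assert d.merges[0] == (("A",), ("B",), 1.0)
        assert d.merges[1][2] == 2.0
        assert d.heights == sorted(d.heights)

    def test_invalid_matrices_rejected(self):
        with pytest.raises(ValueError):
            single_linkage(np.array([[0, 1], [2, 0]], float), ["a", "b"])
        with pytest.raises(ValueError):
            single_linkage(np.array([[0, -1], [-1, 0]], float), ["a", "b"])

    def test_equal_distances_merge_at_common_height(self):
        dist = np.full((4, 4), 2.0)
        np.fill_diagonal(dist, 0.0)
        d = single_linkage(dist, list("abcd"))
        assert all(h == 2.0 for h in d.heights)

    def test_heights_match_brute_force_on_random_matrices(self):
        """Merge heights equal the O(n³) reference on 50 random 8-leaf sets."""
        rng = np.random.default_rng(17)
        for _ in range(50):
            sq = rng.random((8, 8))
            dist = (sq + sq.T) / 2
            np.fill_diagonal(dist, 0.0)
            d = single_linkage(dist, [f"l{i}" for i in range(8)])
            assert np.allclose(d.heights, single_linkage_brute_force(dist))

    def test_heights_match_scipy(self):
        from scipy.cluster.hierarchy import linkage
        from scipy.spatial.distance import squareform

        rng = np.random.default_rng(23)
        sq = rng.random((10, 10))
        dist = (sq + sq.T) / 2
        np.fill_diagonal(dist, 0.0)
        ours = single_linkage(dist, [f"l{i}" for i in range(10)]).heights
        theirs = linkage(squareform(dist), method="single")[:, 2]
        assert np.allclose(sorted(ours), sorted(theirs))

    def test_newick_roundtrip_parses(self):
        dist = np.array([[0, 1, 3], [1, 0, 2], [3, 2, 0]], float)
        nwk = single_linkage(dist, ["A", "B", "C"]).to_newick()
        assert nwk.endswith(";") and "A" in nwk and nwk.count("(") == 2


class TestAnovaTukey:
    def test_two_groups_reduce_to_pooled_t_test(self):
        rng = np.random.default_rng(2)
        a, b = rng.normal(0, 1, 8), rng.normal(1, 1, 8)
        design = toy_design([8, 8], ["a", "b"])
        res = anova_tukey(np.r_[a, b], design)
        t_p = sps.ttest_ind(a, b).pvalue
        assert res.p_value == pytest.approx(t_p, rel=1e-9)
        tukey_p = float(res.tukey["p-adj"].iloc[0])
        assert tukey_p == pytest.approx(t_p, abs=2e-3)

    def test_location_invariance(self):
        rng = np.random.default_rng(4)
        x = rng.normal(size=24)
        design = toy_design([8, 8, 8])
        f1 = anova_tukey(x, design).F
        f2 = anova_tukey(x + 123.4, design).F
        assert f1 == pytest.approx(f2, rel=1e-9)

    def test_degenerate_case_flagged(self):
        design = toy_design([3, 3], ["a", "b"])
        res = anova_tukey(np.full(6, 2.5), design)
        assert res.degenerate
        assert np.isnan(res.p_value)

    def test_small_groups_rejected(self):
        design = GroupDesign.from_lists(["a0", "a1", "b0"], ["a", "a", "b"])
        with pytest.raises(ValueError):
            anova_tukey([1.0, 2.0, 3.0], design)

    def test_vectorised_f_matches_scipy(self):
        rng = np.random.default_rng(9)
        data = rng.normal(size=(20, 4, 12))
        F, p = oneway_f_statistic(data)
        for r in range(20):
            Fr, pr = sps.f_oneway(*data[r])
            assert F[r] == pytest.approx(Fr, rel=1e-10)
            assert p[r] == pytest.approx(pr, rel=1e-8)

    def test_null_type_one_error_calibrated(self):
        """4 groups × n=12 under the null: rejection rate ≈ alpha."""
        rng = np.random.default_rng(2024)
        data = rng.normal(size=(10_000, 4, 12))
        _, p = oneway_f_statistic(data)
        rate = float((p < 0.05).mean())
        assert 0.044 <= rate <= 0.056

    def test_tukey_familywise_error_bounded_under_null(self):
        """Studentised-range FWER at alpha=0.05 over null replicates."""
        rng = np.random.default_rng(77)
        k, n, reps = 4, 12, 5_000
        data = rng.normal(size=(reps, k, n))
        gm = data.mean(axis=2)
        msw = data.var(axis=2, ddof=1).mean(axis=1)
        q = (gm.max(axis=1) - gm.min(axis=1)) / np.sqrt(msw / n)
        qcrit = sps.studentized_range.ppf(0.95, k, k * (n - 1))
        fwer = float((q > qcrit).mean())
        assert fwer <= 0.05 + 3 * np.sqrt(0.05 * 0.95 / reps)


class TestTunel:
    def make_table(self, counts_lengths):
        rows = []
        for i, (c, l) in enumerate(counts_lengths):
            rows.append({"section_id": f"s{i}", "layer": "ONL", "count": c,
                         "length_mm": l})
            rows.append({"section_id": f"s{i}", "layer": "INL", "count": 0,
                         "length_mm": l})
            rows.append({"section_id": f"s{i}", "layer": "GCL", "count": 0,
                         "length_mm": l})
        return pd.DataFrame(rows)

    def test_frequency_is_total_counts_over_total_length(self):
        tables = {
            "a0": self.make_table([(3, 1.0), (5, 2.0), (4, 1.0)]),
            "a1": self.make_table([(0, 1.0), (0, 1.0), (0, 1.0)]),
            "b0": self.make_table([(2, 1.0), (2, 1.0), (2, 1.0)]),
            "b1": self.make_table([(4, 2.0), (4, 2.0), (4, 2.0)]),
        }
        design = GroupDesign.from_lists(["a0", "a1", "b0", "b1"],
                                        ["a", "a", "b", "b"])
        ts = tunel_summary(tables, design)
        f = ts.per_animal.set_index(["sample_id", "layer"])["frequency"]
        assert f[("a0", "ONL")] == pytest.approx(3.0)  # (3+5+4)/(1+2+1)
        assert f[("b1", "ONL")] == pytest.approx(2.0)

    def test_all_zero_counts_give_zero_frequencies(self):
        tables = {
            s: self.make_table([(0, 1.0)] * 3) for s in ("a0", "a1", "b0", "b1")
        }
        design = GroupDesign.from_lists(["a0", "a1", "b0", "b1"],
                                        ["a", "a", "b", "b"])
        ts = tunel_summary(tables, design)
        assert (ts.per_animal["frequency"] == 0).all()

    def test_too_few_sections_excluded_with_warning(self):
        tables = {
            "a0": self.make_table([(1, 1.0), (1, 1.0)]),  # 2 sections
            "a1": self.make_table([(1, 1.0)] * 3),
            "b0": self.make_table([(1, 1.0)] * 3),
            "b1": self.make_table([(1, 1.0)] * 3),
        }
        design = GroupDesign.from_lists(["a0", "a1", "b0", "b1"],
                                        ["a", "a", "b", "b"])
        with pytest.warns(UserWarning, match="sections"):
            ts = tunel_summary(tables, design)
        assert "a0" not in set(ts.per_animal["sample_id"])

    def test_doubled_onl_rate_detected_with_power(self):
        """Tukey flags oir vs control in the ONL at rate ratio 2, n=12."""
        from oirpipe.synth import SyntheticParams, generate_tunel_table

        hits = 0
        reps = 20
        for rep in range(reps):
            tables, ids, groups = {}, [], []
            for gi, (g, rate) in enumerate(
                (("control", 2.0), ("r670", 2.0), ("oir", 4.0), ("r670_oir", 3.0))
            ):
                for i in range(12):
                    sid = f"{g}_{i}"
                    p = SyntheticParams(
                        seed=rep * 1000 + gi * 50 + i,
                        tunel_rates={"GCL": 0.5, "INL": 0.5, "ONL": rate},
                    )
                    tables[sid] = generate_tunel_table(p, n_sections=3)
                    ids.append(sid)
                    groups.append(g)
            design = GroupDesign.from_lists(ids, groups)
            ts = tunel_summary(tables, design)
            tukey = ts.anova["ONL"].tukey
            row = tukey[
                (tukey["group1"].isin(["control", "oir"]))
                & (tukey["group2"].isin(["control", "oir"]))
            ]
            if bool(row["reject"].iloc[0]):
                hits += 1
        assert hits / reps >= 0.8


class TestDistancesToControl:
    def test_control_present_required(self):
        rng = np.random.default_rng(0)
        scores = rng.random((8, 2))
        design = toy_design([4, 4], ["a", "b"])
        cl = manova_mahalanobis(scores, design)
        with pytest.raises(ValueError):
            distances_relative_to_control(cl)

    def test_permutation_invariance_and_zero_self_distance(self):
        rng = np.random.default_rng(8)
        scores = rng.standard_normal((16, 2)) + np.repeat(
            [[0, 0], [1, 1], [2, 0], [0, 2]], 4, axis=0
        )
        ids = [f"s{i}" for i in range(16)]
        groups = (["control"] * 4 + ["r670"] * 4 + ["oir"] * 4 + ["r670_oir"] * 4)
        d1 = manova_mahalanobis(
            scores, GroupDesign.from_lists(ids, groups)
        )
        perm = np.random.default_rng(1).permutation(16)
        d2 = manova_mahalanobis(
            scores[perm],
            GroupDesign.from_lists([ids[i] for i in perm],
                                   [groups[i] for i in perm]),
        )
        t1 = distances_relative_to_control(d1)
        t2 = distances_relative_to_control(d2)
        pd.testing.assert_series_equal(t1, t2)
        ci = d1.group_names.index("control")
        assert d1.distance_matrix[ci, ci] == 0.0
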