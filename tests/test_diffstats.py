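"""Fold changes, t-tests, PLS-DA/NIPALS, S-plot, clustering, volcano."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from thioltrace.diffstats import (
    CohortTable,
    PLSDA,
    compare_groups,
    fold_change,
    heatmap_cluster,
    plsda_fit,
    significance_stars,
    splot,
    two_sample_t,
    volcano,
)
from thioltrace.synthgen import gen_cohort, gen_protein_table


def make_table(case_rows, ctrl_rows, features=None):
    case_rows, ctrl_rows = np.atleast_2d(case_rows), np.atleast_2d(ctrl_rows)
    features = features or [f"f{i}" for i in range(case_rows.shape[1])]
    values = pd.DataFrame(
        np.vstack([case_rows, ctrl_rows]),
        index=[f"P{i}" for i in range(len(case_rows))]
        + [f"H{i}" for i in range(len(ctrl_rows))],
        columns=features,
    )
    group = pd.Series(
        ["PCNSL"] * len(case_rows) + ["HV"] * len(ctrl_rows), index=values.index
    )
    return CohortTable(values=values, group=group)


class TestFoldChange:
    def test_identical_groups_give_one(self):
        t = make_table([[2.0], [2.0]], [[2.0], [2.0]])
        assert fold_change(t, "f0") == 1.0

    def test_two_point_groups(self):
        t = make_table([[2.0], [2.0]], [[1.0], [1.0]])
        assert fold_change(t, "f0") == 2.0

    def test_zero_control_mean_flagged(self):
        t = make_table([[2.0], [2.0]], [[0.0], [0.0]])
        with pytest.raises(ZeroDivisionError):
            fold_change(t, "f0")

    def test_configured_ratio_recovered_on_synthetic_cohort(self):
        t = gen_cohort({"gGlu-Cys": (5.0, 1.89, 0.15)}, n_per_group=30, seed=4)
        assert fold_change(t, "gGlu-Cys") == pytest.approx(1.89, rel=0.12)

    def test_direction_follows_generator_configuration(self):
        # control configured higher -> case/control ratio below 1
        t = gen_cohort({"CA": (5.0, 1 / 1.04, 0.15)}, n_per_group=30, seed=8)
        assert fold_change(t, "CA") < 1.0


class TestTwoSampleT:
    def test_identical_values_give_p_one(self):
        t = make_table([[1.0], [1.0]], [[1.0], [1.0]])
        r = two_sample_t(t, "f0")
        assert r.t_stat == 0.0 and r.p_value == 1.0 and r.stars == ""

    def test_closed_form_pooled_t(self):
        t = make_table([[1.0], [2.0], [3.0]], [[4.0], [5.0], [6.0]])
        r = two_sample_t(t, "f0", variant="student")
        assert r.t_stat == pytest.approx(-3.674, abs=1e-3)
        assert r.p_value == pytest.approx(0.0214, abs=2e-3)
        assert r.stars == "*"

    def test_constant_unequal_groups_floor_p(self):
        t = make_table([[1.0], [1.0]], [[2.0], [2.0]])
        r = two_sample_t(t, "f0")
        assert r.p_value > 0 and r.p_value < 1e-100

    @pytest.mark.parametrize(
        "p,stars", [(0.04, "*"), (0.004, "**"), (0.0004, "***"), (0.2, "")]
    )
    def test_stars_mapping(self, p, stars):
        assert significance_stars(p) == stars

    def test_welch_variant_differs_under_heteroscedasticity(self):
        rng = np.random.default_rng(0)
        t = make_table(rng.normal(0, 5, (10, 1)), rng.normal(1, 0.1, (10, 1)))
        rs = two_sample_t(t, "f0", "student")
        rw = two_sample_t(t, "f0", "welch")
        assert rs.p_value != rw.p_value


def _pls1_eigen_oracle(X, y, k):
    """Independent PLS1: per component, w = dominant eigenvector of X'yy'X."""
    Xa = (X - X.mean(0)) / X.std(0, ddof=1)
    yc = np.where(y == np.unique(y)[1], 1.0, -1.0)
    yc = yc - yc.mean()
    T = []
    Xd, yd = Xa.copy(), yc.copy()
    for _ in range(k):
        M = Xd.T @ np.outer(yd, yd) @ Xd
        vals, vecs = np.linalg.eigh(M)
        w = vecs[:, -1]
        t = Xd @ w
        p = Xd.T @ t / (t @ t)
        q = yd @ t / (t @ t)
        Xd = Xd - np.outer(t, p)
        yd = yd - t * q
        T.append(t)
    return np.column_stack(T)


class TestPlsda:
    def test_separable_groups_split_on_first_component(self):
        rng = np.random.default_rng(1)
        case = np.column_stack([rng.normal(5, 1, 10), rng.normal(0, 1, 10)])
        ctrl = np.column_stack([rng.normal(-5, 1, 10), rng.normal(0, 1, 10)])
        t = make_table(case, ctrl)
        m = plsda_fit(t, n_components=2)
        t1 = m.x_scores_[:, 0]
        g = t.group.to_numpy()
        assert min(t1[g == g[0]]) > max(t1[g != g[0]]) or max(
            t1[g == g[0]]
        ) < min(t1[g != g[0]])

    def test_scores_orthogonal(self):
        t = gen_cohort(seed=2)
        m = plsda_fit(t, n_components=3)
        T = m.x_scores_
        for i in range(3):
            for j in range(i + 1, 3):
                bound = 1e-6 * np.linalg.norm(T[:, i]) * np.linalg.norm(T[:, j])
                assert abs(T[:, i] @ T[:, j]) < bound

    def test_agrees_with_eigen_oracle_on_tiny_matrix(self):
        rng = np.random.default_rng(3)
        X = rng.normal(size=(6, 3))
        y = np.array(["a", "a", "a", "b", "b", "b"])
        m = PLSDA(n_components=2).fit(X, y)
        T_o = _pls1_eigen_oracle(X, y, 2)
        for h in range(2):
            a, b = m.x_scores_[:, h], T_o[:, h]
            assert np.allclose(a, b, atol=1e-8) or np.allclose(a, -b, atol=1e-8)

    def test_agrees_with_sklearn_cross_decomposition(self):
        from sklearn.cross_decomposition import PLSRegression

        rng = np.random.default_rng(4)
        X = rng.normal(size=(12, 5))
        y = np.array(["a"] * 6 + ["b"] * 6)
        m = PLSDA(n_components=3).fit(X, y)
        sk = PLSRegression(n_components=3, scale=True).fit(
            X, np.where(y == "b", 1.0, -1.0)
        )
        for h in range(3):
            a, b = m.x_scores_[:, h], sk.x_scores_[:, h]
            assert np.allclose(np.abs(a), np.abs(b), atol=1e-8)

    def test_three_informative_features_separate_groups_in_3d(self):
        rng = np.random.default_rng(5)
        case = rng.normal(0, 1, (15, 8))
        ctrl = rng.normal(0, 1, (15, 8))
        case[:, :3] += 3.0
        t = make_table(case, ctrl)
        m = plsda_fit(t, n_components=3)
        T = m.x_scores_
        g = (t.group == "PCNSL").to_numpy()
        centroid_dist = np.linalg.norm(T[g].mean(0) - T[~g].mean(0))
        within = max(
            np.linalg.norm(T[g] - T[g].mean(0), axis=1).mean(),
            np.linalg.norm(T[~g] - T[~g].mean(0), axis=1).mean(),
        )
        assert centroid_dist > within

    def test_constant_feature_dropped_with_warning(self):
        rng = np.random.default_rng(6)
        X = rng.normal(size=(10, 3))
        X[:, 1] = 7.0
        y = np.array(["a"] * 5 + ["b"] * 5)
        with pytest.warns(UserWarning, match="constant"):
            m = PLSDA(n_components=2).fit(X, y)
        assert m.kept_features_.tolist() == [True, False, True]

    def test_too_many_components_rejected(self):
        X = np.random.default_rng(0).normal(size=(4, 2))
        with pytest.raises(ValueError):
            PLSDA(n_components=4).fit(X, np.array(["a", "a", "b", "b"]))

    def test_deterministic(self):
        t = gen_cohort(seed=7)
        m1, m2 = plsda_fit(t), plsda_fit(t)
        assert np.array_equal(m1.x_scores_, m2.x_scores_)


class TestSplot:
    def test_feature_identical_to_t1_has_pcorr_one(self):
        rng = np.random.default_rng(8)
        base = rng.normal(size=20)
        X = np.column_stack([base, rng.normal(size=20)])
        y = np.array(["a"] * 10 + ["b"] * 10)
        t = make_table(X[:10] + 10, X[10:] + 10)  # positive, same structure
        m = plsda_fit(t, n_components=1)
        # plug the first score itself in as a feature
        t2 = CohortTable(
            values=t.values.assign(score_clone=m.x_scores_[:, 0]),
            group=t.group,
        )
        m2 = plsda_fit(t2, n_components=1)
        pts = {p.feature: p for p in splot(m2, t2)}
        assert abs(pts["score_clone"].pcorr1) > 0.999

    def test_markers_occupy_arms_noise_near_origin(self):
        rng = np.random.default_rng(9)
        n = 40
        noise = rng.normal(0, 1, (n, 6))
        marker = np.concatenate([np.full(n // 2, 3.0), np.zeros(n // 2)])
        X = np.column_stack([marker + rng.normal(0, 0.3, n), noise])
        t = make_table(X[: n // 2] + 10, X[n // 2 :] + 10)
        m = plsda_fit(t, n_components=1)
        pts = splot(m, t)
        assert abs(pts[0].pcorr1) > 0.8
        assert all(abs(p.pcorr1) < 0.6 for p in pts[1:])

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(st.integers(0, 2**31 - 1))
    def test_pcorr_bounded_on_random_data(self, seed):
        rng = np.random.default_rng(seed)
        X = rng.normal(size=(12, 4))
        t = make_table(X[:6] + 5, X[6:] + 5)
        pts = splot(plsda_fit(t, n_components=1), t)
        for p in pts:
            assert -1.0 - 1e-12 <= p.pcorr1 <= 1.0 + 1e-12


def _brute_average_linkage(points):
    """Naive UPGMA: merge the closest pair of clusters, average over pairs."""
    clusters = [[i] for i in range(len(points))]
    heights = []
    d = lambda a, b: float(np.linalg.norm(points[a] - points[b]))
    while len(clusters) > 1:
        best = None
        for i in range(len(clusters)):
            for j in range(i + 1, len(clusters)):
                dist = np.mean([d(a, b) for a in clusters[i] for b in clusters[j]])
                if best is None or dist < best[0]:
                    best = (dist, i, j)
        dist, i, j = best
        heights.append(dist)
        clusters = [c for k, c in enumerate(clusters) if k not in (i, j)] + [
            clusters[i] + clusters[j]
        ]
    return heights


class TestHeatmapCluster:
    def test_zscores_have_mean_zero_sd_one(self):
        t = gen_cohort(seed=10)
        z, _, _, _ = heatmap_cluster(t)
        assert np.allclose(z.mean(axis=0), 0, atol=1e-12)
        assert np.allclose(z.std(axis=0, ddof=1), 1, atol=1e-12)

    def test_duplicated_features_are_adjacent_leaves(self):
        rng = np.random.default_rng(11)
        X = rng.normal(size=(12, 4))
        X[:, 3] = X[:, 0]  # exact duplicate feature
        t = make_table(X[:6] + 10, X[6:] + 10)
        _, feat_order, _, _ = heatmap_cluster(t)
        pos = {f: i for i, f in enumerate(feat_order)}
        assert abs(pos[0] - pos[3]) == 1

    def test_merge_heights_match_brute_force_oracle(self):
        rng = np.random.default_rng(12)
        X = rng.normal(size=(4, 5))  # 5 features x 4 samples after z-score
        t = make_table(X[:2] + 5, X[2:] + 5)
        z, _, _, link = heatmap_cluster(t)
        got = sorted(link[:, 2])
        expected = sorted(_brute_average_linkage(z.T.to_numpy()))
        assert np.allclose(got, expected, atol=1e-10)

    def test_single_sample_rejected(self):
        values = pd.DataFrame([[1.0, 2.0]], index=["s"], columns=["a", "b"])
        with pytest.raises(ValueError):
            CohortTable(values=values, group=pd.Series(["x"], index=["s"]))


class TestVolcano:
    def test_planted_effects_flagged_with_correct_sign(self):
        table, planted = gen_protein_table(
            n_features=340, n_planted=12, effect_sd=3.0, n_per_group=10, seed=13
        )
        v = volcano(table).set_index("feature")
        assert v.loc[planted, "significant"].all()
        # alternating planted signs: both directions must occur and match
        signs = np.sign(v.loc[planted, "log2_fc"])
        assert (signs > 0).any() and (signs < 0).any()

    def test_null_table_flags_about_five_percent(self):
        rates = []
        for seed in range(20):
            table, _ = gen_protein_table(
                n_features=340, n_planted=0, effect_sd=0.0, n_per_group=10, seed=seed
            )
            v = volcano(table)
            rates.append(v["significant"].mean())
        assert np.mean(rates) == pytest.approx(0.05, abs=0.012)


class TestCompareGroups:
    def test_fdr_column_optional_and_monotone(self):
        t = gen_cohort(seed=14)
        plain = compare_groups(t)
        assert "q_value_bh" not in plain.columns
        with_q = compare_groups(t, fdr=True)
        assert (with_q["q_value_bh"] >= with_q["p_value"] - 1e-12).all()
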