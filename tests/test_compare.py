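import numpy as np
import pandas as pd
import pytest

from oracles import (
    chi_square_oracle,
    pca_scores_oracle,
    permanova_exhaustive_oracle,
    permanova_f_oracle,
    welch_t_oracle,
)
from tcrlens.annotate import Clonotype, RepertoireSample
from tcrlens.compare import (
    VJMatrix,
    benjamini_hochberg,
    build_vj_matrix,
    counting_chi_square,
    detect_asymmetric,
    group_t_test,
    pca_ordination,
    per_combination_t_tests,
    permanova,
)


def make_sample(sample_id, group, combos):
    """combos: list of (v, j, count)."""
    total = sum(c for _, _, c in combos)
    clonotypes = [
        Clonotype(v, j, f"{v}{j}NT{i}", "CASF", c, c / total)
        for i, (v, j, c) in enumerate(combos)
    ]
    return RepertoireSample(sample_id, group, clonotypes, total, total, total)


def matrix_from_values(values: dict[str, dict[str, float]], groups: dict[str, str]) -> VJMatrix:
    df = pd.DataFrame.from_dict(values, orient="index").fillna(0.0)
    df = df.reindex(sorted(df.columns), axis=1)
    return VJMatrix(values=df, groups=pd.Series(groups).loc[df.index])


class TestBuildVjMatrix:
    def test_per_million_arithmetic(self):
        samples = [
            make_sample("a", "case", [("TRBV1", "TRBJ1", 50), ("TRBV2", "TRBJ1", 499_950)]),
            make_sample("b", "control", [("TRBV2", "TRBJ1", 100)]),
        ]
        m = build_vj_matrix(samples)
        assert m.values.loc["a", "TRBV1|TRBJ1"] == pytest.approx(100.0)

    def test_row_sums_per_million(self, small_cohort):
        from tcrlens.simulate import repertoire_from_truth

        samples = [repertoire_from_truth(s) for s in small_cohort.samples]
        m = build_vj_matrix(samples)
        np.testing.assert_allclose(m.values.sum(axis=1), 1e6, atol=1e-3)

    def test_columns_sorted_and_nonzero(self, small_cohort):
        from tcrlens.simulate import repertoire_from_truth

        m = build_vj_matrix([repertoire_from_truth(s) for s in small_cohort.samples])
        assert list(m.values.columns) == sorted(m.values.columns)
        assert (m.values.sum(axis=0) > 0).all()

    def test_shuffled_samples_identical_up_to_row_order(self, small_cohort):
        from tcrlens.simulate import repertoire_from_truth

        samples = [repertoire_from_truth(s) for s in small_cohort.samples]
        m1 = build_vj_matrix(samples)
        m2 = build_vj_matrix(samples[::-1])
        pd.testing.assert_frame_equal(m1.values.sort_index(), m2.values.sort_index())

    def test_duplicate_sample_ids_rejected(self):
        s = make_sample("a", "case", [("TRBV1", "TRBJ1", 10)])
        with pytest.raises(ValueError, match="duplicate"):
            build_vj_matrix([s, s])

    def test_csv_round_trip(self, tmp_path, small_cohort):
        from tcrlens.simulate import repertoire_from_truth

        m = build_vj_matrix([repertoire_from_truth(s) for s in small_cohort.samples])
        path = tmp_path / "vj.csv"
        m.to_csv(path)
        back = VJMatrix.from_csv(path)
        pd.testing.assert_frame_equal(m.values, back.values)
        pd.testing.assert_series_equal(m.groups, back.groups, check_names=False)


class TestDetectAsymmetric:
    def _matrix(self, case_positive, control_positive, n=10):
        values = {}
        groups = {}
        for i in range(n):
            sid = f"case{i:02d}"
            groups[sid] = "case"
            values[sid] = {"TRBV11-1|TRBJ1-1": 100.0 if i < case_positive else 0.0, "TRBVx|TRBJx": 5.0}
        for i in range(n):
            sid = f"ctrl{i:02d}"
            groups[sid] = "control"
            values[sid] = {"TRBV11-1|TRBJ1-1": 80.0 if i < control_positive else 0.0, "TRBVx|TRBJx": 5.0}
        return matrix_from_values(values, groups)

    def test_three_cases_zero_controls_flagged(self):
        # the published asymmetric-table pattern: 0 positive controls, 3 positive cases
        hits = detect_asymmetric(self._matrix(3, 0))
        (hit,) = hits
        assert (hit.v_gene, hit.j_gene) == ("TRBV11-1", "TRBJ1-1")
        assert hit.direction == "case_only"
        assert hit.n_positive_case == 3 and hit.n_positive_control == 0
        assert hit.mean_norm == pytest.approx(100.0)
        assert hit.sd_norm == pytest.approx(0.0)

    def test_below_min_positive_not_flagged(self):
        assert detect_asymmetric(self._matrix(2, 0)) == []

    def test_other_group_nonzero_not_flagged(self):
        assert detect_asymmetric(self._matrix(3, 1)) == []

    def test_control_only_direction(self):
        hits = detect_asymmetric(self._matrix(0, 4))
        (hit,) = hits
        assert hit.direction == "control_only"
        assert hit.n_positive_control == 4

    def test_positivity_threshold(self):
        m = self._matrix(3, 0)
        assert detect_asymmetric(m, positivity_threshold=150.0) == []

    def test_mean_sd_over_positive_samples_only(self):
        values = {
            "case00": {"TRBV1|TRBJ1": 10.0}, "case01": {"TRBV1|TRBJ1": 20.0},
            "case02": {"TRBV1|TRBJ1": 30.0}, "case03": {"TRBV1|TRBJ1": 0.0},
            "ctrl00": {"TRBV1|TRBJ1": 0.0}, "ctrl01": {"TRBV1|TRBJ1": 0.0},
            "ctrl02": {"TRBV1|TRBJ1": 0.0}, "ctrl03": {"TRBV1|TRBJ1": 0.0},
        }
        for v in values.values():
            v["TRBV2|TRBJ2"] = 1.0
        groups = {k: ("case" if k.startswith("case") else "control") for k in values}
        (hit,) = detect_asymmetric(matrix_from_values(values, groups))
        assert hit.mean_norm == pytest.approx(20.0)
        assert hit.sd_norm == pytest.approx(10.0)


class TestGroupTTest:
    def test_identical_groups(self):
        t, p = group_t_test([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert t == 0.0 and p == 1.0

    def test_swap_negates_t_same_p(self):
        a, b = [1.0, 2.0, 5.0], [2.0, 4.0, 9.0]
        t1, p1 = group_t_test(a, b)
        t2, p2 = group_t_test(b, a)
        assert t1 == pytest.approx(-t2)
        assert p1 == pytest.approx(p2)

    def test_matches_textbook_formula(self):
        a, b = [3.1, 4.5, 2.2], [6.0, 5.5, 7.1]
        t, p = group_t_test(a, b)
        t_o, p_o = welch_t_oracle(a, b)
        assert t == pytest.approx(t_o)
        assert p == pytest.approx(p_o)


class TestChiSquare:
    def test_hand_computed_value(self):
        stat, p = counting_chi_square([[9, 1], [3, 7]])
        assert stat == pytest.approx(7.5)
        assert stat == pytest.approx(chi_square_oracle([[9, 1], [3, 7]]))

    def test_symmetric_under_row_swap(self):
        s1, p1 = counting_chi_square([[9, 1], [3, 7]])
        s2, p2 = counting_chi_square([[3, 7], [9, 1]])
        assert s1 == pytest.approx(s2) and p1 == pytest.approx(p2)

    def test_zero_margin_rejected(self):
        with pytest.raises(ValueError, match="margin"):
            counting_chi_square([[0, 0], [3, 7]])

    def test_continuity_correction_flag(self):
        uncorrected, _ = counting_chi_square([[9, 1], [3, 7]], correction=False)
        corrected, _ = counting_chi_square([[9, 1], [3, 7]], correction=True)
        assert corrected < uncorrected


class TestPca:
    def test_identical_samples_identical_scores(self):
        values = {
            "a": {"X|1": 5.0, "Y|1": 1.0, "Z|1": 3.0},
            "b": {"X|1": 5.0, "Y|1": 1.0, "Z|1": 3.0},
            "c": {"X|1": 0.0, "Y|1": 4.0, "Z|1": 3.0},
        }
        m = matrix_from_values(values, {"a": "case", "b": "case", "c": "control"})
        res = pca_ordination(m, n_components=2)
        np.testing.assert_allclose(res.scores.loc["a"], res.scores.loc["b"], atol=1e-12)

    def test_explained_variance_bounded_and_sorted(self, small_cohort):
        from tcrlens.simulate import repertoire_from_truth

        m = build_vj_matrix([repertoire_from_truth(s) for s in small_cohort.samples])
        res = pca_ordination(m, n_components=3)
        evr = res.explained_variance_ratio
        assert evr.sum() <= 1 + 1e-12
        assert all(evr[i] >= evr[i + 1] - 1e-12 for i in range(len(evr) - 1))

    def test_matches_eigendecomposition_oracle(self):
        x = np.array(
            [[2.0, 0.0, 1.0], [0.0, 1.0, 0.0], [4.0, 1.0, 3.0], [0.0, 4.0, 0.0]]
        )
        m = VJMatrix(
            values=pd.DataFrame(x, index=list("abcd"), columns=["V1|J1", "V1|J2", "V2|J1"]),
            groups=pd.Series({"a": "case", "b": "case", "c": "control", "d": "control"}),
        )
        res = pca_ordination(m, n_components=2)
        scores_o, evr_o = pca_scores_oracle(x, 2)
        # signs are conventions; compare up to per-axis sign
        for k in range(2):
            got = res.scores.iloc[:, k].to_numpy()
            want = scores_o[:, k]
            assert np.allclose(got, want, atol=1e-9) or np.allclose(got, -want, atol=1e-9)
        np.testing.assert_allclose(res.explained_variance_ratio, evr_o, atol=1e-12)

    def test_constant_matrix_rejected(self):
        values = {"a": {"X|1": 1.0, "Y|1": 2.0}, "b": {"X|1": 1.0, "Y|1": 2.0}}
        m = matrix_from_values(values, {"a": "case", "b": "control"})
        with pytest.raises(ValueError, match="constant"):
            pca_ordination(m)

    def test_sign_convention_deterministic(self, small_cohort):
        from tcrlens.simulate import repertoire_from_truth

        m = build_vj_matrix([repertoire_from_truth(s) for s in small_cohort.samples])
        r1 = pca_ordination(m)
        r2 = pca_ordination(m)
        pd.testing.assert_frame_equal(r1.scores, r2.scores)


def random_matrix(rng, n_case=3, n_ctrl=3, p=6, shift=0.0):
    values = {}
    groups = {}
    for i in range(n_case):
        sid = f"case{i}"
        values[sid] = {f"V{k}|J": float(v) for k, v in enumerate(rng.random(p) + shift)}
        groups[sid] = "case"
    for i in range(n_ctrl):
        sid = f"ctrl{i}"
        values[sid] = {f"V{k}|J": float(v) for k, v in enumerate(rng.random(p))}
        groups[sid] = "control"
    return matrix_from_values(values, groups)


class TestPermanova:
    def test_exhaustive_matches_enumeration_oracle(self, rng):
        from scipy.spatial.distance import pdist, squareform

        m = random_matrix(rng, 3, 3, p=5, shift=0.4)
        res = permanova(m, distance="euclidean", exhaustive=True)
        x = m.values.to_numpy()
        dist = squareform(pdist(x, metric="euclidean"))
        f_o, p_o = permanova_exhaustive_oracle(dist, 3)
        assert res.n_permutations == 20
        assert res.pseudo_f == pytest.approx(f_o)
        assert res.p_value == pytest.approx(p_o)

    def test_pseudo_f_matches_trace_oracle(self, rng):
        from scipy.spatial.distance import pdist, squareform

        for _ in range(5):
            m = random_matrix(rng, 4, 3, p=7)
            res = permanova(m, distance="bray_curtis", n_perm=9, seed=0)
            dist = squareform(pdist(m.values.to_numpy(), metric="braycurtis"))
            labels = np.array([0] * 4 + [1] * 3)
            assert res.pseudo_f == pytest.approx(permanova_f_oracle(dist, labels))

    def test_group_relabeling_invariance(self, rng):
        m = random_matrix(rng, 4, 4, p=6, shift=0.2)
        res1 = permanova(m, n_perm=99, seed=5)
        flipped = VJMatrix(values=m.values, groups=m.groups.map({"case": "control", "control": "case"}))
        res2 = permanova(flipped, n_perm=99, seed=5)
        assert res1.pseudo_f == pytest.approx(res2.pseudo_f)
        assert res1.p_value == res2.p_value

    def test_separated_clusters_significant(self, rng):
        # 5v5: label permutations recreate the observed partition (F is
        # swap-invariant) about 2/C(10,5) of the time, so the attainable
        # floor is ~0.009; 6v6 comfortably reaches p <= 0.005
        m5 = random_matrix(rng, 5, 5, p=6, shift=5.0)
        assert permanova(m5, n_perm=999, seed=1).p_value <= 0.02
        m6 = random_matrix(rng, 6, 6, p=6, shift=5.0)
        assert permanova(m6, n_perm=999, seed=1).p_value <= 0.005

    def test_reproducible_given_seed(self, rng):
        m = random_matrix(rng, 4, 4, p=6)
        assert permanova(m, n_perm=99, seed=3) == permanova(m, n_perm=99, seed=3)

    def test_degenerate_all_zero_distances(self):
        values = {f"s{i}": {"V|J": 1.0, "W|J": 2.0} for i in range(6)}
        groups = {f"s{i}": ("case" if i < 3 else "control") for i in range(6)}
        m = matrix_from_values(values, groups)
        with pytest.warns(UserWarning, match="zero"):
            res = permanova(m, n_perm=99)
        assert res.p_value == 1.0

    def test_single_sample_group_rejected(self, rng):
        m = random_matrix(rng, 1, 4)
        with pytest.raises(ValueError, match="two groups"):
            permanova(m)


class TestBenjaminiHochberg:
    def test_monotone_and_bounded(self, rng):
        p = rng.random(20)
        adj = benjamini_hochberg(p)
        assert ((adj >= p - 1e-12) & (adj <= 1.0)).all()
        order = np.argsort(p)
        assert (np.diff(adj[order]) >= -1e-12).all()

    def test_against_statsmodels(self, rng):
        from statsmodels.stats.multitest import multipletests

        p = rng.random(15)
        _, adj_sm, _, _ = multipletests(p, method="fdr_bh")
        np.testing.assert_allclose(benjamini_hochberg(p), adj_sm, atol=1e-12)


class TestPerCombinationTests:
    def test_frame_shape_and_bh_column(self, small_cohort):
        from tcrlens.simulate import repertoire_from_truth

        m = build_vj_matrix([repertoire_from_truth(s) for s in small_cohort.samples])
        df = per_combination_t_tests(m)
        assert set(df.columns) == {"combination", "t", "p", "p_bh"}
        assert len(df) == m.values.shape[1]
        assert (df["p_bh"] >= df["p"] - 1e-12).all()
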