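"""MDRD eGFR, staging, GLM/ANOVA, correlations, clustering and peptide selection."""

import itertools

import numpy as np
import pandas as pd
import pytest

from cemspipe.cohort import (
    assign_stage_group,
    cluster_patients,
    compare_clusters,
    correlate,
    fit_line,
    glm_f_unbalanced,
    invert_mdrd_creatinine,
    mdrd_egfr,
    monotone_peptides,
    per_peptide_egfr_correlation,
)
from cemspipe.errors import ValidationError
from cemspipe.matching import PeptideMatrix


class TestMdrd:
    def test_reference_value(self):
        # 88.4 umol/L = 1.0 mg/dL; 186 * 70^-0.203 ~ 78.5
        assert mdrd_egfr(88.4, 70, "M") == pytest.approx(78.5, abs=0.05)

    def test_female_factor(self):
        m = mdrd_egfr(150.0, 60, "M")
        f = mdrd_egfr(150.0, 60, "F")
        assert f == pytest.approx(0.742 * m)

    def test_black_factor(self):
        assert mdrd_egfr(150.0, 60, "M", black=True) == pytest.approx(
            1.210 * mdrd_egfr(150.0, 60, "M")
        )

    def test_non_positive_inputs_rejected(self):
        with pytest.raises(ValidationError):
            mdrd_egfr(0.0, 70, "M")
        with pytest.raises(ValidationError):
            mdrd_egfr(100.0, 0, "M")

    def test_strictly_decreasing_in_creatinine_and_age(self):
        cr = np.linspace(60, 900, 40)
        e = mdrd_egfr(cr, np.full_like(cr, 60.0), ["M"] * 40)
        assert np.all(np.diff(e) < 0)
        ages = np.linspace(20, 90, 40)
        e2 = mdrd_egfr(np.full_like(ages, 150.0), ages, ["F"] * 40)
        assert np.all(np.diff(e2) < 0)

    def test_inversion_round_trip(self):
        for egfr, age, sex in [(78.5, 70, "M"), (15.0, 55, "F"), (120.0, 40, "M")]:
            cr = invert_mdrd_creatinine(egfr, age, sex)
            assert mdrd_egfr(cr, age, sex) == pytest.approx(egfr, abs=1e-9)


class TestStageGroups:
    @pytest.mark.parametrize(
        "egfr,group",
        [(64.3, 1), (90.0, 1), (60.0, 2), (45.0, 2), (30.0, 3), (16.0, 3), (15.0, 4), (5.0, 4)],
    )
    def test_band_assignment(self, egfr, group):
        assert assign_stage_group(egfr) == group

    def test_negative_rejected(self):
        with pytest.raises(ValidationError):
            assign_stage_group(-1.0)

    def test_bad_cutpoints_rejected(self):
        with pytest.raises(ValidationError):
            assign_stage_group(50.0, cutpoints=(30, 60, 15))


class TestGlmF:
    def test_hand_computed_toy_value(self):
        # groups {1,2} and {3,4}: SSB=4 (df 1), SSW=1 (df 2) -> F=8
        res = glm_f_unbalanced([1, 2, 3, 4], ["a", "a", "b", "b"])
        assert res.value == pytest.approx(8.0)
        assert res.df == (1, 2)

    def test_equal_means_give_zero(self):
        res = glm_f_unbalanced([1, 3, 1, 3], ["a", "a", "b", "b"])
        assert res.value == pytest.approx(0.0)

    def test_unbalanced_groups_supported(self):
        res = glm_f_unbalanced([1, 2, 3, 10, 11], ["a", "a", "a", "b", "b"])
        assert res.df == (1, 3)
        assert res.value > 0

    def test_single_group_rejected(self):
        with pytest.raises(ValidationError):
            glm_f_unbalanced([1, 2, 3], ["a", "a", "a"])

    def test_equals_t_squared_for_two_groups(self, rng):
        from scipy import stats

        for _ in range(10):
            a = rng.normal(size=int(rng.integers(3, 12)))
            b = rng.normal(size=int(rng.integers(3, 12)))
            res = glm_f_unbalanced(
                np.concatenate([a, b]), ["a"] * len(a) + ["b"] * len(b)
            )
            t = stats.ttest_ind(a, b, equal_var=True)
            assert res.value == pytest.approx(t.statistic**2, rel=1e-9)
            assert res.p_value == pytest.approx(t.pvalue, rel=1e-9)


class TestCorrelate:
    def test_exact_linearity(self):
        x = np.array([1.0, 2.0, 5.0, 9.0])
        res = correlate(x, 2 * x + 1, "pearson")
        assert res.value == pytest.approx(1.0)

    def test_monotone_nonlinear(self):
        x = np.linspace(0, 5, 12)
        res_s = correlate(x, np.exp(x), "spearman")
        res_p = correlate(x, np.exp(x), "pearson")
        assert res_s.value == pytest.approx(1.0)
        assert res_p.value < 1.0

    def test_constant_input_flagged_not_raised(self):
        res = correlate([1, 1, 1, 1], [1, 2, 3, 4], "pearson")
        assert np.isnan(res.value)
        assert res.note == "constant input"

    def test_missing_pairs_dropped_and_counted(self):
        x = [1.0, 2.0, np.nan, 4.0, 5.0]
        y = [2.0, 4.0, 6.0, np.nan, 10.0]
        res = correlate(x, y, "pearson")
        assert res.n == 3
        assert res.value == pytest.approx(1.0)

    def test_independent_null_is_small(self):
        hits = 0
        for seed in range(20):
            r = np.random.default_rng(seed)
            res = correlate(r.normal(size=1000), r.normal(size=1000), "pearson")
            hits += abs(res.value) < 0.1
        assert hits == 20


class TestFitLine:
    def test_exact_fit_round_trip(self):
        x = np.array([10.0, 30.0, 50.0, 80.0])
        y = -0.019 * x + 1.12
        res = fit_line(x, y)
        assert res.slope == pytest.approx(-0.019)
        assert res.intercept == pytest.approx(1.12)
        assert res.r_squared == pytest.approx(1.0)

    def test_constant_y_degenerate(self):
        res = fit_line([1.0, 2.0, 3.0], [5.0, 5.0, 5.0])
        assert res.slope == pytest.approx(0.0)
        assert res.r_squared == pytest.approx(0.0)

    def test_constant_x_rejected(self):
        with pytest.raises(ValidationError):
            fit_line([2.0, 2.0, 2.0], [1.0, 2.0, 3.0])

    def test_matches_normal_equations_oracle(self, rng):
        for _ in range(10):
            n = int(rng.integers(3, 20))
            x = rng.normal(size=n)
            y = rng.normal(size=n)
            if np.allclose(x, x[0]):
                continue
            res = fit_line(x, y)
            X = np.column_stack([x, np.ones(n)])
            beta = np.linalg.solve(X.T @ X, X.T @ y)
            assert res.slope == pytest.approx(beta[0], rel=1e-9, abs=1e-12)
            assert res.intercept == pytest.approx(beta[1], rel=1e-9, abs=1e-12)


def average_linkage_oracle(X, k):
    """O(n^3) agglomerative average-linkage on Euclidean distances."""
    n = len(X)
    clusters = {i: [i] for i in range(n)}
    while len(clusters) > k:
        best = None
        for a, b in itertools.combinations(sorted(clusters), 2):
            d = np.mean(
                [np.linalg.norm(X[i] - X[j]) for i in clusters[a] for j in clusters[b]]
            )
            if best is None or d < best[0] - 1e-12:
                best = (d, a, b)
        _, a, b = best
        clusters[a] = clusters[a] + clusters[b]
        del clusters[b]
    labels = np.zeros(n, dtype=int)
    for ci, members in enumerate(sorted(clusters.values(), key=min), start=1):
        labels[members] = ci
    return labels


def _matrix_from_array(X, sample_ids=None):
    X = np.asarray(X, dtype=float)
    n_s, n_p = X.shape
    sample_ids = sample_ids or [f"s{i}" for i in range(n_s)]
    intens = pd.DataFrame(
        X.T, index=pd.Index([f"C{k}" for k in range(n_p)], name="peptide_id"),
        columns=sample_ids,
    )
    meta = pd.DataFrame(
        {"mass_da": 1000.0 + np.arange(n_p), "time_min": 20.0 + np.arange(n_p),
         "support": n_s},
        index=intens.index,
    )
    return PeptideMatrix(intens, meta)


class TestClusterPatients:
    def test_single_sample(self):
        m = _matrix_from_array([[1.0, 2.0]])
        labels, _ = cluster_patients(m, k=1)
        assert list(labels) == [1]

    def test_two_well_separated_blobs(self, rng):
        a = rng.normal(2, 0.1, size=(10, 5))
        b = rng.normal(10, 0.1, size=(10, 5))
        m = _matrix_from_array(np.vstack([a, b]))
        labels, _ = cluster_patients(m, k=2, log_transform=False)
        assert labels.iloc[:10].nunique() == 1
        assert labels.iloc[10:].nunique() == 1
        assert labels.iloc[0] != labels.iloc[-1]

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_cubic_oracle_small_n(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(3, 9))
        X = rng.uniform(0.5, 10.0, size=(n, 4))
        k = int(rng.integers(1, n + 1))
        labels, _ = cluster_patients(_matrix_from_array(X), k=k, log_transform=False)
        oracle = average_linkage_oracle(X, k)
        # same partition up to label renaming
        got = {frozenset(np.where(labels.to_numpy() == c)[0]) for c in set(labels)}
        want = {frozenset(np.where(oracle == c)[0]) for c in set(oracle)}
        assert got == want

    def test_invariant_to_peptide_row_relabeling(self, rng):
        X = rng.uniform(1.0, 8.0, size=(12, 8))
        m = _matrix_from_array(X)
        labels1, _ = cluster_patients(m, k=3)
        perm = rng.permutation(m.n_peptides)
        m2 = PeptideMatrix(m.intensities.iloc[perm], m.peptides.iloc[perm])
        labels2, _ = cluster_patients(m2, k=3)
        got1 = {frozenset(labels1.index[labels1 == c]) for c in set(labels1)}
        got2 = {frozenset(labels2.index[labels2 == c]) for c in set(labels2)}
        assert got1 == got2

    def test_k_larger_than_n_rejected(self):
        with pytest.raises(ValidationError):
            cluster_patients(_matrix_from_array([[1.0], [2.0]]), k=3)


class TestCompareClusters:
    def _patients(self, values1, values2):
        ids = [f"a{i}" for i in range(len(values1))] + [f"b{i}" for i in range(len(values2))]
        df = pd.DataFrame({"v": list(values1) + list(values2)}, index=ids)
        assign = pd.Series([1] * len(values1) + [2] * len(values2), index=ids)
        return df, assign

    def test_identical_values_give_p_one(self):
        df, assign = self._patients([5.0] * 10, [5.0] * 10)
        out = compare_clusters(df, assign, ["v"])
        assert out.loc["v", "ranksum_p"] == pytest.approx(1.0)

    def test_large_shift_detected(self, rng):
        df, assign = self._patients(rng.normal(0, 1, 20), rng.normal(3, 1, 20))
        out = compare_clusters(df, assign, ["v"])
        assert out.loc["v", "t_p"] < 0.01
        assert out.loc["v", "ranksum_p"] < 0.01

    def test_type_i_error_calibrated_under_null(self):
        rng = np.random.default_rng(0)
        rejections = 0
        n_rep = 400
        for _ in range(n_rep):
            df, assign = self._patients(rng.normal(size=15), rng.normal(size=15))
            out = compare_clusters(df, assign, ["v"])
            rejections += out.loc["v", "t_p"] < 0.05
        assert abs(rejections / n_rep - 0.05) <= 0.03

    def test_tiny_cluster_rejected(self):
        df, assign = self._patients([1.0], [2.0, 3.0])
        with pytest.raises(ValidationError):
            compare_clusters(df, assign, ["v"])


class TestPerPeptideEgfr:
    def _setup(self, rng, n=40):
        egfr = rng.uniform(5, 90, size=n)
        up = 1000 * (100 - egfr) + rng.normal(0, 200, n)   # rises as eGFR falls
        down = 1000 * egfr + rng.normal(0, 200, n)          # falls as eGFR falls
        flat = np.full(n, 500.0)
        m = _matrix_from_array(np.column_stack([up, down, flat]))
        patients = pd.DataFrame({"egfr": egfr, "dialysis": False},
                                index=m.sample_ids)
        return m, patients

    def test_direction_calls(self, rng):
        m, patients = self._setup(rng)
        out = per_peptide_egfr_correlation(m, patients)
        assert out.loc["C0", "direction"] == "increased-with-CKD"
        assert out.loc["C1", "direction"] == "decreased-with-CKD"
        assert out.loc["C2", "flag"] == "constant"
        assert out.loc["C2", "direction"] is None

    def test_bh_adjustment_is_monotone_and_larger(self, rng):
        m, patients = self._setup(rng)
        out = per_peptide_egfr_correlation(m, patients)
        ok = out["p"].notna()
        assert (out.loc[ok, "p_adj"] >= out.loc[ok, "p"] - 1e-12).all()

    def test_null_false_positive_rate(self):
        rng = np.random.default_rng(1)
        n, n_pep = 30, 300
        X = rng.normal(4, 1, size=(n, n_pep))
        m = _matrix_from_array(10.0 ** X)
        patients = pd.DataFrame(
            {"egfr": rng.uniform(5, 90, n), "dialysis": False}, index=m.sample_ids
        )
        out = per_peptide_egfr_correlation(m, patients)
        fpr = (out["p"] < 0.05).mean()
        assert abs(fpr - 0.05) <= 0.03


class TestMonotonePeptides:
    def _matrix(self, rows):
        # rows: dict peptide -> per-sample values; 8 samples, groups 1,1,2,2,3,3,4,4
        ids = list(rows)
        X = np.array([rows[i] for i in ids], dtype=float)
        intens = pd.DataFrame(X, index=pd.Index(ids, name="peptide_id"),
                              columns=[f"s{i}" for i in range(X.shape[1])])
        meta = pd.DataFrame(
            {"mass_da": 1000.0, "time_min": 25.0, "support": intens.notna().sum(axis=1)},
            index=intens.index,
        )
        groups = pd.Series([1, 1, 2, 2, 3, 3, 4, 4], index=intens.columns)
        return PeptideMatrix(intens, meta), groups

    def test_monotone_kept_nonmonotone_dropped(self):
        m, groups = self._matrix(
            {
                "inc": [1, 1, 2, 2, 3, 3, 4, 4],
                "dec": [4, 4, 3, 3, 2, 2, 1, 1],
                "bump": [1, 1, 3, 3, 2, 2, 4, 4],
                "flat": [2, 2, 2, 2, 2, 2, 2, 2],
            }
        )
        selected, table = monotone_peptides(m, groups, min_frac=0.5)
        assert set(selected) == {"inc", "dec", "flat"}  # ties allowed
        assert list(table.columns) == ["group_1", "group_2", "group_3", "group_4"]
        assert table.loc["inc"].tolist() == [1.0, 2.0, 3.0, 4.0]

    def test_presence_filter_applied_first(self):
        m, groups = self._matrix(
            {
                "sparse": [1, np.nan, np.nan, np.nan, np.nan, np.nan, np.nan, 4],
                "dense": [1, 1, 2, 2, 3, 3, 4, 4],
            }
        )
        selected, table = monotone_peptides(m, groups, min_frac=0.5)
        assert selected == ["dense"]
        assert "sparse" not in table.index

    def test_single_group_rejected(self):
        m, groups = self._matrix({"a": [1] * 8})
        with pytest.raises(ValidationError):
            monotone_peptides(m, pd.Series(1, index=groups.index))
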