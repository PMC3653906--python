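"""Classifier scoring, training and the prognostic table."""

import numpy as np
import pandas as pd
import pytest

from cemspipe.classify import (
    ClassifierModel,
    prognostic_table,
    score_matrix,
    score_sample,
    train_model,
)
from cemspipe.errors import ValidationError
from cemspipe.matching import PeptideMatrix
from cemspipe.peaks import PeptideFeature


def model_of(rows, offset=0.0, cutoff=0.55, missing_policy="zero"):
    panel = pd.DataFrame(rows, columns=["peptide_id", "mass_da", "time_min", "weight"])
    return ClassifierModel(panel=panel, offset=offset, cutoff=cutoff,
                           missing_policy=missing_policy)


def matrix_of(values, masses=None, samples=None):
    values = np.asarray(values, dtype=float)
    n_pep, n_s = values.shape
    samples = samples or [f"s{i}" for i in range(n_s)]
    ids = [f"C{k}" for k in range(n_pep)]
    intens = pd.DataFrame(values, index=pd.Index(ids, name="peptide_id"), columns=samples)
    meta = pd.DataFrame(
        {
            "mass_da": masses if masses is not None else 1000.0 + 100.0 * np.arange(n_pep),
            "time_min": 20.0 + np.arange(n_pep, dtype=float),
            "support": intens.notna().sum(axis=1),
        },
        index=intens.index,
    )
    return PeptideMatrix(intens, meta)


class TestScoreSample:
    def test_zero_weights_return_offset(self):
        m = model_of([("p1", 1000.0, 20.0, 0.0), ("p2", 2000.0, 30.0, 0.0)], offset=0.3)
        r = score_sample([PeptideFeature(1000.0, 20.0, 500.0)], m)
        assert r.score == pytest.approx(0.3)
        assert not r.above_cutoff

    def test_matched_intensity_enters_log10(self):
        m = model_of([("p1", 1000.0, 20.0, 2.0)], offset=0.1)
        r = score_sample([PeptideFeature(1000.0, 20.0, 99.0)], m)
        assert r.score == pytest.approx(0.1 + 2.0 * np.log10(100.0))
        assert r.n_panel_detected == 1

    def test_missing_policy_zero(self):
        m = model_of([("p1", 1000.0, 20.0, 2.0)], offset=0.1)
        r = score_sample([], m)
        assert r.score == pytest.approx(0.1)
        assert r.n_panel_detected == 0

    def test_boundary_score_is_low_risk(self):
        m = model_of([("p1", 1000.0, 20.0, 0.0)], offset=0.55, cutoff=0.55)
        r = score_sample([], m)
        assert r.score == pytest.approx(0.55)
        assert not r.above_cutoff  # strict > for high risk
        r2 = score_sample([], model_of([("p1", 1000.0, 20.0, 0.0)], offset=0.56))
        assert r2.above_cutoff

    def test_linearity_in_log_intensity(self):
        # multiplying every matched intensity by 10 shifts the score by ~sum(weights)
        rows = [(f"p{k}", 1000.0 + 50 * k, 20.0 + k, 0.5 - 0.1 * k) for k in range(4)]
        m = model_of(rows, offset=0.2)
        feats = [PeptideFeature(1000.0 + 50 * k, 20.0 + k, 10_000.0) for k in range(4)]
        feats10 = [PeptideFeature(f.mass, f.time, f.intensity * 10) for f in feats]
        r1, r10 = score_sample(feats, m), score_sample(feats10, m)
        total_w = sum(w for _, _, _, w in rows)
        # log10(1+10 I) - log10(1+I) -> 1 as I >> 1
        assert r10.score - r1.score == pytest.approx(total_w, abs=1e-3)

    def test_empty_panel_rejected(self):
        with pytest.raises(ValidationError):
            model_of([])


class TestScoreMatrix:
    def test_agrees_with_per_sample_scoring(self):
        rows = [("p1", 1000.0, 20.0, 1.0), ("p2", 2000.0, 30.0, -0.5)]
        m = model_of(rows, offset=0.2)
        mat = matrix_of([[100.0, np.nan], [50.0, 400.0]],
                        masses=[1000.0, 2000.0])
        mat.peptides["time_min"] = [20.0, 30.0]
        scored = score_matrix(mat, m)
        for si, sid in enumerate(mat.sample_ids):
            feats = [
                PeptideFeature(mat.peptides["mass_da"].iloc[k],
                               mat.peptides["time_min"].iloc[k], v)
                for k, v in enumerate(mat.intensities[sid])
                if not np.isnan(v)
            ]
            assert scored.loc[sid, "score"] == pytest.approx(score_sample(feats, m).score)

    def test_planted_score_tracks_severity(self, rng):
        from cemspipe import SyntheticConfig, make_planted_model, simulate_study
        from scipy.stats import spearmanr

        cfg = SyntheticConfig(n_patients=200, seed=9)
        study = simulate_study(cfg)
        model = make_planted_model(study, cfg)
        # score the true abundances directly (generator self-consistency)
        mat = PeptideMatrix(
            study.truth.abundance,
            pd.DataFrame(
                {
                    "mass_da": study.panel_meta["mass_da"],
                    "time_min": study.panel_meta["time_min"],
                    "support": 200,
                },
                index=study.truth.abundance.index,
            ),
        )
        scores = score_matrix(mat, model)
        rho = spearmanr(scores["score"], study.truth.severity.loc[scores.index])[0]
        assert rho > 0.9


class TestTrainModel:
    def _planted(self, n=200, n_pep=60, n_info=20, seed=0, shift=1.0):
        rng = np.random.default_rng(seed)
        y = rng.integers(0, 2, size=n)
        logx = rng.normal(4.0, 0.3, size=(n_pep, n))
        logx[:n_info] += shift * y * np.where(np.arange(n_info)[:, None] % 2 == 0, 1, -1)
        return matrix_of(10.0 ** logx), pd.Series(y, index=[f"s{i}" for i in range(n)])

    def test_separable_classes_fit_perfectly(self):
        mat, y = self._planted(n=40, n_pep=10, n_info=4, shift=5.0)
        model = train_model(mat, y, regularization=0.1)
        scores = score_matrix(mat, model)
        acc = ((scores["score"] > 0).astype(int).to_numpy() == y.to_numpy()).mean()
        assert acc == 1.0

    def test_single_class_rejected(self):
        mat, y = self._planted(n=20)
        with pytest.raises(ValidationError):
            train_model(mat, pd.Series(1, index=y.index))

    def test_weight_signs_recover_planted_directions(self):
        mat, y = self._planted(n=200, n_pep=60, n_info=20, shift=1.0, seed=1)
        model = train_model(mat, y, regularization=0.5)
        w = model.panel.set_index("peptide_id")["weight"]
        planted = np.where(np.arange(20) % 2 == 0, 1, -1)
        got = np.sign(w.loc[[f"C{k}" for k in range(20)]].to_numpy())
        assert (got == planted).mean() >= 0.8

    def test_held_out_auroc_on_planted_signal(self):
        from sklearn.metrics import roc_auc_score

        mat, y = self._planted(n=200, n_pep=60, n_info=20, shift=1.0, seed=2)
        train_ids, test_ids = y.index[:100], y.index[100:]
        model = train_model(_sub(mat, train_ids), y.loc[train_ids])
        scores = score_matrix(_sub(mat, test_ids), model)
        auc = roc_auc_score(y.loc[test_ids], scores.loc[test_ids, "score"])
        assert auc > 0.85

    def test_shuffled_labels_give_chance_auroc(self):
        from sklearn.metrics import roc_auc_score

        rng = np.random.default_rng(3)
        aucs = []
        mat, y = self._planted(n=100, n_pep=40, n_info=0, seed=3)
        for rep in range(5):
            y_perm = pd.Series(rng.permutation(y.to_numpy()), index=y.index)
            model = train_model(_sub(mat, y.index[:50]), y_perm.iloc[:50])
            scores = score_matrix(_sub(mat, y.index[50:]), model)
            aucs.append(roc_auc_score(y_perm.iloc[50:], scores.iloc[:, 0]))
        assert abs(np.mean(aucs) - 0.5) <= 0.1


def _sub(mat, sample_ids):
    ids = list(sample_ids)
    return PeptideMatrix(mat.intensities[ids], mat.peptides)


class TestPrognosticTable:
    def test_all_events_above_cutoff(self):
        scores = pd.DataFrame(
            {"score": [0.8] * 15 + [0.3] * 30},
            index=[f"s{i}" for i in range(45)],
        )
        events = pd.Series([True] * 15 + [False] * 30, index=scores.index)
        tab = prognostic_table(scores, events, cutoff=0.55)
        assert tab.sensitivity == 1.0
        assert tab.npv == 1.0
        assert tab.events_below == 0
        assert tab.n_known == 45

    def test_degenerate_no_events_below_cutoff_only(self):
        scores = pd.DataFrame({"score": [0.1, 0.2, 0.3]}, index=list("abc"))
        events = pd.Series([False, False, False], index=list("abc"))
        tab = prognostic_table(scores, events, cutoff=0.55)
        assert tab.specificity == 1.0
        assert np.isnan(tab.sensitivity)
        assert tab.events_above + tab.events_below == 0

    def test_counts_sum_to_known_outcomes(self, rng):
        n = 50
        scores = pd.DataFrame({"score": rng.normal(0.5, 0.3, n)},
                              index=[f"s{i}" for i in range(n)])
        ev = pd.Series(pd.array(rng.integers(0, 2, n), dtype="boolean"),
                       index=scores.index)
        ev.iloc[:5] = pd.NA
        tab = prognostic_table(scores, ev, cutoff=0.55)
        assert tab.n_known == n - 5
        assert tab.n_unknown_outcome == 5

    def test_null_npv_tracks_event_rate(self):
        rng = np.random.default_rng(0)
        n = 1000
        scores = pd.DataFrame({"score": rng.uniform(0, 1, n)},
                              index=[f"s{i}" for i in range(n)])
        rate = 0.2
        events = pd.Series(rng.uniform(size=n) < rate, index=scores.index)
        tab = prognostic_table(scores, events, cutoff=0.5)
        assert tab.npv == pytest.approx(1 - rate, abs=0.05)

    def test_no_overlap_rejected(self):
        scores = pd.DataFrame({"score": [0.1]}, index=["a"])
        with pytest.raises(ValidationError):
            prognostic_table(scores, pd.Series([True], index=["z"]))


class TestModelJson:
    def test_round_trip(self):
        m = model_of([("p1", 1000.0, 20.0, 0.25)], offset=-0.1, cutoff=0.55)
        m2 = ClassifierModel.from_json(m.to_json())
        pd.testing.assert_frame_equal(m.panel, m2.panel)
        assert m2.offset == m.offset and m2.cutoff == m.cutoff

    def test_malformed_rejected(self):
        with pytest.raises(ValidationError):
            ClassifierModel.from_json('{"panel": []}')
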