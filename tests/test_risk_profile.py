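"""Tests for stepwise profile construction, scoring, classification,
calibration and validation transfer."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from cumulrisk import (
    RiskModel,
    apply_to_cohort,
    auc_mann_whitney,
    classify_and_summarize,
    hosmer_lemeshow,
    read_model,
    roc_points,
    score,
    stepwise_select,
    variance_partition,
    write_model,
)

from conftest import toy_cohort


def _scores_frame(p_hat, sample_ids=None):
    p_hat = np.asarray(p_hat, dtype=float)
    y_hat = np.log(p_hat / (1 - p_hat))
    return pd.DataFrame(
        {
            "sample_id": sample_ids or [f"S{i}" for i in range(len(p_hat))],
            "y_hat": y_hat,
            "p_hat": p_hat,
            "predicted_label": (y_hat > 0).astype(int),
        }
    )


class TestStepwise:
    def _cohort_with_signal(self, seed, n_noise=5, n=4000, beta=np.log(1.8)):
        rng = np.random.default_rng(seed)
        x = rng.binomial(2, 0.3, n).astype(float)
        noise = {f"n{i}": rng.binomial(2, 0.3, n).astype(float) for i in range(n_noise)}
        eta = -1.0 + beta * x
        y = (rng.random(n) < 1 / (1 + np.exp(-eta))).astype(int)
        return toy_cohort({"causal": x, **noise}, y), ["causal"] + list(noise)

    def test_recovers_single_causal_marker(self):
        """At OR 1.8 / n=4000 the causal marker is selected, with a strict
        entry threshold keeping noise markers out, in nearly all replicates."""
        exact = 0
        for seed in range(10):
            c, cand = self._cohort_with_signal(seed)
            model = stepwise_select(c, cand, entry_p=0.01, stay_p=0.01)
            exact += model.marker_ids == ["causal"]
        assert exact >= 9

    def test_zero_entry_threshold_gives_covariates_only(self):
        c, cand = self._cohort_with_signal(0)
        model = stepwise_select(c, cand, entry_p=0.0, stay_p=0.05)
        assert model.marker_ids == []

    def test_duplicate_markers_select_at_most_one(self):
        rng = np.random.default_rng(5)
        n = 3000
        x = rng.binomial(2, 0.3, n).astype(float)
        eta = -1.0 + 0.6 * x
        y = (rng.random(n) < 1 / (1 + np.exp(-eta))).astype(int)
        c = toy_cohort({"d1": x, "d2": x.copy()}, y)
        model = stepwise_select(c, ["d1", "d2"], 0.05, 0.05)
        assert len(model.marker_ids) <= 1

    def test_forward_lr_and_score_methods_agree_on_selection(self):
        c, cand = self._cohort_with_signal(7)
        a = stepwise_select(c, cand, 0.01, 0.01, forward_method="score")
        b = stepwise_select(c, cand, 0.01, 0.01, forward_method="lr")
        assert a.marker_ids == b.marker_ids

    def test_invalid_thresholds_rejected(self):
        c, cand = self._cohort_with_signal(1)
        with pytest.raises(ValueError):
            stepwise_select(c, cand, entry_p=0.1, stay_p=0.05)


class TestScore:
    def _unit_model(self, **kw):
        defaults = dict(
            marker_ids=["m"],
            marker_betas=np.array([0.5]),
            covariate_betas={},
            intercept=-1.0,
            center_levels=["A"],
        )
        defaults.update(kw)
        return RiskModel(**defaults)

    def test_zero_linear_predictor_gives_half_probability(self):
        # intercept -1, one marker beta 0.5, dosage 2 -> y_hat = 0
        c = toy_cohort({"m": np.array([2.0, 0.0])}, np.array([1, 0]))
        sc = score(self._unit_model(), c)
        assert sc["y_hat"].iloc[0] == pytest.approx(0.0)
        assert sc["p_hat"].iloc[0] == pytest.approx(0.5)
        assert sc["predicted_label"].iloc[0] == 0  # classified case only if >0

    def test_sigmoid_saturation(self):
        m = self._unit_model(intercept=20.0, marker_ids=[], marker_betas=np.array([]))
        c = toy_cohort({"m": np.array([0.0])}, np.array([1]))
        sc = score(m, c)
        assert sc["p_hat"].iloc[0] > 0.9999
        assert sc["predicted_label"].iloc[0] == 1

    def test_unknown_center_error_lists_valid_labels(self):
        m = self._unit_model(covariate_betas={"center[B]": 0.3},
                             center_levels=["A", "B"])
        c = toy_cohort({"m": np.array([1.0])}, np.array([1]), center=["Z"])
        with pytest.raises(KeyError, match="A"):
            score(m, c)

    def test_missing_marker_error(self):
        m = self._unit_model(marker_ids=["ghost"])
        c = toy_cohort({"m": np.array([1.0])}, np.array([1]))
        with pytest.raises(KeyError, match="ghost"):
            score(m, c)


class TestClassification:
    def test_perfect_separation_summary(self):
        sc = _scores_frame([0.9, 0.8, 0.2, 0.1])
        s = classify_and_summarize(sc, np.array([1, 1, 0, 0]))
        assert (s.sensitivity, s.specificity, s.auc) == (1.0, 1.0, 1.0)

    def test_worked_three_by_three_example(self):
        sc = _scores_frame([0.9, 0.6, 0.4, 0.7, 0.3, 0.2])
        y = np.array([1, 1, 1, 0, 0, 0])
        s = classify_and_summarize(sc, y)
        assert s.sensitivity == pytest.approx(2 / 3)
        assert s.specificity == pytest.approx(2 / 3)
        # exhaustive pair count: 0.9 beats 3 controls, 0.6 and 0.4 beat 2 each
        assert s.auc == pytest.approx(7 / 9)

    def test_random_scores_give_half_auc(self):
        rng = np.random.default_rng(12)
        v = rng.random(4000)
        y = (rng.random(4000) < 0.5).astype(int)
        assert auc_mann_whitney(v, y) == pytest.approx(0.5, abs=0.03)

    def test_auc_matches_sklearn_and_trapezoid(self):
        from sklearn.metrics import roc_auc_score

        rng = np.random.default_rng(9)
        v = np.round(rng.random(500), 2)  # force ties
        y = (rng.random(500) < 0.4).astype(int)
        mine = auc_mann_whitney(v, y)
        assert mine == pytest.approx(roc_auc_score(y, v), abs=1e-12)
        pts = roc_points(v, y)
        trap = np.trapezoid(pts["tpr"], pts["fpr"])
        assert mine == pytest.approx(trap, abs=1e-12)

    def test_empty_group_rejected(self):
        sc = _scores_frame([0.4, 0.6])
        with pytest.raises(ValueError):
            classify_and_summarize(sc, np.array([1, 1]))

    def test_quantiles_use_linear_interpolation(self):
        sc = _scores_frame([0.1, 0.2, 0.3, 0.4, 0.9])
        y = np.array([0, 0, 0, 0, 1])
        s = classify_and_summarize(sc, y)
        assert s.control_quantiles[1] == pytest.approx(0.25)


class TestHosmerLemeshow:
    def test_perfectly_calibrated_bins_give_zero_statistic(self):
        # ten p levels; observed rate in each equals the level exactly
        p, y = [], []
        for lev, k in zip(np.linspace(0.05, 0.95, 10), [20] * 10):
            p += [lev] * k
            y += [1] * int(round(lev * k)) + [0] * (k - int(round(lev * k)))
        res = hosmer_lemeshow(np.array(p), np.array(y), g=10)
        assert res.hl_statistic == pytest.approx(0.0, abs=1e-9)
        assert res.df == 8

    def test_well_specified_model_is_calibrated(self):
        """Fitted correctly specified model: rejection ≈ nominal 5%."""
        from cumulrisk.glm_core import fit_logistic

        rng = np.random.default_rng(33)
        rejects = 0
        reps = 100
        for _ in range(reps):
            n = 1200
            X = np.column_stack([np.ones(n), rng.normal(size=(n, 2))])
            eta = X @ np.array([-0.3, 0.8, -0.5])
            y = (rng.random(n) < 1 / (1 + np.exp(-eta))).astype(float)
            fit = fit_logistic(X, y)
            p_hat = 1 / (1 + np.exp(-(X @ fit.coefficients)))
            rejects += hosmer_lemeshow(p_hat, y).p_value < 0.05
        assert rejects / reps < 0.12

    def test_miscalibrated_scores_rejected(self):
        rng = np.random.default_rng(14)
        n = 3000
        p_true = rng.uniform(0.05, 0.95, n)
        y = (rng.random(n) < p_true).astype(int)
        res = hosmer_lemeshow(p_true**2, y)  # systematically too low
        assert res.p_value < 0.01

    def test_degenerate_bins_are_merged(self):
        rng = np.random.default_rng(7)
        # a solid block of zero-probability scores creates empty-expectation
        # deciles that must fold into their neighbour
        p = np.r_[np.zeros(40), rng.uniform(0.2, 0.8, 160)]
        y = np.r_[np.zeros(40), (rng.random(160) < 0.5).astype(float)]
        res = hosmer_lemeshow(p, y, g=10)
        assert res.n_bins_merged > 0
        assert np.isfinite(res.hl_statistic)

    def test_constant_scores_do_not_crash(self):
        p = np.full(100, 0.5)
        y = np.r_[np.ones(50), np.zeros(50)]
        res = hosmer_lemeshow(p, y, g=10)
        assert np.isfinite(res.hl_statistic)


class TestVariancePartition:
    def test_increments_telescope_to_full_model_r2(self, small_cohort):
        from cumulrisk.glm_core import fit_logistic, nagelkerke_r2

        causal = small_cohort.truth.causal_marker_ids[:3]
        part = variance_partition(
            small_cohort,
            [("center", "center"), ("gender", "gender"), ("drb1", "drb1"),
             ("markers", causal)],
        )
        assert part["r2_increment"].sum() == pytest.approx(
            part["r2_cumulative"].iloc[-1], abs=1e-12
        )
        assert (part["r2_increment"] > -1e-9).all()

    def test_noise_block_adds_nothing(self, null_cohort):
        noise = list(null_cohort.dosages.columns[:3])
        part = variance_partition(null_cohort, [("noise", noise)])
        assert part["r2_increment"].iloc[0] < 0.01

    def test_major_locus_block_dominates_when_it_drives_liability(self):
        rng = np.random.default_rng(2)
        n = 3000
        carrier = rng.binomial(1, 0.3, n)
        weak = rng.binomial(2, 0.3, n).astype(float)
        eta = -1.5 + 2.5 * carrier + 0.1 * weak
        y = (rng.random(n) < 1 / (1 + np.exp(-eta))).astype(int)
        c = toy_cohort({"weak": weak}, y, drb1_status=carrier)
        part = variance_partition(c, [("drb1", "drb1"), ("weak", ["weak"])])
        assert part["r2_increment"].iloc[0] > 5 * part["r2_increment"].iloc[1]


class TestApplyToCohort:
    def _trained(self, small_cohort):
        markers = small_cohort.truth.causal_marker_ids[:5]
        return stepwise_select(small_cohort, markers, 0.05, 0.05)

    def test_frozen_on_training_cohort_reproduces_training_summary(self, small_cohort):
        model = self._trained(small_cohort)
        sc = score(model, small_cohort)
        direct = classify_and_summarize(sc, small_cohort.y)
        _, summary = apply_to_cohort(model, small_cohort, mode="frozen")
        assert summary == direct

    def test_refit_on_training_cohort_recovers_training_coefficients(
        self, small_cohort
    ):
        model = self._trained(small_cohort)
        used, _ = apply_to_cohort(model, small_cohort, mode="refit")
        np.testing.assert_allclose(
            used.marker_betas, model.marker_betas, atol=1e-6
        )
        assert used.intercept == pytest.approx(model.intercept, abs=1e-6)

    def test_noise_trained_model_has_no_transfer_auc(self):
        """Optimism exposure: a profile stepwise-fitted to pure noise shows
        AUC ≈ 0.5 on an independent null cohort."""
        rng = np.random.default_rng(44)
        n = 1500

        def null_cohort(seed):
            r = np.random.default_rng(seed)
            cols = {f"m{i}": r.binomial(2, 0.3, n).astype(float) for i in range(30)}
            y = (r.random(n) < 0.4).astype(int)
            return toy_cohort(cols, y)

        train = null_cohort(1)
        valid = null_cohort(2)
        model = stepwise_select(train, list(train.dosages.columns), 0.05, 0.05)
        _, s_train = apply_to_cohort(model, train, mode="frozen")
        _, s_valid = apply_to_cohort(model, valid, mode="frozen")
        assert s_train.auc > s_valid.auc
        assert abs(s_valid.auc - 0.5) < 0.06

    def test_missing_marker_in_validation_is_reported(self, small_cohort):
        model = self._trained(small_cohort)
        sub = small_cohort.dosages.drop(columns=model.marker_ids[:1])
        from cumulrisk import Cohort

        broken = Cohort(sub, small_cohort.samples,
                        small_cohort.markers, small_cohort.truth)
        with pytest.raises(KeyError, match=model.marker_ids[0]):
            apply_to_cohort(model, broken, mode="frozen")


class TestModelFile:
    def test_round_trip(self, tmp_path, small_cohort):
        markers = small_cohort.truth.causal_marker_ids[:4]
        model = stepwise_select(small_cohort, markers, 0.05, 0.05)
        write_model(model, tmp_path / "m.tsv")
        back = read_model(tmp_path / "m.tsv")
        assert back.marker_ids == model.marker_ids
        np.testing.assert_allclose(back.marker_betas, model.marker_betas)
        assert back.covariate_betas == pytest.approx(model.covariate_betas)
        assert back.intercept == model.intercept
        assert back.center_levels == model.center_levels
        # scoring with the reloaded model is identical
        a = score(model, small_cohort)["p_hat"]
        b = score(back, small_cohort)["p_hat"]
        np.testing.assert_allclose(a, b, atol=1e-15)

    def test_malformed_file_reports_line(self, tmp_path):
        f = tmp_path / "bad.tsv"
        f.write_text("term\tcoefficient\nintercept\t0.0\nmarker:x\toops\n")
        with pytest.raises(ValueError, match="line 3"):
            read_model(f)
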