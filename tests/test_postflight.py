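import numpy as np
import pandas as pd
import pytest

import astrobiodose as abd
from astrobiodose import glmm
from astrobiodose.cohort import COLUMNS
from astrobiodose.postflight import (
    PostflightFit,
    PredictorCombination,
    assemble_postflight_design,
    fit_dose_rate_variant,
    predict_combinations,
    recovery_test,
)
from astrobiodose.simulate import SimConfig

# published post-flight coefficient estimates, model order
# (const, BFO dose, age-50, female, w0, w1*x)
PUB_POST = [-5.751, 14.746, 0.025, 0.162, 0.704, 6.268]

# printed predictor combinations and CAR% (dose Gy, age, female, w1, CAR%)
PUB_COMBOS = [
    ("C1", 0.011, 50, 0, 0.00, 0.37),
    ("C2", 0.011, 50, 1, 0.00, 0.44),
    ("C3", 0.028, 50, 0, 0.00, 0.48),
    ("C4", 0.028, 50, 1, 0.00, 0.56),
    ("C5", 0.041, 50, 0, 0.00, 0.58),
    ("C6", 0.041, 50, 1, 0.00, 0.69),
    ("C7", 0.028, 60, 0, 0.00, 0.61),
    ("C8", 0.028, 50, 0, -0.77, 0.42),
    ("C9", 0.028, 50, 0, 0.77, 0.55),
]


class TestAssembleDesign:
    def test_row_bookkeeping(self, default_cohort, pre_fit_nb):
        cohort, truth = default_cohort
        design = assemble_postflight_design(cohort, pre_fit_nb)
        n_early = int(truth.subjects["has_early"].sum())
        n_late = int(truth.subjects["has_late"].sum())
        assert design.n_baseline == 43
        assert design.n_post == n_early + n_late == 39 + 31
        assert len(design.df) == 43 + 39 + 31

    def test_stage1_with_baseline_rejected(self, default_cohort, pre_fit_full):
        cohort, _ = default_cohort
        with pytest.raises(ValueError, match="baseline"):
            assemble_postflight_design(cohort, pre_fit_full)

    def test_baseline_rows_have_zero_exposure(self, default_cohort, pre_fit_nb):
        cohort, _ = default_cohort
        design = assemble_postflight_design(cohort, pre_fit_nb)
        base = design.df["phase"] == "pre"
        assert (design.df.loc[base, "x"] == 0).all()
        assert (design.df.loc[base, "w1x"] == 0).all()

    def test_subject_permutation_leaves_likelihood(self, default_cohort,
                                                   pre_fit_nb):
        cohort, _ = default_cohort
        design = assemble_postflight_design(cohort, pre_fit_nb)
        params = glmm.pack_params(np.array(PUB_POST), [0.3])
        a = glmm.marginal_loglik(params, design.spec, design.counts)
        shuffled = abd.CohortTable(
            cohort.df.sample(frac=1.0, random_state=5)[COLUMNS]
        )
        design2 = assemble_postflight_design(shuffled, pre_fit_nb)
        b = glmm.marginal_loglik(params, design2.spec, design2.counts)
        assert b == pytest.approx(a, abs=1e-8)


class TestPredictCombinations:
    def test_reproduces_published_car_percent(self):
        pf = PostflightFit.from_coefficients(PUB_POST)
        combos = [
            PredictorCombination(lbl, d, age, f, 0.0, w1)
            for lbl, d, age, f, w1, _ in PUB_COMBOS
        ]
        tab = predict_combinations(pf, combos)
        for (_, _, _, _, _, car), got in zip(PUB_COMBOS, tab["car_pct"]):
            assert got == pytest.approx(car, abs=0.01)

    def test_zero_dose_gives_exp_beta0(self):
        pf = PostflightFit.from_coefficients(PUB_POST)
        tab = predict_combinations(
            pf, [PredictorCombination("z", 0.0, 50, 0, 0.0, 0.0)]
        )
        assert tab["car_pct"].iloc[0] == pytest.approx(100 * np.exp(-5.751))

    def test_monotone_in_dose_when_slope_positive(self):
        pf = PostflightFit.from_coefficients(PUB_POST)
        doses = np.linspace(0.0, 0.05, 8)
        tab = predict_combinations(
            pf,
            [PredictorCombination(f"d{i}", d, 50, 0, 0.0, 0.5)
             for i, d in enumerate(doses)],
        )
        assert np.all(np.diff(tab["car_pct"]) > 0)

    def test_predict_rate_worked_examples(self):
        fit = glmm.MixedPoissonFit.from_coefficients(
            ["const", "x", "a50", "female", "w0", "w1x"], PUB_POST
        )
        rate, _, _ = glmm.predict_rate(
            fit, {"x": 0.011, "a50": 0.0, "female": 0, "w0": 0.0, "w1x": 0.0}
        )
        assert rate == pytest.approx(0.0037, abs=1e-4)
        rate, _, _ = glmm.predict_rate(
            fit, {"x": 0.028, "a50": 10.0, "female": 0, "w0": 0.0, "w1x": 0.0}
        )
        assert rate == pytest.approx(0.0061, abs=1e-4)


class TestPostflightFit:
    def test_intercept_effect_positive_under_shared_background(self, post_fit):
        # truth shares the subject background between baseline and post rows
        assert post_fit.coef("w0") > 0

    def test_prediction_rmse_near_sampling_noise(self, post_fit):
        d = post_fit.design.df
        eta = post_fit.design.spec.X @ post_fit.fit.beta
        obs = d["aberrations"] / d["cells_scored"]
        pred = np.exp(eta)
        rmse = np.sqrt(np.mean((obs - pred) ** 2))
        binom_sd = np.sqrt(np.mean(pred / d["cells_scored"]))
        assert rmse < 2.0 * binom_sd


class TestDoseRateVariant:
    def test_dose_rates_in_published_band(self, default_cohort, pre_fit_nb):
        cohort, _ = default_cohort
        cmp = fit_dose_rate_variant(cohort, pre_fit_nb)
        rates = cmp.dose_rates_cGy_day
        assert rates.between(0.012, 0.024).all()
        assert np.isfinite(cmp.aic_rate) and np.isfinite(cmp.aic_dose)

    def test_constant_duration_is_pure_rescaling(self):
        cohort, _ = abd.simulate_cohort(SimConfig(seed=21))
        df = cohort.df.copy()
        df["mission_duration_days"] = 150.0
        fixed = abd.CohortTable(df[COLUMNS])
        pre = abd.fit_preflight(fixed, include_baseline=False)
        cmp = fit_dose_rate_variant(fixed, pre)
        assert cmp.rate_fit.fit.loglik == pytest.approx(
            cmp.dose_fit.fit.loglik, abs=1e-3
        )
        # x is rescaled by duration/100 (cGy/day), so the slope scales back
        assert cmp.rate_fit.coef("x") == pytest.approx(
            1.5 * cmp.dose_fit.coef("x"), rel=1e-2
        )

    def test_missing_duration_rejected(self, default_cohort, pre_fit_nb):
        cohort, _ = default_cohort
        df = cohort.df.copy()
        df.loc[df["phase"] == "post", "mission_duration_days"] = np.nan
        with pytest.raises(ValueError, match="duration"):
            fit_dose_rate_variant(abd.CohortTable(df[COLUMNS]), pre_fit_nb)


class TestRecovery:
    def _cohort_with_post(self, pairs):
        recs = []
        for i, (k1, k2) in enumerate(pairs):
            common = dict(
                subject_id=f"S{i}", astronaut_id=f"A{i}", mission_number=1,
                age_years=45.0, female=0, mission_duration_days=150.0,
            )
            recs.append(abd.SampleRecord(
                phase="pre", timepoint="baseline", dose_Gy=0.0,
                cells_scored=8000, aberrations=20, **common))
            recs.append(abd.SampleRecord(
                phase="post", timepoint="post_early", dose_Gy=0.02,
                cells_scored=8000, aberrations=k1, **common))
            recs.append(abd.SampleRecord(
                phase="post", timepoint="post_late", dose_Gy=0.02,
                cells_scored=8000, aberrations=k2, **common))
        return abd.CohortTable.from_records(recs)

    def test_identical_timepoints_give_null_result(self):
        res = recovery_test(self._cohort_with_post([(30, 30), (40, 40), (25, 25)]))
        assert res.t == 0.0 and res.p == 1.0 and res.n_pairs == 3

    def test_pair_count_and_means(self, default_cohort):
        cohort, _ = default_cohort
        res = recovery_test(cohort)
        assert res.n_pairs == 31
        assert 0.002 < res.mean_early < 0.01

    def test_halved_late_rates_detected(self):
        hits = 0
        for seed in range(20):
            cohort, _ = abd.simulate_cohort(
                SimConfig(seed=700 + seed, late_rate_mult=0.5)
            )
            hits += recovery_test(cohort).p < 0.05
        assert hits >= 16  # >= 80% power at default cell counts

    def test_too_few_pairs_rejected(self):
        with pytest.raises(ValueError):
            recovery_test(self._cohort_with_post([(30, 31)]))


def test_plugin_truth_never_attenuates_signal(default_cohort):
    """Using the true random effects instead of EB estimates should not
    weaken the radiosensitivity term (EB plug-ins are attenuated by
    estimation error)."""

    class _TruthStage1:
        include_baseline = False

        def __init__(self, truth):
            self._df = truth.subjects.rename(columns={"W0": "w0", "W1": "w1"})

        def subject_effects(self):
            return self._df[["subject_id", "w0", "w1"]]

    z_eb, z_true = [], []
    for seed in range(4):
        cohort, truth = abd.simulate_cohort(
            SimConfig(seed=300 + seed, n_subjects=60, female_count=14)
        )
        pre = abd.fit_preflight(cohort, include_baseline=False)
        post_eb = abd.fit_postflight(assemble_postflight_design(cohort, pre))
        post_tr = abd.fit_postflight(
            assemble_postflight_design(cohort, _TruthStage1(truth))
        )
        z_eb.append(post_eb.coef("w1x") / post_eb.fit.coef_se("w1x"))
        z_true.append(post_tr.coef("w1x") / post_tr.fit.coef_se("w1x"))
    assert np.mean(z_true) >= np.mean(z_eb) - 0.5
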