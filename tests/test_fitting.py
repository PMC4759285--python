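"""Quantile chi-square objective and constrained simplex fitting."""

import pytest

from lexddm.params import CORRECT_SIDE, REFERENCE_PARAMS
from lexddm.predict import predict_condition
from lexddm.fitting import (
    FitSpec,
    FitSpecError,
    QuantileDiffusionModel,
    binned_statistic,
    compare_models,
    quantile_objective,
)
from lexddm.summaries import GroupData

PROBS = (0.1, 0.3, 0.5, 0.7, 0.9)


def prediction_group_data(params_by_condition, n=1000):
    """Grouped data whose summaries equal the model's own predictions
    (the infinite-N / expected-proportion construction)."""
    acc, ntr, cq, eq = {}, {}, {}, {}
    for cond, p in params_by_condition.items():
        pred = predict_condition(p, cond[0])
        corr = CORRECT_SIDE[cond[0]]
        acc[cond] = pred.accuracy
        ntr[cond] = n
        cq[cond] = pred.quantiles_ms(corr)
        eq[cond] = pred.quantiles_ms(corr.opposite)
    return GroupData(PROBS, acc, ntr, cq, eq)


FAST_FIT = dict(n_restarts=1, maxiter_restart=150, maxiter_polish=400)


class TestObjective:
    def test_hand_computed_chi_square(self):
        """One condition, N=100: only the last two bins differ by 0.01
        against predicted masses of 0.05, so X^2 = 100*2*(0.01^2/0.05) = 0.4."""
        obs = (0.1, 0.2, 0.2, 0.2, 0.2, 0.06, 0.04)
        pred = (0.1, 0.2, 0.2, 0.2, 0.2, 0.05, 0.05)
        assert binned_statistic(100, obs, pred, "chisq") == pytest.approx(0.4)

    def test_gsq_zero_iff_equal(self):
        obs = (0.1, 0.2, 0.3, 0.4)
        assert binned_statistic(50, obs, obs, "gsq") == pytest.approx(0.0)
        assert binned_statistic(50, obs, (0.15, 0.15, 0.3, 0.4), "gsq") > 0

    def test_self_fit_objective_is_zero(self):
        gd = prediction_group_data(REFERENCE_PARAMS)
        assert quantile_objective(gd, REFERENCE_PARAMS) == pytest.approx(0.0, abs=1e-4)

    def test_truth_beats_perturbed_drifts_on_expected_proportions(self):
        gd = prediction_group_data(REFERENCE_PARAMS)
        perturbed = {c: p.replace(v=p.v + 0.1) for c, p in REFERENCE_PARAMS.items()}
        assert quantile_objective(gd, REFERENCE_PARAMS) < quantile_objective(gd, perturbed)

    def test_invariant_to_condition_ordering(self):
        gd = prediction_group_data(REFERENCE_PARAMS)
        order = list(REFERENCE_PARAMS)[::-1]
        gd_rev = GroupData(
            gd.quantile_probs,
            {c: gd.accuracy[c] for c in order},
            {c: gd.n_trials[c] for c in order},
            {c: gd.correct_quantiles_ms[c] for c in order},
            {c: gd.error_quantiles_ms[c] for c in order},
        )
        assert quantile_objective(gd, REFERENCE_PARAMS) == pytest.approx(
            quantile_objective(gd_rev, REFERENCE_PARAMS)
        )


class TestFitSpec:
    def test_missing_status_rejected(self):
        with pytest.raises(FitSpecError):
            FitSpec(statuses={"v": ("free",)})

    def test_bad_status_rejected(self):
        statuses = FitSpec.constrained().statuses | {"a": ("fixed",)}
        with pytest.raises(FitSpecError):
            FitSpec(statuses=statuses)

    def test_roundtrip_serialization(self):
        spec = FitSpec.constrained(objective="gsq", n_restarts=3)
        back = FitSpec.from_dict(spec.to_dict())
        assert back == spec

    def test_constraint_scheme_frees_drift_and_ter_only(self):
        spec = FitSpec.constrained()
        entries = spec.free_entries(tuple(REFERENCE_PARAMS))
        names = [n for n, _ in entries]
        assert names.count("v") == 4 and names.count("t_er") == 4
        assert names.count("a") == 1 and len(entries) == 9
        reduced = FitSpec.drift_only().free_entries(tuple(REFERENCE_PARAMS))
        assert len(reduced) == 6


class TestFit:
    def test_all_fixed_spec_returns_fixed_values(self):
        shared = {c: REFERENCE_PARAMS[("word", "nonrepeated")] for c in REFERENCE_PARAMS}
        gd = prediction_group_data(shared)
        spec = FitSpec.all_fixed(shared)
        res = QuantileDiffusionModel(gd, spec).fit(seed=0)
        assert res.n_free == 0 and res.converged
        for c, p in res.params_by_condition.items():
            assert p == shared[c]
        assert res.objective == pytest.approx(quantile_objective(gd, shared))

    def test_fit_recovers_truth_from_expected_proportions(self):
        """On noise-free grouped data the constrained fit drives the
        objective to ~0 and lands near the generating parameters."""
        gd = prediction_group_data(REFERENCE_PARAMS)
        res = QuantileDiffusionModel(gd, FitSpec.constrained(**FAST_FIT)).fit(seed=0)
        assert res.objective < 0.5
        for c, p in res.params_by_condition.items():
            assert p.v == pytest.approx(REFERENCE_PARAMS[c].v, abs=0.03)
            assert p.t_er == pytest.approx(REFERENCE_PARAMS[c].t_er, abs=0.01)

    def test_fit_deterministic_given_seed(self):
        gd = prediction_group_data(REFERENCE_PARAMS)
        spec = FitSpec.constrained(n_restarts=2, maxiter_restart=60, maxiter_polish=60)
        r1 = QuantileDiffusionModel(gd, spec).fit(seed=5)
        r2 = QuantileDiffusionModel(gd, spec).fit(seed=5)
        assert r1.objective == r2.objective
        assert r1.params_by_condition == r2.params_by_condition

    def test_summary_reports_fit(self):
        gd = prediction_group_data(REFERENCE_PARAMS)
        res = QuantileDiffusionModel(gd, FitSpec.all_fixed(
            {c: REFERENCE_PARAMS[("word", "nonrepeated")] for c in REFERENCE_PARAMS}
        )).fit()
        text = res.summary()
        assert "objective" in text and "accuracy" in text


class TestModelComparison:
    def test_nesting_and_improvement_on_expected_data(self):
        """The reduced (drift-only) model cannot absorb a t_er difference;
        the full model is never worse and strictly better here."""
        gd = prediction_group_data(REFERENCE_PARAMS)
        cmp = compare_models(
            gd,
            spec_full=FitSpec.constrained(**FAST_FIT),
            spec_reduced=FitSpec.drift_only(**FAST_FIT),
            seed=0,
        )
        assert cmp.valid
        assert cmp.objective_full <= cmp.objective_reduced + 1e-6
        assert cmp.improvement > 0
        assert cmp.n_free_full == 9 and cmp.n_free_reduced == 6

    def test_identical_specs_give_zero_improvement(self):
        gd = prediction_group_data(REFERENCE_PARAMS)
        spec = FitSpec.constrained(**FAST_FIT)
        cmp = compare_models(gd, spec_full=spec, spec_reduced=spec, seed=0)
        assert abs(cmp.improvement) < 0.05
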