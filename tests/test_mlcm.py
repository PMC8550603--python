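"""Design construction, probit ML fitting and the likelihood-ratio battery."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from regtex import SimulatedObserver, simulate_observer
from regtex.conditions import all_conditions
from regtex.conjoint import table_from_pair_counts
from regtex.mlcm import (BATTERY, FREE_PARAMETER_COUNTS, MODEL_IDS,
                         build_design, fit_model, fit_probit,
                         full_model_estimates, interaction_profile,
                         jitter_effect_ratio, lr_test, model_spec,
                         normalize_group, run_comparisons)
from regtex.stimuli import synthetic_observer_means

#: Nested model pairs implied by the battery structure.
NESTED_CHAINS = [(1, 2), (1, 3), (1, 4), (2, 5), (4, 5), (3, 6), (4, 6),
                 (2, 7), (3, 7), (5, 8), (6, 9), (7, 10), (8, 11), (9, 11),
                 (10, 11), (5, 11), (6, 11), (7, 11), (11, 12)]


@pytest.mark.parametrize("model_id", MODEL_IDS)
def test_free_parameter_counts_and_rank(model_id, synthetic_table):
    spec = model_spec(model_id)
    assert spec.free_parameter_count == FREE_PARAMETER_COUNTS[model_id]
    design = build_design(model_id, synthetic_table)
    assert design.X.shape == (1035, spec.free_parameter_count)
    assert design.column_rank() == spec.free_parameter_count
    assert set(np.unique(design.X)) <= {-1.0, 0.0, 1.0}


def test_reference_levels_fixed_at_zero():
    spec = model_spec(12)
    ref = [c for c in all_conditions()
           if (c.spacing_level, c.size_level, c.jitter_level) == (1, 1, 1)][0]
    assert not spec.condition_row(ref).any()
    assert "sp1.sz1.jt1" not in spec.parameter_names


def test_null_model_loglik_closed_form(synthetic_table):
    fit = fit_model(1, synthetic_table)
    assert fit.coefficients.empty
    assert fit.log_likelihood == pytest.approx(4140 * np.log(0.5))


def test_probit_fit_matches_inverse_cdf_oracle():
    """On isolated pairs the ML estimate is the probit of the observed rate."""
    # pairs (jitter 1 vs jitter k), conditions 0 and 9(k-1) in canonical order
    firsts = [0, 0, 0, 0]
    seconds = [9, 18, 27, 36]
    wins = [21, 9, 5, 1]
    table = table_from_pair_counts(firsts, seconds, wins, 30)
    fit = fit_model(4, table)
    for k, w in zip(range(2, 6), wins):
        expected = -stats.norm.ppf(w / 30)
        assert fit.coefficients[f"jt{k}"] == pytest.approx(expected, abs=1e-6)


def test_irls_matches_statsmodels_glm(synthetic_table):
    """Independent cross-check of the probit optimiser."""
    import statsmodels.api as sm

    design = build_design(5, synthetic_table)
    fit = fit_probit(design)
    glm = sm.GLM(np.column_stack([design.successes,
                                  design.totals - design.successes]),
                 design.X,
                 family=sm.families.Binomial(sm.families.links.Probit()))
    res = glm.fit()
    assert np.allclose(fit.coefficients.to_numpy(), res.params, atol=1e-6)
    assert fit.standard_errors.to_numpy() == pytest.approx(res.bse, abs=1e-5)
    # statsmodels llf includes the binomial coefficient; compare deviances
    assert fit.residual_deviance == pytest.approx(res.deviance, abs=1e-6)


def test_deviance_monotone_under_nesting(synthetic_table):
    fits = {mid: fit_model(mid, synthetic_table) for mid in MODEL_IDS}
    for simple, complex_ in NESTED_CHAINS:
        assert (fits[simple].residual_deviance
                >= fits[complex_].residual_deviance - 1e-6)
        res = lr_test(fits[simple], fits[complex_])
        assert res.degrees_of_freedom == (
            FREE_PARAMETER_COUNTS[complex_] - FREE_PARAMETER_COUNTS[simple])
        assert res.deviance_difference >= 0.0


def test_identical_models_lrt_trivial(synthetic_table):
    fit = fit_model(4, synthetic_table)
    res = lr_test(fit, fit)
    assert res.deviance_difference == 0.0
    assert res.p_value == 1.0


def test_battery_structure_and_jitter_dominance(synthetic_table):
    battery, fits = run_comparisons(synthetic_table)
    assert list(battery.index) == [name for name, _, _ in BATTERY]
    assert len(battery) == 7
    dev = battery["deviance"]
    assert dev["main_jitter"] > 5 * dev["main_spacing"]
    assert dev["main_jitter"] > 5 * dev["main_size"]
    assert battery.loc["main_jitter", "significant"]
    assert (battery["df"] == [2, 2, 4, 8, 8, 4, 16]).all()


def test_additive_observer_shows_no_interaction(pairs45):
    """Means a_i + c_k leave the spacing x jitter interaction test null."""
    means = np.zeros(45)
    for cond in all_conditions():
        means[cond.index] = (0.3 * (cond.spacing_level - 1)
                             - 0.8 * (cond.jitter_level - 1))
    obs = SimulatedObserver(condition_means=means)
    table = simulate_observer(obs, pairs45, 4, seed=33)
    battery, _ = run_comparisons(table)
    assert not battery.loc["interaction_spacing_jitter", "significant"]
    assert battery.loc["main_spacing", "significant"]


def test_full_model_recovers_generating_means(pairs45):
    """Fixed-SD simulation refit with the full model lies on the diagonal."""
    means = synthetic_observer_means()
    obs = SimulatedObserver(condition_means=means)
    table = simulate_observer(obs, pairs45, 100, seed=17)
    est = full_model_estimates(fit_model(12, table))
    true = means - means[0]
    slope, intercept = np.polyfit(true, est.to_numpy(), 1)
    assert slope == pytest.approx(1.0, abs=0.06)
    assert intercept == pytest.approx(0.0, abs=0.1)


def test_interaction_ratio_matches_generator(pairs45):
    """The spacing x jitter profile shows a stronger jitter effect at
    small spacing, in rough proportion to the generator's gain ratio."""
    means = synthetic_observer_means()
    obs = SimulatedObserver(condition_means=means)
    table = simulate_observer(obs, pairs45, 60, seed=19)
    profile = interaction_profile(fit_model(8, table))
    ratio = jitter_effect_ratio(profile, 1, 3)
    # probit fitting marginalises over size nonlinearly, compressing the
    # generator's 1.87 gain ratio; the direction and rough size must hold
    assert 1.3 < ratio < 2.1


def test_normalize_group_anchor_convention():
    est = pd.Series({"sp2": 0.2, "jt5": -2.0})
    group = normalize_group([est], anchor="jt5")
    assert group.mean["jt5"] == pytest.approx(-1.0)
    assert group.mean["sp2"] == pytest.approx(0.1)
    # sign convention holds even for a positive anchor estimate
    flipped = normalize_group([-est], anchor="jt5")
    assert flipped.mean["jt5"] == pytest.approx(-1.0)


def test_normalize_group_max_abs():
    est = pd.Series({"a": 1.0, "b": -4.0})
    group = normalize_group([est], anchor="max_abs")
    assert group.mean["b"] == pytest.approx(-1.0)
    assert group.mean["a"] == pytest.approx(0.25)
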