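"""Discount functions, indifference residuals, per-subject fitting."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from betadelta.discounting import (
    closed_form_oracle, discount_weight, fit_discount_model,
    indifference_residuals,
)
from betadelta.elicitation import SwitchPoint

DELAYS = [(0.0, 1.0 / 30.0), (0.0, 1.0), (1.0, 2.0)]


def sp(value, censoring="interior", half=0.25):
    return SwitchPoint(value=value, censoring=censoring, half_step=half)


def consistent_switch_points(alpha, beta, delta):
    """Switch points that exactly rationalise (beta, delta) at curvature alpha."""
    vals = [
        (10.0 ** alpha / (beta * delta ** (1 / 30))) ** (1 / alpha),
        (10.0 ** alpha / (beta * delta)) ** (1 / alpha),
        10.0 / delta ** (1 / alpha),
    ]
    return [sp(v) for v in vals]


@pytest.mark.parametrize(
    "model, t, params, expected",
    [
        ("quasi_hyperbolic", 0.0, {"beta": 0.5, "delta": 0.9}, 1.0),
        ("exponential", 2.0, {"delta": 0.5}, 0.25),
        ("hyperbolic", 1.0, {"k": 1.08}, 0.480769),
        ("quasi_hyperbolic", 1.0, {"beta": 0.84, "delta": 0.58}, 0.4872),
    ],
)
def test_discount_weight_values(model, t, params, expected):
    assert discount_weight(model, t, params) == pytest.approx(expected, abs=1e-6)


def test_discount_weight_validation():
    with pytest.raises(ValueError):
        discount_weight("weibull", 1.0, {})
    with pytest.raises(ValueError):
        discount_weight("exponential", -1.0, {"delta": 0.9})
    with pytest.raises(ValueError):
        discount_weight("exponential", 1.0, {"delta": 1.5})


@given(
    beta_is_one=st.just(1.0),
    delta=st.floats(min_value=0.05, max_value=1.0),
    t=st.floats(min_value=0.0, max_value=24.0),
)
@settings(deadline=None)
def test_quasi_with_unit_beta_equals_exponential(beta_is_one, delta, t):
    w_q = discount_weight("quasi_hyperbolic", t, {"beta": beta_is_one, "delta": delta})
    w_e = discount_weight("exponential", t, {"delta": delta})
    assert w_q == w_e


def test_residuals_zero_for_rationalising_params():
    sps = consistent_switch_points(1.2, 0.9, 0.8)
    r = indifference_residuals(sps, DELAYS, 1.2, "quasi_hyperbolic",
                               {"beta": 0.9, "delta": 0.8})
    assert np.allclose(r, 0.0, atol=1e-9)


def test_residuals_negative_without_discounting():
    sps = [sp(12.0), sp(14.0), sp(15.0)]
    r = indifference_residuals(sps, DELAYS, 1.0, "quasi_hyperbolic",
                               {"beta": 1.0, "delta": 1.0})
    assert np.all(r < 0)


def test_residual_closed_form_single_task():
    r = indifference_residuals([sp(12.5)], [(0.0, 1.0)], 1.0, "exponential",
                               {"delta": 0.8})
    assert r[0] == pytest.approx(0.0, abs=1e-12)


def test_fit_exponential_matches_analytic_solution():
    # mutually consistent exponential points at delta = 0.8, alpha = 1;
    # the month-delay indifference SP = 12.5 solves delta = 10/12.5 exactly
    vals = [10.0 / 0.8 ** (1 / 30), 10.0 / 0.8, 10.0 / 0.8]
    fit = fit_discount_model([sp(v) for v in vals], DELAYS, 1.0, "exponential")
    assert fit.converged
    assert fit.delta == pytest.approx(0.8, abs=1e-6)


def test_fit_exponential_matches_grid_search():
    sps = [sp(10.4), sp(13.0), sp(14.0)]  # not exactly consistent
    fit = fit_discount_model(sps, DELAYS, 1.0, "exponential")
    grid = np.linspace(1e-3, 1.0, 100_001)
    sp_vals = np.array([s.value for s in sps])
    t1 = np.array([d[0] for d in DELAYS])
    t2 = np.array([d[1] for d in DELAYS])
    rss = ((10.0 * grid[:, None] ** t1 - sp_vals * grid[:, None] ** t2) ** 2).sum(axis=1)
    assert fit.delta == pytest.approx(grid[np.argmin(rss)], abs=1e-4)


@given(
    alpha=st.floats(min_value=0.5, max_value=2.5),
    beta=st.floats(min_value=0.5, max_value=0.99),
    delta=st.floats(min_value=0.2, max_value=0.95),
)
@settings(deadline=None, max_examples=30)
def test_fit_quasi_matches_oracle_on_consistent_points(alpha, beta, delta):
    sps = consistent_switch_points(alpha, beta, delta)
    fit = fit_discount_model(sps, DELAYS, alpha, "quasi_hyperbolic")
    oracle = closed_form_oracle(
        dict(zip(("task1", "task2", "task3"), sps)),
        dict(zip(("task1", "task2", "task3"), DELAYS)),
        alpha,
    )
    assert fit.converged
    assert fit.beta == pytest.approx(oracle["beta"], abs=1e-4)
    assert fit.delta == pytest.approx(oracle["delta"], abs=1e-4)


def test_closed_form_oracle_examples():
    sps = {"task2": sp(13.889), "task3": sp(12.5)}
    delays = {"task2": (0.0, 1.0), "task3": (1.0, 2.0)}
    oracle = closed_form_oracle(sps, delays, 1.0)
    assert oracle["delta"] == pytest.approx(0.8, abs=1e-4)
    assert oracle["beta"] == pytest.approx(0.9, abs=1e-3)
    trivial = closed_form_oracle({"task2": sp(11.0), "task3": sp(10.0)}, delays, 1.0)
    assert trivial["delta"] == pytest.approx(1.0)
    censored = closed_form_oracle(
        {"task2": sp(13.9), "task3": sp(12.5, censoring="never_switched")}, delays, 1.0
    )
    assert censored is None


def test_always_later_boundary_gives_patient_delta():
    """A subject who always takes the later payment pins delta at 1."""
    # a grid starting at 10.25 imputes always-later blocks at 10.0
    sps = [sp(10.0, censoring="always_later"),
           sp(10.0, censoring="always_later"),
           sp(10.0, censoring="always_later")]
    fit = fit_discount_model(sps, DELAYS, 1.0, "exponential")
    assert fit.delta == pytest.approx(1.0)
    assert "delta_at_upper_bound" in fit.boundary_flags


def test_quasi_rss_never_exceeds_exponential(small_recovery):
    """Nesting: the two-parameter model fits at least as well, per subject."""
    from betadelta.pipeline import fit_dataset

    _, _, dataset = small_recovery
    fits = fit_dataset(dataset).fits
    wide = fits.pivot(index="subject_id", columns="model", values="rss")
    assert (wide["quasi_hyperbolic"] <= wide["exponential"] + 1e-9).all()
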