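"""Cohort generation and choice simulation."""

import dataclasses

import numpy as np
import pandas as pd
import pytest

from betadelta.elicitation import MplTask, RiskSituation, switch_value, validate_block
from betadelta.synthetic import (
    AgentTruth, CohortConfig, GroupSpec, assemble_dataset, default_config,
    generate_cohort, mpl_templates_for, read_dataset, recovery_config,
    risk_templates_for, simulate_cohort_dataset, simulate_discount_choices,
    simulate_risk_choices,
)


def agent(**kw):
    base = dict(subject_id="s", group="PG", alpha=1.0, beta=0.9, delta=0.8,
                k=1.0, sogs=8, age=35, sex="M", income=1200, alcohol=2,
                smoking=10, education=12)
    base.update(kw)
    return AgentTruth(**base)


def test_seeded_determinism_bytes(tmp_path):
    cfg = default_config(seed=5)
    for d in ("a", "b"):
        _, ds = simulate_cohort_dataset(cfg)
        ds.write(tmp_path / d)
    for name in ("subjects.csv", "risk_choices.csv", "discount_choices.csv", "truth.csv"):
        assert (tmp_path / "a" / name).read_bytes() == (tmp_path / "b" / name).read_bytes()


def test_degenerate_distributions_hit_medians_exactly():
    spec = GroupSpec(alpha_median=1.53, alpha_sigma=0.0, beta_median=0.84,
                     beta_sigma=0.0, delta_median=0.58, delta_sigma=0.0,
                     k_median=1.08, k_sigma=0.0, sogs_mean=8.0, sogs_sd=0.0)
    cfg = CohortConfig(seed=1, n_per_group={"PG": 5}, groups={"PG": spec})
    for a in generate_cohort(cfg):
        assert a.beta == pytest.approx(0.84)
        assert a.delta == pytest.approx(0.58)
        assert a.alpha == pytest.approx(1.53)


def test_sogs_group_mean_converges():
    cfg = default_config(seed=9, n_per_group={"PG": 10_000})
    sogs = np.array([a.sogs for a in generate_cohort(cfg)])
    assert abs(sogs.mean() - 8.36) < 0.1


def test_study_sizes_give_74_subjects():
    cohort = generate_cohort(default_config(seed=2))
    assert len(cohort) == 74
    counts = pd.Series([a.group for a in cohort]).value_counts()
    assert counts["C"] == 26 and counts["HG"] == 23 and counts["PG"] == 25


def test_invalid_distribution_names_the_field():
    spec = dataclasses.replace(GroupSpec(
        alpha_median=1.0, alpha_sigma=0.2, beta_median=0.9, beta_sigma=0.2,
        delta_median=0.8, delta_sigma=0.2, k_median=0.5, k_sigma=0.2,
        sogs_mean=4.0, sogs_sd=2.0), delta_sigma=-1.0)
    cfg = CohortConfig(seed=0, n_per_group={"C": 2}, groups={"C": spec})
    with pytest.raises(ValueError, match="delta_sigma"):
        generate_cohort(cfg)


def test_risk_neutral_agent_ties_to_lottery():
    sit = RiskSituation("s", "r", x=20.0, y=0.0, p=0.5,
                        certain_payments=(6.0, 8.0, 10.0, 12.0, 14.0))
    (filled,) = simulate_risk_choices(agent(alpha=1.0), [sit])
    assert filled.choices == tuple("LLLCC")  # tie at 10 resolves to the lottery


def test_sure_thing_lottery_always_chosen():
    sit = RiskSituation("s", "r", x=20.0, y=0.0, p=1.0,
                        certain_payments=tuple(np.arange(1.0, 20.0)))
    (filled,) = simulate_risk_choices(agent(alpha=0.7), [sit])
    assert set(filled.choices) == {"L"}


def test_risk_switch_near_closed_form_ce():
    alpha = 1.53
    sit = RiskSituation("s", "r", x=20.0, y=0.0, p=0.5,
                        certain_payments=tuple(np.round(np.arange(1.0, 20.0, 0.5), 3)))
    (filled,) = simulate_risk_choices(agent(alpha=alpha), [sit])
    ce_true = (0.5 * 20.0 ** alpha) ** (1 / alpha)
    sp = switch_value(filled)
    assert abs(sp.value - ce_true) <= sp.half_step


def test_patient_agent_always_later_impatient_always_sooner():
    tasks = [MplTask("s", "task2", 0.0, 1.0, 10.0, (12.0, 14.0, 16.0, 18.0, 20.0))]
    patient = simulate_discount_choices(agent(beta=1.0, delta=1.0), tasks)
    assert set(patient[0].choices) == {"B"}
    impatient = simulate_discount_choices(agent(delta=1e-3, beta=1e-3), tasks)
    assert set(impatient[0].choices) == {"A"}


def test_discount_switch_row_from_inequality():
    # later iff 0.9 * 0.8 * SP > 10, i.e. SP > 13.889 -> first B at 14
    tasks = [MplTask("s", "task2", 0.0, 1.0, 10.0, (12.0, 14.0, 16.0, 18.0, 20.0))]
    (filled,) = simulate_discount_choices(agent(alpha=1.0, beta=0.9, delta=0.8), tasks)
    assert filled.choices == ("A", "B", "B", "B", "B")


@pytest.mark.parametrize("seed", range(4))
def test_noise_free_blocks_have_single_switch(seed):
    rng = np.random.default_rng(seed)
    a = agent(alpha=float(rng.uniform(0.4, 2.5)), beta=float(rng.uniform(0.5, 1.0)),
              delta=float(rng.uniform(0.2, 0.95)))
    cfg = recovery_config(seed=seed, n_per_group=1)
    blocks = simulate_discount_choices(a, mpl_templates_for("s", cfg))
    blocks += simulate_risk_choices(a, risk_templates_for("s", cfg))
    for b in blocks:
        assert validate_block(b.choices).valid


def test_increasing_delta_never_raises_switch_row():
    """A more patient agent switches to the later payment no later."""
    cfg = recovery_config(seed=0, n_per_group=1)
    tasks = mpl_templates_for("s", cfg)

    def first_later_row(delta):
        (t2_block,) = [b for b in simulate_discount_choices(
            agent(delta=delta), tasks) if b.task_id == "task2"]
        verdict = validate_block(t2_block.choices)
        return verdict.switch_row if verdict.switch_row is not None else len(t2_block.choices)

    rows = [first_later_row(d) for d in np.linspace(0.2, 0.99, 15)]
    assert all(a >= b for a, b in zip(rows, rows[1:]))


def test_noisy_choices_are_seeded_and_can_be_inconsistent():
    cfg = recovery_config(seed=21, n_per_group=6, noise_temperature=0.05)
    _, ds1 = simulate_cohort_dataset(cfg)
    _, ds2 = simulate_cohort_dataset(cfg)
    pd.testing.assert_frame_equal(ds1.discount_choices, ds2.discount_choices)
    with pytest.raises(ValueError):  # noisy rows need an explicit generator
        simulate_risk_choices(agent(noise_temperature=0.1),
                              risk_templates_for("s", cfg))


def test_assemble_round_trip(tmp_path, small_recovery):
    _, _, dataset = small_recovery
    dataset.write(tmp_path)
    back = read_dataset(tmp_path)
    pd.testing.assert_frame_equal(back.subjects, dataset.subjects,
                                  check_dtype=False)  # ints re-read as int64
    assert np.allclose(back.discount_choices["later_amount"],
                       dataset.discount_choices["later_amount"])
    assert (back.risk_choices["choice"] == dataset.risk_choices["choice"]).all()


def test_assemble_rejects_empty_and_missing():
    with pytest.raises(ValueError, match="empty"):
        assemble_dataset([], [], [])
    a = agent()
    cfg = default_config()
    risk = simulate_risk_choices(a, risk_templates_for("s", cfg))
    with pytest.raises(ValueError, match="s"):
        assemble_dataset([a], risk, [])  # discounting task missing


def test_missing_dataset_directory_errors(tmp_path):
    with pytest.raises(FileNotFoundError, match="subjects.csv"):
        read_dataset(tmp_path / "nope")
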