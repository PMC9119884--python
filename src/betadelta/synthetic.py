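"""Synthetic cohorts of agents with known risk and time preferences.

Generates agents in three groups — non-gambling controls (C), habitual
gamblers (HG) and problem gamblers (PG) — with per-group distributions of
utility curvature alpha (log-normal), present bias beta and monthly
discount factor delta (logit-normal, so both stay in (0, 1)), hyperbolic
rate k (log-normal), gambling-severity SOGS scores (normal, rounded and
clipped to the instrument's 0–20 range) and matched demographics.  Default
locations follow the study conditions the package is built around: group
sizes 26/23/25, SOGS means 0.42/3.96/8.36, quasi-hyperbolic medians
(beta, delta) = (0.98, 0.88) / (0.97, 0.84) / (0.84, 0.58), alpha medians
0.95/0.98/1.53.

Each agent's choices are then simulated row by row through the two
elicitation tasks: 14 lottery-vs-certain price lists (certainty
equivalents) and three intertemporal price lists with a fixed 10 EUR sooner
payment (today vs tomorrow, today vs one month, one month vs two months;
delays in months, tomorrow = 1/30).  A noise-free agent maximises
discounted power utility and therefore switches at most once per block;
with ``noise_temperature`` > 0 each row is a logistic draw in the utility
difference, which can produce the inconsistent blocks the validation stage
must catch.  Everything is deterministic given the configured seed.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .elicitation import MplTask, RiskSituation

__all__ = [
    "AgentTruth",
    "GroupSpec",
    "CohortConfig",
    "Dataset",
    "default_config",
    "recovery_config",
    "default_risk_templates",
    "generate_cohort",
    "simulate_risk_choices",
    "simulate_discount_choices",
    "simulate_cohort_dataset",
    "assemble_dataset",
    "read_dataset",
]

GROUPS = ("C", "HG", "PG")
DELAY_SCHEME = {"task1": (0.0, 1.0 / 30.0), "task2": (0.0, 1.0), "task3": (1.0, 2.0)}
SOONER_AMOUNT = 10.0
SOGS_RANGE = (0, 20)


@dataclass(frozen=True)
class AgentTruth:
    """Ground-truth preferences and covariates for one simulated agent."""

    subject_id: str
    group: str
    alpha: float
    beta: float
    delta: float
    k: float
    sogs: int
    age: float
    sex: str
    income: float
    alcohol: float
    smoking: float
    education: float
    noise_temperature: float = 0.0

    def __post_init__(self) -> None:
        if self.group not in GROUPS:
            raise ValueError(f"unknown group {self.group!r}")
        if self.alpha <= 0:
            raise ValueError("alpha must be positive")
        if not (0 < self.beta <= 1) or not (0 < self.delta <= 1):
            raise ValueError("beta and delta must be in (0, 1]")
        if self.k <= 0:
            raise ValueError("k must be positive")
        if not (SOGS_RANGE[0] <= self.sogs <= SOGS_RANGE[1]):
            raise ValueError(f"SOGS must be within {SOGS_RANGE}")
        if self.noise_temperature < 0:
            raise ValueError("noise_temperature must be non-negative")


@dataclass(frozen=True)
class GroupSpec:
    """Generating distributions for one group.

    ``alpha`` and ``k`` are log-normal (median, log-space sigma); ``beta``
    and ``delta`` are logit-normal (median, logit-space sigma), which keeps
    them strictly inside (0, 1); SOGS and the demographics are normal with
    the stated mean/SD, clipped to their supports after rounding where the
    instrument is integer-valued.  A sigma of 0 collapses the distribution
    to its median (useful for exact-recovery tests).
    """

    alpha_median: float
    alpha_sigma: float
    beta_median: float
    beta_sigma: float
    delta_median: float
    delta_sigma: float
    k_median: float
    k_sigma: float
    sogs_mean: float
    sogs_sd: float
    age_mean: float = 39.0
    age_sd: float = 15.0
    female_share: float = 0.16
    income_mean: float = 1570.0
    income_sd: float = 1200.0
    alcohol_mean: float = 4.5
    alcohol_sd: float = 6.0
    smoking_mean: float = 38.0
    smoking_sd: float = 53.0
    education_mean: float = 12.6
    education_sd: float = 2.2

    def validate(self, group: str) -> None:
        for name in ("alpha_sigma", "beta_sigma", "delta_sigma", "k_sigma",
                     "sogs_sd", "age_sd", "income_sd", "alcohol_sd",
                     "smoking_sd", "education_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"group {group}: {name} must be non-negative")
        for name in ("alpha_median", "k_median"):
            if getattr(self, name) <= 0:
                raise ValueError(f"group {group}: {name} must be positive")
        for name in ("beta_median", "delta_median"):
            v = getattr(self, name)
            if not (0 < v < 1):
                raise ValueError(f"group {group}: {name} must be in (0, 1)")
        if not (0 <= self.female_share <= 1):
            raise ValueError(f"group {group}: female_share must be in [0, 1]")


# Study-condition defaults: SOGS / demographics moments and the per-group
# preference medians (alpha; exponential delta; hyperbolic k; quasi beta,
# delta) reported for controls, habitual and problem gamblers.  Spreads are
# set to reproduce roughly the reported interquartile ranges.
_DEFAULT_GROUPS = {
    "C": GroupSpec(
        alpha_median=0.95, alpha_sigma=0.25,
        beta_median=0.98, beta_sigma=0.35,
        delta_median=0.88, delta_sigma=0.45,
        k_median=0.16, k_sigma=0.6,
        sogs_mean=0.42, sogs_sd=0.99,
        age_mean=40.46, age_sd=15.22, female_share=5 / 26,
        income_mean=1778.08, income_sd=1533.34,
        alcohol_mean=4.47, alcohol_sd=5.34,
        smoking_mean=37.88, smoking_sd=70.75,
        education_mean=12.96, education_sd=2.24,
    ),
    "HG": GroupSpec(
        alpha_median=0.98, alpha_sigma=0.25,
        beta_median=0.97, beta_sigma=0.5,
        delta_median=0.84, delta_sigma=0.5,
        k_median=0.25, k_sigma=0.6,
        sogs_mean=3.96, sogs_sd=2.96,
        age_mean=37.57, age_sd=14.16, female_share=3 / 23,
        income_mean=1603.17, income_sd=1195.96,
        alcohol_mean=3.72, alcohol_sd=3.73,
        smoking_mean=32.05, smoking_sd=41.36,
        education_mean=12.52, education_sd=2.39,
    ),
    "PG": GroupSpec(
        alpha_median=1.53, alpha_sigma=0.25,
        beta_median=0.84, beta_sigma=0.5,
        delta_median=0.58, delta_sigma=0.4,
        k_median=1.08, k_sigma=0.6,
        sogs_mean=8.36, sogs_sd=3.82,
        age_mean=38.48, age_sd=15.13, female_share=4 / 25,
        income_mean=1323.00, income_sd=813.52,
        alcohol_mean=5.41, alcohol_sd=9.64,
        smoking_mean=46.28, smoking_sd=47.19,
        education_mean=12.28, education_sd=1.95,
    ),
}

STUDY_GRID = (12.0, 14.0, 16.0, 18.0, 20.0)


def fine_grid(lo: float = 10.1, hi: float = 150.1, step: float = 0.5) -> tuple[float, ...]:
    """Ascending later-amount grid for recovery studies.

    Starts just above the 10 EUR sooner payment so that near-patient agents
    (present bias close to 1) still switch inside the list, and runs high
    enough that steep discounters in the generated tails do too.
    """
    return tuple(np.round(np.arange(lo, hi + step / 2, step), 6))


def model_recovery_grid(hi: float = 150.1) -> tuple[float, ...]:
    """Graded later-amount grid for model-recovery studies.

    Discriminating the quasi-hyperbolic model from the one-parameter models
    hinges on the today-vs-tomorrow list, whose indifference amounts sit
    just above the 10 EUR sooner payment (a present bias of 1 puts them
    within a few percent of 10).  A uniform coarse grid cannot resolve that
    region: its half-step imputation error masquerades as present bias and
    inflates the two-parameter model's fit even for agents without one.
    Hence titration-style spacing: 0.1 EUR steps up to 12, 0.5 above.
    """
    near = np.round(np.arange(10.1, 12.0, 0.1), 6)
    far = np.round(np.arange(12.0, hi + 0.25, 0.5), 6)
    return tuple(np.unique(np.concatenate([near, far])))


def default_risk_templates(step_divisor: int = 20) -> tuple[tuple, ...]:
    """14 gain-domain lottery situations: p in {1/8..7/8} over two stake pairs.

    Each situation is (x, y, p, certain_payment_grid); the grid steps
    through (y, x) in (x - y)/step_divisor increments.  The exact stake
    table of the original task is not published, so these are the package's
    stand-in defaults with the same structure (14 situations, gains only).
    """
    out = []
    for x, y in ((20.0, 0.0), (30.0, 10.0)):
        s = (x - y) / step_divisor
        grid = tuple(np.round(np.arange(y + s, x - s / 2, s), 6))
        for i in range(1, 8):
            out.append((x, y, i / 8.0, grid))
    return tuple(out)


@dataclass(frozen=True)
class CohortConfig:
    """Everything that determines a synthetic dataset, seed included."""

    seed: int = 0
    n_per_group: Mapping[str, int] | int = field(
        default_factory=lambda: {"C": 26, "HG": 23, "PG": 25}
    )
    groups: Mapping[str, GroupSpec] = field(default_factory=lambda: dict(_DEFAULT_GROUPS))
    later_amount_grid: tuple[float, ...] = STUDY_GRID
    delay_scheme: Mapping[str, tuple[float, float]] = field(
        default_factory=lambda: dict(DELAY_SCHEME)
    )
    risk_templates: tuple[tuple, ...] = field(default_factory=default_risk_templates)
    noise_temperature: float = 0.0
    generating_model: str = "quasi_hyperbolic"

    def sizes(self) -> dict[str, int]:
        if isinstance(self.n_per_group, int):
            n = {g: self.n_per_group for g in self.groups}
        else:
            n = dict(self.n_per_group)
        for g, v in n.items():
            if v < 1:
                raise ValueError(f"n_per_group for {g} must be >= 1")
        if not n:
            raise ValueError("no groups configured")
        return n

    def validate(self) -> None:
        self.sizes()
        for g, spec in self.groups.items():
            spec.validate(g)
        grid = np.asarray(self.later_amount_grid, dtype=float)
        if grid.size < 2 or np.any(np.diff(grid) <= 0):
            raise ValueError("later_amount_grid must ascend strictly")
        if grid[0] <= SOONER_AMOUNT:
            raise ValueError("later_amount_grid must start above the 10 EUR sooner payment")
        for x, y, p, cg in self.risk_templates:
            cg = np.asarray(cg, dtype=float)
            if np.any(np.diff(cg) <= 0):
                raise ValueError(f"certain-payment grid for ({x}, {y}, {p}) must ascend")
        if self.noise_temperature < 0:
            raise ValueError("noise_temperature must be non-negative")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["n_per_group"] = (self.n_per_group if isinstance(self.n_per_group, int)
                            else dict(self.n_per_group))
        d["groups"] = {g: asdict(s) for g, s in self.groups.items()}
        d["delay_scheme"] = {k: [float(t) for t in v]
                             for k, v in self.delay_scheme.items()}
        d["later_amount_grid"] = [float(v) for v in self.later_amount_grid]
        d["risk_templates"] = [
            [float(x), float(y), float(p), [float(v) for v in gr]]
            for x, y, p, gr in self.risk_templates
        ]
        return d

    def content_hash(self) -> str:
        payload = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:12]


def default_config(seed: int = 0, **overrides) -> CohortConfig:
    """Study-condition defaults: 26/23/25 subjects, the 5-row 12–20 grid."""
    return replace(CohortConfig(seed=seed), **overrides)


def recovery_config(seed: int = 0, n_per_group: int = 200, step: float = 0.5,
                    **overrides) -> CohortConfig:
    """Fine-grid conditions for parameter-recovery studies.

    Later amounts run 10.5–150 EUR in ``step`` increments so that even
    steep discounters in the generated tails switch inside the list, and
    the risk-task certain-payment grids are twice as fine as the study
    defaults; elicitation error is then bounded by half a grid step.
    """
    base = dict(
        n_per_group=n_per_group,
        later_amount_grid=fine_grid(step=step),
        risk_templates=default_risk_templates(step_divisor=40),
    )
    base.update(overrides)
    return replace(CohortConfig(seed=seed), **base)


# ---------------------------------------------------------------------------
# Cohort generation
# ---------------------------------------------------------------------------

def _logit(p: float) -> float:
    return float(np.log(p / (1.0 - p)))


def _draw_logit_normal(rng, median: float, sigma: float, n: int) -> np.ndarray:
    z = rng.standard_normal(n) * sigma + _logit(median)
    return 1.0 / (1.0 + np.exp(-z))


def _draw_lognormal(rng, median: float, sigma: float, n: int) -> np.ndarray:
    return np.exp(rng.standard_normal(n) * sigma + np.log(median))


def generate_cohort(config: CohortConfig) -> list[AgentTruth]:
    """Draw all agents; fully determined by ``config.seed``."""
    config.validate()
    sizes = config.sizes()
    rng = np.random.default_rng(config.seed)
    agents: list[AgentTruth] = []
    counter = 1
    for group in sorted(sizes):
        spec = config.groups[group]
        n = sizes[group]
        alpha = _draw_lognormal(rng, spec.alpha_median, spec.alpha_sigma, n)
        beta = _draw_logit_normal(rng, spec.beta_median, spec.beta_sigma, n)
        delta = _draw_logit_normal(rng, spec.delta_median, spec.delta_sigma, n)
        k = _draw_lognormal(rng, spec.k_median, spec.k_sigma, n)
        sogs = np.clip(
            np.rint(rng.standard_normal(n) * spec.sogs_sd + spec.sogs_mean),
            *SOGS_RANGE,
        ).astype(int)
        age = np.clip(np.rint(rng.standard_normal(n) * spec.age_sd + spec.age_mean), 18, 80)
        sex = np.where(rng.random(n) < spec.female_share, "F", "M")
        income = np.clip(
            np.round(rng.standard_normal(n) * spec.income_sd + spec.income_mean, 2), 0, None
        )
        alcohol = np.clip(
            np.round(rng.standard_normal(n) * spec.alcohol_sd + spec.alcohol_mean, 1), 0, None
        )
        smoking = np.clip(
            np.rint(rng.standard_normal(n) * spec.smoking_sd + spec.smoking_mean), 0, None
        )
        education = np.clip(
            np.rint(rng.standard_normal(n) * spec.education_sd + spec.education_mean), 8, 20
        )
        for i in range(n):
            agents.append(AgentTruth(
                subject_id=f"S{counter:04d}", group=group,
                alpha=float(alpha[i]), beta=float(beta[i]), delta=float(delta[i]),
                k=float(k[i]), sogs=int(sogs[i]), age=float(age[i]), sex=str(sex[i]),
                income=float(income[i]), alcohol=float(alcohol[i]),
                smoking=float(smoking[i]), education=float(education[i]),
                noise_temperature=config.noise_temperature,
            ))
            counter += 1
    return agents


# ---------------------------------------------------------------------------
# Choice simulation
# ---------------------------------------------------------------------------

def _choices_from_diff(diff: np.ndarray, scale: float, temperature: float,
                       take_on_tie: bool,
                       rng: np.random.Generator | None) -> np.ndarray:
    """Boolean take/leave per row; logistic in the utility difference if noisy.

    ``diff`` is divided by the fixed option's utility ``scale`` before the
    logistic, so the temperature is dimensionless (a 0.05 temperature means
    a ~5% relative utility gap gives a ~73% choice probability) and noise
    severity does not depend on the agent's curvature, under which raw
    utilities 10**alpha span orders of magnitude.
    """
    if temperature == 0:
        return diff >= 0 if take_on_tie else diff > 0
    if rng is None:
        raise ValueError("noisy simulation requires a random generator")
    p_take = 1.0 / (1.0 + np.exp(-diff / (temperature * scale)))
    return rng.random(diff.size) < p_take


def risk_templates_for(subject_id: str, config: CohortConfig) -> list[RiskSituation]:
    return [
        RiskSituation(subject_id=subject_id, situation_id=f"R{i + 1:02d}",
                      x=x, y=y, p=p, certain_payments=tuple(grid))
        for i, (x, y, p, grid) in enumerate(config.risk_templates)
    ]


def mpl_templates_for(subject_id: str, config: CohortConfig) -> list[MplTask]:
    return [
        MplTask(subject_id=subject_id, task_id=task_id, t1=t1, t2=t2,
                sooner_amount=SOONER_AMOUNT,
                later_amounts=tuple(config.later_amount_grid))
        for task_id, (t1, t2) in sorted(config.delay_scheme.items())
    ]


def simulate_risk_choices(
    agent: AgentTruth,
    situations: Sequence[RiskSituation],
    rng: np.random.Generator | None = None,
) -> list[RiskSituation]:
    """Fill each lottery block with the agent's row-wise choices.

    A noise-free agent takes the lottery exactly when
    p*x^a + (1-p)*y^a >= c^a (ties go to the lottery), hence switches to
    the certain payment at most once per block.
    """
    out = []
    for sit in situations:
        grid = sit.grid
        eu = sit.p * sit.x ** agent.alpha + (1.0 - sit.p) * sit.y ** agent.alpha
        diff = eu - grid ** agent.alpha
        take = _choices_from_diff(diff, eu, agent.noise_temperature,
                                  take_on_tie=True, rng=rng)
        choices = tuple("L" if t else "C" for t in take)
        out.append(replace(sit, subject_id=agent.subject_id, choices=choices))
    return out


def simulate_discount_choices(
    agent: AgentTruth,
    tasks: Sequence[MplTask],
    model: str = "quasi_hyperbolic",
    rng: np.random.Generator | None = None,
) -> list[MplTask]:
    """Fill each intertemporal block under the generating ``model``.

    A noise-free agent takes the later payment exactly when
    D(t2) * SP^a > D(t1) * 10^a (ties go to the sooner payment).
    """
    from .discounting import discount_weight  # local import avoids a cycle

    params = {"beta": agent.beta, "delta": agent.delta, "k": agent.k}
    out = []
    for task in tasks:
        grid = task.grid
        d1 = discount_weight(model, task.t1, params)
        d2 = discount_weight(model, task.t2, params)
        u_sooner = d1 * task.sooner_amount ** agent.alpha
        diff = d2 * grid ** agent.alpha - u_sooner
        take = _choices_from_diff(diff, u_sooner, agent.noise_temperature,
                                  take_on_tie=False, rng=rng)
        choices = tuple("B" if t else "A" for t in take)
        out.append(replace(task, subject_id=agent.subject_id, choices=choices))
    return out


# ---------------------------------------------------------------------------
# Dataset assembly and round-trip
# ---------------------------------------------------------------------------

@dataclass
class Dataset:
    """The on-disk CSV bundle, held as data frames."""

    subjects: pd.DataFrame
    risk_choices: pd.DataFrame
    discount_choices: pd.DataFrame
    truth: pd.DataFrame | None = None

    def write(self, outdir, header: str | None = None) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        frames = {
            "subjects.csv": self.subjects,
            "risk_choices.csv": self.risk_choices,
            "discount_choices.csv": self.discount_choices,
        }
        if self.truth is not None:
            frames["truth.csv"] = self.truth
        for name, df in frames.items():
            path = outdir / name
            with open(path, "w") as fh:
                if header:
                    fh.write(f"# {header}\n")
                df.to_csv(fh, index=False, float_format="%.10g")


def read_dataset(indir) -> Dataset:
    """Load a CSV bundle written by :meth:`Dataset.write` (or by hand)."""
    indir = Path(indir)
    for required in ("subjects.csv", "risk_choices.csv", "discount_choices.csv"):
        if not (indir / required).exists():
            raise FileNotFoundError(
                f"{indir / required} not found: the dataset directory must hold "
                "subjects.csv, risk_choices.csv and discount_choices.csv "
                "(for the published study, download the deposited data first)"
            )
    truth_path = indir / "truth.csv"
    return Dataset(
        subjects=pd.read_csv(indir / "subjects.csv", comment="#"),
        risk_choices=pd.read_csv(indir / "risk_choices.csv", comment="#"),
        discount_choices=pd.read_csv(indir / "discount_choices.csv", comment="#"),
        truth=pd.read_csv(truth_path, comment="#") if truth_path.exists() else None,
    )


def assemble_dataset(
    cohort: Sequence[AgentTruth],
    risk_blocks: Sequence[RiskSituation],
    discount_blocks: Sequence[MplTask],
) -> Dataset:
    """Bundle simulated choices into the documented CSV schemas.

    Every agent must appear in both tasks; missing subjects are reported by
    id rather than silently producing a ragged dataset.
    """
    if not cohort:
        raise ValueError("empty cohort: nothing to assemble")
    ids = [a.subject_id for a in cohort]
    risk_ids = {b.subject_id for b in risk_blocks}
    disc_ids = {b.subject_id for b in discount_blocks}
    missing = [sid for sid in ids if sid not in risk_ids or sid not in disc_ids]
    if missing:
        raise ValueError(f"subjects missing a task: {missing}")

    subjects = pd.DataFrame([
        {"subject_id": a.subject_id, "group": a.group, "sogs": a.sogs,
         "age": a.age, "sex": a.sex, "income": a.income, "alcohol": a.alcohol,
         "smoking": a.smoking, "education": a.education}
        for a in cohort
    ])
    risk_rows = []
    for b in risk_blocks:
        for i, (c, amount) in enumerate(zip(b.choices, b.certain_payments)):
            risk_rows.append({
                "subject_id": b.subject_id, "situation_id": b.situation_id,
                "x": b.x, "y": b.y, "p": b.p,
                "certain_payment": amount, "choice": c, "row_index": i + 1,
            })
    disc_rows = []
    for b in discount_blocks:
        for i, (c, amount) in enumerate(zip(b.choices, b.later_amounts)):
            disc_rows.append({
                "subject_id": b.subject_id, "task_id": b.task_id,
                "t1_months": b.t1, "t2_months": b.t2,
                "sooner_amount": b.sooner_amount, "later_amount": amount,
                "choice": c, "row_index": i + 1,
            })
    truth = pd.DataFrame([
        {"subject_id": a.subject_id, "alpha": a.alpha, "beta": a.beta,
         "delta": a.delta, "k": a.k}
        for a in cohort
    ])
    return Dataset(
        subjects=subjects,
        risk_choices=pd.DataFrame(risk_rows),
        discount_choices=pd.DataFrame(disc_rows),
        truth=truth,
    )


def simulate_cohort_dataset(config: CohortConfig) -> tuple[list[AgentTruth], Dataset]:
    """Generate a cohort, simulate both tasks and assemble the CSV bundle.

    Per-subject noise streams are spawned from the config seed, so the
    bundle is reproducible row for row.
    """
    cohort = generate_cohort(config)
    if not cohort:
        raise ValueError("empty cohort")
    seeds = np.random.SeedSequence(config.seed).spawn(len(cohort))
    risk_blocks: list[RiskSituation] = []
    disc_blocks: list[MplTask] = []
    for agent, ss in zip(cohort, seeds):
        rng = np.random.default_rng(ss) if config.noise_temperature > 0 else None
        risk_blocks.extend(
            simulate_risk_choices(agent, risk_templates_for(agent.subject_id, config), rng)
        )
        disc_blocks.extend(
            simulate_discount_choices(
                agent, mpl_templates_for(agent.subject_id, config),
                model=config.generating_model, rng=rng,
            )
        )
    return cohort, assemble_dataset(cohort, risk_blocks, disc_blocks)
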