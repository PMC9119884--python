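"""Turn row-wise multiple-price-list choices into switching points.

A multiple price list (MPL) is a block of binary choices between a fixed
option and a varying option whose value ascends down the rows.  A consistent
subject switches at most once; the indifference value is bracketed by the
last pre-switch and first post-switch amounts.  Two block types appear here:

* intertemporal blocks — a fixed sooner payment (10 EUR at delay ``t1``)
  against ascending later payments at delay ``t2``; choices ``A`` (sooner)
  or ``B`` (later); the switch reveals the later-amount indifference point;
* risk blocks — a fixed binary lottery ``(x, p; y, 1-p)`` against ascending
  certain payments; choices ``L`` (lottery) or ``C`` (certain); the switch
  reveals the certainty equivalent.

Blocks with more than one switch are inconsistent and are excluded (not
repaired); blocks with no switch carry only an interval bound and are
imputed half a grid step beyond the boundary, flagged as censored.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "MplTask",
    "RiskSituation",
    "SwitchPoint",
    "SubjectInputs",
    "BlockVerdict",
    "validate_block",
    "switch_value",
    "collect_subject_inputs",
    "read_risk_choices",
    "read_discount_choices",
]

Censoring = Literal["interior", "never_switched", "always_later"]


@dataclass(frozen=True)
class MplTask:
    """One intertemporal price-list block for one subject.

    ``t1``/``t2`` are the sooner/later delays in months; ``later_amounts``
    must ascend strictly and start above the fixed ``sooner_amount``.
    ``choices`` holds one of ``"A"`` (sooner) / ``"B"`` (later) per row;
    ``None`` until simulated or read from data.
    """

    subject_id: str
    task_id: str
    t1: float
    t2: float
    sooner_amount: float
    later_amounts: tuple[float, ...]
    choices: tuple[str, ...] | None = None

    def __post_init__(self) -> None:
        if not (self.t2 > self.t1 >= 0):
            raise ValueError(
                f"task {self.task_id}: need t2 > t1 >= 0, got t1={self.t1}, t2={self.t2}"
            )
        amounts = np.asarray(self.later_amounts, dtype=float)
        if amounts.size < 2 or np.any(np.diff(amounts) <= 0):
            raise ValueError(f"task {self.task_id}: later_amounts must ascend strictly")
        if amounts[0] <= self.sooner_amount:
            raise ValueError(
                f"task {self.task_id}: smallest later amount {amounts[0]} must exceed "
                f"the sooner amount {self.sooner_amount}"
            )
        if self.choices is not None and len(self.choices) != amounts.size:
            raise ValueError(f"task {self.task_id}: one choice per row required")

    @property
    def grid(self) -> np.ndarray:
        return np.asarray(self.later_amounts, dtype=float)


@dataclass(frozen=True)
class RiskSituation:
    """One lottery-vs-certain block: lottery (x with prob p, else y)."""

    subject_id: str
    situation_id: str
    x: float
    y: float
    p: float
    certain_payments: tuple[float, ...]
    choices: tuple[str, ...] | None = None

    def __post_init__(self) -> None:
        if not (self.x > self.y >= 0):
            raise ValueError(
                f"situation {self.situation_id}: need x > y >= 0, got x={self.x}, y={self.y}"
            )
        if not (0 < self.p <= 1):
            raise ValueError(f"situation {self.situation_id}: p must be in (0, 1]")
        grid = np.asarray(self.certain_payments, dtype=float)
        if grid.size < 2 or np.any(np.diff(grid) <= 0):
            raise ValueError(
                f"situation {self.situation_id}: certain_payments must ascend strictly"
            )
        if self.choices is not None and len(self.choices) != grid.size:
            raise ValueError(f"situation {self.situation_id}: one choice per row required")

    @property
    def grid(self) -> np.ndarray:
        return np.asarray(self.certain_payments, dtype=float)


@dataclass(frozen=True)
class SwitchPoint:
    """An elicited indifference value with its censoring status.

    ``half_step`` is half the grid step at the switch location — the
    resolution limit the price list imposes on the value.
    """

    value: float
    censoring: Censoring
    half_step: float


@dataclass(frozen=True)
class BlockVerdict:
    valid: bool
    n_switches: int
    switch_row: int | None  # first row on the varying option, None if censored


@dataclass
class SubjectInputs:
    """Everything the estimation stages need for one subject."""

    subject_id: str
    switch_points: dict[str, SwitchPoint] = field(default_factory=dict)
    delays: dict[str, tuple[float, float]] = field(default_factory=dict)
    ce_observations: list[dict] = field(default_factory=list)


_FIXED_FIRST = {"A", "L"}  # codes meaning "stayed with the fixed option"
_VARYING = {"B", "C"}


def validate_block(choices: Sequence[str]) -> BlockVerdict:
    """Count switches from the fixed option to the varying option.

    A block is valid iff the choice sequence, read down ascending rows,
    changes at most once.  Any change (in either direction) counts as a
    switch, so a ``B…A…B`` pattern is invalid, not "one switch up and one
    down".
    """
    if len(choices) == 0:
        raise ValueError("empty choice vector")
    codes = [c.strip().upper() for c in choices]
    for c in codes:
        if c not in _FIXED_FIRST | _VARYING:
            raise ValueError(f"unknown choice code {c!r}")
    flips = sum(1 for a, b in zip(codes, codes[1:]) if a != b)
    valid = flips <= 1
    switch_row: int | None = None
    if valid:
        varying = [c in _VARYING for c in codes]
        if any(varying):
            if varying[0]:
                switch_row = 0
            else:
                switch_row = varying.index(True)
    return BlockVerdict(valid=valid, n_switches=flips, switch_row=switch_row)


def switch_value(block: MplTask | RiskSituation, convention: str = "midpoint") -> SwitchPoint:
    """Convert a valid block's choices into a :class:`SwitchPoint`.

    Interior switches take the midpoint of the bracketing amounts
    (``convention="midpoint"``), the first post-switch amount
    (``convention="first_post"``), or the last pre-switch amount
    (``convention="last_pre"``).  Midpoint minimises worst-case grid error;
    ``last_pre`` is the conservative lower bracket, which never overstates
    how much extra money a subject demanded and therefore cannot manufacture
    spurious present bias out of grid resolution (used by the
    model-recovery harness; see the methods note).  Censored blocks are
    imputed half a grid step beyond the boundary and flagged: a subject who
    never leaves the fixed option values it above the whole grid
    (``never_switched``); one who takes the varying option from row 1
    values the fixed option below the grid (``always_later``).
    """
    if block.choices is None:
        raise ValueError("block has no choices")
    if convention not in ("midpoint", "first_post", "last_pre"):
        raise ValueError(f"unknown switching-point convention {convention!r}")
    verdict = validate_block(block.choices)
    ident = f"subject {block.subject_id}, block " + (
        block.task_id if isinstance(block, MplTask) else block.situation_id
    )
    if not verdict.valid:
        raise ValueError(f"{ident}: {verdict.n_switches} switches, expected at most 1")
    grid = block.grid
    if verdict.switch_row is None:  # never took the varying option
        half = (grid[-1] - grid[-2]) / 2.0
        return SwitchPoint(value=grid[-1] + half, censoring="never_switched", half_step=half)
    if verdict.switch_row == 0:  # varying option from the first row
        half = (grid[1] - grid[0]) / 2.0
        return SwitchPoint(value=grid[0] - half, censoring="always_later", half_step=half)
    lo = grid[verdict.switch_row - 1]
    hi = grid[verdict.switch_row]
    half = (hi - lo) / 2.0
    value = {"midpoint": (lo + hi) / 2.0, "first_post": hi, "last_pre": lo}[convention]
    return SwitchPoint(value=float(value), censoring="interior", half_step=float(half))


# ---------------------------------------------------------------------------
# CSV readers and per-subject assembly
# ---------------------------------------------------------------------------

_RISK_COLS = ["subject_id", "situation_id", "x", "y", "p", "certain_payment", "choice", "row_index"]
_DISC_COLS = [
    "subject_id", "task_id", "t1_months", "t2_months",
    "sooner_amount", "later_amount", "choice", "row_index",
]


def _read_csv(path, required: list[str]) -> pd.DataFrame:
    df = pd.read_csv(path, comment="#")
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    return df


def read_risk_choices(path) -> list[RiskSituation]:
    """Read ``risk_choices.csv`` into per-(subject, situation) blocks.

    Rows are sorted by ascending certain payment regardless of file order.
    """
    df = _read_csv(path, _RISK_COLS)
    blocks = []
    for (sid, sit), grp in df.groupby(["subject_id", "situation_id"], sort=True):
        grp = grp.sort_values("certain_payment")
        if grp["certain_payment"].duplicated().any():
            raise ValueError(f"duplicate rows for subject {sid}, situation {sit}")
        blocks.append(
            RiskSituation(
                subject_id=str(sid),
                situation_id=str(sit),
                x=float(grp["x"].iloc[0]),
                y=float(grp["y"].iloc[0]),
                p=float(grp["p"].iloc[0]),
                certain_payments=tuple(grp["certain_payment"].astype(float)),
                choices=tuple(grp["choice"].astype(str)),
            )
        )
    return blocks


def read_discount_choices(path) -> list[MplTask]:
    """Read ``discount_choices.csv`` into per-(subject, task) blocks."""
    df = _read_csv(path, _DISC_COLS)
    blocks = []
    for (sid, task), grp in df.groupby(["subject_id", "task_id"], sort=True):
        grp = grp.sort_values("later_amount")
        if grp["later_amount"].duplicated().any():
            raise ValueError(f"duplicate rows for subject {sid}, task {task}")
        blocks.append(
            MplTask(
                subject_id=str(sid),
                task_id=str(task),
                t1=float(grp["t1_months"].iloc[0]),
                t2=float(grp["t2_months"].iloc[0]),
                sooner_amount=float(grp["sooner_amount"].iloc[0]),
                later_amounts=tuple(grp["later_amount"].astype(float)),
                choices=tuple(grp["choice"].astype(str)),
            )
        )
    return blocks


def collect_subject_inputs(
    risk_blocks: Sequence[RiskSituation],
    discount_blocks: Sequence[MplTask],
    n_discount_tasks: int = 3,
    convention: str = "midpoint",
) -> tuple[dict[str, SubjectInputs], pd.DataFrame]:
    """Group blocks by subject and elicit switch points / certainty equivalents.

    Returns ``(inputs, exclusions)``.  Subjects missing any block or holding
    any multi-switch block land in the exclusion report (columns
    ``subject_id``, ``reason``) and are absent from ``inputs``; censored
    blocks are kept, imputed and flagged.
    """
    by_subject: dict[str, SubjectInputs] = {}
    exclusions: list[dict] = []
    risk_ids = {b.subject_id for b in risk_blocks}
    disc_ids = {b.subject_id for b in discount_blocks}
    bad: dict[str, list[str]] = {}

    for sid in sorted(risk_ids | disc_ids):
        reasons = []
        if sid not in risk_ids:
            reasons.append("missing risk task")
        if sid not in disc_ids:
            reasons.append("missing discounting task")
        if reasons:
            bad[sid] = reasons

    for block in risk_blocks:
        verdict = validate_block(block.choices)
        if not verdict.valid:
            bad.setdefault(block.subject_id, []).append(
                f"risk block {block.situation_id}: {verdict.n_switches} switches"
            )
    for block in discount_blocks:
        verdict = validate_block(block.choices)
        if not verdict.valid:
            bad.setdefault(block.subject_id, []).append(
                f"discount block {block.task_id}: {verdict.n_switches} switches"
            )

    seen_disc: set[tuple[str, str]] = set()
    for block in discount_blocks:
        key = (block.subject_id, block.task_id)
        if key in seen_disc:
            raise ValueError(f"duplicate discounting block for subject/task {key}")
        seen_disc.add(key)
        if block.subject_id in bad:
            continue
        sub = by_subject.setdefault(block.subject_id, SubjectInputs(block.subject_id))
        sub.switch_points[block.task_id] = switch_value(block, convention)
        sub.delays[block.task_id] = (block.t1, block.t2)

    seen_risk: set[tuple[str, str]] = set()
    for block in risk_blocks:
        key = (block.subject_id, block.situation_id)
        if key in seen_risk:
            raise ValueError(f"duplicate risk block for subject/situation {key}")
        seen_risk.add(key)
        if block.subject_id in bad:
            continue
        sp = switch_value(block, convention)
        sub = by_subject.setdefault(block.subject_id, SubjectInputs(block.subject_id))
        sub.ce_observations.append(
            {"x": block.x, "y": block.y, "p": block.p,
             "ce": sp.value, "censoring": sp.censoring, "half_step": sp.half_step}
        )

    incomplete = [
        sid for sid, sub in by_subject.items()
        if len(sub.switch_points) != n_discount_tasks or not sub.ce_observations
    ]
    for sid in incomplete:
        bad.setdefault(sid, []).append("incomplete task set")
        by_subject.pop(sid)

    for sid in sorted(bad):
        for reason in bad[sid]:
            exclusions.append({"subject_id": sid, "reason": reason})
    report = pd.DataFrame(exclusions, columns=["subject_id", "reason"])
    return by_subject, report
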