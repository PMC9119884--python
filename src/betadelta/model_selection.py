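"""BIC-based adjudication between the candidate discounting models.

Per-subject fits are scored with the Gaussian least-squares BIC

    BIC = n * ln(RSS / n) + p * ln(n)

(the additive constant cancels in any BIC difference).  Subject BICs are
summed within a scope (overall or one group); a pooled-residual mode is
available for matching codebases that fit one model per group.  Differences
between models are read on Raftery's rules-of-thumb scale: a dBIC in (0, 2]
is weak evidence against the higher-BIC model, (2, 6] positive, (6, 10]
strong, above 10 very strong.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Sequence

import pandas as pd

__all__ = [
    "BicRecord",
    "EvidenceLabel",
    "bic_from_fit",
    "aggregate_bic",
    "evidence_label",
    "comparison_table",
]

_RSS_FLOOR = 1e-300  # below this an RSS is treated as an exact fit


@dataclass(frozen=True)
class BicRecord:
    scope: str  # "subject", "group" or "overall"
    model: str
    bic: float
    n_obs: int
    n_free: int


@dataclass(frozen=True)
class EvidenceLabel:
    delta_bic: float
    label: str  # weak | positive | strong | very_strong


def bic_from_fit(rss: float, n_obs: int, n_free: int) -> float:
    """Gaussian least-squares BIC up to an additive constant.

    An exact fit (rss = 0, possible with 2 free parameters on 3 switch
    points) returns ``-inf`` as a boundary marker; callers exclude such
    subjects from aggregates.
    """
    if n_obs < 1:
        raise ValueError("n_obs must be at least 1")
    if n_free < 1 or n_free > n_obs:
        raise ValueError("need n_obs >= n_free >= 1")
    if rss < 0:
        raise ValueError("rss must be non-negative")
    if rss <= _RSS_FLOOR:
        return float("-inf")
    return n_obs * math.log(rss / n_obs) + n_free * math.log(n_obs)


def aggregate_bic(records: Sequence[BicRecord], scope: str) -> BicRecord:
    """Sum per-subject BICs into one scope-level record.

    Subjects whose BIC is the ``-inf`` exact-fit marker are dropped with a
    warning (a perfect 3-point fit carries no likelihood information on
    this scale).  All records must share one model.
    """
    if not records:
        raise ValueError("no BIC records to aggregate")
    models = {r.model for r in records}
    if len(models) > 1:
        raise ValueError(f"cannot aggregate across models {sorted(models)}")
    usable = [r for r in records if math.isfinite(r.bic)]
    dropped = len(records) - len(usable)
    if dropped:
        warnings.warn(
            f"excluded {dropped} exact-fit (rss=0) subject(s) from the "
            f"{scope} BIC aggregate", stacklevel=2,
        )
    if not usable:
        raise ValueError("all subjects had rss=0; aggregate BIC undefined")
    return BicRecord(
        scope=scope,
        model=models.pop(),
        bic=float(sum(r.bic for r in usable)),
        n_obs=sum(r.n_obs for r in usable),
        n_free=usable[0].n_free,
    )


def pooled_bic(rss_total: float, n_obs_total: int, n_free: int) -> float:
    """Alternative aggregation: one BIC from pooled residuals across subjects."""
    return bic_from_fit(rss_total, n_obs_total, n_free)


def evidence_label(delta_bic: float) -> EvidenceLabel:
    """Raftery rule-of-thumb label for a non-negative BIC difference."""
    if delta_bic < 0:
        raise ValueError("delta BIC must be non-negative; order the models first")
    if delta_bic <= 2:
        label = "weak"
    elif delta_bic <= 6:
        label = "positive"
    elif delta_bic <= 10:
        label = "strong"
    else:
        label = "very_strong"
    return EvidenceLabel(delta_bic=float(delta_bic), label=label)


_COMPARISONS = [
    ("exponential", "quasi_hyperbolic"),
    ("hyperbolic", "quasi_hyperbolic"),
    ("hyperbolic", "exponential"),
]


def comparison_table(
    fits: pd.DataFrame,
    groups: pd.Series | None = None,
    mode: str = "sum",
) -> pd.DataFrame:
    """Model-comparison table: one row per ordered model pair.

    ``fits`` needs columns ``subject_id``, ``model``, ``rss``, ``n_points``,
    ``n_free``.  Columns are ``overall`` plus one per group label when
    ``groups`` (indexed by subject_id) is given; each dBIC = BIC(first) −
    BIC(second) comes with its evidence label.  ``mode`` is ``"sum"``
    (per-subject BICs summed) or ``"pooled"`` (BIC of pooled residuals).
    """
    if mode not in ("sum", "pooled"):
        raise ValueError(f"unknown BIC aggregation mode {mode!r}")

    def scope_bic(sub: pd.DataFrame, model: str, scope: str) -> float:
        rows = sub[sub["model"] == model]
        if rows.empty:
            raise ValueError(f"no {model} fits in scope {scope}")
        if mode == "pooled":
            return pooled_bic(rows["rss"].sum(), int(rows["n_points"].sum()),
                              int(rows["n_free"].iloc[0]))
        recs = [
            BicRecord("subject", model, bic_from_fit(r.rss, int(r.n_points), int(r.n_free)),
                      int(r.n_points), int(r.n_free))
            for r in rows.itertuples()
        ]
        return aggregate_bic(recs, scope).bic

    scopes: dict[str, pd.DataFrame] = {"overall": fits}
    if groups is not None:
        for g in pd.unique(groups):
            ids = groups[groups == g].index
            scopes[str(g)] = fits[fits["subject_id"].isin(ids)]

    out = []
    for worse, better in _COMPARISONS:
        row: dict[str, object] = {"comparison": f"{worse} - {better}"}
        for scope, sub in scopes.items():
            d = scope_bic(sub, worse, scope) - scope_bic(sub, better, scope)
            row[scope] = d
            row[f"{scope}_evidence"] = (
                evidence_label(d).label if d >= 0 else f"favors_{worse}"
            )
        out.append(row)
    return pd.DataFrame(out)
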