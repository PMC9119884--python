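"""Group comparisons: normality gating, rank tests, post hocs, regressions.

Group sizes here are small (fewer than 30 per group) and the fitted
preference parameters are far from normal, so the omnibus comparison is the
tie-corrected Kruskal–Wallis test, gated by a Shapiro–Wilk check, with
Dunn's rank-based post hoc z-tests under Bonferroni correction.  Continuous
associations are reported as OLS regressions (outcome on SOGS, a male
indicator and age) and Pearson correlations in the conventional
"r(df) = value" form with df = n − 2.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from typing import Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

__all__ = [
    "GroupTestResult",
    "RegressionResult",
    "shapiro_wilk",
    "kruskal_wallis",
    "dunn_bonferroni",
    "ols_fit",
    "pearson_report",
    "normality_gate",
]


@dataclass(frozen=True)
class PairResult:
    pair: tuple[str, str]
    z: float
    p_adjusted: float


@dataclass(frozen=True)
class GroupTestResult:
    variable: str
    test: str
    statistic: float
    df: int
    p_value: float
    post_hoc: tuple[PairResult, ...] = field(default=())
    notes: str = ""


@dataclass(frozen=True)
class RegressionResult:
    outcome: str
    terms: dict  # name -> {"estimate", "se", "p"}
    r_squared: float
    n_obs: int


def shapiro_wilk(values: Sequence[float]) -> dict:
    """Shapiro–Wilk normality test; the gate for choosing rank tests."""
    x = np.asarray(values, dtype=float)
    if not (3 <= x.size <= 5000):
        raise ValueError(f"Shapiro-Wilk needs 3 <= n <= 5000, got n={x.size}")
    if np.ptp(x) == 0:
        raise ValueError("Shapiro-Wilk is undefined for constant input")
    w, p = stats.shapiro(x)
    return {"W": float(w), "p": float(p)}


def normality_gate(values: Sequence[float], group_sizes: Sequence[int],
                   alpha: float = 0.05, small_n: int = 30) -> dict:
    """Decide parametric vs nonparametric testing and log both reasons.

    Nonparametric tests are selected when the pooled variable fails
    Shapiro–Wilk at ``alpha`` or any group has fewer than ``small_n``
    observations; both conditions are reported.
    """
    sw = shapiro_wilk(values)
    non_normal = sw["p"] < alpha
    small = any(n < small_n for n in group_sizes)
    return {
        "shapiro_W": sw["W"],
        "shapiro_p": sw["p"],
        "non_normal": bool(non_normal),
        "small_groups": bool(small),
        "use_nonparametric": bool(non_normal or small),
    }


def _check_groups(groups: Sequence[Sequence[float]]) -> list[np.ndarray]:
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    arrs = [np.asarray(g, dtype=float) for g in groups]
    if any(a.size == 0 for a in arrs):
        raise ValueError("every group must be nonempty")
    return arrs


def kruskal_wallis(groups: Sequence[Sequence[float]], variable: str = "",
                   labels: Sequence[str] | None = None) -> GroupTestResult:
    """Tie-corrected Kruskal–Wallis H with a chi-square reference.

    H = 12/(N(N+1)) * sum n_i (Rbar_i - (N+1)/2)^2, divided by the tie
    correction; df = number of groups − 1.
    """
    arrs = _check_groups(groups)
    pooled = np.concatenate(arrs)
    if np.ptp(pooled) == 0:
        h, p = 0.0, 1.0  # scipy raises on all-identical; H is 0 by symmetry
    else:
        h, p = stats.kruskal(*arrs)
    return GroupTestResult(
        variable=variable, test="kruskal_wallis",
        statistic=float(h), df=len(arrs) - 1, p_value=float(p),
    )


def _rank_means(arrs: list[np.ndarray]) -> tuple[list[float], float, int]:
    """Average-rank group means, the tie-sum T = sum(t^3 - t), and N."""
    pooled = np.concatenate(arrs)
    ranks = stats.rankdata(pooled)
    sizes = [a.size for a in arrs]
    edges = np.cumsum([0] + sizes)
    means = [float(ranks[edges[i]:edges[i + 1]].mean()) for i in range(len(arrs))]
    _, counts = np.unique(pooled, return_counts=True)
    tie_sum = float(np.sum(counts ** 3 - counts))
    return means, tie_sum, pooled.size


def dunn_bonferroni(groups: Sequence[Sequence[float]],
                    labels: Sequence[str] | None = None) -> list[PairResult]:
    """Dunn's post hoc z-tests on pooled ranks, Bonferroni-adjusted.

    z_ij = (Rbar_i − Rbar_j) / sqrt[(N(N+1)/12 − T/(12(N−1))) (1/n_i + 1/n_j)]
    with T the tie correction; two-sided p-values are multiplied by the
    number of pairs and capped at 1.
    """
    arrs = _check_groups(groups)
    if labels is None:
        labels = [str(i + 1) for i in range(len(arrs))]
    means, tie_sum, n_total = _rank_means(arrs)
    var_base = n_total * (n_total + 1) / 12.0 - tie_sum / (12.0 * (n_total - 1))
    n_pairs = len(arrs) * (len(arrs) - 1) // 2
    out = []
    for i, j in combinations(range(len(arrs)), 2):
        se = np.sqrt(var_base * (1.0 / arrs[i].size + 1.0 / arrs[j].size))
        z = 0.0 if se == 0 else (means[i] - means[j]) / se
        p_raw = 2.0 * stats.norm.sf(abs(z))
        out.append(PairResult(
            pair=(str(labels[i]), str(labels[j])),
            z=float(z),
            p_adjusted=float(min(1.0, n_pairs * p_raw)),
        ))
    return out


def ols_fit(outcome: Sequence[float], design: pd.DataFrame,
            outcome_name: str = "outcome") -> RegressionResult:
    """OLS of an outcome on a design (e.g. SOGS, Male, Age), with intercept.

    Conventional (non-robust) standard errors.  A rank-deficient design is
    rejected with the offending columns named.
    """
    y = np.asarray(outcome, dtype=float)
    X = design.astype(float).copy()
    if y.size != len(X):
        raise ValueError("outcome and design must have the same number of rows")
    if y.size <= X.shape[1] + 1:
        raise ValueError("need more observations than regression terms")
    if np.isnan(y).any() or X.isna().any().any():
        raise ValueError("missing values are not allowed in the regression")
    Xc = sm.add_constant(X, prepend=True, has_constant="add")
    rank = np.linalg.matrix_rank(Xc.to_numpy())
    if rank < Xc.shape[1]:
        raise ValueError(f"rank-deficient design; check collinearity among {list(X.columns)}")
    res = sm.OLS(y, Xc).fit()
    terms = {
        ("Intercept" if name == "const" else str(name)): {
            "estimate": float(res.params[name]),
            "se": float(res.bse[name]),
            "p": float(res.pvalues[name]),
        }
        for name in Xc.columns
    }
    return RegressionResult(outcome=outcome_name, terms=terms,
                            r_squared=float(res.rsquared), n_obs=int(y.size))


def pearson_report(x: Sequence[float], y: Sequence[float]) -> dict:
    """Pearson correlation reported as "r(df) = r" with df = n − 2."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("need two equal-length samples with n >= 3")
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
        raise ValueError("inputs must be finite")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("correlation is undefined for a zero-variance input")
    r, p = stats.pearsonr(x, y)
    df = x.size - 2
    return {"r": float(r), "df": df, "p": float(p),
            "formatted": f"r({df})={r:.2f}"}
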