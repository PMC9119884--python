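"""End-to-end stages: choices -> switch points -> alpha -> discount fits -> stats.

This is the programmatic spine under the command-line interface: each
function takes and returns plain data frames with the documented column
schemas, so the stages compose in memory exactly as they do on disk.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import discounting, group_inference, model_selection
from .elicitation import collect_subject_inputs, read_discount_choices, read_risk_choices
from .synthetic import Dataset
from .utility import estimate_alpha

__all__ = ["FitOutput", "fit_dataset", "stats_battery"]

_TASK_ORDER = ("task1", "task2", "task3")


@dataclass
class FitOutput:
    fits: pd.DataFrame          # one row per subject x model (fits.csv schema)
    alphas: pd.DataFrame        # subject_id, alpha, alpha_rss, alpha_converged
    exclusions: pd.DataFrame    # subject_id, reason
    inputs: dict                # subject_id -> SubjectInputs (for diagnostics)


def _blocks_from_frames(dataset: Dataset):
    import io

    # reuse the CSV readers' grouping/sorting logic without touching disk
    risk_buf = io.StringIO(dataset.risk_choices.to_csv(index=False))
    disc_buf = io.StringIO(dataset.discount_choices.to_csv(index=False))
    return read_risk_choices(risk_buf), read_discount_choices(disc_buf)


def fit_dataset(
    dataset: Dataset,
    convention: str = "midpoint",
    residual_space: str = "money",
    models: tuple[str, ...] = discounting.MODELS,
) -> FitOutput:
    """Run elicitation, curvature estimation and all discounting fits.

    Subjects with missing or inconsistent (multi-switch) blocks are listed
    in ``exclusions`` and skipped; censored blocks are imputed half a grid
    step beyond the boundary and propagate their flags into
    ``boundary_flags``.
    """
    risk_blocks, disc_blocks = _blocks_from_frames(dataset)
    inputs, exclusions = collect_subject_inputs(
        risk_blocks, disc_blocks, convention=convention
    )

    alpha_rows, fit_rows = [], []
    for sid in sorted(inputs):
        sub = inputs[sid]
        est = estimate_alpha(sub.ce_observations, residual_space=residual_space)
        alpha_rows.append({
            "subject_id": sid, "alpha": est.alpha, "alpha_rss": est.rss,
            "alpha_converged": est.converged,
        })
        task_ids = sorted(sub.switch_points, key=lambda t: sub.delays[t])
        sps = [sub.switch_points[t] for t in task_ids]
        delays = [sub.delays[t] for t in task_ids]
        censored = [t for t in task_ids if sub.switch_points[t].censoring != "interior"]
        for model in models:
            fit = discounting.fit_discount_model(sps, delays, est.alpha, model)
            flags = list(fit.boundary_flags) + [
                f"censored_{t}_{sub.switch_points[t].censoring}" for t in censored
            ]
            fit_rows.append({
                "subject_id": sid, "model": model,
                "delta": fit.delta, "k": fit.k, "beta": fit.beta,
                "rss": fit.rss, "n_points": fit.n_points, "n_free": fit.n_free,
                "converged": fit.converged, "boundary_flags": ";".join(flags),
                "alpha": est.alpha,
            })

    fits = pd.DataFrame(
        fit_rows,
        columns=["subject_id", "model", "delta", "k", "beta", "rss", "n_points",
                 "n_free", "converged", "boundary_flags", "alpha"],
    )
    alphas = pd.DataFrame(
        alpha_rows, columns=["subject_id", "alpha", "alpha_rss", "alpha_converged"]
    )
    return FitOutput(fits=fits, alphas=alphas, exclusions=exclusions, inputs=inputs)


def model_comparison(fits: pd.DataFrame, subjects: pd.DataFrame,
                     mode: str = "sum") -> pd.DataFrame:
    groups = subjects.set_index("subject_id")["group"]
    return model_selection.comparison_table(fits, groups=groups, mode=mode)


def stats_battery(
    fits: pd.DataFrame,
    subjects: pd.DataFrame,
    alpha_level: float = 0.05,
) -> dict[str, pd.DataFrame]:
    """The group-comparison battery on the quasi-hyperbolic parameters.

    Returns ``group_stats`` (Shapiro gate, Kruskal–Wallis omnibus and
    Dunn–Bonferroni post hocs for beta, delta, alpha, SOGS and the matching
    demographics), ``regressions`` (OLS of beta and delta on SOGS, a male
    indicator and age) and ``correlations`` (delta–beta Pearson overall and
    per group, formatted as "r(df)=r").
    """
    quasi = fits[fits["model"] == "quasi_hyperbolic"].set_index("subject_id")
    merged = subjects.set_index("subject_id").join(
        quasi[["beta", "delta", "alpha"]], how="inner"
    ).reset_index()
    if merged.empty:
        raise ValueError("no subjects shared between fits and subject metadata")
    group_labels = [g for g in ("C", "HG", "PG") if g in set(merged["group"])]

    def by_group(col):
        return [merged.loc[merged["group"] == g, col].to_numpy(dtype=float)
                for g in group_labels]

    stat_rows = []
    for col in ("beta", "delta", "alpha", "sogs", "age", "income",
                "alcohol", "smoking", "education"):
        if col not in merged.columns:
            continue
        groups = by_group(col)
        try:
            gate = group_inference.normality_gate(
                merged[col].to_numpy(dtype=float), [len(g) for g in groups],
                alpha=alpha_level,
            )
        except ValueError:  # constant variable: the gate still picks rank tests
            gate = {"shapiro_W": float("nan"), "shapiro_p": float("nan"),
                    "use_nonparametric": True}
        omnibus = group_inference.kruskal_wallis(groups, variable=col,
                                                 labels=group_labels)
        row = {
            "variable": col, "test": omnibus.test,
            "statistic": omnibus.statistic, "df": omnibus.df,
            "p_value": omnibus.p_value,
            "shapiro_W": gate["shapiro_W"], "shapiro_p": gate["shapiro_p"],
            "nonparametric": gate["use_nonparametric"],
        }
        for pr in group_inference.dunn_bonferroni(groups, labels=group_labels):
            tag = f"{pr.pair[0]}_vs_{pr.pair[1]}"
            row[f"z_{tag}"] = pr.z
            row[f"p_{tag}"] = pr.p_adjusted
        stat_rows.append(row)
    group_stats = pd.DataFrame(stat_rows)

    design = pd.DataFrame({
        "SOGS": merged["sogs"].astype(float),
        "Male": (merged["sex"].astype(str).str.upper() == "M").astype(float),
        "Age": merged["age"].astype(float),
    })
    reg_rows = []
    for outcome in ("beta", "delta"):
        res = group_inference.ols_fit(merged[outcome], design, outcome_name=outcome)
        for term, vals in res.terms.items():
            reg_rows.append({
                "outcome": outcome, "term": term, "estimate": vals["estimate"],
                "se": vals["se"], "p": vals["p"],
                "r_squared": res.r_squared, "n_obs": res.n_obs,
            })
    regressions = pd.DataFrame(reg_rows)

    corr_rows = []
    scopes = [("overall", merged)] + [
        (g, merged[merged["group"] == g]) for g in group_labels
    ]
    for name, sub in scopes:
        if len(sub) < 3:
            continue
        rep = group_inference.pearson_report(sub["delta"], sub["beta"])
        corr_rows.append({"scope": name, **rep})
    correlations = pd.DataFrame(corr_rows)

    return {"group_stats": group_stats, "regressions": regressions,
            "correlations": correlations}
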