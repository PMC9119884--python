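# Methods

## Elicitation model

Both experimental tasks are multiple price lists (MPLs): a fixed option
against a varying option whose value ascends down the rows, with the row
where preference flips revealing an indifference value.

- **Risk task.** 14 gain-domain situations, each a fixed binary lottery
  (x with probability p, else y; x > y ≥ 0) against ascending certain
  payments. The flip from lottery (`L`) to certain (`C`) brackets the
  certainty equivalent.
- **Discounting task.** Three lists with a fixed sooner payment of 10 EUR:
  today vs tomorrow, today vs one month, one month vs two months. Delays
  are coded in months with tomorrow = 1/30, so δ is a monthly factor and
  the today-vs-tomorrow list identifies β almost directly
  (β·δ^(1/30) ≈ β). The flip from sooner (`A`) to later (`B`) brackets the
  later-amount indifference point. The delay coding is configurable.

A consistent block has at most one flip. Multi-switch blocks are excluded
(listed in an exclusion report), never repaired. Censored blocks — no flip
observed — are imputed half a grid step beyond the boundary and flagged;
a configuration switch drops them instead.

**Switching-point conventions.** The default converts an interior flip to
the midpoint of the bracketing amounts (minimum worst-case grid error).
Two alternatives exist: `first_post` (the first post-switch amount, for
matching codebases that use that convention) and `last_pre` (the last
pre-switch amount — the conservative lower bracket). The model-recovery
harness uses `last_pre`; see "Model recovery and the boundary null" below.

## Estimation

Curvature: α is fitted by nonlinear least squares on money-space residuals
`CE_observed − CE_predicted(α)` over the 14 situations, with
`CE_predicted = (p·x^α + (1−p)·y^α)^(1/α)`, bounds [0.05, 10], a
deterministic start ladder {0.5, 1, 2}, and tolerances of 1e−14 on the
objective. A transformed-space residual option
(`CE^α − (p·x^α + (1−p)·y^α)`) is provided; money space is the default
because its residual scale is comparable across situations. Non-convergence
of every start is reported as a flag, not an exception.

Discounting: per subject and model, the three utility-space residuals
`r_i = 10^α·D(t₁ᵢ) − SPᵢ^α·D(t₂ᵢ)` are minimised over the free parameters
with box bounds δ, β ∈ [0.001, 1], k ∈ [0.001, 100], start ladder
δ ∈ {0.3, 0.6, 0.9}, β ∈ {0.7, 0.95}, k ∈ {0.1, 0.5, 2}, lowest objective
winning (ties: lexicographically smallest parameter vector). Estimates
within 1e−6 of a bound are clamped to it and flagged — a present bias
wanting β > 1 is reported as β = 1, never allowed outside its range.

For consistent interior switch points the closed forms
`δ = (10/SP₃)^α` (month-vs-two-months list; β cancels between two
non-immediate dates) and `β = 10^α/(δ·SP₂^α)` (today-vs-month list) serve
as independent oracles; the optimiser must and does reproduce them to
1e−4 in the test suite, and the exponential fit is checked against an
exhaustive 100 001-point grid search.

## Model comparison

Per-subject Gaussian least-squares BIC, `n·ln(RSS/n) + p·ln(n)` with n = 3
observations and p free parameters (the additive constant cancels in
differences). Aggregation sums subject BICs within a scope (overall or one
group); a pooled-residual mode (`BIC` of summed RSS at summed n) is
available by configuration. An exact fit (RSS = 0) is representable: the
subject is flagged and excluded from aggregates with a warning. ΔBIC is
read on Raftery's scale: (0, 2] weak, (2, 6] positive, (6, 10] strong,
> 10 very strong; boundary values fall in the lower interval.

## Group inference

Small groups (< 30) and non-normal parameter distributions motivate rank
tests: the gate logs both the pooled Shapiro–Wilk p-value (at 0.05) and
the small-group condition. The omnibus test is tie-corrected
Kruskal–Wallis; post hocs are Dunn z-tests on the pooled ranks with the
standard tie term, two-sided (the conservative choice where sidedness is
unstated) and Bonferroni-multiplied with a cap at 1. Regressions of β and
δ on SOGS, a male indicator (derived from the sex field, M = 1) and age
use OLS with conventional standard errors. Correlations are Pearson,
reported as `r(df) = r` with df = n − 2.

## Power analysis

Two-sample t-test power is exact via the noncentral t distribution
(noncentrality d·√(n/2), df = 2n − 2); required n is the smallest integer
reaching the target power, found by upward search, never by a closed-form
approximation. Wilcoxon–Mann–Whitney sizing divides the fractional t-test
requirement by the asymptotic relative efficiency 3/π of the rank test
under a normal parent — the convention of standard power calculators,
which reproduces the pair (21, 22) at d = 0.79 — and a seeded Monte-Carlo
mode cross-checks the result by simulating the rank-sum test.

## Synthetic cohorts

Agents are drawn per group: α and k log-normal (median, log-σ), β and δ
logit-normal (median, logit-σ; supports respected by construction), SOGS
normal with the group mean/SD then rounded and clipped to the
instrument's 0–20 range, demographics (age, sex, income, alcohol,
smoking, education) normal with the study-condition moments, clipped to
sensible supports. Default group sizes are 26/23/25 (C/HG/PG); default
medians: α 0.95/0.98/1.53, β 0.98/0.97/0.84, δ 0.88/0.84/0.58,
k 0.16/0.25/1.08; SOGS means 0.42/3.96/8.36 (SD 0.99/2.96/3.82). The
logit/log spreads (0.25–0.5) roughly match the reported interquartile
ranges. Everything is determined by the configured seed (per-subject
noise streams are spawned from it), and identical configurations produce
byte-identical CSV bundles.

A noise-free agent maximises discounted power utility row by row — ties
go to the lottery in the risk task and to the sooner payment in the
discounting task, so a block can never flip more than once. With
`noise_temperature` τ > 0, each row's choice is logistic in the utility
difference divided by τ times the fixed option's utility; normalising by
the utility scale keeps τ dimensionless, because raw utilities 10^α span
orders of magnitude across agents. Noisy rows are independent, so fine
grids with many near-threshold rows produce realistic multi-switch
(excludable) blocks.

The exact stakes of the original 14 risk situations are not published;
the default templates keep the structure (two stake pairs, p ∈
{1/8, …, 7/8}, ascending certain-payment grids of 19 rows) and are fully
configurable, as are the later-amount grids (study default: 12–20 EUR in
steps of 2, the published example list).

**What the generator does not emulate:** hypothetical-vs-real incentive
effects, order and learning effects, loss-domain choices, and any
dependence of choice noise on delay or stake. Passing recovery tests
therefore demonstrate correctness of the estimation machinery under the
stated choice model, not behavioural realism of any particular cohort.

## Validation studies

**Parameter recovery** (`studies.parameter_recovery_study`): 200
noise-free agents per group, later amounts 10.1–150.1 EUR in 0.5 EUR
steps (the low start keeps near-patient agents — β·δ^(1/30) close to
1 — interior; the high end covers steep discounters in the generated
tails), risk grids at half the study step. Per agent the recovery error
is compared against the *grid-induced tolerance*: the spread of the
closed-form parameter across the bracketing grid amounts and across the
curvature interval that the certainty-equivalent brackets identify
(each CE bracket inverts to an α interval through the monotonicity of
the predicted CE in α; their intersection is the data-consistent set).
An estimator inside that tolerance has extracted everything the
discretised choices can identify.

**Model recovery and the boundary null**
(`studies.model_recovery_study`): cohorts of 10 PG-like agents are
simulated from a chosen generating model and adjudicated by summed BIC.
Two design points matter, both consequences of an identifiability
analysis rather than tuning:

1. *Grid*: with delays (0, 1) and (1, 2) months, data from a β = 1 agent
   are mutually consistent across the two future lists under exponential
   discounting, so the entire exponential RSS comes from the
   today-vs-tomorrow list, whose indifference amounts sit within a few
   percent of 10 EUR. A uniform coarse grid cannot resolve that region:
   its imputation error masquerades as present bias. The harness
   therefore uses a titration-style grid, 0.1 EUR steps over 10.1–12 and
   0.5 above (`synthetic.model_recovery_grid`).
2. *Convention*: with the midpoint convention the sign of the remaining
   short-delay discretisation residual is essentially symmetric, and its
   negative half is absorbed by β as spurious present bias — the β = 1
   null then maps outside the admissible space β ≤ 1 about half the
   time, and the two-parameter model earns more than the ln 3 BIC
   penalty from pure grid error. The conservative `last_pre` convention
   (never overstating the amount a subject demanded) makes the spurious
   component non-negative, the β estimate clamps at 1, and the null
   becomes interior-representable. Under it, β < 1 cohorts yield
   ΔBIC(exponential − quasi) in the hundreds while β = 1 cohorts yield
   ≈ −n·ln 3 (the penalty dominating), and hyperbolic-world cohorts are
   assigned the hyperbolic model.

The default estimation convention remains midpoint; `last_pre` is a
deliberate, documented choice of the model-recovery harness only.

## File schemas

| file | columns |
|---|---|
| `subjects.csv` | subject_id, group, sogs, age, sex, income, alcohol, smoking, education |
| `risk_choices.csv` | subject_id, situation_id, x, y, p, certain_payment, choice (L/C), row_index |
| `discount_choices.csv` | subject_id, task_id, t1_months, t2_months, sooner_amount, later_amount, choice (A/B), row_index |
| `truth.csv` (synthetic only) | subject_id, alpha, beta, delta, k |
| `fits.csv` | subject_id, model, delta, k, beta, rss, n_points, n_free, converged, boundary_flags, alpha |
| `exclusions.csv` | subject_id, reason |
| `model_comparison.csv` | comparison, then per scope (overall, C, HG, PG): ΔBIC and evidence label |
| `group_stats.csv` | variable, test, statistic, df, p_value, shapiro gate, per-pair Dunn z and adjusted p |
| `regressions.csv` | outcome, term, estimate, se, p, r_squared, n_obs |
| `correlations.csv` | scope, r, df, p, formatted |

CSV dialect: UTF-8, comma-separated, one header row, `.` decimal
separator; every output starts with a `# config_hash=…` provenance line
and the resolved configuration is serialised next to the outputs as
`run_config.yaml`.

## Known limitations

- Three switch points per subject is the identification floor: the
  quasi-hyperbolic fit is exactly determined up to one residual
  dimension, so per-subject BIC differences lean on very little data;
  aggregate (summed) comparisons are the meaningful ones.
- Censored blocks carry only interval information; the half-step
  imputation is a convention, and group contrasts of near-boundary
  parameters (β close to 1) inherit it.
- The α correction treats curvature as error-free in step 4; no
  uncertainty propagates from the risk task into the discounting fit.
- Monthly-unit δ and the 1/30 tomorrow coding are conventions; estimates
  are only comparable across studies using the same coding.
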