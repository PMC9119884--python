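# betadelta

Risk-corrected temporal-discounting estimation from multiple-price-list
(MPL) choice data, built for studies that compare delay discounting across
gambling groups (non-gambling controls **C**, habitual gamblers **HG**,
problem gamblers **PG**).

## The scientific problem

People discount delayed rewards; problem gamblers discount them unusually
steeply. Competing models disagree about *how*:

- **exponential**: `DU(x, t) = δ^t · U(x)` — constant per-period discount
  factor δ ∈ (0, 1];
- **hyperbolic**: `DU(x, t) = U(x) / (1 + k·t)` — declining impatience with
  rate k > 0;
- **quasi-hyperbolic (β–δ)**: `DU(x, 0) = U(x)` and
  `DU(x, t) = β · δ^t · U(x)` for t > 0 — an immediate present bias
  β ∈ (0, 1] on top of long-run discounting δ.

Because discounting operates on utility rather than money, curvature must
be removed first: each subject's power utility `U(x) = x^α` is estimated
from the certainty equivalents (CE) of binary gain lotteries, where
`CE^α = p·x^α + (1 − p)·y^α`. Estimation then proceeds per subject:

1. estimate α from the 14 risk-task certainty equivalents;
2. transform the fixed 10 EUR sooner payment, `U(10) = 10^α`;
3. transform each intertemporal switching point, `U(SP) = SP^α`;
4. solve `DU(10, t₁) ≈ DU(SP, t₂)` for the model parameters (δ; k; or
   β, δ) by nonlinear least squares over the three MPL tasks
   (today vs tomorrow, today vs one month, one month vs two months;
   delays in months, tomorrow = 1/30).

Models are adjudicated by summed BIC with Raftery's ΔBIC evidence scale,
groups are compared with Shapiro–Wilk-gated Kruskal–Wallis tests and
Dunn–Bonferroni post hocs, severity effects with OLS of β and δ on SOGS
(South Oaks Gambling Screen), and the planned two-group contrast is sized
with noncentral-t / Wilcoxon–Mann–Whitney power calculations.

A first-class synthetic-cohort generator simulates agents with known
(α, β, δ, k), SOGS scores and demographics, pushes them row by row through
both MPL tasks, and lets every stage be validated by parameter recovery —
no data download needed.

## Worked example

```bash
betadelta simulate --seed 7 --n-per-group 26,23,25 --out demo/data
betadelta stats --data demo/data --out demo/run
betadelta power --d 0.79
```

The simulate step writes a 74-subject bundle (`subjects.csv`,
`risk_choices.csv`, `discount_choices.csv`, plus `truth.csv` with the
generating parameters). The stats step runs the full pipeline and prints
the δ–β correlations:

```
overall: r(72)=0.46, p=4.14e-05
C: r(24)=-0.06, p=0.789
HG: r(21)=0.01, p=0.977
PG: r(23)=-0.43, p=0.0331
```

`group_stats.csv` holds the omnibus and post hoc battery — for this seed
the β comparison gives H(2) = 44.82, p < 0.001, with PG differing from
both C and HG (adjusted p ≤ 0.0001) while C vs HG does not reject
(p = 0.102): the generated problem gamblers are detectably more
present-biased. `regressions.csv` shows β falling by 0.011 and δ by 0.031
per SOGS point (both p < 0.001). The model-comparison table
(`model_comparison.csv`) reads:

```
                    comparison    overall  overall_evidence ...         PG PG_evidence
exponential - quasi_hyperbolic 468.068296       very_strong ... 284.760853 very_strong
 hyperbolic - quasi_hyperbolic 461.373176       very_strong ... 288.666914 very_strong
```

i.e. very strong summed-BIC evidence for the β–δ model, strongest in the
PG group — the qualitative signature of present-biased discounters. And

```
   d  n_ttest  n_wmw
0.79       21     22
```

is the sizing of a two-group contrast for an effect of d = 0.79 at
one-sided α = 0.05 and 80% power: 21 subjects per group for the t-test,
22 for the rank-sum test (3/π efficiency).

File schemas are documented in `docs/methods.md`; every output carries the
resolved run-configuration hash in a `#` header line.

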