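# sparselogit

Odds-ratio estimation for **sparse binary data**: few events, unbalanced
covariate levels, or both.  In that regime the maximum-likelihood (ML)
odds ratio from a logistic regression can be biased upward or downward by
a large factor — even in big cohorts — and can be infinite under
separation.  `sparselogit` implements eight estimators side by side so
that epidemiologists and biostatisticians can compare them on the same
data, together with a scenario-based simulation engine for studying
their bias, coverage and convergence behavior.

## Methods

For outcomes $Y_i \sim \mathrm{Bernoulli}(\pi_i)$ with
$\operatorname{logit}(\pi_i) = \beta^\top x_i$ (intercept at position 0):

| Label | Estimator | Point estimate |
|-------|-----------|----------------|
| `ML`  | maximum likelihood | root of the score $U(\beta)=\sum_i (y_i-\pi_i)x_i$ |
| `FIR` | Firth's penalized likelihood | maximizer of $l(\beta)+\tfrac12\log\lvert I(\beta)\rvert$ |
| `EX`  | exact conditional | conditional MLE of the sufficient statistic $T_j=\sum_i y_i x_{ij}$ given all other $T_J$; median-unbiased at the support boundary |
| `MDP` | mid-P exact | same point estimate, tail inversion with half weight on the observed point mass |
| `NP`  | Bayesian, $N(0,100)$ prior | posterior median |
| `HG`  | Bayesian, hyper-g prior $\beta\mid g \sim N(0, g\,\mathrm{diag}(\tfrac12))$, $f(g)=\tfrac{a-2}{2}(1+g)^{-a/2}$, $a=4$ | posterior median |
| `F1`  | log F(1,1) data augmentation | maximizer of $l(\beta)+\beta_j/2-\log(1+e^{\beta_j})$ |
| `F2`  | log F(2,2) data augmentation | maximizer of $l(\beta)+\beta_j-2\log(1+e^{\beta_j})$ |

Frequentist intervals are profile-likelihood (deviance inversion);
exact/mid-P intervals invert the conditional tail probabilities;
Bayesian intervals are equal-tailed 95% credible intervals.

## Worked example

The bundled cohort table for hydramnios vs neonatal death (1 death among
10 exposed births, 16 among 2,982 unexposed) is the canonical sparse
2×2: the event is rare and the exposure is rare.

```python
from sparselogit import (TwoByTwoTable, fit_ml, fit_firth, fit_logf,
                         LogFPriorSpec, profile_likelihood_ci)
import numpy as np

data = TwoByTwoTable(a=1, b=9, c=16, d=2966).to_dataset()

ml = fit_ml(data)
lo, hi = profile_likelihood_ci(data, ml, 1)
print(f"ML   OR {ml.odds_ratio():.1f}  ({np.exp(lo):.1f}-{np.exp(hi):.1f})")
print(f"FIR  OR {fit_firth(data).odds_ratio():.1f}")
print(f"F1   OR {fit_logf(data, LogFPriorSpec(1.0)).odds_ratio():.1f}")
print(f"F2   OR {fit_logf(data, LogFPriorSpec(2.0)).odds_ratio():.1f}")
```

prints

```
ML   OR 20.6  (1.1-119.6)
FIR  OR 28.4
F1   OR 11.2
F2   OR 5.6
```

The ML odds ratio of 20.6 is implausibly large for a single exposure;
Firth's penalty moves it *further* from the null (a documented artifact
of the Jeffreys prior on very sparse tables), while the log-F priors —
which encode 95% prior odds-ratio intervals of roughly (1/648, 648) for
F(1,1) and (1/39, 39) for F(2,2) — shrink it to 11.2 and 5.6.

The same comparison for all eight methods:

```bash
sparselogit case-study            # bundled tables, Table-style report
sparselogit simulate --scenario 4 --n 100 --ne 5 --pix1 0.05 --or 1 \
    --reps 1000 --seed 7 --out metrics.csv
sparselogit fit mydata.csv --outcome died --methods ML,FIR,F1,F2
```

## Simulation engine

`ScenarioConfig`/`generate_replicates` reproduce six covariate
scenarios (a lone rare exposure up to an eight-covariate cohort mimic),
with the intercept calibrated by exact enumeration so the expected
event count hits a target `n_e`.  `run_scenario_cell` +
`summarize` compute per-method bias, average OR, coverage and
convergence rates, restricted (by default) to replicates where the ML
fit converged with the exposure OR inside the estimability window
[0.001, 999].

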