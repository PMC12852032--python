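# c2pkpd

PK/PD modelling and outcome statistics for a preclinical anti-complement-C2
antibody program in rats.

Complement component C2 sits at the junction of the classical and lectin
pathways; blocking it is a candidate strategy against ischemia-reperfusion
injury such as delayed graft function after kidney transplantation.  This
package re-implements, as a tested and reusable pipeline, the computational
core of such a program:

* **`c2pkpd.tmdd`** — a target-mediated drug disposition (TMDD) model:
  two-compartment antibody kinetics (CL, V_c, Q, V_p, zero-order input)
  coupled to target turnover and binding,

  dA_c/dt = In(t) − (CL/V_c)A_c − (Q/V_c)A_c + (Q/V_p)A_p − V_c(k_on·C·R − k_off·RC)
  dA_p/dt = (Q/V_c)A_c − (Q/V_p)A_p
  dR/dt   = k_in − k_out·R − k_on·C·R + k_off·RC
  dRC/dt  = k_on·C·R − k_off·RC − k_int·RC

  with C = A_c/V_c in nM of binding sites, observables total antibody
  (C + RC), free C2 (R) and total C2 (R + RC) in µg/mL.
* **`c2pkpd.nca`** — non-compartmental analysis of IV-bolus profiles:
  linear-up/log-down AUC and AUMC, adjusted-R² lambda-z window selection,
  C0 back-extrapolation, AUC∞, CL, V_z, V_ss.
* **`c2pkpd.population`** — nonlinear mixed-effects estimation by SAEM
  (stochastic-approximation EM) with log-normal inter-individual
  variability, proportional residual error, the M3 left-censored
  likelihood for below-LLOQ free-C2 data (each BLQ record contributes
  log Φ((LLOQ − f)/s)), empirical-Bayes estimates and visual predictive
  checks.
* **`c2pkpd.regimen`** — virtual-population simulation and dose-regimen
  evaluation against the ≥95% free-C2 suppression criterion
  (LLOQ 0.9375 µg/mL = 5% of the 18.75 µg/mL baseline).
* **`c2pkpd.outcomes`** — transplant-outcome statistics on log scales: a
  day-3 heterogeneous-variance model (Welch–Satterthwaite) and
  longitudinal REML models with per-treatment-group heterogeneous
  compound-symmetry (CSH) or ARH(1) covariance, with Wald contrasts
  reported as percent reductions.
* **`c2pkpd.synthetic`** — generators that emulate both study designs:
  the single-ascending-dose PK/PD study (2–50 mg/kg, n=3/group, nine
  sampling times over 21 days, two pre-dose baselines) and the
  kidney-transplant outcome study (creatinine/BUN/NGAL at days 3, 5, 7,
  14 with group sizes 18/11/9/7 vs 9/8/7/6).
* **`c2pkpd.pipeline` / `c2pkpd.cli`** — configuration, seed substreams,
  run manifests and turnkey replications (`c2pkpd replicate-pkpd`,
  `c2pkpd replicate-outcomes`).

## Worked example

```python
import numpy as np
from c2pkpd import *

grid = np.linspace(0, 21, 421)
prof = simulate_individual(DEFAULT_PARAMS, expand_regimen([(0, 50)]), grid)
# free C2 at day 21 after one 50 mg/kg dose:
print(prof.c2_free_pct_baseline[-1])     # 2.78  (% of baseline: >95% suppressed)

model, pk_design, outcome_design = default_generator_config()
summary = evaluate_regimen(model, expand_regimen([(0, 50), (3, 25)]),
                           n=200, horizon=14.0, seed=1)
print(summary.median_duration)           # 14.00 (days, censored at horizon)

table = generate_transplant_outcomes(outcome_design, seed=1)
day3 = fit_day3(table, "creatinine")
fit = fit_longitudinal(table, "creatinine", "CSH")
across = wald_contrast(fit, "across-days")
print(round(day3.pct_reduction, 1))      # 47.5  (% lower creatinine, day 3)
print(round(across.pct_reduction, 1))    # 48.0  (% lower across days 3-14)
```

The typical-rat 50 mg/kg profile prints (µg/mL):

```
day  0.25: mab 1081.5   free C2 0.022 ( 0.11%)   total C2  24.1
day     3: mab  513.6   free C2 0.058 ( 0.31%)   total C2  73.1
day    14: mab  282.2   free C2 0.199 ( 1.06%)   total C2 159.2
day    21: mab  192.0   free C2 0.521 ( 2.78%)   total C2 174.3
```

Free C2 stays below 5% of its 18.75 µg/mL baseline for the full 21 days
while total C2 accumulates ~9.3-fold (complex is cleared ten times slower
than free target, k_out/k_int = 10).  The one-dataset outcome estimates
(47.5% and 48.0% above) scatter around the generating effects of 40% and
49%; their Monte-Carlo means over 500 replicates are recovered by the
acceptance script below.

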