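# Methods

This note records the models, the frozen default parameters and the design
choices behind `c2pkpd`, in the spirit of a model-description vignette.

## Structural PK/PD model

Antibody disposition is a two-compartment model with linear clearance and
zero-order input; an IV bolus is represented as a 0.001-day (~1.4 min)
infusion, configurable per dose event.  Target (C2) kinetics follow the
full TMDD form: zero-order synthesis `kin`, first-order degradation
`kout`, second-order binding `kon`, dissociation `koff`, and first-order
elimination of the complex `kint`.  The bivalent IgG is modelled per
binding site (two independent sites of 75 kDa each), which keeps a single
second-order reaction while preserving molar binding capacity; doses in
mg/kg convert to nmol/kg of sites.  The complex is confined to the
central compartment and there is no peripheral target — the minimal
structure consistent with a one-compartment target description.  The
internal unit system is nM, nmol/kg and days; all I/O is µg/mL, mg/kg and
days, with conc(µg/mL) = conc(nM)·MW·1e-6 (MW 102 kDa for C2).

Integration uses LSODA (stiff-capable) with relative tolerance 1e-9 and
absolute tolerance 1e-12 nM, integrating piecewise between infusion
switch points and keeping per-segment dense output so threshold crossings
can be refined by bisection against the continuous solution.  States are
clipped at zero only for reporting, never inside the right-hand side; a
state below −1e-6·max(R0, 1) aborts with an integration error.

### Default parameters

| parameter | value | unit | rationale |
|---|---|---|---|
| CL | 0.004712 | L/day/kg | with Vc, Q, Vp: terminal t½ = 12.5 d |
| Vc, Vp | 0.040 | L/kg | plasma-scale central volume |
| Q | 0.020 | L/day/kg | inter-compartment clearance |
| Tinf | 0.001 | day | IV bolus as a short zero-order input |
| kin | 238.97 | nM/day | R0 = kin/kout = 183.8 nM = 18.75 µg/mL |
| kout | 1.3 | 1/day | see calibration note below |
| kon | 0.0864 | 1/(nM·day) | KD = koff/kon = 1 nM, slow off-rate |
| koff | 0.0864 | 1/day | |
| kint | 0.13 | 1/day | kout/kint = 10 → ~10-fold total-C2 plateau |
| mw_site | 75 000 | g/mol | 150 kDa IgG, 2 sites |
| mw_target | 102 000 | g/mol | human C2 mass assumed for rat |

The baseline 18.75 µg/mL is pinned by the free-C2 assay LLOQ of
0.9375 µg/mL corresponding to exactly 5% of baseline (≥95% suppression).

**Calibration of the turnover scale.**  Four observations constrain the
target arm jointly: (i) the 12.5-day terminal half-life of the antibody,
(ii) the 18.75 µg/mL free-C2 baseline, (iii) a ~10-fold rise of total C2
within the 21-day study at ≥25 mg/kg, and (iv) ≥95% free-C2 suppression
for the full 21 days at 50 mg/kg.  (i) and (ii) fix CL/Vc/Q/Vp and
kin/kout; (iii) fixes the ratio kout/kint = 10 and requires kint·21 to be
large enough to approach the plateau; (iv) caps the absolute turnover
scale, because every eliminated complex consumes one antibody binding
site — the cumulative consumption is ≈ kin·Vc per day at saturation, and
a turnover scale too fast exhausts a 50 mg/kg dose (667 nmol sites/kg)
before day 21 and lets free C2 rebound.  kout = 1.3/day (kint = 0.13,
kin = 238.97 nM/day) balances (iii) against (iv): the typical rat ends
day 21 at 2.8% of baseline and peaks at a 9.3-fold total-C2 rise.  The
value was chosen once from a scan of kint ∈ [0.11, 0.17] and frozen.

## Non-compartmental analysis

IV-bolus conventions: C0 is back-extrapolated log-linearly through the
first two quantifiable points (falling back to the first observed value
when they do not decline); the [0, t1] segment uses C0; AUC/AUMC use the
linear-up/log-down rule per segment (the log trapezoid is exact for
exponential decay); lambda-z is searched over terminal windows (last
3, 4, … points after excluding Cmax) by maximal adjusted R², ties within
1e-4 resolved toward more points; extrapolation uses the observed last
quantifiable concentration.  BLQ records are excluded outright — no
zero-substitution — which protects the terminal phase; the antibody
profiles this NCA is applied to contain no interior BLQ by design.

## Population estimation (SAEM + M3)

Inter-individual variability is log-normal with diagonal omega on the
structural parameters; residual error is proportional per observable
(antibody and free C2 get separate sigmas) with an SD floor of
sigma·LLOQ/2 to avoid degeneracy as predictions approach zero.  BLQ
observations contribute the left-censoring probability log Φ((LLOQ−f)/s)
(the M3 treatment), evaluated through the log-CDF so deep censoring stays
finite; rows after the last quantifiable observation are retained.

The E-step runs component-wise random-walk Metropolis on each
individual's log-parameters phi (prior N(log theta, omega)) — sampling
phi rather than deviations keeps cached predictions valid across M-step
updates of theta.  Three transitions per individual per iteration;
proposal scales adapt by ±10% toward a 30–45% acceptance rate.  The
M-step applies stochastic-approximation updates (step 1 during the K1
burn-in, then 1/(k−K1)) to the sufficient statistics, giving closed-form
updates: theta from the mean of phi, omega from second moments (floored
at 1e-6), sigma from mean squared weighted residuals of quantified rows.
Defaults K1=300, K2=200, one chain; runs are bit-reproducible given the
seed.  The binding constants kon/koff default to fixed: an LLOQ-censored
free-C2 design cannot identify them at this scale.  If no estimated
parameter carries IIV the fit degenerates to a pooled Nelder-Mead
maximum-likelihood optimisation.  Empirical-Bayes estimates maximise the
individual posterior from the prior mode and one random start.

The VPC simulates replicate studies under the design, applies the same
BLQ censoring to both sides, imputes censored values at LLOQ/2, and
reports 5/50/95 percentile bands of the per-time medians.

## Regimen evaluation

Virtual rats draw eta ~ N(0, omega); profiles run on a 0.05-day grid and
the ≥95%-suppression crossings are refined by bisection on the continuous
solution (sub-hour accuracy).  An individual's suppression duration is
the length of the first contiguous interval with free C2 ≤5% of the
model baseline, censored at the horizon.  The regimen success statistic
is the population median duration — the criterion quantile is not
otherwise pinned down — with the 5th percentile reported alongside.

## Outcome statistics

All outcome models work on log values.  The day-3 model is a two-group
linear model with heterogeneous residual variance, i.e. Welch's
comparison with Satterthwaite df in closed form.  The longitudinal model
has group, day and group×day as categorical fixed effects
(reference-cell coding, control/day-3 reference) and block-diagonal
residual covariance by animal with per-treatment-group parameters:
CSH, cov(s,t) = σ_s σ_t [ρ + (1−ρ)1(s=t)], or ARH(1),
cov(s,t) = σ_s σ_t ρ^|pos(s)−pos(t)| with positional lags (days
3/5/7/14 → positions 1–4, matching the usual repeated-measures
definition rather than calendar spacing).  Fitting is REML; the
quadratic form is evaluated in a centred decomposition (within-pattern
scatter plus explicit mean residuals) and the GLS system is solved with
diagonal equilibration, so exactly-noise-free data are interpolated
without loss of precision; residual SDs are floored at 1e-4 and the
correlation is bounded to (−0.99, 0.99) via a tanh transform.
Optimisation is derivative-free Nelder-Mead from three deterministic
starts (moment-based SDs with ρ=0.3, pooled flat SDs with ρ=0, moment
SDs with ρ=0.7); the guard starts run on a reduced budget and are
polished only if they win.  Animals with partial follow-up contribute
their available rows (likelihood-based missing-at-random handling).

Contrasts: "day-3" is the group difference at the reference day;
"across-days" averages the four per-day group differences on the log
scale (the interaction-averaged definition).  Effects are reported as
100·(1 − exp(cᵀβ)) with CI endpoints transformed the same way.  Degrees
of freedom are Satterthwaite — 2(cᵀVc)²/(∇ᵀ Var(θ̂) ∇) with the gradient
and the REML information obtained by central finite differences — used
in place of Kenward-Roger, which would require the full adjusted
covariance; for these designs the two are near-identical.  An
independent cross-check against `nlme::gls` (REML, `varIdent` +
`corCompSymm`/`corAR1`) agrees to six decimals on single-group data.

## Synthetic-data generators

The PK/PD generator draws per-animal random effects, simulates the TMDD
model at the protocol times, applies proportional noise, and left-censors
at the LLOQ while writing the uncensored values to a separate truth
table; pre-dose baselines get independent proportional noise around the
individual steady state.  The default conditions are: doses 2/5/10/25/50
mg/kg, three rats each; samples at 5 min, 6 h, 24 h, 48 h, days 3, 5, 7,
14, 21 plus baselines at −7 and −1 days; omega 0.05 on CL, Vc, kin;
sigma 0.10 (antibody) and 0.15 (free C2); LLOQs 0.1 (antibody — chosen
low enough that no antibody record censors) and 0.9375 µg/mL (free C2).

The outcome generator draws each animal's four-day log-vector from a
multivariate normal with per-day means, one per-group SD and CS(ρ=0.4)
(creatinine) or AR1(ρ=0.5) (BUN, NGAL) correlation, exponentiates, and
truncates follow-up deterministically to the published per-day group
sizes (18/11/9/7 treated, 9/8/7/6 control).  Only the treated/control
ratios and the SDs are calibrated to reported effects — creatinine
multipliers 0.60/0.45/0.50/0.50 (day-3 effect 40%, across-day 49.0%),
BUN 0.67/0.466³ (33% and 49.0%), SDs chosen so the day-3 Welch SE at the
printed sizes (~0.189 for creatinine) matches the reported CI width.
Absolute levels (creatinine 4.0→0.8 mg/dL, BUN 120→30 mg/dL, NGAL fold
8→2) are plausible placeholders for a severe ischemia-reperfusion course
that resolves over two weeks.  Attrition is deterministic, not a dropout
process — the published group sizes are reproduced exactly, so mortality
dynamics are out of scope.

What the generators do **not** emulate: assay mechanics (plate effects,
calibration curves), dose-timing deviations, correlated IIV, covariate
effects, or informative dropout.  Passing recovery tests therefore shows
the estimators are consistent under their own assumptions at the study's
sample sizes, not that those assumptions hold in real data.

## Problem sizes and numerical choices in the test suite

Monte-Carlo checks use the sizes the analyses prescribe: 500 replicates
for the outcome-effect recoveries, 1000 for day-3 CI coverage, 1000
virtual rats for the regimen criterion.  The SAEM recovery test runs
K1=100/K2=60 on the rich 30-animal design, which is well past trajectory
stabilisation for a two-parameter linear sub-model; omega recovery is
judged against the realised variance of the generated random effects,
the generating truth for that dataset.  SAEM simulations inside the
E-step use rtol 1e-8 (the estimation target is statistical, not
quadrature-limited); all reported simulations use the 1e-9 default.

## Known limitations

* Full TMDD only — no quasi-steady-state or quasi-equilibrium variants;
  no subcutaneous absorption, FcRn recycling, peripheral target, or
  complement-activity (C3-deposition) output.
* Whether the antibody assay measures total or free drug is ambiguous;
  the observable is defined as total antibody (free + complexed sites).
* Diagonal omega; no covariate model; no FOCE/Laplace alternative.
* The day-3 and across-days contrasts assume the day set {3,5,7,14};
  other day sets reuse the first day as reference.
* Satterthwaite df relies on finite-difference curvature of the REML
  surface and can be unstable when a variance sits at its floor.
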