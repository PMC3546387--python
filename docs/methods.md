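# Methods

## Model

`tvcsim` generates event times from a Cox proportional-hazards model with one
time-varying covariate z(t) and a vector of fixed covariates x entering
through their linear predictor η = β′x:

    h(t | x, z(·)) = h0(t) · exp(β_t · z(t) + η),

with the log link throughout, as is standard for Cox regression in the
biomedical literature.  β_t is the log hazard ratio per unit of z.  Event
times are produced by the inverse cumulative-hazard transform: with
u ~ U(0,1),

    T = H⁻¹(−log u),        H(t) = ∫₀ᵗ h0(s) · exp(β_t z(s) + η) ds.

Three baseline families are supported — the only standard parametric
survival families that share the proportional-hazards property:

| family      | h0(t)          | H0(t)               | H0⁻¹(h)              |
|-------------|----------------|---------------------|-----------------------|
| exponential | λ              | λt                  | h/λ                   |
| Weibull     | λν t^(ν−1)     | λt^ν                | (h/λ)^(1/ν)           |
| Gompertz    | λ e^(αt)       | (λ/α)(e^(αt) − 1)   | (1/α) log(1 + αh/λ)   |

Weibull ν = 1 and Gompertz α = 0 coincide with the exponential (the α → 0
limit is taken analytically, with a guard for subnormal α).  For Gompertz
α < 0 the total hazard saturates at λ/(−α): targets at or beyond the bound
return the +∞ never-event sentinel, which censoring later converts to a
censored record.  There is no silent truncation of event times.

## Covariate paths and closed-form inversion

Piecewise-constant paths (time-invariant, single 0→1 switch at t0,
alternating multi-switch with any number of switches) use the segment
decomposition of H: over exposure intervals with constant z_j,
H accrues as exp(η + β_t z_j)·[H0(stop) − H0(start)], so the inverse locates
the interval whose cumulative-hazard range contains the target (computed at
the breakpoints) and applies the segment's analytic inverse.  Conventions:

* switches are left-closed — the switch instant belongs to the post-switch
  state — which keeps H continuous and the piecewise inverse well defined;
* a target exactly equal to a breakpoint hazard belongs to the *later*
  interval, consistent with left closure (the two branches agree at the
  boundary, so this only fixes which formula is evaluated);
* the inverse multiplies by exp(−(η + β_t z_j)) rather than dividing by the
  exponential, so that the degenerate cases (t0 = 0, or β_t = 0) reproduce
  the classical time-invariant draws bit-for-bit where the float paths
  coincide and to ulp-level accuracy otherwise.

The linear cumulative-dose path z(t) = k·t (constant dose rate k > 0) has
closed-form H and log-form inverse under exponential and Gompertz baselines
(effective rate b = β_t·k shifts the exponential/Gompertz slope).  Under a
Weibull baseline the integrand λν s^(ν−1) e^(bs) has no elementary
antiderivative for general ν:

* for b < 0, H(t) is a scaled regularized lower incomplete gamma function;
  `scipy.special.gammainc/gammaincinv` evaluate and invert it exactly, and
  the total hazard saturates at λ e^η Γ(ν+1) (−b)^(−ν);
* for b > 0, H is evaluated by the everywhere-convergent power series
  ∫₀ᵗ s^(ν−1) e^(bs) ds = t^ν Σ_m (bt)^m / (m!(ν+m)) and inverted by
  bracketed Brent root finding;
* `invert_closed_form` deliberately raises for this combination rather than
  silently falling back — sampling (`draw_event_times(method="auto")`) routes
  it through the exact special-function path above.

A companion pair, `cumulative_hazard_powerscale_dose` /
`invert_linear_dose_weibull_powerscale`, implements the related dose path
z(t) = k·t^ν (dose accruing uniformly in operational Weibull time), the only
dose path for which the Weibull baseline admits a log-form closed inverse:
T = [log(1 + β_t k h e^(−η)/λ) / (β_t k)]^(1/ν).  It is kept clearly distinct
from the calendar-time dose z(t) = k·t; a test verifies by quadrature which
integrand each corresponds to, and that the two differ.

## Numeric oracle

`invert_numeric` brackets the root of H(t) = target by doubling from t = 1
and polishes with Brent's method (relative tolerance 1e−12, absolute 1e−14);
if H stays below the target out to a configurable horizon (default 1e12) it
returns +∞.  For the Weibull/linear-dose pair it integrates the hazard by
adaptive quadrature instead of reusing the series/incomplete-gamma forms, so
the oracle stays independent of every closed-form path it validates.  The
randomized oracle-equivalence check (1000 instances across families,
trajectories, parameter ranges λ ∈ [1e−3, 1], ν ∈ [0.4, 2.5], α ∈ [−0.3, 0.3],
η, β_t ∈ [−1.5, 1.5]) asserts agreement to 1e−8 relative.

## Censoring and counting-process export

Times are in days throughout.  Two mechanisms:

* **fixed-percentile** (administrative): all subjects censored at the
  empirical p-th percentile (linear-interpolation quantile, fixed for
  reproducibility) of the finite event times, default p = 0.32 so events are
  observed for ~32% of subjects.  The cutoff is computed per replicate over
  all generated event times (the source study does not say whether it is
  taken before or after treatment assignment; this is the package's choice).
* **uniform** (random): per-subject censoring time C ~ U(1 day, q75), q75 the
  75th percentile of finite event times; observed time = min(T, C).

Follow-up is exported as counting-process (start, stop] records on which z is
constant; the final record carries the event status, zero-length intervals
are dropped, and intervals tile [0, observed time] exactly.  A linear-dose
path is exported on an explicit user-supplied grid (a documented
approximation; the power study uses only binary treatments).

## Cox fitting

Counting-process rows are fitted as left-truncated observations (`entry` =
interval start), the standard Andersen–Gill encoding of start–stop data, via
`statsmodels` `PHReg` with Breslow tie handling and Newton iterations (BFGS
fallback before a replicate is flagged nonconvergent and excluded, with a
logged count).  A test verifies the fit agrees with lifelines'
`CoxTimeVaryingFitter` on the same records to 1e−5; `PHReg` is used in the
replicate loop because its vectorized likelihood makes thousand-replicate
studies practical on one CPU.

## Synthetic population for the power study

The power experiment emulates a registry-based design whose fitted linear
predictors are not public, so the cohort is a structural stand-in: one
standardized-normal continuous covariate (age) and ten binary
severity/comorbidity indicators (female 35%, CHF 15%, cardiogenic shock 2%,
arrhythmia 10%, pulmonary edema 5%, complicated diabetes 8%, stroke 4%,
acute renal disease 3%, chronic renal disease 3%, malignancy 5%) with
log-hazard coefficients between 0.15 and 1.8 chosen once so that sd(η) ≈ 1.0,
the spread typical of a validated mortality prediction rule (c-statistic
near 0.8).  Prevalences and coefficients are configurable.  Samples of 2500
are drawn with replacement from a 115,856-row population table, mirroring the
emulated study's resampling design.

Consequences: absolute power values and the pre-treatment death fractions
depend on this stand-in η distribution and on the baseline parameters, so
they characterize the synthetic conditions, not the original registry; only
qualitative orderings across scenarios are asserted.  What the generator does
not emulate: covariate correlations (covariates are independent), measurement
error, model misspecification of the mortality rule, and calendar-time entry
staggering.

## Power study design

Baseline Weibull(λ = 0.001, ν = 0.6) (time in days), treatment hazard ratios
0.5–0.95 in steps of 0.05, 1000 replicates by default.  Five binary-treatment
scenarios on a 13,581-day window w: S1 — 50% treated from baseline, 50% never;
S2 — all treated at t0 ~ U(1, w); S3 — as S2 with t0 ~ U(1, 6000);
S4 — 50% alternate at w/3, 2w/3, w (ending treated), 50% never;
S5 — 50% alternate at w/3, 2w/3 (ending untreated), 50% never.  The 50%
allocations are exact n//2 splits over a seeded shuffle (the source design
does not say exact vs Bernoulli; exact was chosen for lower Monte-Carlo
variance).  Each replicate fits treatment (time-varying) plus the eleven
fixed covariates (`adjust="covariates"`; `"eta"` fits the true linear
predictor as a single covariate — statistically equivalent adjustment, useful
when speed matters) and records the two-sided Wald p-value at α = 0.05; no
multiplicity adjustment across the grid, since each cell is a separate
experiment.  Power is the rejection fraction with binomial Monte-Carlo
standard error √(p(1−p)/R).  Replicates are seeded from the master seed via
`SeedSequence` spawn keys (cell index, replicate index), making the full grid
reproducible and cells independent.

For S2/S3 the fraction of subjects dying before their assigned treatment
time is reported as a diagnostic; under administrative censoring at the 32nd
percentile it comes out near 25% (S2) and 15% (S3) for the default synthetic
population.

## Problem sizes

Validation runs use: 1000 randomized instances for oracle equivalence;
100,000 draws per family × trajectory cell for the distributional (KS) check;
50 seeds × n = 10,000 for parameter recovery; 2000 replicates × n = 500 for
null calibration; 200 replicates × n = 2500 × 5 scenarios for the power
ordering.  `scripts/acceptance.py` recomputes the same quantities at smaller
desk scale (400 instances, 20,000 draws, 10 × n = 4000 recovery, 800 null
replicates, 100 power replicates at n = 1000), sizes chosen so a full run
completes in a few minutes on one CPU while keeping every Monte-Carlo
standard error small relative to the effects examined.

## Known limitations

* One time-varying covariate per subject; no time-varying *coefficients*, no
  competing risks, no frailty, no left truncation of the generated data
  (truncation appears only as the fitting encoding), no informative
  censoring.
* Continuous paths other than z(t) = k·t (and its power-scale variant) are
  out of scope; a measured-biomarker path would need the numeric route.
* The Weibull/linear-dose b > 0 series evaluation overflows to +∞ for
  b·t ≳ 700; event-time targets (−log u) never reach that regime, but direct
  cumulative-hazard queries at extreme times can.
* Wald tests at very small event counts (< ~40 events) can be mildly
  anticonservative; the calibration check is run at n = 500 with ~160 events.
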