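# tvcsim

Simulate event times from Cox proportional-hazards models with **time-varying
covariates**, and use the simulator for Monte-Carlo power studies of
time-varying treatments.

Simulation studies of survival methods need a data-generating process.  For
time-invariant covariates the classical recipe inverts the baseline
cumulative hazard: `T = H0⁻¹(−log u / exp(β′x))`, `u ~ U(0,1)`.  But many
exposures change during follow-up — an organ transplant received mid-study, a
drug started and stopped, a dose accumulating day by day — and analysing such
an exposure as if fixed at baseline produces immortal-time bias (the
hazard-ratio estimate is pulled below the truth, because pre-exposure
person-time can contain no deaths among the exposed).  Studying that bias, or
computing power for a time-dependent treatment, requires generating event
times whose hazard actually tracks z(t).

`tvcsim` implements the model

    h(t | x, z(·)) = h0(t) · exp(β_t · z(t) + β′x)

for exponential, Weibull, and Gompertz baselines — the three standard
parametric families with the proportional-hazards property — and inverts the
subject-specific cumulative hazard **in closed form** for:

* a binary covariate switching 0 → 1 once at time t0 (`SingleSwitchTrajectory`),
* a binary covariate alternating any number of times (`PiecewiseBinaryTrajectory`),
* a linear cumulative dose z(t) = k·t under exponential/Gompertz baselines
  (`LinearDoseTrajectory`; the Weibull case has no elementary closed form and
  is handled by exact incomplete-gamma / root-finding inversion),
* the degenerate time-invariant covariate (`TimeInvariantTrajectory`), to
  which every formula reduces when t0 = 0 or β_t = 0.

A numeric inversion of the integral-defined cumulative hazard ships alongside
as an independent oracle, and the test suite holds the closed forms to it at
1e−8 relative over randomized instances.  On top sit the two censoring
mechanisms (administrative at a percentile of event times; per-subject
uniform), a counting-process (start–stop) exporter for time-varying Cox fits,
and a replicated power study across five treatment-assignment scenarios.

## Worked example

Generate event times for subjects who start treatment (hazard ratio 0.5) at
day 3000, censor administratively so 32% are events, and fit a time-varying
Cox model to the exported records:

```python
import numpy as np
from tvcsim import (BaselineHazard, SingleSwitchTrajectory, SubjectSpec,
                    draw_event_times, censor_fixed_percentile,
                    expand_counting_process, records_to_dataframe,
                    fit_start_stop_cox)

b = BaselineHazard.weibull(lam=0.001, nu=0.6)        # time in days
rng = np.random.default_rng(1)
subjects = [SubjectSpec(eta=float(e), beta_t=np.log(0.5),
                        trajectory=SingleSwitchTrajectory(t0=float(t)))
            for e, t in zip(rng.normal(0, 1, 5000), rng.uniform(1, 13581, 5000))]

times = draw_event_times(b, subjects, seed=2)        # +inf = never-event
outcomes = censor_fixed_percentile(times, 0.32)
records = []
for i, (s, o) in enumerate(zip(subjects, outcomes)):
    records.extend(expand_counting_process(s, o, i))
fit = fit_start_stop_cox(records_to_dataframe(records), ["z", "eta"])
print(fit.round(3))
```

```
      coef     se    p
z   -0.590  0.083  0.0
eta  1.006  0.028  0.0
```

The treatment coefficient recovers log 0.5 ≈ −0.693 within sampling error,
and the coefficient on the true linear predictor is ~1, as it should be for a
correctly specified model.  Coding the same treatment as a baseline
(ever-treated) covariate instead gives a strongly negative estimate even when
the true effect is null — the immortal-time bias the counting-process format
avoids (see `tests/test_power_study.py::test_immortal_time_bias_direction`).

## Command line

```
tvcsim simulate --family weibull --lambda 0.001 --nu 0.6 --beta-t -0.7 \
    --trajectory single-switch --t0 3000 --n 1000 --seed 7 --out sim.csv
tvcsim power config.yaml --out power.csv
```

`simulate` writes the start–stop CSV (`subject_id,start,stop,status,z,eta`);
`power` runs the full grid (scenarios × hazard ratios × replicates) from a
YAML config.  Every output carries a `<out>.manifest.json` with the complete
configuration and master seed, sufficient to reproduce it byte-for-byte.

## Power study

`estimate_power` reproduces a registry-style experiment: samples of 2500
drawn with replacement from a synthetic 115,856-subject cohort (one
continuous + ten binary covariates standing in for an AMI mortality risk
model; see `docs/methods.md`), five binary-treatment scenarios from
treated-at-baseline to repeatedly alternating, Weibull(0.001, 0.6) baseline,
hazard ratios 0.5–0.95, and a Wald test of the time-varying treatment at
α = 0.05 in each replicate.  Treatments fixed at baseline yield the highest
power; uniformly-timed mid-study initiation intermediate; alternating
treatment schedules the lowest.

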