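"""Monte-Carlo power study for time-varying treatments in a Cox model.

Emulates a registry-based power calculation: a synthetic cohort with one
continuous and ten binary baseline covariates stands in for an AMI-registry
population (whose fitted linear predictors are not public), a binary
treatment is assigned under one of five scenarios, event times are drawn from
a Cox-Weibull model (default shape 0.6, scale 0.001, time in days), follow-up
is censored by one of two mechanisms, and a time-varying Cox model is fitted
to the counting-process records.  Power is the fraction of replicates in
which the treatment coefficient's two-sided Wald test rejects at the 0.05
level.

Treatment scenarios (follow-up window w = 13581 days, short window 6000):

* S1 -- 50% treated from baseline (time-invariant), 50% never treated.
* S2 -- everyone switches untreated -> treated at t0 ~ U(1, w).
* S3 -- as S2 with t0 ~ U(1, 6000).
* S4 -- 50% alternate untreated/treated at w/3, 2w/3, w; 50% never treated.
* S5 -- 50% alternate at w/3, 2w/3; 50% never treated.

Under S2/S3 a subject can die before treatment was to be assigned; the
fraction doing so is reported as a diagnostic.  The start-stop Cox fits are
delegated to :class:`statsmodels.duration.hazard_regression.PHReg`, which
accepts counting-process data through its left-truncation ``entry`` argument.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from statsmodels.duration.hazard_regression import PHReg
from statsmodels.tools.sm_exceptions import ConvergenceWarning

from .baseline_hazards import BaselineHazard
from .counting_process import censor_fixed_percentile, censor_uniform, expand_counting_process
from .engine import SubjectSpec, draw_event_times
from .trajectories import (
    PiecewiseBinaryTrajectory,
    SingleSwitchTrajectory,
    TimeInvariantTrajectory,
    Trajectory,
)

__all__ = [
    "SCENARIOS",
    "COVARIATE_SPEC",
    "ScenarioConfig",
    "PowerStudyConfig",
    "ReplicateResult",
    "synth_population",
    "assign_treatment",
    "run_replicate",
    "estimate_power",
    "fit_start_stop_cox",
]

logger = logging.getLogger("tvcsim")

SCENARIOS = ("S1", "S2", "S3", "S4", "S5")

# Synthetic stand-in for an AMI mortality risk model: one standardized
# continuous covariate (age) and ten binary severity/comorbidity indicators,
# each as (prevalence, log-hazard coefficient).  Coefficients are chosen so
# the linear predictor eta = beta'x has standard deviation ~1, the spread
# typical of a validated mortality prediction rule; see docs/methods.md.
COVARIATE_SPEC: dict[str, tuple[float | None, float]] = {
    "age_std": (None, 0.80),  # standardized normal
    "female": (0.35, 0.15),
    "chf": (0.15, 0.90),
    "shock": (0.02, 1.80),
    "arrhythmia": (0.10, 0.50),
    "pulm_edema": (0.05, 0.60),
    "diabetes_compl": (0.08, 0.50),
    "stroke": (0.04, 0.70),
    "acute_renal": (0.03, 1.00),
    "chronic_renal": (0.03, 0.80),
    "malignancy": (0.05, 0.90),
}


@dataclass(frozen=True)
class ScenarioConfig:
    """One treatment-assignment scenario with its follow-up windows (days)."""

    scenario: str
    window: float = 13581.0
    short_window: float = 6000.0

    def __post_init__(self) -> None:
        if self.scenario not in SCENARIOS:
            raise ValueError(f"unknown scenario {self.scenario!r}; expected one of {SCENARIOS}")
        if not (self.window > 0 and self.short_window > 0):
            raise ValueError("windows must be positive")


@dataclass(frozen=True)
class PowerStudyConfig:
    """Design of the full power experiment.

    Defaults mirror the registry study the synthetic population emulates:
    samples of 2500 drawn with replacement from a population of 115856,
    Weibull(lam=0.001, nu=0.6) baseline, hazard ratios 0.5-0.95 in steps of
    0.05, 1000 replicates, two-sided Wald test at alpha = 0.05.  ``adjust``
    selects the fitted adjustment set: "covariates" (the 11 baseline
    covariates, as in the emulated study), "eta" (the true linear predictor
    as one covariate), or "none".
    """

    n_subjects: int = 2500
    n_replicates: int = 1000
    hr_grid: tuple[float, ...] = tuple(round(0.5 + 0.05 * i, 2) for i in range(10))
    baseline: BaselineHazard = field(
        default_factory=lambda: BaselineHazard.weibull(0.001, 0.6)
    )
    censoring: str = "fixed_percentile"
    censor_fraction: float = 0.32
    alpha_level: float = 0.05
    scenarios: tuple[str, ...] = SCENARIOS
    n_population: int = 115856
    adjust: str = "covariates"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_subjects < 1 or self.n_replicates < 1 or self.n_population < 1:
            raise ValueError("n_subjects, n_replicates and n_population must be >= 1")
        if any(not 0.0 < hr <= 1.0 for hr in self.hr_grid):
            raise ValueError(f"hr_grid values must lie in (0, 1], got {self.hr_grid}")
        if self.censoring not in ("fixed_percentile", "uniform"):
            raise ValueError(f"unknown censoring {self.censoring!r}")
        if self.adjust not in ("covariates", "eta", "none"):
            raise ValueError(f"unknown adjust {self.adjust!r}")
        for scen in self.scenarios:
            if scen not in SCENARIOS:
                raise ValueError(f"unknown scenario {scen!r}")


@dataclass(frozen=True)
class ReplicateResult:
    """Treatment-coefficient estimate from one simulated sample."""

    coef: float
    se: float
    p_value: float
    converged: bool
    frac_died_pre_treatment: float


def synth_population(
    n_pop: int,
    seed: int | np.random.SeedSequence | None = None,
    *,
    covariate_spec: dict[str, tuple[float | None, float]] | None = None,
) -> pd.DataFrame:
    """Generate the synthetic cohort table: covariate columns plus eta = beta'x.

    Each covariate with prevalence ``None`` is standardized normal; the rest
    are Bernoulli(prevalence).  Reproducible for a fixed seed.
    """
    if n_pop < 1:
        raise ValueError(f"n_pop >= 1 required, got {n_pop}")
    spec = COVARIATE_SPEC if covariate_spec is None else covariate_spec
    rng = np.random.default_rng(seed)
    cols: dict[str, np.ndarray] = {}
    eta = np.zeros(n_pop)
    for name, (prevalence, coef) in spec.items():
        if prevalence is None:
            x = rng.standard_normal(n_pop)
        else:
            x = (rng.uniform(size=n_pop) < prevalence).astype(float)
        cols[name] = x
        eta += coef * x
    df = pd.DataFrame(cols)
    df["eta"] = eta
    return df


def assign_treatment(
    sc: ScenarioConfig,
    n: int,
    seed: int | np.random.SeedSequence | None = None,
    *,
    rng: np.random.Generator | None = None,
) -> list[Trajectory]:
    """Per-subject treatment trajectories for one scenario.

    The 50%-treated scenarios use an exact n//2 split over a seeded shuffle;
    S2/S3 assign everyone a switch time uniform on [1, window].
    """
    if n < 1:
        raise ValueError(f"n >= 1 required, got {n}")
    if rng is None:
        rng = np.random.default_rng(seed)
    scen = sc.scenario
    if scen in ("S2", "S3"):
        upper = sc.window if scen == "S2" else sc.short_window
        t0 = rng.uniform(1.0, upper, size=n)
        return [SingleSwitchTrajectory(float(t)) for t in t0]
    if scen == "S1":
        treated: Trajectory = SingleSwitchTrajectory(0.0)
    elif scen == "S4":
        treated = PiecewiseBinaryTrajectory(
            (sc.window / 3.0, 2.0 * sc.window / 3.0, sc.window)
        )
    else:  # S5
        treated = PiecewiseBinaryTrajectory((sc.window / 3.0, 2.0 * sc.window / 3.0))
    never: Trajectory = TimeInvariantTrajectory(0.0)
    order = rng.permutation(n)
    trajs: list[Trajectory] = [never] * n
    for i in order[: n // 2]:
        trajs[i] = treated
    return trajs


# ---------------------------------------------------------------------------
# Cox fitting on start-stop records


def _fit_arrays(
    start: np.ndarray,
    stop: np.ndarray,
    status: np.ndarray,
    exog: np.ndarray,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, bool]:
    """Newton fit of the Andersen-Gill partial likelihood; (params, se, pvalues, ok)."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        warnings.simplefilter("ignore", RuntimeWarning)
        model = PHReg(stop, exog, status=status, entry=start, ties="breslow")
        for method in ("newton", "bfgs"):
            try:
                res = model.fit(method=method, disp=False)
            except (np.linalg.LinAlgError, ValueError, OverflowError):
                continue
            params, bse, pvalues = res.params, res.bse, res.pvalues
            if np.all(np.isfinite(params)) and np.all(np.isfinite(bse)):
                return params, bse, pvalues, True
    k = exog.shape[1]
    nan = np.full(k, np.nan)
    return nan, nan, nan, False


def fit_start_stop_cox(
    df: pd.DataFrame, covariate_cols: list[str] | tuple[str, ...] = ("z",)
) -> pd.DataFrame:
    """Fit a Cox model with time-varying covariates on a start-stop table.

    ``df`` needs columns start, stop, status plus the covariate columns.
    Returns a table indexed by covariate with columns coef, se, p (two-sided
    Wald).  Counting-process rows enter as left-truncated observations, the
    standard Andersen-Gill encoding.
    """
    cols = list(covariate_cols)
    exog = df[cols].to_numpy(dtype=float)
    params, bse, pvalues, ok = _fit_arrays(
        df["start"].to_numpy(dtype=float),
        df["stop"].to_numpy(dtype=float),
        df["status"].to_numpy(dtype=float),
        exog,
    )
    if not ok:
        raise RuntimeError("Cox fit did not converge")
    return pd.DataFrame({"coef": params, "se": bse, "p": pvalues}, index=cols)


# ---------------------------------------------------------------------------
# Replicates


def _sample_and_simulate(
    cfg: PowerStudyConfig,
    sc: ScenarioConfig,
    hr: float,
    seed: int | np.random.SeedSequence,
    population: pd.DataFrame,
):
    """Shared replicate front half: sample cohort, assign treatment, draw, censor."""
    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    ss_design, ss_events, ss_censor = ss.spawn(3)
    rng = np.random.default_rng(ss_design)

    idx = rng.integers(0, len(population), size=cfg.n_subjects)
    eta = population["eta"].to_numpy()[idx]
    trajs = assign_treatment(sc, cfg.n_subjects, rng=rng)
    beta_t = math.log(hr)
    subjects = [SubjectSpec(float(e), beta_t, tr) for e, tr in zip(eta, trajs)]

    times = draw_event_times(cfg.baseline, subjects, ss_events)
    if cfg.censoring == "fixed_percentile":
        outcomes = censor_fixed_percentile(times, cfg.censor_fraction)
    else:
        outcomes = censor_uniform(times, ss_censor)
    return idx, subjects, outcomes


def run_replicate(
    cfg: PowerStudyConfig,
    sc: ScenarioConfig,
    hr: float,
    seed: int | np.random.SeedSequence,
    population: pd.DataFrame | None = None,
) -> ReplicateResult:
    """One simulated sample: generate, censor, expand, fit; Wald p for treatment.

    Fully determined by ``seed`` (three independent child streams drive cohort
    sampling/treatment assignment, event draws, and censoring).
    """
    if population is None:
        population = synth_population(cfg.n_population, np.random.SeedSequence(cfg.seed))
    idx, subjects, outcomes = _sample_and_simulate(cfg, sc, hr, seed, population)

    records = []
    for i, (s, o) in enumerate(zip(subjects, outcomes)):
        records.extend(expand_counting_process(s, o, i))
    start = np.array([r.start for r in records])
    stop = np.array([r.stop for r in records])
    status = np.array([r.status for r in records], dtype=float)
    z = np.array([r.z for r in records])
    sub = np.array([r.subject_id for r in records])

    if cfg.adjust == "covariates":
        x_cols = [c for c in population.columns if c != "eta"]
        adjustment = population[x_cols].to_numpy()[idx][sub]
        exog = np.column_stack([z, adjustment])
    elif cfg.adjust == "eta":
        exog = np.column_stack([z, np.array([r.eta for r in records])])
    else:
        exog = z[:, None]

    params, bse, pvalues, ok = _fit_arrays(start, stop, status, exog)

    died_pre = 0
    for s, o in zip(subjects, outcomes):
        t0 = getattr(s.trajectory, "t0", 0.0)
        if o.status == 1 and t0 > 0 and o.time < t0:
            died_pre += 1

    return ReplicateResult(
        coef=float(params[0]),
        se=float(bse[0]),
        p_value=float(pvalues[0]),
        converged=ok,
        frac_died_pre_treatment=died_pre / cfg.n_subjects,
    )


def estimate_power(
    cfg: PowerStudyConfig, population: pd.DataFrame | None = None
) -> pd.DataFrame:
    """Rejection proportion per (scenario, hazard ratio) cell with Monte-Carlo SE.

    Returns one row per cell: power = r/R over converged replicates, its
    binomial standard error sqrt(p(1-p)/R), the number of excluded
    (nonconvergent) replicates, and the mean fraction of subjects dying
    before their treatment time (informative for S2/S3).
    """
    if population is None:
        population = synth_population(cfg.n_population, np.random.SeedSequence(cfg.seed))
    root = np.random.SeedSequence(cfg.seed)
    rows = []
    for si, scen in enumerate(cfg.scenarios):
        sc = ScenarioConfig(scen)
        for hi, hr in enumerate(cfg.hr_grid):
            cell = np.random.SeedSequence(
                entropy=root.entropy, spawn_key=(si, hi)
            )
            rep_seeds = cell.spawn(cfg.n_replicates)
            rejections = 0
            used = 0
            excluded = 0
            died_pre = []
            for rep_seed in rep_seeds:
                res = run_replicate(cfg, sc, hr, rep_seed, population)
                if not res.converged:
                    excluded += 1
                    continue
                used += 1
                rejections += res.p_value <= cfg.alpha_level
                died_pre.append(res.frac_died_pre_treatment)
            if excluded:
                logger.warning(
                    "scenario %s hr %.2f: excluded %d nonconvergent replicates",
                    scen, hr, excluded,
                )
            power = rejections / used if used else float("nan")
            mc_se = math.sqrt(power * (1 - power) / used) if used else float("nan")
            rows.append(
                {
                    "scenario": scen,
                    "censoring": cfg.censoring,
                    "hr": hr,
                    "n": cfg.n_subjects,
                    "replicates": used,
                    "excluded": excluded,
                    "power": power,
                    "mc_se": mc_se,
                    "frac_died_pre_treatment": float(np.mean(died_pre)) if died_pre else 0.0,
                }
            )
    return pd.DataFrame(rows)
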