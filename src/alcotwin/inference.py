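"""Weighted least-squares estimation and the χ² model-rejection test.

The fit quality of a parameter vector θ is the SEM-weighted residual sum

    V(θ) = Σ_i Σ_k Σ_j ((y_ikj − ŷ_ikj(θ)) / SEM_ikj)²

over studies i, observables k and time points j.  Under the null hypothesis
that the data were generated by the model with additive Gaussian noise,
V(θ) is χ²-distributed; the model is rejected when V exceeds the χ²
quantile at significance α with degrees of freedom equal to the number of
data points.  Estimation searches log10 parameter space within the
published bounds using scipy's dual annealing or differential evolution.
"""

from __future__ import annotations

import math
import time
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .model import OBSERVABLE_NAMES
from .params import Anthropometrics, ParameterSet, PARAM_INDEX, PARAM_NAMES
from .schedule import InputSchedule
from .simulate import SimOptions, SimulationError, simulate

__all__ = [
    "Observation", "Experiment", "Dataset", "FitResult", "CostBreakdown",
    "EstimationConfig", "wls_cost", "chi2_threshold", "chi2_test",
    "estimate_parameters", "DETECTION_LIMIT_START",
]

# markers reported as zero until their assay detection limit is passed are
# excluded before these times (min)
DETECTION_LIMIT_START: dict[str, float] = {"yEtS": 30.0, "yEtG": 75.0}


@dataclass(frozen=True)
class Observation:
    study_id: str
    experiment_id: str
    observable: str
    time: float
    value: float
    sem: float
    n: int = 1

    def __post_init__(self) -> None:
        if self.observable not in OBSERVABLE_NAMES:
            raise ValueError(f"unknown observable {self.observable!r}; "
                             f"allowed: {OBSERVABLE_NAMES}")
        if not self.sem > 0:
            raise ValueError(f"SEM must be positive, got {self.sem}")


@dataclass(frozen=True)
class Experiment:
    """One experimental arm: its schedule and subject anthropometrics."""

    schedule: InputSchedule
    anthro: Anthropometrics


@dataclass
class Dataset:
    """Observations grouped with their per-experiment schedules/subjects."""

    observations: list[Observation]
    experiments: dict[str, Experiment]

    def __post_init__(self) -> None:
        for ob in self.observations:
            if ob.experiment_id not in self.experiments:
                raise ValueError(f"observation references unknown experiment "
                                 f"{ob.experiment_id!r}")
            horizon = self.experiments[ob.experiment_id].schedule.horizon
            if not 0 <= ob.time <= horizon:
                raise ValueError(f"observation time {ob.time} outside horizon "
                                 f"[0, {horizon}] of {ob.experiment_id!r}")

    def __len__(self) -> int:
        return len(self.observations)

    @property
    def df(self) -> pd.DataFrame:
        return pd.DataFrame([{"study_id": o.study_id, "experiment_id": o.experiment_id,
                              "observable": o.observable, "time_min": o.time,
                              "value": o.value, "sem": o.sem, "n": o.n}
                             for o in self.observations])

    def filter_detection_limits(
            self, starts: dict[str, float] | None = None) -> "Dataset":
        """Drop observations before per-marker detection-limit start times."""
        starts = DETECTION_LIMIT_START if starts is None else starts
        kept = [o for o in self.observations
                if o.time > starts.get(o.observable, -math.inf)]
        return Dataset(observations=kept, experiments=dict(self.experiments))


@dataclass
class CostBreakdown:
    total: float
    by_study: dict[str, float]
    n_points: int
    failed: bool = False
    message: str = ""


def _simulate_experiment(exp: Experiment, params: ParameterSet,
                         times: np.ndarray, options: SimOptions):
    grid = np.unique(np.concatenate([[0.0], times, [exp.schedule.horizon]]))
    return simulate(exp.schedule, exp.anthro, params, t_grid=grid, options=options)


def wls_cost(dataset: Dataset, params: ParameterSet,
             options: SimOptions | None = None) -> CostBreakdown:
    """SEM-weighted least-squares cost of a parameter vector on a dataset.

    A simulation failure returns an infinite cost with a diagnostic instead
    of raising, so optimizers can treat the point as infeasible.
    """
    options = options or SimOptions()
    by_study: dict[str, float] = {}
    obs_by_exp: dict[str, list[Observation]] = {}
    for o in dataset.observations:
        obs_by_exp.setdefault(o.experiment_id, []).append(o)
    total = 0.0
    for exp_id, obs in obs_by_exp.items():
        times = np.unique([o.time for o in obs])
        try:
            traj = _simulate_experiment(dataset.experiments[exp_id], params,
                                        times, options)
        except (SimulationError, FloatingPointError, ValueError) as err:
            return CostBreakdown(total=math.inf, by_study={}, n_points=len(dataset),
                                 failed=True, message=f"{exp_id}: {err}")
        for o in obs:
            yhat = float(traj.observable_at(o.observable, o.time))
            r2 = ((o.value - yhat) / o.sem) ** 2
            total += r2
            by_study[o.study_id] = by_study.get(o.study_id, 0.0) + r2
    return CostBreakdown(total=total, by_study=by_study, n_points=len(dataset))


def chi2_threshold(alpha: float, df: int) -> float:
    """Inverse χ² CDF at 1 − α with df degrees of freedom."""
    if not 0 < alpha < 1:
        raise ValueError(f"alpha must be in (0, 1), got {alpha}")
    if not (isinstance(df, (int, np.integer)) and df >= 1):
        raise ValueError(f"df must be a positive integer, got {df}")
    return float(stats.chi2.ppf(1.0 - alpha, df))


def chi2_test(cost: float, df: int, alpha: float = 0.05) -> dict:
    """Model rejection test: reject only if cost is strictly above threshold."""
    if cost < 0:
        raise ValueError("cost must be non-negative")
    thr = chi2_threshold(alpha, df)
    return {"pass": bool(cost <= thr), "threshold": thr, "cost": float(cost),
            "df": int(df), "alpha": float(alpha)}


@dataclass(frozen=True)
class EstimationConfig:
    method: str = "differential_evolution"   # or "dual_annealing"
    seed: int = 0
    budget: int = 50                         # optimizer iterations (maxiter)
    popsize: int = 12                        # DE population multiplier
    polish: bool = True
    init: str = "latinhypercube"             # or "warm": population around x0
    warm_spread_dex: float = 0.5             # decades, for init="warm"
    sim_options: SimOptions = field(default_factory=lambda: SimOptions(rtol=1e-6, atol=1e-9))

    def __post_init__(self) -> None:
        if self.method not in ("differential_evolution", "dual_annealing"):
            raise ValueError(f"unknown optimizer {self.method!r}")
        if self.init not in ("latinhypercube", "warm"):
            raise ValueError(f"unknown init scheme {self.init!r}")
        if self.seed is None:
            raise ValueError("a seed is mandatory for estimation")


@dataclass
class FitResult:
    parameters: ParameterSet
    free_names: tuple[str, ...]
    cost: float
    df: int
    threshold: float
    passed: bool
    seed: int
    trace: list[tuple[int, float]] = field(default_factory=list)
    runtime_s: float = 0.0

    def to_dict(self) -> dict:
        return {"free_parameters": {n: self.parameters[n] for n in self.free_names},
                "cost": self.cost, "df": self.df, "threshold": self.threshold,
                "pass": self.passed, "seed": self.seed, "runtime_s": self.runtime_s}


def make_objective(dataset: Dataset, base_params: ParameterSet,
                   free_names: tuple[str, ...], options: SimOptions):
    """Return f(log10 θ_free) -> cost, plus the log10 bounds box."""
    for n in free_names:
        if n not in PARAM_INDEX:
            raise KeyError(f"unknown parameter {n!r}")
    bounds = [(math.log10(base_params.lower[n]), math.log10(base_params.upper[n]))
              for n in free_names]

    def objective(x: np.ndarray) -> float:
        updates = {n: 10.0 ** xi for n, xi in zip(free_names, x)}
        cb = wls_cost(dataset, base_params.replace(**updates), options)
        return cb.total

    return objective, bounds


def estimate_parameters(dataset: Dataset, free_names,
                        base_params: ParameterSet | None = None,
                        config: EstimationConfig | None = None,
                        alpha: float = 0.05) -> FitResult:
    """Global estimation of a subset of parameters against a dataset.

    Searches log10 space within the published bounds.  The returned cost is
    never worse than the cost at the starting (base) parameter values, and
    the run is reproducible given the config seed.  ``budget=0`` evaluates
    and returns the starting point only.
    """
    if len(dataset) == 0:
        raise ValueError("dataset is empty")
    free_names = tuple(free_names)
    base = base_params or ParameterSet()
    cfg = config or EstimationConfig()
    objective, bounds = make_objective(dataset, base, free_names, cfg.sim_options)

    trace: list[tuple[int, float]] = []
    t_start = time.time()
    x_start = np.array([math.log10(np.clip(base[n], base.lower[n], base.upper[n]))
                        for n in free_names])
    start_cost = objective(x_start)

    if cfg.budget <= 0 or not free_names:
        best_x, best_cost = x_start, start_cost
    elif cfg.method == "dual_annealing":
        res = optimize.dual_annealing(
            objective, bounds=bounds, x0=x_start, seed=cfg.seed,
            maxiter=max(cfg.budget, 1), no_local_search=not cfg.polish)
        best_x, best_cost = res.x, float(res.fun)
        trace.append((res.nfev, best_cost))
    else:
        if cfg.init == "warm":
            # population scattered around the start: suited to refits where
            # a credible parameter vector already exists
            rng = np.random.default_rng(cfg.seed)
            n_pop = max(cfg.popsize * len(free_names), 5)
            pop = x_start + rng.normal(0.0, cfg.warm_spread_dex,
                                       size=(n_pop, len(free_names)))
            lo = np.array([b[0] for b in bounds])
            hi = np.array([b[1] for b in bounds])
            init = np.clip(pop, lo, hi)
            init[0] = x_start
        else:
            init = "latinhypercube"
        # tol=0: the relative-tolerance stop fires spuriously when the whole
        # population sits high on a flat plateau; spend the full budget
        res = optimize.differential_evolution(
            objective, bounds=bounds, x0=x_start, seed=cfg.seed, init=init,
            maxiter=cfg.budget, popsize=cfg.popsize, polish=cfg.polish, tol=0.0)
        best_x, best_cost = res.x, float(res.fun)
        trace.append((res.nfev, best_cost))

    if not math.isfinite(best_cost) and not math.isfinite(start_cost):
        raise RuntimeError("optimizer budget exhausted without a finite cost")
    if best_cost > start_cost:  # global methods may wander; keep the better point
        best_x, best_cost = x_start, start_cost

    if best_x is x_start:  # avoid a lossy log10 round-trip of the start values
        params = base
    else:
        params = base.replace(**{n: 10.0 ** xi
                                 for n, xi in zip(free_names, best_x)})
    df = len(dataset)
    thr = chi2_threshold(alpha, df)
    return FitResult(parameters=params, free_names=free_names, cost=best_cost,
                     df=df, threshold=thr, passed=best_cost <= thr, seed=cfg.seed,
                     trace=trace, runtime_s=time.time() - t_start)
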