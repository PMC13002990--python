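"""Profile-style uncertainty of parameters and predictions.

A property p̂ (a parameter value, or a simulated observable at one time
point) is bounded by solving, for each direction,

    minimize ± p̂(θ)   subject to   V(θ) ≤ T,

where V is the weighted least-squares cost and T the χ² threshold.  The
constraint is relaxed into the objective as an L1 penalty with an offset:

    penalty = |p̂| + |p̂₀|·(1 + (V(θ) − T))   if V(θ) > T,  else 0,

with p̂₀ the property value at the feasible start.  The non-smooth penalty
is handled by the same seeded global optimizer used for estimation
(differential evolution), warm-started from the best fit.  Maximization is
the same problem with p̂ negated.

For model predictions a cheaper seeded-ensemble envelope is also provided:
log-normal parameter draws around the best fit are filtered by V(θ) ≤ T and
the band is the pointwise min/max of the accepted trajectories.  It
under-covers relative to the per-point optimization but shares its
semantics, and is the default for multi-marker scenario comparison.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
from scipy import optimize

from .inference import Dataset, EstimationConfig, make_objective
from .params import Anthropometrics, ParameterSet
from .schedule import InputSchedule
from .simulate import SimOptions, SimulationError, simulate

__all__ = [
    "PropertyBound", "UncertaintyBand", "InfeasibleStartError",
    "penalized_extremum", "profile_parameter_bound", "prediction_band",
    "ensemble_band",
]

CONSTRAINT_TOL_FRACTION = 1e-3  # accepted V(θ) overshoot at a reported bound


class InfeasibleStartError(RuntimeError):
    """No starting point with cost below the threshold was available."""


@dataclass(frozen=True)
class PropertyBound:
    property_id: str
    lower: float
    upper: float
    best: float
    lower_cost: float
    upper_cost: float
    threshold: float
    feasible: bool

    def contains(self, value: float) -> bool:
        return self.lower - 1e-12 <= value <= self.upper + 1e-12


@dataclass
class UncertaintyBand:
    observable: str
    times: np.ndarray
    lower: np.ndarray
    upper: np.ndarray
    best: np.ndarray
    threshold: float
    method: str = "optimize"

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.lower = np.asarray(self.lower, dtype=float)
        self.upper = np.asarray(self.upper, dtype=float)
        self.best = np.asarray(self.best, dtype=float)

    @property
    def width(self) -> np.ndarray:
        return self.upper - self.lower

    def to_frame(self):
        import pandas as pd
        return pd.DataFrame({"observable": self.observable, "time_min": self.times,
                             "lower": self.lower, "upper": self.upper,
                             "best": self.best})


def _penalty(prop: float, prop0: float, cost: float, threshold: float) -> float:
    if cost > threshold:
        return abs(prop) + abs(prop0) * (1.0 + (cost - threshold))
    return 0.0


def penalized_extremum(property_fn: Callable[[np.ndarray], float],
                       cost_fn: Callable[[np.ndarray], float],
                       bounds: Sequence[tuple[float, float]],
                       x0: np.ndarray, threshold: float, direction: str,
                       seed: int = 0, maxiter: int = 60, popsize: int = 15,
                       warm_spread: float = 0.5,
                       ) -> tuple[float, np.ndarray, float]:
    """Extremal feasible value of a scalar property under a cost constraint.

    Returns (property value, argument, cost at argument).  ``direction`` is
    'min' or 'max'; maximization negates the property inside the objective.
    The optimizer population is seeded around the feasible start (the
    feasible set is a neighbourhood of it) with ``warm_spread`` SD in the
    search-space units, and the best feasible point evaluated anywhere in
    the search is the one reported.  Raises InfeasibleStartError when the
    start violates the constraint.
    """
    if direction not in ("min", "max"):
        raise ValueError("direction must be 'min' or 'max'")
    x0 = np.asarray(x0, dtype=float)
    c0 = cost_fn(x0)
    if not c0 <= threshold:
        raise InfeasibleStartError(
            f"start cost {c0:.6g} exceeds threshold {threshold:.6g}")
    sign = 1.0 if direction == "min" else -1.0
    p0 = sign * property_fn(x0)
    tol = threshold * (1.0 + CONSTRAINT_TOL_FRACTION)
    best = {"p": p0, "x": x0.copy(), "c": c0}

    def objective(x: np.ndarray) -> float:
        p = sign * property_fn(x)
        c = cost_fn(x)
        if not math.isfinite(c):
            return abs(p) + abs(p0) * 1e6 + 1e6
        if c <= threshold and p < best["p"]:
            best.update(p=p, x=np.array(x), c=c)
        return p + _penalty(p, p0, c, threshold)

    rng = np.random.default_rng(seed)
    lo = np.array([b[0] for b in bounds])
    hi = np.array([b[1] for b in bounds])
    n_pop = max(popsize * len(x0), 5)
    init = np.clip(x0 + rng.normal(0.0, warm_spread, size=(n_pop, len(x0))),
                   lo, hi)
    init[0] = x0
    res = optimize.differential_evolution(
        objective, bounds=bounds, x0=x0, seed=seed, maxiter=maxiter,
        popsize=popsize, init=init, tol=1e-10, polish=False)
    # the optimizer's end point may be (slightly) infeasible; also consider it
    c_res = cost_fn(res.x)
    if c_res <= tol and sign * property_fn(res.x) < best["p"]:
        best.update(p=sign * property_fn(res.x), x=np.array(res.x), c=c_res)
    return sign * best["p"], best["x"], best["c"]


def profile_parameter_bound(dataset: Dataset, name: str, direction: str,
                            threshold: float, free_names=None,
                            base_params: ParameterSet | None = None,
                            config: EstimationConfig | None = None) -> tuple[float, float]:
    """Extremal feasible value of one parameter given a dataset constraint.

    ``free_names`` are the parameters allowed to move (default: just
    ``name``); the search runs in log10 space within the published bounds.
    Returns (bound value, cost at bound).
    """
    base = base_params or ParameterSet()
    cfg = config or EstimationConfig()
    free_names = tuple(free_names) if free_names else (name,)
    if name not in free_names:
        raise ValueError(f"{name!r} must be among the free parameters")
    cost_fn, bounds = make_objective(dataset, base, free_names, cfg.sim_options)
    idx = free_names.index(name)

    def prop(x: np.ndarray) -> float:
        return 10.0 ** x[idx]

    x0 = np.array([math.log10(np.clip(base[n], base.lower[n], base.upper[n]))
                   for n in free_names])
    val, x_at, c_at = penalized_extremum(prop, cost_fn, bounds, x0, threshold,
                                         direction, seed=cfg.seed,
                                         maxiter=cfg.budget, popsize=cfg.popsize)
    return val, c_at


def parameter_bounds(dataset: Dataset, name: str, threshold: float,
                     free_names=None, base_params: ParameterSet | None = None,
                     config: EstimationConfig | None = None) -> PropertyBound:
    """Two-sided profile bound [lower, upper] for one parameter."""
    base = base_params or ParameterSet()
    lo, c_lo = profile_parameter_bound(dataset, name, "min", threshold,
                                       free_names, base, config)
    hi, c_hi = profile_parameter_bound(dataset, name, "max", threshold,
                                       free_names, base, config)
    return PropertyBound(property_id=name, lower=min(lo, hi), upper=max(lo, hi),
                         best=base[name], lower_cost=c_lo, upper_cost=c_hi,
                         threshold=threshold, feasible=True)


def prediction_band(dataset: Dataset, observable: str, t_grid,
                    threshold: float, schedule: InputSchedule | None = None,
                    anthro: Anthropometrics | None = None,
                    free_names=("VmaxADH", "k_EtOHuptake"),
                    base_params: ParameterSet | None = None,
                    config: EstimationConfig | None = None,
                    method: str = "optimize") -> UncertaintyBand:
    """Min/max envelope of a simulated observable under the cost constraint.

    The scenario simulated may differ from the calibration experiments: pass
    ``schedule``/``anthro`` to band a prediction (defaults to the dataset's
    first experiment).  ``method='optimize'`` solves the penalized problem
    per time point (time points are independent; results do not depend on
    evaluation order); ``method='ensemble'`` uses the filtered-draw envelope.
    """
    base = base_params or ParameterSet()
    cfg = config or EstimationConfig()
    t_grid = np.asarray(t_grid, dtype=float)
    exp0 = next(iter(dataset.experiments.values()))
    schedule = schedule or exp0.schedule
    anthro = anthro or exp0.anthro
    free_names = tuple(free_names)

    if method == "ensemble":
        return ensemble_band(dataset, observable, t_grid, threshold, schedule,
                             anthro, free_names, base, cfg)
    if method != "optimize":
        raise ValueError("method must be 'optimize' or 'ensemble'")

    cost_fn, bounds = make_objective(dataset, base, free_names, cfg.sim_options)
    sim_grid = np.unique(np.concatenate([[0.0], t_grid, [schedule.horizon]]))

    def predict(x: np.ndarray) -> np.ndarray:
        updates = {n: 10.0 ** xi for n, xi in zip(free_names, x)}
        traj = simulate(schedule, anthro, base.replace(**updates),
                        t_grid=sim_grid, options=cfg.sim_options)
        return traj.observable_at(observable, t_grid)

    x0 = np.array([math.log10(np.clip(base[n], base.lower[n], base.upper[n]))
                   for n in free_names])
    best = predict(x0)
    lower = np.empty_like(t_grid)
    upper = np.empty_like(t_grid)
    cache: dict[bytes, np.ndarray] = {}

    def predict_cached(x: np.ndarray) -> np.ndarray:
        key = np.asarray(x).tobytes()
        if key not in cache:
            cache[key] = predict(x)
        return cache[key]

    for j in range(len(t_grid)):
        def prop(x, jj=j):
            return float(predict_cached(x)[jj])
        lo, _, _ = penalized_extremum(prop, cost_fn, bounds, x0, threshold,
                                      "min", seed=cfg.seed, maxiter=cfg.budget,
                                      popsize=cfg.popsize)
        hi, _, _ = penalized_extremum(prop, cost_fn, bounds, x0, threshold,
                                      "max", seed=cfg.seed, maxiter=cfg.budget,
                                      popsize=cfg.popsize)
        lower[j] = min(lo, hi, best[j])
        upper[j] = max(lo, hi, best[j])
    return UncertaintyBand(observable=observable, times=t_grid, lower=lower,
                           upper=upper, best=best, threshold=threshold,
                           method="optimize")


def ensemble_band(dataset: Dataset, observable: str, t_grid,
                  threshold: float, schedule: InputSchedule,
                  anthro: Anthropometrics, free_names,
                  base_params: ParameterSet, config: EstimationConfig,
                  n_draws: int = 60, spread_dex: float = 0.15) -> UncertaintyBand:
    """Envelope over seeded log-normal parameter draws filtered by the cost.

    Draws are log10-normal around the best fit with ``spread_dex`` decades
    SD, clipped to the published bounds; a draw enters the ensemble iff its
    calibration cost stays below the threshold.  The best fit is always a
    member, so the band contains the best-fit trajectory pointwise.
    """
    t_grid = np.asarray(t_grid, dtype=float)
    free_names = tuple(free_names)
    rng = np.random.default_rng(config.seed)
    cost_fn, bounds = make_objective(dataset, base_params, free_names,
                                     config.sim_options)
    x0 = np.array([math.log10(np.clip(base_params[n], base_params.lower[n],
                                      base_params.upper[n])) for n in free_names])
    if not cost_fn(x0) <= threshold:
        raise InfeasibleStartError("best fit violates the cost threshold")
    draws = [x0]
    for _ in range(n_draws):
        x = x0 + rng.normal(0.0, spread_dex, size=len(free_names))
        x = np.clip(x, [b[0] for b in bounds], [b[1] for b in bounds])
        if cost_fn(x) <= threshold:
            draws.append(x)

    sim_grid = np.unique(np.concatenate([[0.0], t_grid, [schedule.horizon]]))
    curves = []
    for x in draws:
        updates = {n: 10.0 ** xi for n, xi in zip(free_names, x)}
        try:
            traj = simulate(schedule, anthro, base_params.replace(**updates),
                            t_grid=sim_grid, options=config.sim_options)
        except SimulationError:
            continue
        curves.append(traj.observable_at(observable, t_grid))
    curves = np.array(curves)
    return UncertaintyBand(observable=observable, times=t_grid,
                           lower=curves.min(axis=0), upper=curves.max(axis=0),
                           best=curves[0], threshold=threshold,
                           method="ensemble")
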