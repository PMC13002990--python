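"""Population sensitivity sweeps and forensic scenario discrimination.

Two questions are answered here.  First, how robust is a prediction across
a population: anthropometrics are swept over realistic ranges (weight is
reconstructed as BMI·height²) and each virtual subject is simulated under
the same drinking challenge; trajectories are keyed by total body water,
the main determinant of exposure.  Second, can two claimed drinking
scenarios be told apart from samples: the uncertainty bands of each marker
are compared between scenarios, and the time intervals where the bands are
disjoint — after the last drink has ended, when the fast absorption phase
no longer dominates — are where a measurement can discriminate them.  The
non-overlap rule (with an optional conservatism margin) is this package's
operationalisation of "deviating behaviour"; reports flag it as such.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np

from .inference import Dataset, EstimationConfig, Observation
from .params import Anthropometrics, ParameterSet, derive_volumes
from .schedule import InputSchedule
from .simulate import SimOptions, Trajectory, simulate
from .uncertainty import UncertaintyBand, ensemble_band

__all__ = [
    "PopulationSpec", "ScenarioComparison", "PlausibilityReport",
    "population_sweep", "deviation_intervals", "plausibility_report",
]


@dataclass(frozen=True)
class PopulationSpec:
    """Anthropometric ranges of a virtual population (full-factorial grid)."""

    sexes: tuple[str, ...] = ("male", "female")
    age_range: tuple[float, float] = (20.0, 80.0)
    bmi_range: tuple[float, float] = (18.0, 32.0)
    height_range_female: tuple[float, float] = (1.5, 1.8)
    height_range_male: tuple[float, float] = (1.6, 1.95)
    grid_size: int = 3          # points per axis of the factorial grid
    n_samples: int | None = None  # Latin-hypercube sample count (optional)
    seed: int = 0

    def __post_init__(self) -> None:
        for lo, hi in (self.age_range, self.bmi_range,
                       self.height_range_female, self.height_range_male):
            if not lo < hi:
                raise ValueError("population ranges must be non-degenerate")

    def individuals(self) -> list[Anthropometrics]:
        """Enumerate the virtual subjects (grid or seeded Latin hypercube)."""
        out = []
        if self.n_samples is None:
            for sex in self.sexes:
                h_lo, h_hi = (self.height_range_male if sex == "male"
                              else self.height_range_female)
                axes = (np.linspace(*self.age_range, self.grid_size),
                        np.linspace(*self.bmi_range, self.grid_size),
                        np.linspace(h_lo, h_hi, self.grid_size))
                for age, bmi, h in itertools.product(*axes):
                    out.append(Anthropometrics(sex=sex, weight=bmi * h * h,
                                               height=h, age=age))
        else:
            from scipy.stats import qmc
            sampler = qmc.LatinHypercube(d=3, seed=self.seed)
            u = sampler.random(self.n_samples)
            rng = np.random.default_rng(self.seed)
            for row in u:
                sex = self.sexes[rng.integers(len(self.sexes))]
                h_lo, h_hi = (self.height_range_male if sex == "male"
                              else self.height_range_female)
                age = self.age_range[0] + row[0] * np.ptp(self.age_range)
                bmi = self.bmi_range[0] + row[1] * np.ptp(self.bmi_range)
                h = h_lo + row[2] * (h_hi - h_lo)
                out.append(Anthropometrics(sex=sex, weight=bmi * h * h,
                                           height=h, age=age))
        return out


def population_sweep(spec: PopulationSpec, schedule: InputSchedule,
                     params: ParameterSet, t_grid=None,
                     options: SimOptions | None = None,
                     ) -> list[tuple[Anthropometrics, float, Trajectory]]:
    """Simulate one challenge across a population; returns (subject, TBW L, trajectory)."""
    results = []
    for anthro in spec.individuals():
        vols = derive_volumes(anthro, params)
        traj = simulate(schedule, anthro, params, t_grid=t_grid, options=options)
        results.append((anthro, vols.TBW_L, traj))
    results.sort(key=lambda r: r[1])
    return results


@dataclass
class ScenarioComparison:
    """Per-marker time windows where two scenarios are distinguishable."""

    intervals: dict[str, list[tuple[float, float]]]
    window_start: float
    margin: float
    note: str = ("deviation = strict non-overlap of the two uncertainty bands "
                 "(package operationalisation; no standard quantitative "
                 "threshold exists)")

    @property
    def any_deviation(self) -> bool:
        return any(len(v) > 0 for v in self.intervals.values())

    def to_dict(self) -> dict:
        return {"window_start": self.window_start, "margin": self.margin,
                "note": self.note,
                "intervals": {k: [list(iv) for iv in v]
                              for k, v in self.intervals.items()}}


def _runs_to_intervals(times: np.ndarray, flags: np.ndarray) -> list[tuple[float, float]]:
    intervals = []
    i = 0
    n = len(times)
    while i < n:
        if flags[i]:
            j = i
            while j + 1 < n and flags[j + 1]:
                j += 1
            intervals.append((float(times[i]), float(times[j])))
            i = j + 1
        else:
            i += 1
    return intervals


def deviation_intervals(bands_a: dict[str, UncertaintyBand] | UncertaintyBand,
                        bands_b: dict[str, UncertaintyBand] | UncertaintyBand,
                        window_start: float, margin: float = 0.0,
                        ) -> ScenarioComparison:
    """Time intervals where the (margin-expanded) bands of A and B are disjoint.

    Bands must share a time grid per marker.  Intervals are clipped to
    t >= window_start (end of the last drink of the claimed scenario).
    The comparison is symmetric in A and B, and a larger margin can only
    shrink the intervals.
    """
    if isinstance(bands_a, UncertaintyBand):
        bands_a = {bands_a.observable: bands_a}
    if isinstance(bands_b, UncertaintyBand):
        bands_b = {bands_b.observable: bands_b}
    if margin < 0:
        raise ValueError("margin must be non-negative")
    intervals: dict[str, list[tuple[float, float]]] = {}
    for name in sorted(set(bands_a) & set(bands_b)):
        a, b = bands_a[name], bands_b[name]
        if len(a.times) != len(b.times) or not np.allclose(a.times, b.times):
            raise ValueError(f"bands for {name!r} are on different time grids")
        disjoint = ((a.lower - margin > b.upper + margin)
                    | (b.lower - margin > a.upper + margin))
        disjoint &= a.times >= window_start
        intervals[name] = _runs_to_intervals(a.times, disjoint)
    return ScenarioComparison(intervals=intervals, window_start=window_start,
                              margin=margin)


@dataclass
class PlausibilityReport:
    """Sample-by-sample consistency of measurements with a claimed scenario."""

    flags: list[dict]
    per_marker: dict[str, dict]
    verdict: str                      # consistent | inconsistent | indeterminate
    threshold: float
    consistency_fraction: float = 1.0

    def to_dict(self) -> dict:
        return {"verdict": self.verdict, "threshold": self.threshold,
                "per_marker": self.per_marker, "samples": self.flags}


def plausibility_report(claimed: InputSchedule, samples: list[Observation],
                        anthro: Anthropometrics, params: ParameterSet,
                        calibration: Dataset, threshold: float,
                        free_names=("VmaxADH", "k_EtOHuptake", "VmaxEtG", "VmaxEtS"),
                        config: EstimationConfig | None = None,
                        min_inside_fraction: float = 0.95,
                        sem_multiplier: float = 2.0) -> PlausibilityReport:
    """Could the claimed scenario have generated these samples?

    The claimed scenario is simulated with its uncertainty band per marker
    (ensemble envelope under the calibration-cost constraint); each sample
    is flagged inside/outside its band, allowing for its own measurement
    uncertainty (the band is widened by ``sem_multiplier`` × SEM of the
    sample).  Verdict: ``indeterminate`` with no samples; ``consistent``
    when every marker keeps at least ``min_inside_fraction`` of its samples
    inside; else ``inconsistent``.
    """
    cfg = config or EstimationConfig()
    if not samples:
        return PlausibilityReport(flags=[], per_marker={}, verdict="indeterminate",
                                  threshold=threshold, consistency_fraction=float("nan"))
    for s in samples:
        if not 0 <= s.time <= claimed.horizon:
            raise ValueError(f"sample at t={s.time} outside the simulation "
                             f"horizon [0, {claimed.horizon}]")
    markers = sorted({s.observable for s in samples})
    bands = {}
    for m in markers:
        t_m = np.unique([s.time for s in samples if s.observable == m])
        bands[m] = ensemble_band(calibration, m, t_m, threshold, claimed,
                                 anthro, free_names, params, cfg)
    flags = []
    per_marker: dict[str, dict] = {}
    for s in samples:
        band = bands[s.observable]
        j = int(np.argmin(np.abs(band.times - s.time)))
        slack = sem_multiplier * s.sem
        inside = bool(band.lower[j] - slack - 1e-12 <= s.value
                      <= band.upper[j] + slack + 1e-12)
        flags.append({"observable": s.observable, "time_min": s.time,
                      "value": s.value, "lower": float(band.lower[j]),
                      "upper": float(band.upper[j]), "inside": inside})
        pm = per_marker.setdefault(s.observable, {"n": 0, "inside": 0})
        pm["n"] += 1
        pm["inside"] += inside
    for m, pm in per_marker.items():
        pm["fraction_inside"] = pm["inside"] / pm["n"]
        pm["consistent"] = pm["fraction_inside"] >= min_inside_fraction
    total = len(flags)
    frac = sum(f["inside"] for f in flags) / total
    verdict = ("consistent" if all(pm["consistent"] for pm in per_marker.values())
               else "inconsistent")
    return PlausibilityReport(flags=flags, per_marker=per_marker, verdict=verdict,
                              threshold=threshold, consistency_fraction=frac)
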