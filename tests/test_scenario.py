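"""Population sweeps, deviation intervals, and plausibility verdicts."""

import numpy as np
import pytest

import alcotwin as at
from alcotwin.inference import EstimationConfig, Observation
from alcotwin.uncertainty import UncertaintyBand


def _const_band(name, times, lo, hi):
    times = np.asarray(times, dtype=float)
    lo = np.broadcast_to(np.asarray(lo, dtype=float), times.shape)
    hi = np.broadcast_to(np.asarray(hi, dtype=float), times.shape)
    return UncertaintyBand(observable=name, times=times, lower=lo, upper=hi,
                           best=(lo + hi) / 2, threshold=1.0)


class TestPopulationSpec:
    @pytest.mark.parametrize("bmi, height, weight", [
        (18.0, 1.5, 40.5),
        (32.0, 1.95, 121.68),
    ])
    def test_weight_from_bmi_and_height(self, bmi, height, weight):
        spec = at.PopulationSpec(sexes=("male",), bmi_range=(bmi, bmi + 1),
                                 height_range_male=(height, height + 0.01),
                                 grid_size=1)
        subj = spec.individuals()[0]
        assert subj.weight == pytest.approx(weight)

    def test_default_ranges(self):
        spec = at.PopulationSpec()
        assert spec.age_range == (20.0, 80.0)
        assert spec.bmi_range == (18.0, 32.0)
        assert spec.height_range_female == (1.5, 1.8)
        assert spec.height_range_male == (1.6, 1.95)

    def test_degenerate_range_rejected(self):
        with pytest.raises(ValueError):
            at.PopulationSpec(age_range=(50.0, 50.0))

    def test_latin_hypercube_seeded(self):
        a = at.PopulationSpec(n_samples=5, seed=3).individuals()
        b = at.PopulationSpec(n_samples=5, seed=3).individuals()
        assert a == b


class TestPopulationSweep:
    @pytest.fixture(scope="class")
    def sweep(self, params):
        spec = at.PopulationSpec(sexes=("male", "female"), grid_size=2, seed=0)
        sched = at.build_wang_protocol(70.0)
        grid = np.arange(0.0, 361.0, 5.0)
        return at.population_sweep(spec, sched, params, t_grid=grid,
                                   options=at.SimOptions(rtol=1e-6, atol=1e-9))

    def test_keyed_and_sorted_by_tbw(self, sweep):
        tbw = [r[1] for r in sweep]
        assert tbw == sorted(tbw)
        assert len(sweep) == 2 * 2 ** 3

    def test_peak_bac_decreases_with_tbw_across_population(self, sweep):
        """A fixed absolute dose hits small bodies harder: peak blood
        alcohol falls with total body water across the mixed population."""
        tbw = np.array([r[1] for r in sweep])
        peaks = np.array([r[2].observables["yEtOH"].max() for r in sweep])
        r = np.corrcoef(tbw, peaks)[0, 1]
        assert r < -0.8

    def test_peak_bac_strictly_nonincreasing_within_sex(self, params):
        """Sweeping body size alone (one sex, fixed age/height), the peak
        is monotone in TBW."""
        spec = at.PopulationSpec(sexes=("male",), grid_size=4,
                                 age_range=(40.0, 40.001),
                                 height_range_male=(1.8, 1.8001))
        sched = at.build_wang_protocol(70.0)
        grid = np.arange(0.0, 361.0, 5.0)
        sweep = at.population_sweep(spec, sched, params, t_grid=grid,
                                    options=at.SimOptions(rtol=1e-6, atol=1e-9))
        peaks = [r[2].observables["yEtOH"].max() for r in sweep]
        assert np.all(np.diff(peaks) <= 1e-9)

    def test_identical_subjects_identical_trajectories(self, params):
        spec = at.PopulationSpec(sexes=("male",), grid_size=1,
                                 age_range=(30, 30.0001),
                                 bmi_range=(25, 25.0001),
                                 height_range_male=(1.8, 1.80001))
        sched = at.build_wang_protocol(70.0)
        grid = np.arange(0.0, 121.0, 10.0)
        r = at.population_sweep(spec, sched, params, t_grid=grid)
        r2 = at.population_sweep(spec, sched, params, t_grid=grid)
        assert np.array_equal(r[0][2].states, r2[0][2].states)


class TestDeviationIntervals:
    def test_identical_bands_no_deviation(self):
        t = np.arange(0.0, 101.0, 10.0)
        band = _const_band("yEtOH", t, 1.0, 2.0)
        comp = at.deviation_intervals(band, band, window_start=0.0)
        assert comp.intervals["yEtOH"] == []
        assert not comp.any_deviation

    def test_disjoint_constant_bands_whole_window(self):
        t = np.arange(0.0, 101.0, 10.0)
        a = _const_band("yEtOH", t, 1.0, 2.0)
        b = _const_band("yEtOH", t, 3.0, 4.0)
        comp = at.deviation_intervals(a, b, window_start=0.0)
        assert comp.intervals["yEtOH"] == [(0.0, 100.0)]

    def test_partial_overlap_interval_resolved_on_grid(self):
        # A: [1,2] before t=100 then [1,5]; B: [4,6] throughout ->
        # the bands are disjoint only before 100, up to grid resolution
        t = np.arange(0.0, 201.0, 10.0)
        upper_a = np.where(t < 100.0, 2.0, 5.0)
        a = UncertaintyBand("yEtOH", t, np.full_like(t, 1.0), upper_a,
                            np.full_like(t, 1.5), threshold=1.0)
        b = _const_band("yEtOH", t, 4.0, 6.0)
        comp = at.deviation_intervals(a, b, window_start=0.0)
        assert comp.intervals["yEtOH"] == [(0.0, 90.0)]

    def test_symmetric_in_arguments(self):
        t = np.arange(0.0, 101.0, 10.0)
        a = _const_band("yUAC", t, 1.0, 2.0)
        b = _const_band("yUAC", t, 2.5, 3.0)
        ab = at.deviation_intervals(a, b, window_start=0.0)
        ba = at.deviation_intervals(b, a, window_start=0.0)
        assert ab.intervals == ba.intervals

    def test_margin_only_shrinks_intervals(self):
        t = np.arange(0.0, 101.0, 10.0)
        a = _const_band("yEtG", t, 1.0, 2.0)
        b = _const_band("yEtG", t, 2.4, 3.0)
        wide = at.deviation_intervals(a, b, window_start=0.0, margin=0.0)
        narrow = at.deviation_intervals(a, b, window_start=0.0, margin=0.3)
        len_wide = sum(e - s for s, e in wide.intervals["yEtG"])
        len_narrow = sum(e - s for s, e in narrow.intervals["yEtG"])
        assert len_narrow <= len_wide
        assert narrow.intervals["yEtG"] == []  # 0.3 margin closes a 0.4 gap

    def test_window_start_clips(self):
        t = np.arange(0.0, 101.0, 10.0)
        a = _const_band("yEtOH", t, 1.0, 2.0)
        b = _const_band("yEtOH", t, 3.0, 4.0)
        comp = at.deviation_intervals(a, b, window_start=50.0)
        assert comp.intervals["yEtOH"] == [(50.0, 100.0)]

    def test_mismatched_grids_rejected(self):
        a = _const_band("yEtOH", np.arange(0, 101, 10.0), 1, 2)
        b = _const_band("yEtOH", np.arange(0, 101, 20.0), 3, 4)
        with pytest.raises(ValueError, match="grid"):
            at.deviation_intervals(a, b, window_start=0.0)


class TestPlausibility:
    @pytest.fixture(scope="class")
    def setup(self, male, params):
        sched = at.build_wang_protocol(male.weight)
        calib = at.generate_study(sched, male, params, seed=31,
                                  sampling=at.SamplingPlan(end=300.0),
                                  noise=at.NoiseModel(sem_mode="known"))
        thr = at.chi2_threshold(0.05, len(calib))
        claimed = at.build_fig5_protocol(male.weight, "male", "alternative")
        return sched, calib, thr, claimed

    def test_empty_samples_indeterminate(self, setup, male, params):
        _, calib, thr, claimed = setup
        rep = at.plausibility_report(claimed, [], male, params, calib, thr)
        assert rep.verdict == "indeterminate"

    def test_self_generated_data_consistent(self, setup, male, params):
        """Noiseless samples simulated from the claimed scenario itself sit
        inside its own uncertainty band: the verdict must be consistent."""
        _, calib, thr, claimed = setup
        traj = at.simulate(claimed, male, params)
        times = [120.0, 240.0, 360.0, 480.0]
        samples = [Observation("case", "e", m, t,
                               float(traj.observable_at(m, t)), sem=0.01)
                   for m in ("yEtOH", "yUAC", "yEtG", "yEtS") for t in times]
        rep = at.plausibility_report(claimed, samples, male, params, calib, thr,
                                     config=EstimationConfig(seed=13))
        assert rep.verdict == "consistent"
        assert all(f["inside"] for f in rep.flags)

    def test_wrong_scenario_flagged(self, setup, male, params):
        """Samples from a much larger single-drink challenge are flagged
        against a claim of a small one."""
        _, calib, thr, _ = setup
        small_claim = at.build_single_drink_protocol(male.weight, 0.3,
                                                     urination_interval=None)
        big = at.build_fig5_protocol(male.weight, "male", "alternative")
        traj = at.simulate(big, male, params)
        samples = [Observation("case", "e", "yEtOH", t,
                               float(traj.observable_at("yEtOH", t)), sem=0.5)
                   for t in (60.0, 90.0, 120.0)]
        rep = at.plausibility_report(small_claim, samples, male, params,
                                     calib, thr,
                                     config=EstimationConfig(seed=13))
        assert rep.verdict == "inconsistent"
        assert any(not f["inside"] for f in rep.flags)

    def test_samples_outside_horizon_rejected(self, setup, male, params):
        _, calib, thr, claimed = setup
        samples = [Observation("case", "e", "yEtOH", 10_000.0, 1.0, 1.0)]
        with pytest.raises(ValueError, match="horizon"):
            at.plausibility_report(claimed, samples, male, params, calib, thr)
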