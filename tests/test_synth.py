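import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ramanqc import synth
from ramanqc.errors import (ConfigurationError, DomainError,
                            InvalidMeasurementError)
from ramanqc.synth import (ExtractionKinetics, GeneratorConfig, OutlierSpec,
                           PureComponentSpectrum, SamplingSchedule,
                           SolubleSolidMeasurement, compute_soluble_solid,
                           default_axis, default_components, generate_dataset,
                           render_spectrum, schedule_timepoints,
                           solve_kinetics_for_range)


class TestSolubleSolid:
    def test_no_residue(self):
        assert compute_soluble_solid(SolubleSolidMeasurement(3.0, 10.0, 10.0)) == 0.0

    def test_hand_arithmetic(self):
        assert compute_soluble_solid(
            SolubleSolidMeasurement(2.0, 10.0, 10.05)) == pytest.approx(2.5)
        assert compute_soluble_solid(
            SolubleSolidMeasurement(3.0, 12.0, 12.06)) == pytest.approx(2.0)

    def test_nonpositive_aliquot(self):
        with pytest.raises(InvalidMeasurementError):
            compute_soluble_solid(SolubleSolidMeasurement(0.0, 10.0, 10.1))

    def test_residue_below_empty_bottle(self):
        with pytest.raises(InvalidMeasurementError):
            compute_soluble_solid(SolubleSolidMeasurement(2.0, 10.0, 9.9))


class TestSchedule:
    def test_default_first_stage_18_points(self):
        pts = schedule_timepoints(SamplingSchedule())
        stage1 = [t for s, t in pts if s == 1]
        # enumerate: 5,10,...,60 then 70,...,120
        assert stage1 == [5 * i for i in range(1, 13)] + [60 + 10 * i for i in range(1, 7)]
        assert len(stage1) == 18

    def test_default_total_counts(self):
        pts = schedule_timepoints(SamplingSchedule())
        per_stage = {s: sum(1 for q, _ in pts if q == s) for s in (1, 2, 3)}
        assert per_stage == {1: 18, 2: 15, 3: 15}

    def test_90min_stage_15_points(self):
        s = SamplingSchedule(stage_durations=(90.0,))
        assert len(schedule_timepoints(s)) == 15

    def test_degenerate_uniform_schedule(self):
        s = SamplingSchedule(stage_durations=(60.0,), dense_interval=10.0,
                             sparse_interval=10.0, dense_window=30.0)
        pts = [t for _, t in schedule_timepoints(s)]
        assert pts == [10.0, 20.0, 30.0, 40.0, 50.0, 60.0]

    def test_zero_interval_rejected(self):
        with pytest.raises(ConfigurationError):
            SamplingSchedule(dense_interval=0.0)

    @given(duration=st.integers(40, 200), dense=st.integers(2, 15),
           sparse=st.integers(2, 25), window=st.integers(10, 40))
    @settings(max_examples=50, deadline=None)
    def test_counts_match_closed_form(self, duration, dense, sparse, window):
        window = min(window, duration)
        s = SamplingSchedule(stage_durations=(float(duration),),
                             dense_interval=float(dense),
                             sparse_interval=float(sparse),
                             dense_window=float(window))
        pts = schedule_timepoints(s)
        expected = window // dense + (duration - window) // sparse
        assert len(pts) == expected
        minutes = [t for _, t in pts]
        assert minutes == sorted(set(minutes))


class TestComponents:
    def test_axis_shape(self):
        axis = default_axis()
        assert axis.size == 1175
        assert axis[0] == 176.0
        assert np.allclose(np.diff(axis), 2.83)
        assert axis[-1] <= 3500.0

    def test_peak_outside_axis_rejected(self):
        comp = PureComponentSpectrum("x", (50.0,), (10.0,), (1.0,))
        with pytest.raises(ConfigurationError):
            comp.evaluate(default_axis())

    def test_invalid_widths(self):
        with pytest.raises(ConfigurationError):
            PureComponentSpectrum("x", (1000.0,), (0.0,), (1.0,))


class TestRender:
    def test_all_zero(self, small_axis):
        comps = default_components()
        out = render_spectrum([0.0] * len(comps), comps, small_axis)
        assert np.all(out == 0.0)

    def test_peak_location(self, small_axis):
        comp = PureComponentSpectrum("x", (1000.0,), (15.0,), (1.0,))
        out = render_spectrum([2.0], [comp], small_axis)
        assert np.argmax(out) == np.argmin(np.abs(small_axis - 1000.0))

    def test_negative_concentration_rejected(self, small_axis):
        with pytest.raises(DomainError):
            render_spectrum([-1.0], default_components()[:1], small_axis)

    def test_count_mismatch_rejected(self, small_axis):
        with pytest.raises(DomainError):
            render_spectrum([1.0, 2.0], default_components()[:1], small_axis)

    @given(st.lists(st.floats(0.0, 50.0), min_size=6, max_size=6),
           st.lists(st.floats(0.0, 50.0), min_size=6, max_size=6),
           st.floats(0.1, 10.0))
    @settings(max_examples=30, deadline=None)
    def test_linearity_superposition(self, c1, c2, alpha):
        axis = default_axis(resolution=40.0)
        comps = default_components()
        a = render_spectrum(c1, comps, axis)
        b = render_spectrum(c2, comps, axis)
        mixed = render_spectrum(np.array(c1) + alpha * np.array(c2), comps, axis)
        np.testing.assert_allclose(mixed, a + alpha * b, rtol=1e-9, atol=1e-9)


class TestKinetics:
    def test_nondecreasing_within_stage(self):
        k = ExtractionKinetics(100.0, 0.02, c_floor=10.0)
        for stage in (1, 2, 3):
            values = [k.concentration(stage, t) for t in range(1, 120)]
            assert all(b >= a for a, b in zip(values, values[1:]))

    def test_solver_hits_range(self):
        k = solve_kinetics_for_range(418.7, 4882.7, rate=0.015)
        pts = schedule_timepoints(SamplingSchedule())
        values = [k.concentration(s, t) for s, t in pts]
        assert min(values) == pytest.approx(418.7, rel=1e-9)
        assert max(values) == pytest.approx(4882.7, rel=1e-9)

    def test_solver_rejects_bad_range(self):
        with pytest.raises(ConfigurationError):
            solve_kinetics_for_range(10.0, 5.0, rate=0.02)


class TestGenerateDataset:
    def test_sample_counts_paper_schedule(self):
        cfg = GeneratorConfig(drop_last=False, axis_resolution=40.0,
                              replicates=1, outliers=OutlierSpec(count=0))
        ds = generate_dataset(cfg, seed=0)
        assert ds.spectra.n_samples == 336  # 7 x (18 + 15 + 15)
        cfg = GeneratorConfig(drop_last=True, axis_resolution=40.0,
                              replicates=1, outliers=OutlierSpec(count=0))
        assert generate_dataset(cfg, seed=0).spectra.n_samples == 335

    def test_replicates_multiply_rows(self, tiny_dataset):
        # 2 batches x 48 time points x 2 replicates
        assert tiny_dataset.spectra.n_samples == 2 * 48 * 2

    def test_zero_outliers(self):
        cfg = GeneratorConfig(n_batches=1, replicates=1, axis_resolution=40.0,
                              outliers=OutlierSpec(count=0))
        assert generate_dataset(cfg, seed=1).outlier_ids == []

    def test_outlier_ids_subset_of_samples(self, tiny_dataset):
        sample_ids = {s.split("#")[0] for s in tiny_dataset.spectra.sample_ids}
        assert set(tiny_dataset.outlier_ids) <= sample_ids

    def test_references_cover_all_samples(self, tiny_dataset):
        ref_ids = set(tiny_dataset.references.sample_ids)
        sample_ids = {s.split("#")[0] for s in tiny_dataset.spectra.sample_ids}
        assert ref_ids == sample_ids

    def test_determinism(self):
        cfg = GeneratorConfig(n_batches=1, replicates=2, axis_resolution=40.0)
        a = generate_dataset(cfg, seed=7)
        b = generate_dataset(cfg, seed=7)
        np.testing.assert_array_equal(a.spectra.intensities, b.spectra.intensities)
        assert a.outlier_ids == b.outlier_ids
        assert a.references.table.equals(b.references.table)

    def test_different_seeds_differ(self):
        cfg = GeneratorConfig(n_batches=1, replicates=1, axis_resolution=40.0)
        a = generate_dataset(cfg, seed=1)
        b = generate_dataset(cfg, seed=2)
        assert not np.array_equal(a.spectra.intensities, b.spectra.intensities)

    def test_too_many_outliers_rejected(self):
        cfg = GeneratorConfig(n_batches=1, replicates=1, axis_resolution=40.0,
                              outliers=OutlierSpec(count=48))
        with pytest.raises(ConfigurationError):
            generate_dataset(cfg, seed=0)

    def test_soluble_solid_span(self):
        ds = generate_dataset(GeneratorConfig(axis_resolution=40.0), seed=3)
        tab = ds.references.table
        ss = tab[tab.analyte == "soluble_solid"]["value"]
        assert ss.min() == pytest.approx(418.7, rel=0.15)
        assert ss.max() == pytest.approx(4882.7, rel=0.15)

    def test_writes_are_deterministic(self, tmp_path):
        cfg = GeneratorConfig(n_batches=1, replicates=1, axis_resolution=40.0)
        paths = {}
        for name in ("a", "b"):
            ds = generate_dataset(cfg, seed=9)
            paths[name] = synth.write_dataset(ds, tmp_path / name)
        for key in paths["a"]:
            with open(paths["a"][key], "rb") as fa, open(paths["b"][key], "rb") as fb:
                assert fa.read() == fb.read(), key
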