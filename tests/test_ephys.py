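"""Channel-trace analysis: histograms, levels, idealization, pore model."""

import numpy as np
import pytest

import helipore as hp
from helipore.ephys import (
    CurrentTrace,
    all_points_histogram,
    conductance,
    detect_levels,
    idealize,
    latency,
    pore_radius,
    read_trace_delimited,
    read_trace_raw,
    summarize_levels,
    write_trace_delimited,
)


class TestHistogram:
    def test_constant_trace_single_bin(self):
        tr = CurrentTrace(np.full(2000, 1.234), 50_000, 50.0)
        counts, edges = all_points_histogram(tr, 0.05)
        assert counts.sum() == 2000
        assert np.count_nonzero(counts) == 1

    def test_two_level_mass_ratio(self):
        q = np.array([[0.0, 100.0], [900.0, 0.0]])  # ~90/10 occupancy
        spec = hp.TraceSpec([2.0], q, noise_sigma=0.1, duration=4.0, seed=0)
        tr, truth = hp.generate_channel_trace(spec)
        counts, edges = all_points_histogram(tr, 0.05)
        centers = 0.5 * (edges[:-1] + edges[1:])
        closed = counts[np.abs(centers) < 0.5].sum()
        open_ = counts[np.abs(centers - 2.0) < 0.5].sum()
        assert closed / open_ == pytest.approx(9.0, rel=0.25)

    def test_pure_noise_unimodal_at_zero(self):
        rng = np.random.default_rng(0)
        tr = CurrentTrace(rng.normal(0, 0.15, 50_000), 50_000, 50.0)
        counts, edges = all_points_histogram(tr, 0.05)
        mode = 0.5 * (edges[np.argmax(counts)] + edges[np.argmax(counts) + 1])
        assert abs(mode) < 0.1
        assert detect_levels(tr) == []


class TestDetectLevels:
    def test_three_level_recovery(self, three_level_trace):
        spec, trace, _ = three_level_trace
        levels = detect_levels(trace)
        assert len(levels) == 3
        for lv, amp in zip(levels, spec.amplitudes):
            assert lv.mean_amplitude == pytest.approx(amp, rel=0.05)

    def test_gmm_method_agrees(self, three_level_trace):
        spec, trace, _ = three_level_trace
        levels = detect_levels(trace, method="gmm")
        assert len(levels) == 3
        for lv, amp in zip(levels, spec.amplitudes):
            assert lv.mean_amplitude == pytest.approx(amp, rel=0.05)

    def test_levels_closer_than_noise_merge(self):
        q = np.zeros((3, 3))
        q[0, 1:] = 30.0
        q[1:, 0] = 300.0
        spec = hp.TraceSpec([1.0, 1.1], q, noise_sigma=0.15, duration=2.0, seed=2)
        tr, _ = hp.generate_channel_trace(spec)
        levels = detect_levels(tr)
        assert len(levels) == 1  # unresolvable: merged

    def test_dc_offset_leaves_amplitudes_unchanged(self, three_level_trace):
        spec, trace, _ = three_level_trace
        shifted = CurrentTrace(
            trace.samples + 4.0, trace.sampling_rate, trace.holding_potential
        )
        a0 = [lv.mean_amplitude for lv in detect_levels(trace)]
        a1 = [lv.mean_amplitude for lv in detect_levels(shifted)]
        assert np.allclose(a0, a1, atol=0.02)


class TestIdealize:
    def test_dwell_time_recovery(self):
        close_rate = 400.0
        q = np.array([[0.0, 50.0], [close_rate, 0.0]])
        spec = hp.TraceSpec([3.0], q, noise_sigma=0.1, duration=20.0, seed=3)
        tr, _ = hp.generate_channel_trace(spec)
        levels = detect_levels(tr)
        ev = idealize(tr, levels)
        assert ev.dwell.mean() == pytest.approx(1.0 / close_rate, rel=0.10)

    def test_constant_open_single_event(self):
        tr = CurrentTrace(np.full(5000, 3.0), 50_000, 50.0)
        ev = idealize(tr, [hp.ConductanceLevel(1, 3.0, 0.0)], baseline=0.0)
        assert len(ev) == 1
        assert ev.dwell.iloc[0] == pytest.approx(0.1)

    def test_alternating_single_samples_suppressed(self):
        samples = np.zeros(1000)
        samples[::2] = 3.0  # 1-sample spikes
        tr = CurrentTrace(samples, 50_000, 50.0)
        ev = idealize(tr, [hp.ConductanceLevel(1, 3.0, 0.0)], baseline=0.0,
                      min_duration=2)
        assert len(ev) == 0 or ev.dwell.max() < 2 / 50_000 * 1.5


class TestLatency:
    def test_programmed_onset_recovered(self):
        q = np.array([[0.0, 50.0], [200.0, 0.0]])
        spec = hp.TraceSpec([3.0], q, noise_sigma=0.1, duration=6.0,
                            quiet_until=4.2, seed=4)
        tr, truth = hp.generate_channel_trace(spec)
        lv = detect_levels(tr)
        lat = latency(tr, levels=lv, min_duration=5)
        assert lat >= 4.2
        from helipore.synthetic import first_detectable_opening

        first_sample = first_detectable_opening(
            truth["state_per_sample"], spec.sampling_rate, min_duration=5
        )
        assert abs(lat - first_sample) <= 1.0 / spec.sampling_rate + 1e-12

    def test_quiet_trace_flagged(self):
        rng = np.random.default_rng(1)
        tr = CurrentTrace(rng.normal(0, 0.1, 10_000), 50_000, 50.0)
        with pytest.warns(UserWarning, match="latency undefined"):
            assert np.isnan(latency(tr, detection_threshold=1.0))

    def test_event_in_first_sample_is_zero(self):
        tr = CurrentTrace(np.full(100, 3.0), 50_000, 50.0)
        assert latency(tr, detection_threshold=1.5) == 0.0


class TestConductance:
    @pytest.mark.parametrize("amp,expected", [(3.21, 64.24), (2.46, 49.22),
                                              (0.58, 11.54), (25.38, 507.54)])
    def test_published_worked_examples(self, amp, expected):
        """Printed amplitudes over +50 mV reproduce the printed pS values."""
        assert conductance(amp, 50.0) == pytest.approx(expected, rel=0.01)

    def test_zero_amplitude(self):
        assert conductance(0.0, 50.0) == 0.0

    def test_linear_in_amplitude_inverse_in_potential(self):
        grid_a = np.linspace(0.1, 10, 7)
        grid_v = np.array([10.0, 25.0, 50.0, 100.0])
        for v in grid_v:
            g = np.array([conductance(a, v) for a in grid_a])
            assert np.allclose(g, grid_a / v * 1000.0)
        for a in grid_a:
            g = np.array([conductance(a, v) for v in grid_v])
            assert np.allclose(g * grid_v, g[0] * grid_v[0])

    def test_zero_potential_rejected(self):
        with pytest.raises(ValueError):
            conductance(1.0, 0.0)


class TestPoreRadius:
    def test_zero_conductance_limit(self):
        assert pore_radius(0.0) == 0.0
        assert pore_radius(-5.0) == 0.0

    def test_sqrt_scaling_cylinder(self):
        for g in (10.0, 64.0, 500.0):
            assert pore_radius(4 * g) == pytest.approx(2 * pore_radius(g), rel=1e-9)

    def test_access_resistance_requires_wider_pore(self):
        """At equal G the access-resistance model always returns a larger
        radius than the bare cylinder (numeric scan over 1-1000 pS)."""
        for g in np.linspace(1.0, 1000.0, 200):
            r_cyl = pore_radius(g, model="cylinder")
            r_acc = pore_radius(g, model="cylinder_with_access_resistance")
            assert r_acc >= r_cyl
            # and it solves its own equation
            kappa, l = 3.5, 4e-9
            r = r_acc * 1e-9
            g_back = 1.0 / (l / (kappa * np.pi * r**2) + 1 / (2 * kappa * r))
            assert g_back * 1e12 == pytest.approx(g, rel=1e-6)

    def test_published_radius_column_from_conductances(self):
        """kappa=3.5 S/m, l=4 nm maps the published conductances onto the
        published radius column (printed precision, one cell off by 0.01)."""
        table = [(17.89, 0.08), (507.54, 0.43), (11.54, 0.06), (108.56, 0.19)]
        for g, r in table:
            assert pore_radius(g) == pytest.approx(r, abs=0.015)


def test_summary_table_carries_model_metadata(three_level_trace):
    _, trace, _ = three_level_trace
    levels = detect_levels(trace)
    df = summarize_levels(levels, trace.holding_potential)
    assert list(df.level_index) == [1, 2, 3]
    assert df.attrs["params"]["conductivity"] == 3.5
    assert np.all(np.diff(df.mean_amplitude) > 0)
    assert np.allclose(df.conductance, df.mean_amplitude / 50.0 * 1000.0)


def test_trace_io_roundtrips(tmp_path, three_level_trace):
    _, trace, _ = three_level_trace
    short = CurrentTrace(trace.samples[:5000], trace.sampling_rate,
                         trace.holding_potential, "t")
    p = tmp_path / "trace.csv"
    write_trace_delimited(short, p)
    back = read_trace_delimited(p)
    assert back.sampling_rate == short.sampling_rate
    assert back.holding_potential == short.holding_potential
    assert np.allclose(back.samples, short.samples, atol=1e-4)

    raw = tmp_path / "trace.f32"
    short.samples.astype("<f4").tofile(raw)
    (tmp_path / "trace.f32.json").write_text(
        '{"rate_hz": 50000, "potential_mv": 50, "label": "t"}'
    )
    back2 = read_trace_raw(raw)
    assert np.allclose(back2.samples, short.samples, atol=1e-4)
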