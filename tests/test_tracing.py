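import numpy as np
import pytest

from pwvloop.errors import AnatomyError, InsufficientDataError, TracingQualityError
from pwvloop.image_io import UltrasoundRecording
from pwvloop.synthetic import (
    DopplerRender,
    MModeRender,
    SyntheticSubject,
    generate_run,
    render_doppler,
    render_mmode,
)
from pwvloop.tracing import (
    WallTrace,
    diameter_waveform,
    smooth_trace,
    trace_doppler_envelope,
    trace_wall,
)


def _band_image(n_cols=300, rows=120, near=(40, 45), far=(80, 85), intensity=200.0, ecg=(110, 120)):
    img = np.zeros((rows, n_cols))
    img[near[0] : near[1]] = intensity
    img[far[0] : far[1]] = intensity
    img[ecg[0] + 2] = 250.0
    return UltrasoundRecording(img, "mmode", 3.5, 0.05, ecg_band=ecg)


class TestTraceWall:
    def test_flat_band_inner_edge(self):
        rec = _band_image()
        near = trace_wall(rec, "near", roi=(30, 60), threshold=100)
        np.testing.assert_array_equal(near.rows, np.full(300, 44.0))

    def test_far_wall_inner_edge_is_shallowest(self):
        rec = _band_image()
        far = trace_wall(rec, "far", roi=(70, 100), threshold=100)
        np.testing.assert_array_equal(far.rows, np.full(300, 80.0))

    def test_exclusion_interval_marked_missing(self):
        rec = _band_image()
        near = trace_wall(rec, "near", roi=(30, 60), threshold=100, exclusions=[(100, 120)])
        assert np.all(~np.isfinite(near.rows[100:120]))
        assert np.all(np.isfinite(near.rows[:100]))

    def test_sinusoidal_band_within_one_pixel(self):
        n = 400
        cols = np.arange(n)
        center = 50 + 8 * np.sin(2 * np.pi * cols / 150)
        img = np.zeros((120, n))
        for c in range(n):
            r = int(round(center[c]))
            img[r - 3 : r + 1, c] = 200.0  # inner edge at r
        rec = UltrasoundRecording(img, "mmode", 3.5, 0.05, ecg_band=(110, 120))
        near = trace_wall(rec, "near", roi=(30, 70), threshold=100)
        assert np.max(np.abs(near.rows - center)) <= 1.0

    def test_too_many_missing_columns(self):
        img = np.zeros((60, 100))
        img[40:44, :30] = 200.0  # only 30% of columns traced
        rec = UltrasoundRecording(img, "mmode", 3.5, 0.05, ecg_band=(50, 60))
        with pytest.raises(TracingQualityError):
            trace_wall(rec, "near", roi=(30, 50), threshold=100)

    def test_threshold_monotonicity_on_band(self):
        rec = _band_image(intensity=200.0)
        low = trace_wall(rec, "near", roi=(30, 60), threshold=50)
        high = trace_wall(rec, "near", roi=(30, 60), threshold=150)
        # raising the threshold never moves the inner edge deeper than truth
        assert np.all(high.rows <= low.rows.max())
        np.testing.assert_array_equal(low.rows, high.rows)


class TestSmoothTrace:
    def test_linear_trace_preserved(self):
        cols = np.arange(300)
        rows = 50 + 0.02 * cols
        sm = smooth_trace(WallTrace(rows=rows, wall="near", roi=(0, 100), threshold=1))
        assert np.max(np.abs(sm.rows - rows)) <= 0.1

    def test_gap_filled_within_one_pixel(self):
        cols = np.arange(600)
        true = 100 + 12 * np.sin(2 * np.pi * cols / 240)
        rows = true.copy()
        rows[300:320] = np.nan
        sm = smooth_trace(WallTrace(rows=rows, wall="far", roi=(80, 120), threshold=1))
        assert np.all(np.isfinite(sm.rows))
        assert np.max(np.abs(sm.rows - true)) <= 1.0

    def test_default_smoothing_parameter(self):
        import inspect

        from pwvloop.tracing import DEFAULT_SMOOTHING

        assert DEFAULT_SMOOTHING == 0.001
        assert inspect.signature(smooth_trace).parameters["smoothing_parameter"].default == 0.001

    def test_insufficient_points(self):
        rows = np.full(50, np.nan)
        rows[[3, 10, 20]] = 40.0
        with pytest.raises(InsufficientDataError):
            smooth_trace(WallTrace(rows=rows, wall="near", roi=(30, 50), threshold=1))

    def test_outlier_rejected_before_fit(self):
        cols = np.arange(400)
        true = 60 + 5 * np.sin(2 * np.pi * cols / 200)
        rows = true.copy()
        rows[200] = 110.0  # isolated artefact spike
        sm = smooth_trace(WallTrace(rows=rows, wall="near", roi=(40, 120), threshold=1))
        assert abs(sm.rows[200] - true[200]) <= 1.0


class TestDiameterWaveform:
    def test_constant_separation(self):
        near = WallTrace(rows=np.full(100, 44.0), wall="near", roi=(30, 60), threshold=1)
        far = WallTrace(rows=np.full(100, 84.0), wall="far", roi=(70, 100), threshold=1)
        wf = diameter_waveform(near, far, value_cal=0.05, time_cal=3.5)
        np.testing.assert_allclose(wf.values, 2.0)
        assert wf.kind == "diameter"

    def test_crossing_walls_error(self):
        rows_n = np.full(100, 44.0)
        rows_f = np.full(100, 84.0)
        rows_f[50] = 44.0
        near = WallTrace(rows=rows_n, wall="near", roi=(30, 60), threshold=1)
        far = WallTrace(rows=rows_f, wall="far", roi=(40, 100), threshold=1)
        with pytest.raises(AnatomyError):
            diameter_waveform(near, far, 0.05, 3.5)

    def test_generator_round_trip_under_two_calibrations(self, quiet_subject):
        run = generate_run(quiet_subject, 4, "diameter")
        cfg = MModeRender()
        rec, truth = render_mmode(run, cfg)
        near = smooth_trace(trace_wall(rec, "near", roi=(20, 120), threshold=110))
        far = smooth_trace(trace_wall(rec, "far", roi=(180, 290), threshold=110))
        wf = diameter_waveform(near, far, rec.value_cal, rec.time_cal)
        true_d = (truth["far_rows"] - truth["near_rows"]) * cfg.value_cal
        assert np.max(np.abs(wf.values - true_d)) < 2 * cfg.value_cal
        assert np.all(np.isfinite(np.log(wf.values)))


class TestDopplerEnvelope:
    def test_triangular_envelope_peak(self):
        n = 700
        cols = np.arange(n)
        u = np.maximum(0.0, 1.0 - np.abs(cols - 350) / 300.0)  # peak 1.0 m/s
        img = np.full((300, n), 5.0)
        baseline = 250
        for c in range(n):
            env = baseline - int(round(u[c] / 0.01))
            img[env : baseline + 1, c] = 180.0
        rec = UltrasoundRecording(img, "doppler", 2.5, 0.01, ecg_band=(280, 300), baseline_row=baseline)
        wf = trace_doppler_envelope(rec, threshold=90)
        assert abs(wf.values.max() - 1.0) <= 2 * 0.01

    def test_silent_diastole_filled_near_zero(self):
        n = 500
        cols = np.arange(n)
        u = np.where(np.abs(cols - 350) < 80, 1.0 - np.abs(cols - 350) / 80.0, 0.005)
        img = np.full((300, n), 5.0)
        baseline = 250
        for c in range(n):
            if u[c] <= 0.01 and 150 < c < 185:
                continue  # a 34-column window entirely below threshold
            env = baseline - int(round(u[c] / 0.01))
            img[env : baseline + 1, c] = 180.0
        rec = UltrasoundRecording(img, "doppler", 2.5, 0.01, ecg_band=(280, 300), baseline_row=baseline)
        wf = trace_doppler_envelope(rec, threshold=90)
        assert np.all(np.isfinite(wf.values))
        assert np.max(np.abs(wf.values[155:180])) <= 2 * 0.01

    def test_envelope_at_baseline_is_zero(self):
        img = np.full((100, 200), 5.0)
        img[80, :] = 180.0  # envelope exactly at the baseline row
        rec = UltrasoundRecording(img, "doppler", 2.5, 0.01, ecg_band=(90, 100), baseline_row=80)
        wf = trace_doppler_envelope(rec, threshold=90)
        np.testing.assert_allclose(wf.values, 0.0, atol=1e-9)

    def test_background_noise_below_threshold_invariant(self, quiet_subject):
        run = generate_run(quiet_subject, 3, "velocity")
        rec, _ = render_doppler(run, DopplerRender())
        wf_clean = trace_doppler_envelope(rec, threshold=65)
        rng = np.random.default_rng(0)
        noisy = rec.pixels + rng.integers(0, 30, rec.pixels.shape)  # stays below threshold
        rec2 = UltrasoundRecording(noisy, "doppler", rec.time_cal, rec.value_cal,
                                   ecg_band=rec.ecg_band, baseline_row=rec.baseline_row)
        wf_noisy = trace_doppler_envelope(rec2, threshold=65)
        np.testing.assert_allclose(wf_clean.values, wf_noisy.values, atol=1e-9)

    def test_generator_round_trip_under_two_calibrations(self, quiet_subject):
        run = generate_run(quiet_subject, 4, "velocity")
        cfg = DopplerRender()
        rec, truth = render_doppler(run, cfg)
        wf = trace_doppler_envelope(rec, threshold=65)
        true_u = (cfg.baseline_row - truth["envelope_rows"]) * cfg.value_cal
        assert np.max(np.abs(wf.values - true_u)) < 2 * cfg.value_cal

    def test_mostly_missing_is_error(self):
        img = np.full((100, 200), 5.0)
        img[60, :20] = 180.0
        rec = UltrasoundRecording(img, "doppler", 2.5, 0.01, ecg_band=(90, 100), baseline_row=80)
        with pytest.raises(TracingQualityError):
            trace_doppler_envelope(rec, threshold=90)
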