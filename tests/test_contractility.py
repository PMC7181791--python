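"""Edge tracking, baseline, beat segmentation and metrics."""

import numpy as np
import pytest

from ringforce.beam import fit_calibration
from ringforce.contractility import (
    EdgeTrace,
    EdgeTrackingError,
    compare_automated_manual,
    compute_baseline,
    compute_metrics,
    detect_beats,
    track_edge,
)
from ringforce.imaging import Kymograph
from ringforce.synthetic import (
    SceneSpec,
    WaveformSpec,
    make_waveform,
    render_kymograph,
)

FPS = 100.0


def make_trace(disp_um, fps=FPS, pixel_size=1.0, raw=None, baseline=0.0):
    disp_um = np.asarray(disp_um, dtype=float)
    n = len(disp_um)
    return EdgeTrace(
        t=np.arange(n) / fps,
        raw_position_px=disp_um / pixel_size if raw is None else raw,
        displacement_um=disp_um,
        baseline_px=baseline,
        fps=fps,
        pixel_size_um=pixel_size,
    )


# ---------------------------------------------------------------------------
# tracking


def test_track_sinusoidal_edge_within_quarter_pixel():
    scene = SceneSpec(duration_s=5.0)
    t = np.arange(scene.n_frames) / scene.fps
    wf = 2.5 * (1 - np.cos(2 * np.pi * t))  # sinusoid, 0..5 µm
    kym, truth = render_kymograph(scene, wf)
    trace = track_edge(kym)
    assert np.max(np.abs(trace.raw_position_px - truth["edge_px"])) <= 0.25


def test_track_static_edge_constant_zero_displacement():
    scene = SceneSpec(duration_s=3.0)
    kym, truth = render_kymograph(scene, np.zeros(scene.n_frames))
    trace = track_edge(kym)
    assert np.ptp(trace.raw_position_px) < 1e-9
    assert np.allclose(trace.displacement_um, 0.0, atol=1e-9)
    assert trace.baseline_px == pytest.approx(truth["rest_edge_px"], abs=0.3)


def test_track_with_pixel_noise_amplitude_within_2pct():
    scene = SceneSpec(duration_s=10.0, seed=7)
    dyn_range = scene.background_level - scene.post_level
    noisy = SceneSpec(**{**scene.__dict__, "pixel_noise_sd": 0.05 * dyn_range})
    wf, truth = make_waveform(WaveformSpec(amplitude_um=10.0), scene.fps,
                              scene.duration_s)
    kym, _ = render_kymograph(noisy, wf)
    trace = track_edge(kym)
    beats = detect_beats(trace)
    metrics = compute_metrics(trace, beats)
    assert metrics.contraction_amplitude_um == pytest.approx(10.0, rel=0.02)


def test_untrackable_kymograph_raises_with_rows():
    flat = Kymograph(matrix=np.full((300, 50), 5.0), fps=FPS, pixel_size_um=1.0,
                     scanline_row=0)
    with pytest.raises(EdgeTrackingError) as exc:
        track_edge(flat)
    assert len(exc.value.rows) == 300


# ---------------------------------------------------------------------------
# baseline


def test_baseline_of_constant_trace():
    trace = make_trace(np.zeros(500), raw=np.full(500, 42.0))
    assert compute_baseline(trace) == pytest.approx(42.0, abs=1e-12)


def test_baseline_on_flat_diastole_beats():
    wf, _ = make_waveform(WaveformSpec(amplitude_um=8.0), FPS, 10.0)
    raw = 30.0 + wf  # pixel positions, pixel_size 1
    assert compute_baseline(raw, fps=FPS) == pytest.approx(30.0, abs=0.3)


def test_drifting_baseline_keeps_per_beat_amplitude_within_3pct():
    scene = SceneSpec(duration_s=20.0)
    wf, truth = make_waveform(
        WaveformSpec(amplitude_um=10.0, drift_rate_um_per_s=0.1 * scene.pixel_size_um),
        scene.fps, scene.duration_s,
    )  # 1 px per 10 s of drift
    kym, _ = render_kymograph(scene, wf)
    trace = track_edge(kym)
    beats = detect_beats(trace)
    amps = np.array([b.amplitude_um for b in beats])
    assert np.all(np.abs(amps - 10.0) / 10.0 <= 0.03)


def test_short_trace_rejected():
    with pytest.raises(ValueError):
        compute_baseline(np.zeros(50), fps=FPS)  # 0.5 s < 2 s window


# ---------------------------------------------------------------------------
# beats and metrics


def test_flat_trace_has_no_beats_and_zero_metrics():
    trace = make_trace(np.zeros(1000))
    beats = detect_beats(trace)
    assert beats == []
    m = compute_metrics(trace, beats)
    assert m.beats_per_minute == 0.0 and m.n_beats == 0


def test_twenty_beats_in_twenty_seconds():
    wf, truth = make_waveform(WaveformSpec(bpm=60, amplitude_um=10.0), FPS, 20.0)
    trace = make_trace(wf)
    beats = detect_beats(trace)
    assert len(beats) == 20 == len(truth.beats)
    m = compute_metrics(trace, beats)
    assert m.beats_per_minute == pytest.approx(60.0, abs=1e-9)


def test_prominence_filters_small_beat_class():
    wf_big, _ = make_waveform(WaveformSpec(bpm=30, amplitude_um=8.0), FPS, 20.0)
    small_spec = WaveformSpec(bpm=30, amplitude_um=0.2, contraction_time_s=0.15,
                              relaxation_time_s=0.3)
    wf_small, _ = make_waveform(small_spec, FPS, 20.0)
    wf = wf_big + np.roll(wf_small, 100)  # interleave small beats
    beats = detect_beats(make_trace(wf), min_prominence_um=1.0)
    assert len(beats) == 10  # only the 8 µm class


def test_beat_indices_ordered_and_positive_amplitude():
    wf, _ = make_waveform(WaveformSpec(), FPS, 10.0)
    beats = detect_beats(make_trace(wf))
    for b in beats:
        assert b.onset_idx < b.peak_idx < b.end_idx
        assert b.amplitude_um > 0


def test_triangular_beat_velocity_matches_analytic_slope():
    spec = WaveformSpec(bpm=30, amplitude_um=10.0, contraction_time_s=0.1,
                        relaxation_time_s=0.4)
    wf, truth = make_waveform(spec, FPS, 10.0)
    trace = make_trace(wf)
    beats = detect_beats(trace)
    m = compute_metrics(trace, beats)
    # analytic rise slope 100 µm/s; allow one discretization-step slope
    one_step = truth.beats[0].max_rise_slope_um_s / (spec.contraction_time_s * FPS)
    assert abs(m.contraction_velocity_um_s - 100.0) <= one_step + 1e-9
    assert abs(m.relaxation_velocity_um_s - 25.0) <= 25.0 / (0.4 * FPS) + 1e-9


def test_force_from_amplitude_with_linear_calibration():
    d = np.arange(1.0, 13.0)
    curve = fit_calibration(np.column_stack([d, 2.0 * d]))
    wf, _ = make_waveform(WaveformSpec(amplitude_um=10.1), FPS, 10.0)
    trace = make_trace(wf)
    m = compute_metrics(trace, detect_beats(trace), curve)
    assert m.force_un == pytest.approx(20.2, rel=1e-9)


def test_mismatched_beats_rejected():
    wf, _ = make_waveform(WaveformSpec(), FPS, 10.0)
    trace = make_trace(wf)
    beats = detect_beats(trace)
    short = make_trace(wf[:300])
    with pytest.raises(ValueError):
        compute_metrics(short, beats)


# ---------------------------------------------------------------------------
# invariants


def test_scale_equivariance_in_pixel_size():
    scene = SceneSpec(duration_s=10.0)
    wf, _ = make_waveform(WaveformSpec(amplitude_um=6.0), scene.fps, scene.duration_s)
    kym, _ = render_kymograph(scene, wf)
    alpha = 2.0
    kym_scaled = Kymograph(matrix=kym.matrix.copy(), fps=kym.fps,
                           pixel_size_um=alpha * kym.pixel_size_um,
                           scanline_row=kym.scanline_row)
    m1 = compute_metrics(tr1 := track_edge(kym), detect_beats(tr1))
    tr2 = track_edge(kym_scaled)
    m2 = compute_metrics(tr2, detect_beats(tr2, min_prominence_um=alpha))
    assert m2.contraction_amplitude_um == pytest.approx(
        alpha * m1.contraction_amplitude_um, rel=1e-9)
    assert m2.contraction_velocity_um_s == pytest.approx(
        alpha * m1.contraction_velocity_um_s, rel=1e-9)
    assert m2.beats_per_minute == pytest.approx(m1.beats_per_minute, rel=1e-12)


def test_time_reversal_swaps_velocities():
    scene = SceneSpec(duration_s=10.0)
    wf, _ = make_waveform(WaveformSpec(amplitude_um=8.0), scene.fps, scene.duration_s)
    kym, _ = render_kymograph(scene, wf)
    rev = Kymograph(matrix=kym.matrix[::-1].copy(), fps=kym.fps,
                    pixel_size_um=kym.pixel_size_um, scanline_row=kym.scanline_row)
    m_fwd = compute_metrics(t1 := track_edge(kym), detect_beats(t1))
    m_rev = compute_metrics(t2 := track_edge(rev), detect_beats(t2))
    one_step_rise = m_fwd.contraction_velocity_um_s / (0.15 * scene.fps)
    one_step_fall = m_fwd.relaxation_velocity_um_s / (0.3 * scene.fps)
    assert abs(m_rev.contraction_velocity_um_s - m_fwd.relaxation_velocity_um_s) \
        <= one_step_fall + 1e-6
    assert abs(m_rev.relaxation_velocity_um_s - m_fwd.contraction_velocity_um_s) \
        <= one_step_rise + 1e-6


def test_metrics_deterministic_bit_identical():
    scene = SceneSpec(duration_s=5.0, pixel_noise_sd=50.0, seed=3)
    wf, _ = make_waveform(WaveformSpec(noise_sd_um=0.1, seed=3), scene.fps,
                          scene.duration_s)
    kym, _ = render_kymograph(scene, wf)
    m1 = compute_metrics(t1 := track_edge(kym), detect_beats(t1))
    m2 = compute_metrics(t2 := track_edge(kym), detect_beats(t2))
    assert m1 == m2


# ---------------------------------------------------------------------------
# automated vs manual agreement


def test_identical_vectors_perfect_agreement():
    v = np.array([1.0, 2.0, 5.0, 9.0])
    rep = compare_automated_manual(v, v)
    assert rep.pearson_r == pytest.approx(1.0)
    assert rep.slope == pytest.approx(1.0)
    assert rep.intercept == pytest.approx(0.0, abs=1e-12)


def test_near_linear_agreement(rng):
    manual = rng.uniform(1, 12, 50)
    auto = 1.02 * manual + rng.normal(0, 0.1, 50)
    rep = compare_automated_manual(auto, manual)
    assert rep.pearson_r > 0.99
    assert 0.98 <= rep.slope <= 1.06
    # residuals consistent with the closed-form least-squares line
    x = np.column_stack([manual, np.ones_like(manual)])
    beta = np.linalg.lstsq(x, auto, rcond=None)[0]
    assert rep.slope == pytest.approx(beta[0], rel=1e-9)


def test_exact_negation_anticorrelated():
    v = np.array([1.0, 2.0, 4.0, 8.0])
    rep = compare_automated_manual(-v, v)
    assert rep.pearson_r == pytest.approx(-1.0)


def test_zero_variance_rejected():
    with pytest.raises(ValueError):
        compare_automated_manual(np.ones(5), np.arange(5.0))
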