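"""Sub-pixel edge tracking of a post through a kymograph and beat metrics.

Each kymograph row is one scanline at one time point; the post/background
boundary crosses every row.  The tracker interpolates the first half-range
intensity crossing scanning from the post side, constrained to a window
around the previous row's edge, giving a sub-pixel position trace.  Beats
are segmented from the baseline-corrected displacement and summarised as
beats per minute, contraction amplitude, contraction velocity, relaxation
velocity, and (given a calibration) contractile force.

Sign convention: displacement toward the well centre — i.e. contraction —
is positive.  For the left post of a pair this is motion to the right
(increasing column), which is ``direction=+1``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.signal import find_peaks

from ringforce.beam import CalibrationCurve, force_from_deflection
from ringforce.imaging import Kymograph

__all__ = [
    "EdgeTrace",
    "Beat",
    "ContractilityMetrics",
    "CorrelationReport",
    "EdgeTrackingError",
    "track_edge",
    "compute_baseline",
    "detect_beats",
    "compute_metrics",
    "compare_automated_manual",
    "metrics_to_frame",
]

BASELINE_WINDOW_S = 2.0
BASELINE_PERCENTILE = 10.0


class EdgeTrackingError(RuntimeError):
    """No intensity crossing found in too many rows; lists the rows."""

    def __init__(self, message: str, rows: list[int]):
        super().__init__(message)
        self.rows = rows


@dataclass
class EdgeTrace:
    """Sub-pixel edge position over time, baseline-corrected to µm."""

    t: np.ndarray  # s, one per kymograph row
    raw_position_px: np.ndarray  # sub-pixel edge column per row
    displacement_um: np.ndarray  # signed; contraction positive
    baseline_px: float  # scalar diastolic reference (median of rolling floor)
    fps: float
    pixel_size_um: float

    def __post_init__(self) -> None:
        n = len(self.t)
        if not (len(self.raw_position_px) == len(self.displacement_um) == n):
            raise ValueError("t, raw_position_px, displacement_um must align")


@dataclass(frozen=True)
class Beat:
    """One contraction: onset/peak/end row indices and per-beat measures."""

    onset_idx: int
    peak_idx: int
    end_idx: int
    amplitude_um: float
    contraction_velocity_um_s: float
    relaxation_velocity_um_s: float


@dataclass(frozen=True)
class ContractilityMetrics:
    beats_per_minute: float
    contraction_amplitude_um: float
    contraction_velocity_um_s: float
    relaxation_velocity_um_s: float
    force_un: float | None
    n_beats: int
    duration_s: float


@dataclass(frozen=True)
class CorrelationReport:
    pearson_r: float
    slope: float
    intercept: float
    residuals: np.ndarray


def _first_crossing(segment: np.ndarray, polarity: str) -> float | None:
    """Sub-pixel index of the first half-range crossing, scanning left→right.

    ``polarity="rising"`` looks for dark→bright (left post, right edge);
    ``"falling"`` for bright→dark (right post, left edge).
    """
    lo, hi = float(segment.min()), float(segment.max())
    if hi == lo:
        return None
    t = 0.5 * (lo + hi)
    s = segment.astype(float)
    if polarity == "rising":
        below = s < t
        idx = np.nonzero(below[:-1] & ~below[1:])[0]
    elif polarity == "falling":
        above = s > t
        idx = np.nonzero(above[:-1] & ~above[1:])[0]
    else:
        raise ValueError("polarity must be 'rising' or 'falling'")
    if idx.size == 0:
        return None
    j = int(idx[0])
    return j + (t - s[j]) / (s[j + 1] - s[j])


def track_edge(
    kym: Kymograph,
    polarity: str = "rising",
    window_px: int = 15,
    direction: int = +1,
    max_missing_frac: float = 0.05,
) -> EdgeTrace:
    """Track the post edge through every kymograph row at sub-pixel precision.

    Per row, the edge is the linear interpolation of the first crossing of
    the half-range intensity threshold scanning from the post side; rows
    after the first are searched within ±``window_px`` of the previous
    row's edge to enforce continuity.  Rows without a crossing inherit the
    previous position; if more than ``max_missing_frac`` of rows lack one,
    an :class:`EdgeTrackingError` is raised listing them.
    """
    mat = np.asarray(kym.matrix, dtype=float)
    n, width = mat.shape
    positions = np.empty(n)
    missing: list[int] = []
    prev: float | None = None
    for i in range(n):
        if prev is None:
            lo, hi = 0, width
        else:
            lo = max(0, int(np.floor(prev)) - window_px)
            hi = min(width, int(np.ceil(prev)) + window_px + 1)
        pos = _first_crossing(mat[i, lo:hi], polarity)
        if pos is None:
            missing.append(i)
            positions[i] = prev if prev is not None else np.nan
        else:
            positions[i] = lo + pos
            prev = positions[i]
    if len(missing) > max_missing_frac * n:
        raise EdgeTrackingError(
            f"no edge crossing in {len(missing)}/{n} rows", missing
        )
    if np.isnan(positions[0]):
        first_valid = np.flatnonzero(~np.isnan(positions))[0]
        positions[: first_valid + 1] = positions[first_valid]
    t = np.arange(n) / kym.fps
    baseline_series, baseline_scalar = _rolling_baseline(
        positions, kym.fps, direction=direction
    )
    displacement = direction * (positions - baseline_series) * kym.pixel_size_um
    return EdgeTrace(
        t=t,
        raw_position_px=positions,
        displacement_um=displacement,
        baseline_px=baseline_scalar,
        fps=kym.fps,
        pixel_size_um=kym.pixel_size_um,
    )


def _rolling_baseline(
    raw_px: np.ndarray,
    fps: float,
    direction: int = +1,
    window_s: float = BASELINE_WINDOW_S,
    percentile: float = BASELINE_PERCENTILE,
) -> tuple[np.ndarray, float]:
    """Diastolic floor of the position trace.

    Centred rolling ``percentile`` (10th by default, of the contraction-
    positive signal) over a ``window_s`` window tracks slow drift of the
    resting position; the median across windows summarises it as a scalar.
    """
    n = len(raw_px)
    win = int(round(window_s * fps))
    if n < win:
        raise ValueError(
            f"trace ({n} samples) shorter than the {window_s} s baseline window"
        )
    q = percentile / 100.0 if direction > 0 else 1.0 - percentile / 100.0
    series = (
        pd.Series(raw_px)
        .rolling(win, center=True, min_periods=max(2, win // 2))
        .quantile(q)
        .to_numpy()
    )
    return series, float(np.median(series))


def compute_baseline(
    trace: EdgeTrace | np.ndarray,
    fps: float | None = None,
    direction: int = +1,
    window_s: float = BASELINE_WINDOW_S,
    percentile: float = BASELINE_PERCENTILE,
) -> float:
    """Scalar diastolic baseline (px) of a raw position trace."""
    if isinstance(trace, EdgeTrace):
        raw, fps = trace.raw_position_px, trace.fps
    else:
        raw = np.asarray(trace, dtype=float)
        if fps is None:
            raise ValueError("fps is required when passing a bare array")
    _, scalar = _rolling_baseline(
        raw, fps, direction=direction, window_s=window_s, percentile=percentile
    )
    return scalar


def detect_beats(
    trace: EdgeTrace,
    min_prominence_um: float = 1.0,
    min_interval_s: float = 0.25,
) -> list[Beat]:
    """Segment contractions from the baseline-corrected displacement.

    Peaks are local maxima with prominence ≥ ``min_prominence_um`` and
    spacing ≥ ``min_interval_s``; ties break toward the earlier index.
    Onset/end are the nearest samples at 10% of the peak amplitude flanking
    each peak.  Zero beats is an empty list, not an error.
    """
    disp = trace.displacement_um
    distance = max(1, int(round(min_interval_s * trace.fps)))
    peaks, _ = find_peaks(disp, prominence=min_prominence_um, distance=distance)
    grad = np.gradient(disp, 1.0 / trace.fps)  # µm/s, central differences
    beats: list[Beat] = []
    for p in peaks:
        amp = float(disp[p])
        thr = 0.1 * amp
        below = np.flatnonzero(disp[:p] <= thr)
        onset = int(below[-1]) if below.size else 0
        after = np.flatnonzero(disp[p + 1 :] <= thr)
        end = int(p + 1 + after[0]) if after.size else len(disp) - 1
        if not onset < p < end:
            continue
        beats.append(
            Beat(
                onset_idx=onset,
                peak_idx=int(p),
                end_idx=end,
                amplitude_um=amp,
                contraction_velocity_um_s=float(np.max(grad[onset : p + 1])),
                relaxation_velocity_um_s=float(np.max(-grad[p : end + 1])),
            )
        )
    return beats


def compute_metrics(
    trace: EdgeTrace,
    beats: list[Beat],
    curve: CalibrationCurve | None = None,
) -> ContractilityMetrics:
    """Aggregate per-beat measures into one record per tissue.

    Beat rate comes from the median inter-peak interval (robust to partial
    beats at the video boundaries); amplitude and the two velocities are
    medians across beats; force converts the amplitude through the supplied
    calibration.  Fewer than two beats reports 0 beats per minute.
    """
    n = len(trace.t)
    for b in beats:
        if not 0 <= b.onset_idx < b.peak_idx < b.end_idx < n:
            raise ValueError("beat indices do not fit the trace")
    duration = n / trace.fps
    if len(beats) >= 2:
        intervals = np.diff([b.peak_idx for b in beats]) / trace.fps
        bpm = 60.0 / float(np.median(intervals))
    else:
        bpm = 0.0
    if beats:
        amplitude = float(np.median([b.amplitude_um for b in beats]))
        cvel = float(np.median([b.contraction_velocity_um_s for b in beats]))
        rvel = float(np.median([b.relaxation_velocity_um_s for b in beats]))
    else:
        amplitude = cvel = rvel = 0.0
    force = float(force_from_deflection(amplitude, curve)) if curve else None
    return ContractilityMetrics(
        beats_per_minute=bpm,
        contraction_amplitude_um=amplitude,
        contraction_velocity_um_s=cvel,
        relaxation_velocity_um_s=rvel,
        force_un=force,
        n_beats=len(beats),
        duration_s=duration,
    )


def compare_automated_manual(
    auto: np.ndarray, manual: np.ndarray
) -> CorrelationReport:
    """Agreement between automated and manually measured amplitudes.

    Pearson r plus the least-squares line auto = slope·manual + intercept,
    with per-point residuals for inspection.
    """
    auto = np.asarray(auto, dtype=float)
    manual = np.asarray(manual, dtype=float)
    if auto.shape != manual.shape or auto.ndim != 1 or len(auto) < 3:
        raise ValueError("need two equal-length vectors of at least 3 values")
    if np.std(auto) == 0 or np.std(manual) == 0:
        raise ValueError("zero variance in one of the vectors")
    fit = stats.linregress(manual, auto)
    residuals = auto - (fit.slope * manual + fit.intercept)
    return CorrelationReport(
        pearson_r=float(fit.rvalue),
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        residuals=residuals,
    )


def metrics_to_frame(records: dict[str, ContractilityMetrics]) -> pd.DataFrame:
    """Per-plate metrics table keyed by well id."""
    rows = []
    for well, m in records.items():
        rows.append(
            {
                "well": well,
                "n_beats": m.n_beats,
                "bpm": m.beats_per_minute,
                "amplitude_um": m.contraction_amplitude_um,
                "contraction_velocity_um_s": m.contraction_velocity_um_s,
                "relaxation_velocity_um_s": m.relaxation_velocity_um_s,
                "force_uN": m.force_un,
            }
        )
    return pd.DataFrame(rows)
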