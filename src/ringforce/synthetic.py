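"""Ground-truthed synthetic data for every pipeline stage.

Generators emulate the study's measurement conditions so the full stack is
testable without experimental data:

* contraction waveforms — periodic pulses with a fast upstroke and slower
  relaxation, optional pixel noise, drift and timing jitter;
* bright-field scenes — two dark vertical posts in a bright well, the
  tracked post's inner edge displaced per frame with sub-pixel
  anti-aliasing and a Gaussian optical blur, rendered as full videos
  (20 s at 100 frames/s by default) or directly as kymographs;
* CCD response tables — y = X·beta + noise on a face-centred design, with
  a preset effect structure dominated by a positive cardiomyocyte-fraction
  effect and a concave collagen effect;
* dose-response tables — Hill-type scaling of contraction amplitude for
  positive/negative inotrope profiles over the standard five-dose panel
  (1 nM ... 10 µM).

Every generator is a pure function of its spec and seed, and returns
machine-readable ground truth sufficient to score the downstream analysis.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter1d

from ringforce.design import (
    CCDDesign,
    FactorSpec,
    quadratic_design_matrix,
    quadratic_term_names,
)
from ringforce.imaging import Kymograph, VideoStream, WellImage

__all__ = [
    "WaveformSpec",
    "WaveformTruth",
    "SceneSpec",
    "TRUE_BEAT_FIELDS",
    "make_waveform",
    "render_video",
    "render_kymograph",
    "make_well_image",
    "default_ccd_factors",
    "paper_like_ccd_beta",
    "make_ccd_responses",
    "DEFAULT_DOSES_M",
    "COMPOUND_PRESETS",
    "make_dose_response",
]


# ---------------------------------------------------------------------------
# Contraction waveforms


@dataclass(frozen=True)
class WaveformSpec:
    """Periodic contraction waveform parameters.

    One beat rises linearly (or with cosine smoothing) from 0 to
    ``amplitude_um`` over ``contraction_time_s`` and falls back over
    ``relaxation_time_s``; beats repeat at ``60 / bpm`` seconds.  The
    remaining diastolic interval must be positive.
    """

    bpm: float = 60.0
    amplitude_um: float = 10.0
    contraction_time_s: float = 0.15
    relaxation_time_s: float = 0.3
    noise_sd_um: float = 0.0
    drift_rate_um_per_s: float = 0.0
    smoothing: str = "linear"  # "linear" | "cosine"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.amplitude_um < 0:
            raise ValueError("amplitude_um must be non-negative")
        if self.bpm <= 0:
            raise ValueError("bpm must be positive")
        period = 60.0 / self.bpm
        if self.contraction_time_s + self.relaxation_time_s >= period:
            raise ValueError(
                "contraction_time_s + relaxation_time_s must be shorter than "
                f"the beat period {period:.3f} s"
            )


@dataclass(frozen=True)
class TrueBeat:
    onset_idx: int
    peak_idx: int
    end_idx: int
    amplitude_um: float
    max_rise_slope_um_s: float
    max_fall_slope_um_s: float


TRUE_BEAT_FIELDS = (
    "onset_idx",
    "peak_idx",
    "end_idx",
    "amplitude_um",
    "max_rise_slope_um_s",
    "max_fall_slope_um_s",
)


@dataclass
class WaveformTruth:
    beats: list[TrueBeat]
    clean_um: np.ndarray  # waveform before noise/drift
    amplitude_um: float
    bpm: float


def make_waveform(
    spec: WaveformSpec, fps: float, duration_s: float
) -> tuple[np.ndarray, WaveformTruth]:
    """Sample the waveform at ``fps`` for ``duration_s`` seconds.

    Returns the (noise- and drift-contaminated) displacement in µm and the
    ground truth: the clean waveform plus per-beat onset/peak/end sample
    indices, amplitude and the analytic extreme phase slopes
    (±amplitude/phase-time for linear smoothing, ×π/2 for cosine).
    """
    n = int(round(fps * duration_s))
    t = np.arange(n) / fps
    period = 60.0 / spec.bpm
    phase = np.mod(t, period)
    a, ct, rt = spec.amplitude_um, spec.contraction_time_s, spec.relaxation_time_s
    clean = np.zeros(n)
    rise = phase < ct
    fall = (phase >= ct) & (phase < ct + rt)
    if spec.smoothing == "cosine":
        clean[rise] = 0.5 * a * (1 - np.cos(np.pi * phase[rise] / ct))
        clean[fall] = 0.5 * a * (1 + np.cos(np.pi * (phase[fall] - ct) / rt))
        slope_factor = np.pi / 2.0
    elif spec.smoothing == "linear":
        clean[rise] = a * phase[rise] / ct
        clean[fall] = a * (1 - (phase[fall] - ct) / rt)
        slope_factor = 1.0
    else:
        raise ValueError("smoothing must be 'linear' or 'cosine'")
    beats: list[TrueBeat] = []
    if a > 0:
        k = 0
        while True:
            start = k * period
            peak = start + ct
            if peak >= duration_s:
                break
            beats.append(
                TrueBeat(
                    onset_idx=int(round(start * fps)),
                    peak_idx=min(int(round(peak * fps)), n - 1),
                    end_idx=min(int(round((start + ct + rt) * fps)), n - 1),
                    amplitude_um=a,
                    max_rise_slope_um_s=slope_factor * a / ct,
                    max_fall_slope_um_s=slope_factor * a / rt,
                )
            )
            k += 1
    rng = np.random.default_rng(spec.seed)
    out = clean + spec.drift_rate_um_per_s * t
    if spec.noise_sd_um > 0:
        out = out + rng.normal(0.0, spec.noise_sd_um, size=n)
    truth = WaveformTruth(
        beats=beats, clean_um=clean, amplitude_um=a, bpm=spec.bpm
    )
    return out, truth


# ---------------------------------------------------------------------------
# Scene rendering


@dataclass(frozen=True)
class SceneSpec:
    """Bright-field scene: two dark vertical posts in a bright well.

    The left post is the tracked one; its right (well-centre-facing) edge
    moves with the waveform.  ``psf_sigma_px`` applies a Gaussian optical
    blur across the scanline, as real bright-field optics band-limit the
    edge.  Intensities are on a 16-bit scale.
    """

    width_px: int = 220
    height_px: int = 60
    pixel_size_um: float = 0.2
    post_width_px: int = 25
    post_height_px: int = 48
    post_separation_px: int = 120  # static gap between resting inner edges
    background_level: float = 3000.0
    post_level: float = 600.0
    pixel_noise_sd: float = 0.0
    psf_sigma_px: float = 0.8
    fps: float = 100.0
    duration_s: float = 20.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.post_height_px > self.height_px:
            raise ValueError("posts must fit inside the frame vertically")
        n = self.fps * self.duration_s
        if abs(n - round(n)) > 1e-9:
            raise ValueError("fps * duration_s must be an integer frame count")

    @property
    def n_frames(self) -> int:
        return int(round(self.fps * self.duration_s))

    @property
    def left_post_x0(self) -> float:
        return 10.0  # left edge of the tracked post, px

    @property
    def left_edge_rest_px(self) -> float:
        """Resting position of the tracked (inner) edge, px."""
        return self.left_post_x0 + self.post_width_px

    @property
    def right_post_x0(self) -> float:
        return self.left_edge_rest_px + self.post_separation_px


def _interval_coverage(width: int, lo: float, hi: float) -> np.ndarray:
    """Per-column overlap of the interval [lo, hi) with pixel [j-0.5, j+0.5)."""
    j = np.arange(width, dtype=float)
    return np.clip(np.minimum(j + 0.5, hi) - np.maximum(j - 0.5, lo), 0.0, 1.0)


def _scanline_profiles(scene: SceneSpec, edge_px: np.ndarray) -> np.ndarray:
    """Noise-free intensity profiles, one row per time point."""
    w = scene.width_px
    j = np.arange(w, dtype=float)
    # tracked post: [x0, edge(t)); coverage varies per frame
    lo = scene.left_post_x0
    cov_left = np.clip(
        np.minimum(j[None, :] + 0.5, edge_px[:, None]) - np.maximum(j[None, :] - 0.5, lo),
        0.0,
        1.0,
    )
    cov_right = _interval_coverage(
        w, scene.right_post_x0, scene.right_post_x0 + scene.post_width_px
    )
    cov = cov_left + cov_right[None, :]
    profiles = scene.background_level + (scene.post_level - scene.background_level) * cov
    if scene.psf_sigma_px > 0:
        profiles = gaussian_filter1d(profiles, scene.psf_sigma_px, axis=1)
    return profiles


def _edge_positions(scene: SceneSpec, waveform_um: np.ndarray) -> np.ndarray:
    edge = scene.left_edge_rest_px + np.asarray(waveform_um) / scene.pixel_size_um
    if np.any(edge >= scene.right_post_x0 - 2) or np.any(edge <= scene.left_post_x0 + 1):
        raise ValueError("waveform drives the tracked edge out of its gap")
    return edge


def render_kymograph(
    scene: SceneSpec, waveform_um: np.ndarray
) -> tuple[Kymograph, dict]:
    """Render the centre-row kymograph directly (fast path).

    Equivalent to rendering the full video and stacking its centre row,
    since the scene is vertically uniform across the posts.
    """
    if len(waveform_um) != scene.n_frames:
        raise ValueError("waveform length must equal fps * duration_s")
    edge = _edge_positions(scene, waveform_um)
    profiles = _scanline_profiles(scene, edge)
    if scene.pixel_noise_sd > 0:
        rng = np.random.default_rng(scene.seed)
        profiles = profiles + rng.normal(0, scene.pixel_noise_sd, profiles.shape)
    kym = Kymograph(
        matrix=profiles,
        fps=scene.fps,
        pixel_size_um=scene.pixel_size_um,
        scanline_row=scene.height_px // 2,
    )
    truth = {"edge_px": edge, "rest_edge_px": scene.left_edge_rest_px}
    return kym, truth


def render_video(
    scene: SceneSpec, waveform_um: np.ndarray
) -> tuple[VideoStream, dict]:
    """Render the full frame stack with per-frame ground truth.

    Frame t shows both posts with the tracked edge at its ground-truth
    sub-pixel position; pixel noise is seeded Gaussian.  Ground truth
    includes the true edge column per frame and both post centroids.
    """
    if len(waveform_um) != scene.n_frames:
        raise ValueError("waveform length must equal fps * duration_s")
    edge = _edge_positions(scene, waveform_um)
    profiles = _scanline_profiles(scene, edge)
    h, w, n = scene.height_px, scene.width_px, scene.n_frames
    top = (h - scene.post_height_px) // 2
    bottom = top + scene.post_height_px
    frames = np.full((n, h, w), scene.background_level, dtype=float)
    frames[:, top:bottom, :] = profiles[:, None, :]
    if scene.pixel_noise_sd > 0:
        rng = np.random.default_rng(scene.seed)
        frames = frames + rng.normal(0, scene.pixel_noise_sd, frames.shape)
    frames = np.clip(frames, 0, 65535)
    video = VideoStream(
        frames=frames.astype(np.uint16),
        fps=scene.fps,
        pixel_size_um=scene.pixel_size_um,
    )
    cy = 0.5 * (top + bottom - 1)
    truth = {
        "edge_px": edge,
        "rest_edge_px": scene.left_edge_rest_px,
        "scanline_row": h // 2,
        "left_post_centroid_xy": (
            0.5 * (scene.left_post_x0 + edge[0]) - 0.5,
            cy,
        ),
        "right_post_centroid_xy": (
            scene.right_post_x0 + 0.5 * scene.post_width_px - 0.5,
            cy,
        ),
    }
    return video, truth


def make_well_image(
    scene: SceneSpec, noise_sd: float | None = None, seed: int | None = None
) -> tuple[WellImage, dict]:
    """Single baseline frame (no contraction) for post-detection tests."""
    static = SceneSpec(
        **{
            **scene.__dict__,
            "duration_s": 1.0 / scene.fps,
            "pixel_noise_sd": scene.pixel_noise_sd if noise_sd is None else noise_sd,
            "seed": scene.seed if seed is None else seed,
        }
    )
    video, truth = render_video(static, np.zeros(1))
    image = WellImage(
        pixels=video.frames[0], pixel_size_um=scene.pixel_size_um
    )
    return image, truth


# ---------------------------------------------------------------------------
# CCD response surfaces


def default_ccd_factors() -> list[FactorSpec]:
    """The three tissue-formulation factors with their standard levels."""
    return [
        FactorSpec("cardiomyocyte_pct", 50.0, 70.0, 90.0),
        FactorSpec("collagen_mg_ml", 1.8, 2.0, 2.2),
        FactorSpec("total_cells", 40_000.0, 70_000.0, 100_000.0),
    ]


def paper_like_ccd_beta() -> pd.Series:
    """Preset coefficients (coded units, response = deflection in µm).

    Effect structure: a strong positive cardiomyocyte-fraction effect (the
    dominant linear term, optimum on the +1 face, i.e. 90% CM), a concave
    collagen effect with its ridge slightly above the mid level
    (2.03 mg/mL), and a concave cell-count effect peaking a little above
    the mid level (75,400 cells).  No interactions.
    """
    factors = default_ccd_factors()
    names = quadratic_term_names(factors)
    beta = pd.Series(0.0, index=names)
    beta["intercept"] = 5.5
    beta["cardiomyocyte_pct"] = 3.0
    beta["collagen_mg_ml"] = 0.6
    beta["total_cells"] = 0.36
    beta["cardiomyocyte_pct^2"] = -0.5
    beta["collagen_mg_ml^2"] = -2.0
    beta["total_cells^2"] = -1.0
    return beta


def make_ccd_responses(
    design: CCDDesign,
    coefficients: pd.Series | np.ndarray | None = None,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> tuple[np.ndarray, dict]:
    """Draw responses y = X·beta + N(0, noise_sd²) on a design.

    Returns the response vector and ground truth (true beta and term
    names).  ``coefficients=None`` uses the preset surface.
    """
    beta = paper_like_ccd_beta() if coefficients is None else coefficients
    beta_arr = np.asarray(beta, dtype=float)
    X = quadratic_design_matrix(design.coded)
    if beta_arr.shape != (X.shape[1],):
        raise ValueError(
            f"coefficient vector must have length {X.shape[1]}, got {beta_arr.shape}"
        )
    y = X @ beta_arr
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        y = y + rng.normal(0.0, noise_sd, size=len(y))
    truth = {
        "beta": beta_arr,
        "term_names": quadratic_term_names(design.factors),
        "noise_sd": noise_sd,
    }
    return y, truth


# ---------------------------------------------------------------------------
# Dose-response tables

#: The standard five-dose screening panel, molar.
DEFAULT_DOSES_M = (1e-9, 1e-8, 1e-7, 1e-6, 1e-5)

#: Hill profiles qualitatively matching the reference inotropes: myosin
#: inhibition and L-type calcium block reduce amplitude; beta-adrenergic
#: stimulation increases it, saturating around the micromolar dose.
COMPOUND_PRESETS: dict[str, dict] = {
    "blebbistatin_like": {"emax": 0.85, "ec50": 2e-7, "hill": 1.2, "direction": -1},
    "isoproterenol_like": {"emax": 0.4, "ec50": 5e-8, "hill": 1.0, "direction": +1},
    "nifedipine_like": {"emax": 0.9, "ec50": 3e-7, "hill": 1.0, "direction": -1},
}


def hill_effect(dose_m: np.ndarray, emax: float, ec50: float, hill: float) -> np.ndarray:
    d = np.asarray(dose_m, dtype=float)
    return emax * d**hill / (d**hill + ec50**hill)


def make_dose_response(
    compound_profile: dict | str,
    doses_m: tuple[float, ...] = DEFAULT_DOSES_M,
    n_per_dose: int = 3,
    n_experiments: int = 3,
    vehicle_amplitude_um: float = 10.0,
    noise_sd_um: float = 0.5,
    seed: int = 0,
    compound_name: str | None = None,
) -> tuple[pd.DataFrame, dict]:
    """Simulate a drug-screen table with Hill-type amplitude scaling.

    Amplitude = vehicle_amplitude · (1 + direction · effect(dose)) with
    seeded Gaussian well-to-well noise; each experiment has ``n_per_dose``
    wells per dose plus the same number of vehicle wells.  Ground truth
    carries the noiseless relative-change curve.
    """
    if isinstance(compound_profile, str):
        compound_name = compound_name or compound_profile
        compound_profile = COMPOUND_PRESETS[compound_profile]
    compound_name = compound_name or "compound"
    doses = np.asarray(doses_m, dtype=float)
    if np.any(doses <= 0):
        raise ValueError("doses must be positive (vehicle rows are added separately)")
    effect = compound_profile["direction"] * hill_effect(
        doses, compound_profile["emax"], compound_profile["ec50"],
        compound_profile["hill"],
    )
    clean = vehicle_amplitude_um * (1.0 + effect)
    rng = np.random.default_rng(seed)
    rows = []
    widx = 0
    for exp in range(1, n_experiments + 1):
        for _ in range(n_per_dose):
            rows.append(
                {
                    "well": f"W{widx:03d}",
                    "compound": compound_name,
                    "dose_molar": "vehicle",
                    "amplitude_um": vehicle_amplitude_um
                    + rng.normal(0, noise_sd_um),
                    "experiment": f"exp{exp}",
                }
            )
            widx += 1
        for dose, mu in zip(doses, clean):
            for _ in range(n_per_dose):
                rows.append(
                    {
                        "well": f"W{widx:03d}",
                        "compound": compound_name,
                        "dose_molar": dose,
                        "amplitude_um": mu + rng.normal(0, noise_sd_um),
                        "experiment": f"exp{exp}",
                    }
                )
                widx += 1
    table = pd.DataFrame(rows)
    truth = {
        "doses_m": doses,
        "clean_amplitude_um": clean,
        "clean_relative_change": effect,
        "vehicle_amplitude_um": vehicle_amplitude_um,
    }
    return table, truth
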