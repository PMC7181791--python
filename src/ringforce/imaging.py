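"""Well-image and video handling: post detection, focus scoring, kymographs.

Coordinate convention (used package-wide): images are row-major with the
origin at the top-left; row = y, column = x; indices are 0-based; bounding
boxes are half-open ``(row0, col0, row1, col1)``.

Posts are imaged under transmitted light and appear as dark, vertically
elongated components on a bright background.  A whole-well low-magnification
image locates the posts; a high-frame-rate video of a small ROI around one
post tip is then reduced to a kymograph by taking one scanline per frame.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
import tifffile
from scipy import ndimage
from skimage.filters import threshold_otsu
from skimage.measure import label, regionprops

__all__ = [
    "WellImage",
    "VideoStream",
    "PostLocation",
    "Kymograph",
    "PostDetectionError",
    "detect_posts",
    "focus_score",
    "extract_roi",
    "build_kymograph",
    "read_video_tiff",
    "write_video_tiff",
    "read_kymograph",
    "write_kymograph",
]


class PostDetectionError(RuntimeError):
    """Fewer candidate posts than expected; carries the candidates found."""

    def __init__(self, message: str, candidates: list["PostLocation"]):
        super().__init__(message)
        self.candidates = candidates


@dataclass
class WellImage:
    """Single grayscale frame of one well with its pixel calibration."""

    pixels: np.ndarray
    pixel_size_um: float
    bit_depth: int = 16

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim != 2 or self.pixels.size == 0:
            raise ValueError("pixels must be a non-empty 2-D array")
        if not self.pixel_size_um > 0:
            raise ValueError("pixel_size_um must be positive")


@dataclass
class VideoStream:
    """Ordered stack of equally shaped frames with acquisition metadata."""

    frames: np.ndarray  # (n_frames, height, width)
    fps: float
    pixel_size_um: float

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames)
        if self.frames.ndim != 3 or self.frames.shape[0] == 0:
            raise ValueError("frames must be a (time, row, col) stack")
        if not self.fps > 0:
            raise ValueError("fps must be positive")
        if not self.pixel_size_um > 0:
            raise ValueError("pixel_size_um must be positive")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def duration_s(self) -> float:
        return self.n_frames / self.fps


@dataclass(frozen=True)
class PostLocation:
    """Centroid and bounding box of one detected post."""

    x: float  # column, px
    y: float  # row, px
    side: str  # "left" | "right"
    bbox: tuple[int, int, int, int]  # (row0, col0, row1, col1), half-open


@dataclass
class Kymograph:
    """Time × position intensity matrix: one scanline per video frame."""

    matrix: np.ndarray  # (n_frames, width)
    fps: float
    pixel_size_um: float
    scanline_row: int

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix)
        if self.matrix.ndim != 2:
            raise ValueError("kymograph matrix must be 2-D (time x position)")

    @property
    def n_frames(self) -> int:
        return self.matrix.shape[0]

    @property
    def duration_s(self) -> float:
        return self.n_frames / self.fps


def detect_posts(
    image: WellImage,
    expected_posts: int = 2,
    dark_posts: bool = True,
    min_area_px: int = 20,
    max_area_frac: float = 0.25,
    min_aspect: float = 1.5,
) -> list[PostLocation]:
    """Locate cantilever posts in a low-magnification well image.

    Global Otsu threshold → connected components → filter by area range and
    vertical aspect ratio (height/width ≥ ``min_aspect``; posts are upright).
    Candidates are sorted by centroid x; ties break toward the leftmost.
    Deterministic for a fixed image.

    Raises
    ------
    PostDetectionError
        If fewer filtered components than ``expected_posts`` are found; the
        exception carries the candidates that passed the filters.
    """
    if expected_posts not in (1, 2):
        raise ValueError("expected_posts must be 1 or 2")
    img = np.asarray(image.pixels, dtype=float)
    if np.ptp(img) == 0:
        raise PostDetectionError("image has no contrast; found 0 candidates", [])
    thresh = threshold_otsu(img)
    foreground = img < thresh if dark_posts else img > thresh
    labels = label(foreground)
    candidates: list[PostLocation] = []
    for region in regionprops(labels):
        r0, c0, r1, c1 = region.bbox
        h, w = r1 - r0, c1 - c0
        if region.area < min_area_px or region.area > max_area_frac * img.size:
            continue
        if w == 0 or h / w < min_aspect:
            continue
        cy, cx = region.centroid
        candidates.append(PostLocation(x=cx, y=cy, side="", bbox=(r0, c0, r1, c1)))
    candidates.sort(key=lambda p: p.x)
    if len(candidates) < expected_posts:
        raise PostDetectionError(
            f"expected {expected_posts} posts, found {len(candidates)} candidates",
            candidates,
        )
    if expected_posts == 1:
        chosen = [candidates[0]]
        sides = ["left"]
    else:
        chosen = [candidates[0], candidates[-1]]
        sides = ["left", "right"]
    return [replace(p, side=s) for p, s in zip(chosen, sides)]


def focus_score(image: WellImage | np.ndarray) -> float:
    """Sharpness score: variance of the discrete Laplacian.

    Higher is sharper; a constant image scores 0.  The argmax over a focal
    stack selects the best-focused slice (contrast-maximising autofocus as a
    pure function — no hardware control).
    """
    img = image.pixels if isinstance(image, WellImage) else image
    lap = ndimage.laplace(np.asarray(img, dtype=float))
    return float(lap.var())


def extract_roi(
    video: VideoStream,
    post: PostLocation,
    half_width_px: int,
    half_height_px: int,
) -> VideoStream:
    """Crop every frame to a window centred on the post, clipped to bounds."""
    n, h, w = video.frames.shape
    cy, cx = int(round(post.y)), int(round(post.x))
    r0, r1 = max(0, cy - half_height_px), min(h, cy + half_height_px)
    c0, c1 = max(0, cx - half_width_px), min(w, cx + half_width_px)
    if r1 <= r0 or c1 <= c0:
        raise ValueError("ROI is empty after clipping to frame bounds")
    return VideoStream(
        frames=video.frames[:, r0:r1, c0:c1].copy(),
        fps=video.fps,
        pixel_size_um=video.pixel_size_um,
    )


def build_kymograph(video: VideoStream, scanline_row: int | str = "center") -> Kymograph:
    """Stack one pixel row of every frame into a time × position matrix.

    ``scanline_row="center"`` selects ``floor(height / 2)``.  Row ``t`` of
    the kymograph is pixel row ``scanline_row`` of frame ``t``.
    """
    h = video.frames.shape[1]
    row = h // 2 if scanline_row == "center" else int(scanline_row)
    if not 0 <= row < h:
        raise ValueError(f"scanline_row {row} outside frame height {h}")
    return Kymograph(
        matrix=video.frames[:, row, :].copy(),
        fps=video.fps,
        pixel_size_um=video.pixel_size_um,
        scanline_row=row,
    )


# ---------------------------------------------------------------------------
# I/O: multi-page TIFF stacks with a JSON sidecar for acquisition metadata.


def _sidecar(path: Path) -> Path:
    return path.with_suffix(".json")


def write_video_tiff(video: VideoStream, path: str | Path) -> None:
    path = Path(path)
    tifffile.imwrite(path, video.frames)
    _sidecar(path).write_text(
        json.dumps({"fps": video.fps, "pixel_size_um": video.pixel_size_um})
    )


def read_video_tiff(
    path: str | Path,
    fps: float | None = None,
    pixel_size_um: float | None = None,
) -> VideoStream:
    """Read a multi-page TIFF; metadata from the JSON sidecar unless given."""
    path = Path(path)
    frames = tifffile.imread(path)
    if frames.ndim == 2:
        frames = frames[None]
    meta = {}
    if _sidecar(path).exists():
        meta = json.loads(_sidecar(path).read_text())
    fps = fps if fps is not None else meta.get("fps")
    pixel_size_um = (
        pixel_size_um if pixel_size_um is not None else meta.get("pixel_size_um")
    )
    if fps is None or pixel_size_um is None:
        raise ValueError("fps and pixel_size_um must come from sidecar JSON or args")
    return VideoStream(frames=frames, fps=fps, pixel_size_um=pixel_size_um)


def write_kymograph(kym: Kymograph, path: str | Path) -> None:
    path = Path(path)
    mat = kym.matrix
    if mat.dtype != np.uint16:
        lo, hi = float(mat.min()), float(mat.max())
        scale = 65535.0 / (hi - lo) if hi > lo else 1.0
        mat = ((mat - lo) * scale).astype(np.uint16)
    tifffile.imwrite(path, mat)
    _sidecar(path).write_text(
        json.dumps(
            {
                "fps": kym.fps,
                "pixel_size_um": kym.pixel_size_um,
                "scanline_row": kym.scanline_row,
            }
        )
    )


def read_kymograph(path: str | Path) -> Kymograph:
    path = Path(path)
    meta = json.loads(_sidecar(path).read_text())
    return Kymograph(
        matrix=tifffile.imread(path),
        fps=meta["fps"],
        pixel_size_um=meta["pixel_size_um"],
        scanline_row=meta["scanline_row"],
    )
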