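"""TIRF image analysis: MT mass, plus-end spots, kymographs, counting.

Mirrors the measurement chain used on real single-molecule nucleation
movies:

* **MT mass** — per frame, an Otsu threshold removes background, the mean
  of the masked frame is recorded, and the first frame's mean is
  subtracted; traces are optionally normalized to a buffer control at a
  reference time.  Because the mask zeroes sub-threshold pixels but the
  mean runs over the whole frame, the trace is proportional to total
  polymer signal.
* **Plus-end spots** — crop, 3x3 mean smooth, Yen threshold, Sobel edge
  filter on the binary mask, connected-component count with a size
  filter.  Spot counts proxy microtubule number in crowded fields.
* **Kymographs** — space-time matrices sampled along a microtubule's
  axis; the number of growing edges classifies nucleation (one growing
  edge = templated, anchored minus end; two = spontaneous), the
  growing-edge slope gives the growth speed, and the largest extent the
  maximum length.
* **Count trajectories** — automated birth detection: a connected
  component that does not touch the (dilated) previous frame's mask is a
  new microtubule; cumulative births form the N(t) curve that the kinetic
  model is fitted to.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import NamedTuple, Sequence

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage import filters, measure, morphology

from .io import MovieStack
from .kinetics import CountTrajectory

__all__ = [
    "MassTrace",
    "SpotCount",
    "KymographRecord",
    "CountResult",
    "measure_mass_trace",
    "count_plus_end_spots",
    "extract_kymograph",
    "classify_nucleation",
    "growth_speed_and_length",
    "count_trajectory_from_movie",
]

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# MT mass
# ---------------------------------------------------------------------------


@dataclass
class MassTrace:
    """Background-corrected total-MT-signal trace."""

    times: np.ndarray
    raw_mean: np.ndarray
    corrected: np.ndarray
    normalized: np.ndarray | None = None

    def value_at(self, time_s: float, which: str = "corrected") -> float:
        """Trace value at the frame nearest to ``time_s``."""
        idx = int(np.argmin(np.abs(self.times - time_s)))
        arr = getattr(self, which)
        if arr is None:
            raise ValueError(f"trace has no {which!r} values")
        return float(arr[idx])

    def to_frame(self) -> pd.DataFrame:
        out = pd.DataFrame(
            {"time_s": self.times, "raw_mean": self.raw_mean,
             "corrected": self.corrected}
        )
        if self.normalized is not None:
            out["normalized"] = self.normalized
        return out


def _masked_mean(frame: np.ndarray) -> float:
    """Mean over the full frame after zeroing sub-Otsu pixels.

    A constant frame has no Otsu threshold; it carries no signal above
    background, so 0 is recorded.
    """
    frame = np.asarray(frame, dtype=float)
    if frame.max() == frame.min():
        logger.debug("constant frame: threshold undefined, recording 0")
        return 0.0
    thr = filters.threshold_otsu(frame)
    return float(np.where(frame > thr, frame, 0.0).mean())


def measure_mass_trace(
    movie: MovieStack,
    control: MassTrace | None = None,
    reference_time: float = 300.0,
) -> MassTrace:
    """Per-frame MT mass: Otsu-masked mean, first-frame subtracted.

    If a ``control`` trace is supplied the corrected trace is divided by
    the control's corrected value at ``reference_time``.
    """
    if movie.n_frames < 2:
        raise ValueError("need at least 2 frames for a mass trace")
    raw = np.array([_masked_mean(f) for f in movie.data])
    corrected = raw - raw[0]
    normalized = None
    if control is not None:
        ref = control.value_at(reference_time, "corrected")
        if ref == 0:
            raise ValueError("control trace is 0 at the reference time")
        normalized = corrected / ref
    return MassTrace(
        times=movie.frame_times, raw_mean=raw, corrected=corrected,
        normalized=normalized,
    )


# ---------------------------------------------------------------------------
# Plus-end spot counting
# ---------------------------------------------------------------------------


class SpotCount(NamedTuple):
    frame_index: int
    window: tuple[int, int, int, int]  # (x0, y0, width, height), px
    count: int


def count_plus_end_spots(
    frame: np.ndarray,
    pixel_size_um: float,
    window_um: tuple[float, float] | None = (50.0, 50.0),
    origin_px: tuple[int, int] = (0, 0),
    min_size_px: int = 2,
    max_size_px: int = 200,
    frame_index: int = 0,
) -> SpotCount:
    """Count plus-end marker spots in a cropped window.

    Crop -> 3x3 mean smooth -> Yen threshold -> Sobel edge filter on the
    binary mask -> connected components within the size filter.  Two spots
    closer than the blur scale merge into one component and are counted
    once.  A blank (constant) crop counts 0.
    """
    frame = np.asarray(frame, dtype=float)
    x0, y0 = origin_px
    if window_um is None:
        crop = frame[y0:, x0:]
    else:
        wx = int(round(window_um[0] / pixel_size_um))
        wy = int(round(window_um[1] / pixel_size_um))
        if y0 + wy > frame.shape[0] or x0 + wx > frame.shape[1]:
            wx = min(wx, frame.shape[1] - x0)
            wy = min(wy, frame.shape[0] - y0)
            logger.debug("window clipped to frame bounds: %dx%d px", wx, wy)
        crop = frame[y0 : y0 + wy, x0 : x0 + wx]
    window = (x0, y0, crop.shape[1], crop.shape[0])
    if crop.size == 0 or crop.max() == crop.min():
        return SpotCount(frame_index, window, 0)
    smoothed = ndimage.uniform_filter(crop, size=3)
    if smoothed.max() == smoothed.min():
        return SpotCount(frame_index, window, 0)
    mask = smoothed > filters.threshold_yen(smoothed)
    if not mask.any() or mask.all():
        return SpotCount(frame_index, window, 0)
    edges = filters.sobel(mask.astype(float)) > 0
    labels = measure.label(edges)
    count = sum(
        1
        for region in measure.regionprops(labels)
        if min_size_px <= region.area <= max_size_px
    )
    return SpotCount(frame_index, window, count)


# ---------------------------------------------------------------------------
# Kymographs
# ---------------------------------------------------------------------------


@dataclass
class KymographRecord:
    """Space-time intensity matrix along one microtubule axis."""

    line: np.ndarray  # (n_points, 2) polyline, (x, y) px
    matrix: np.ndarray  # intensity, shape (n_positions, n_frames)
    pixel_size_um: float
    frame_interval_s: float
    edges: dict[str, np.ndarray] = field(default_factory=dict)
    n_growing_edges: int | None = None
    classification: str | None = None  # templated | spontaneous | indeterminate
    growth_speed_um_min: float | None = None
    max_length_um: float | None = None
    censored: bool = False

    @property
    def n_positions(self) -> int:
        return self.matrix.shape[0]

    @property
    def n_frames(self) -> int:
        return self.matrix.shape[1]


def extract_kymograph(
    movie: MovieStack, line: Sequence[Sequence[float]], width_px: int = 3
) -> KymographRecord:
    """Sample the movie along a polyline, max-projected across its width.

    Positions are spaced 1 px along the polyline's arc length; at each
    position the intensity is the maximum over ``width_px`` samples taken
    perpendicular to the local direction.
    """
    line = np.asarray(line, dtype=float)
    if line.ndim != 2 or line.shape[0] < 2 or line.shape[1] != 2:
        raise ValueError("line must be a polyline of >= 2 (x, y) points")
    seg_vecs = np.diff(line, axis=0)
    seg_lens = np.hypot(seg_vecs[:, 0], seg_vecs[:, 1])
    total = seg_lens.sum()
    if total == 0:
        raise ValueError("degenerate (zero-length) line")
    h, w = movie.data.shape[1:]
    if (line[:, 0].min() < 0 or line[:, 0].max() > w - 1
            or line[:, 1].min() < 0 or line[:, 1].max() > h - 1):
        raise ValueError("line extends outside the frame bounds")

    n_pos = int(math.floor(total)) + 1
    arc = np.linspace(0.0, total, n_pos)
    cum = np.concatenate([[0.0], np.cumsum(seg_lens)])
    seg_idx = np.clip(np.searchsorted(cum, arc, side="right") - 1, 0,
                      len(seg_lens) - 1)
    local = (arc - cum[seg_idx]) / np.where(seg_lens[seg_idx] == 0, 1,
                                            seg_lens[seg_idx])
    pts = line[seg_idx] + seg_vecs[seg_idx] * local[:, None]
    tangents = seg_vecs[seg_idx] / np.where(seg_lens[seg_idx] == 0, 1,
                                            seg_lens[seg_idx])[:, None]
    normals = np.column_stack([-tangents[:, 1], tangents[:, 0]])

    offsets = np.arange(width_px) - (width_px - 1) / 2.0
    # sample coordinates: (n_pos, width) each for x and y
    xs = pts[:, 0][:, None] + normals[:, 0][:, None] * offsets[None, :]
    ys = pts[:, 1][:, None] + normals[:, 1][:, None] * offsets[None, :]
    coords = np.stack([ys.ravel(), xs.ravel()])

    matrix = np.empty((n_pos, movie.n_frames))
    for fi in range(movie.n_frames):
        sampled = ndimage.map_coordinates(
            movie.data[fi].astype(float), coords, order=1, mode="nearest"
        ).reshape(n_pos, width_px)
        matrix[:, fi] = sampled.max(axis=1)
    return KymographRecord(
        line=line,
        matrix=matrix,
        pixel_size_um=movie.pixel_size_um,
        frame_interval_s=movie.frame_interval_s,
    )


def _edge_traces(kymo: KymographRecord) -> tuple[np.ndarray, np.ndarray]:
    """Per-frame supra-threshold extent: (lower, upper) positions, NaN where
    no signal."""
    m = kymo.matrix
    if m.max() == m.min():
        return (np.full(kymo.n_frames, np.nan),) * 2
    # half-maximum threshold between robust background and signal levels:
    # a step edge blurred by a symmetric PSF crosses half-max exactly at
    # the true edge, so extents are unbiased by the blur width
    lo, hi = np.percentile(m, [1.0, 99.0])
    if hi == lo:
        lo, hi = m.min(), m.max()
    thr = lo + 0.5 * (hi - lo)
    mask = m > thr
    lower = np.full(kymo.n_frames, np.nan)
    upper = np.full(kymo.n_frames, np.nan)
    for fi in range(kymo.n_frames):
        rows = np.flatnonzero(mask[:, fi])
        if rows.size:
            lower[fi] = rows[0]
            upper[fi] = rows[-1]
    return lower, upper


def _is_growing(trace: np.ndarray, direction: int, min_disp_px: float = 2.0) -> bool:
    """An edge grows if it moves monotonically >= min_disp_px in its
    outward direction with a positive fitted slope magnitude."""
    valid = np.flatnonzero(np.isfinite(trace))
    if valid.size < 3:
        return False
    disp = (trace[valid[-1]] - trace[valid[0]]) * direction
    if disp < min_disp_px:
        return False
    slope = np.polyfit(valid, trace[valid], 1)[0] * direction
    return slope > 0


def classify_nucleation(kymo: KymographRecord) -> str:
    """Templated vs spontaneous nucleation from growing-edge count.

    One growing edge (the other boundary stationary) means an anchored,
    template-nucleated microtubule; two growing edges mean spontaneous
    bidirectional growth.  With no growing edge the record is
    ``"indeterminate"`` and excluded from rate counts.
    """
    lower, upper = _edge_traces(kymo)
    kymo.edges = {"lower": lower, "upper": upper}
    growing = int(_is_growing(upper, +1)) + int(_is_growing(lower, -1))
    kymo.n_growing_edges = growing
    if growing == 1:
        kymo.classification = "templated"
    elif growing == 2:
        kymo.classification = "spontaneous"
    else:
        logger.info("kymograph has no growing edge; marking indeterminate")
        kymo.classification = "indeterminate"
    return kymo.classification


def growth_speed_and_length(
    kymo: KymographRecord,
    pixel_size_um: float | None = None,
    frame_interval_s: float | None = None,
) -> tuple[float, float]:
    """Growth speed (µm/min) and maximum length (µm) from a kymograph.

    Speed is the least-squares slope of the growing-edge position vs
    time; if both edges grow the faster one (the plus end) is used.
    Maximum length is the largest supra-threshold extent observed.  The
    record is flagged censored when the growing edge reaches the end of
    the sampled line.
    """
    px = pixel_size_um if pixel_size_um is not None else kymo.pixel_size_um
    dt = frame_interval_s if frame_interval_s is not None else kymo.frame_interval_s
    if not kymo.edges:
        classify_nucleation(kymo)
    lower, upper = kymo.edges["lower"], kymo.edges["upper"]
    valid = np.flatnonzero(np.isfinite(upper))
    if valid.size < 3:
        raise ValueError("need >= 3 frames of detected signal")

    slopes = []
    if _is_growing(upper, +1):
        slopes.append(np.polyfit(valid * dt, upper[valid], 1)[0])
        if np.any(upper[valid] >= kymo.n_positions - 1):
            kymo.censored = True
    if _is_growing(lower, -1):
        slopes.append(-np.polyfit(valid * dt, lower[valid], 1)[0])
        if np.any(lower[valid] <= 0):
            kymo.censored = True
    speed_px_s = max(slopes) if slopes else 0.0
    speed = max(0.0, speed_px_s) * px * 60.0
    max_len = float(np.nanmax(upper - lower)) * px
    kymo.growth_speed_um_min = speed
    kymo.max_length_um = max_len
    return speed, max_len


# ---------------------------------------------------------------------------
# Automated count trajectories
# ---------------------------------------------------------------------------


class CountResult(NamedTuple):
    trajectory: CountTrajectory
    origins: pd.DataFrame  # columns: id, birth_time_s, x_px, y_px


def count_trajectory_from_movie(
    movie: MovieStack,
    window_um: tuple[float, float] | None = (40.0, 40.0),
    max_time_s: float = 150.0,
    min_area_px: int = 3,
    dilation_px: int = 5,
) -> CountResult:
    """Cumulative nucleation events vs time by automated birth detection.

    Frames up to ``max_time_s`` are thresholded inside the analysis
    window; a labelled component whose pixels do not touch the union of
    all previously seen signal (dilated by ``dilation_px``) is a new
    microtubule.  The cumulative "seen" mask exploits that microtubules
    only grow in this assay: flickering segments of an already-counted
    microtubule can never register as fresh births.  The movie must cover
    the analysis window in time unless ``max_time_s`` is overridden to
    something shorter.
    """
    if movie.duration_s < max_time_s:
        raise ValueError(
            f"movie covers only {movie.duration_s:.0f} s < {max_time_s:.0f} s "
            "analysis window; pass a shorter max_time_s to override"
        )
    if window_um is None:
        crop_slice = (slice(None), slice(None))
    else:
        wx = min(int(round(window_um[0] / movie.pixel_size_um)),
                 movie.data.shape[2])
        wy = min(int(round(window_um[1] / movie.pixel_size_um)),
                 movie.data.shape[1])
        crop_slice = (slice(0, wy), slice(0, wx))

    sel = movie.frame_times <= max_time_s + 1e-9
    times = movie.frame_times[sel]
    counts = np.zeros(times.size, dtype=float)
    seen_mask = None
    footprint = morphology.disk(dilation_px)
    origins: list[dict] = []
    total = 0
    for fi, t in enumerate(times):
        frame = movie.data[fi][crop_slice].astype(float)
        # light pre-smoothing suppresses shot noise before thresholding; on
        # a signal-free noisy frame Otsu splits the noise histogram and
        # floods the mask, so a mask covering most of the window is treated
        # as "no signal detected" rather than as one giant microtubule
        smooth = ndimage.gaussian_filter(frame, 1.0)
        if smooth.max() == smooth.min():
            mask = np.zeros(frame.shape, dtype=bool)
        else:
            # Otsu alone splits the background mode on signal-poor noisy
            # frames; floor the threshold at a robust background ceiling
            # (median + 5 sigma via MAD) so noise specks never register
            med = np.median(smooth)
            mad_sigma = 1.4826 * np.median(np.abs(smooth - med))
            thr = max(filters.threshold_otsu(smooth), med + 5.0 * mad_sigma)
            mask = smooth > thr
        labels = measure.label(mask)
        # the size filter must apply to the mask itself, not only to the
        # birth test: a sub-threshold-size germ would otherwise poison the
        # next frame's "known" mask and its MT would never register
        areas = np.bincount(labels.ravel())
        areas[0] = 0
        mask = areas[labels] >= min_area_px
        labels = measure.label(mask)
        known = (
            ndimage.binary_dilation(seen_mask, footprint)
            if seen_mask is not None
            else np.zeros(frame.shape, dtype=bool)
        )
        for region in measure.regionprops(labels):
            component = labels == region.label
            if not (component & known).any():
                cy, cx = region.centroid
                origins.append(
                    {"id": total, "birth_time_s": float(t),
                     "x_px": float(cx), "y_px": float(cy)}
                )
                total += 1
        seen_mask = mask if seen_mask is None else (seen_mask | mask)
        counts[fi] = total
    traj = CountTrajectory(times, counts)
    return CountResult(
        trajectory=traj,
        origins=pd.DataFrame(origins,
                             columns=["id", "birth_time_s", "x_px", "y_px"]),
    )
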