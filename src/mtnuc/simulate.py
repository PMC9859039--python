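"""Synthetic TIRF movies of surface-templated microtubule nucleation.

The generator turns the discrete nucleation recursion into individual
microtubule tracks and renders them as diffraction-blurred, noisy image
stacks with exact ground truth, so the image pipeline can be validated
without any real microscopy data.

Model of the field of view:

* New microtubules appear according to the integerized recursion count —
  fractional increments accumulate and a whole track is spawned each time
  the running count crosses an integer (floor-with-carry).
* Each track nucleates at a uniformly random sub-pixel position with one
  of ``n_orientations`` equally spaced orientations (multiples of
  360°/n starting at 0°).
* Templated (anchored) tracks keep their minus end fixed at the
  nucleation site and elongate their plus end at a constant speed;
  spontaneous tracks additionally advance their minus end in the opposite
  direction at ``minus_speed_fraction`` of the plus-end speed, giving the
  bidirectional growth that distinguishes them in kymographs.
* Rendering integrates a constant line density of fluorescence along each
  segment (clipped to the plane), convolves with a Gaussian approximation
  of the point-spread function, optionally adds a plus-end marker channel
  (a Gaussian comet per growing end), then applies a simple camera model:
  Poisson shot noise on the signal, Gaussian read noise, constant offset.

There are no catastrophes, no spontaneous background nucleation beyond
what the caller configures, and no photobleaching: the abstraction is a
drift-free, single-plane assay.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import NamedTuple, Sequence

import numpy as np
import pandas as pd
from scipy import ndimage

from .io import MovieStack
from .kinetics import CountTrajectory, NucleationKinetics, eq2_trajectory

__all__ = [
    "SimulationConfig",
    "RenderSettings",
    "MicrotubuleTrack",
    "TrackSegment",
    "GroundTruth",
    "simulate_tracks",
    "grow_tracks",
    "render_movie",
]


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for one simulated movie.

    Defaults mirror the assay being emulated: a 40x40 px plane, 1 s
    simulation step, one frame every 2 s for 300 s, eight discrete
    orientations, all nucleation templated (anchored minus ends).
    """

    kinetics: NucleationKinetics
    growth_speed: float = 1.5  # µm/min, constant for all MTs
    plane_size: tuple[int, int] = (40, 40)  # (width, height), px
    pixel_size: float = 0.16  # µm/px
    dt_sim: float = 1.0  # s
    frame_interval: float = 2.0  # s
    duration: float = 300.0  # s
    n_orientations: int = 8
    seed: int = 0
    templated_fraction: float = 1.0
    minus_speed_fraction: float = 0.5  # minus-end speed for unanchored MTs

    def __post_init__(self) -> None:
        if min(self.plane_size) < 8:
            raise ValueError("plane must be at least 8 px per side")
        if not self.growth_speed > 0:
            raise ValueError("growth_speed must be > 0")
        if self.frame_interval < self.dt_sim:
            raise ValueError("frame_interval must be >= dt_sim")
        if not 0.0 <= self.templated_fraction <= 1.0:
            raise ValueError("templated_fraction must be in [0, 1]")
        if self.n_orientations < 1:
            raise ValueError("n_orientations must be >= 1")

    @property
    def growth_speed_um_s(self) -> float:
        return self.growth_speed / 60.0


@dataclass(frozen=True)
class RenderSettings:
    """Optics and camera model for rendering.

    Intensities are arbitrary camera units; ``mt_intensity`` is signal per
    µm of polymer, ``comet_intensity`` total signal per plus-end marker.
    ``noise_model`` is one of ``"none"``, ``"gaussian"``,
    ``"poisson-gaussian"``.
    """

    psf_sigma: float = 0.2  # µm
    mt_intensity: float = 500.0  # a.u. per µm
    eb1_channel: bool = False
    comet_sigma: float = 0.2  # µm
    comet_intensity: float = 800.0  # a.u. per comet
    background: float = 100.0  # a.u.
    noise_model: str = "poisson-gaussian"
    read_noise_sigma: float = 2.0  # a.u.
    camera_offset: float = 100.0  # a.u.
    bit_depth: int = 16

    def __post_init__(self) -> None:
        if not self.psf_sigma > 0:
            raise ValueError("psf_sigma must be > 0")
        for name in ("mt_intensity", "comet_intensity", "background",
                     "camera_offset", "read_noise_sigma"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.noise_model not in ("none", "gaussian", "poisson-gaussian"):
            raise ValueError(f"unknown noise_model {self.noise_model!r}")


@dataclass(frozen=True)
class MicrotubuleTrack:
    """One simulated microtubule."""

    id: int
    birth_time: float  # s
    origin: tuple[float, float]  # (x, y), px, continuous
    orientation_deg: float
    anchored: bool  # templated => minus end fixed at origin

    def length_um(self, t: float, config: SimulationConfig) -> float:
        """True polymer length at time t (plus- plus minus-end growth)."""
        if t <= self.birth_time:
            return 0.0
        v = config.growth_speed_um_s
        rate = v if self.anchored else v * (1.0 + config.minus_speed_fraction)
        return rate * (t - self.birth_time)

    def endpoints_px(
        self, t: float, config: SimulationConfig
    ) -> tuple[np.ndarray, np.ndarray]:
        """(minus_end, plus_end) pixel coordinates at time t, unclipped."""
        dt = max(0.0, t - self.birth_time)
        v_px = config.growth_speed_um_s / config.pixel_size
        ang = math.radians(self.orientation_deg)
        u = np.array([math.cos(ang), math.sin(ang)])
        o = np.array(self.origin, dtype=float)
        plus = o + u * v_px * dt
        if self.anchored:
            minus = o
        else:
            minus = o - u * v_px * dt * config.minus_speed_fraction
        return minus, plus


class TrackSegment(NamedTuple):
    """A track's rendered extent at one time point."""

    track_id: int
    p0: tuple[float, float]  # clipped minus end, px
    p1: tuple[float, float]  # clipped plus end, px
    clipped: bool  # any part of the true segment lies out of plane
    true_length_um: float


def _clip_segment(p0, p1, width, height):
    """Liang-Barsky clip of segment p0->p1 to [0, width-1] x [0, height-1].

    Returns (q0, q1, clipped) or None if fully outside.
    """
    x0, y0 = p0
    x1, y1 = p1
    dx, dy = x1 - x0, y1 - y0
    t0, t1 = 0.0, 1.0
    for p, q in (
        (-dx, x0 - 0.0),
        (dx, (width - 1.0) - x0),
        (-dy, y0 - 0.0),
        (dy, (height - 1.0) - y0),
    ):
        if p == 0.0:
            if q < 0.0:
                return None
            continue
        r = q / p
        if p < 0.0:
            if r > t1:
                return None
            t0 = max(t0, r)
        else:
            if r < t0:
                return None
            t1 = min(t1, r)
    q0 = (x0 + t0 * dx, y0 + t0 * dy)
    q1 = (x0 + t1 * dx, y0 + t1 * dy)
    return q0, q1, (t0 > 0.0 or t1 < 1.0)


@dataclass
class GroundTruth:
    """Exact per-simulation truth paired with a rendered movie."""

    tracks: list[MicrotubuleTrack]
    trajectory: CountTrajectory  # real-valued recursion output at dt_sim
    config: SimulationConfig

    def counts_at(self, times) -> np.ndarray:
        """Integerized cumulative nucleation count at each query time."""
        births = np.sort([trk.birth_time for trk in self.tracks])
        return np.searchsorted(births, np.atleast_1d(times), side="right").astype(int)

    def tracks_table(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "id": [t.id for t in self.tracks],
                "birth_time_s": [t.birth_time for t in self.tracks],
                "x_px": [t.origin[0] for t in self.tracks],
                "y_px": [t.origin[1] for t in self.tracks],
                "orientation_deg": [t.orientation_deg for t in self.tracks],
                "class": [
                    "templated" if t.anchored else "spontaneous"
                    for t in self.tracks
                ],
            }
        )

    def frame_truth(self, t: float) -> pd.DataFrame:
        """Live tracks at time t with plus-end positions and true lengths."""
        rows = []
        for trk in self.tracks:
            if trk.birth_time > t:
                continue
            minus, plus = trk.endpoints_px(t, self.config)
            rows.append(
                {
                    "id": trk.id,
                    "plus_x_px": plus[0],
                    "plus_y_px": plus[1],
                    "minus_x_px": minus[0],
                    "minus_y_px": minus[1],
                    "length_um": trk.length_um(t, self.config),
                    "class": "templated" if trk.anchored else "spontaneous",
                }
            )
        return pd.DataFrame(
            rows,
            columns=[
                "id", "plus_x_px", "plus_y_px", "minus_x_px", "minus_y_px",
                "length_um", "class",
            ],
        )

    def total_length_um(self, t: float, in_plane_only: bool = False) -> float:
        """Summed polymer length at time t; optionally only the in-plane part."""
        total = 0.0
        w, h = self.config.plane_size
        for trk in self.tracks:
            if trk.birth_time > t:
                continue
            if not in_plane_only:
                total += trk.length_um(t, self.config)
                continue
            minus, plus = trk.endpoints_px(t, self.config)
            clip = _clip_segment(minus, plus, w, h)
            if clip is None:
                continue
            q0, q1, _ = clip
            total += (
                math.hypot(q1[0] - q0[0], q1[1] - q0[1]) * self.config.pixel_size
            )
        return total

    def to_json(self, path: str | Path) -> None:
        payload = {
            "n_tracks": len(self.tracks),
            "tracks": self.tracks_table().to_dict(orient="records"),
            "trajectory": {
                "time_s": self.trajectory.times.tolist(),
                "count": self.trajectory.counts.tolist(),
            },
            "config": {
                "k": self.config.kinetics.k,
                "n_max": self.config.kinetics.n_max,
                "growth_speed_um_min": self.config.growth_speed,
                "plane_size_px": list(self.config.plane_size),
                "pixel_size_um": self.config.pixel_size,
                "dt_sim_s": self.config.dt_sim,
                "frame_interval_s": self.config.frame_interval,
                "duration_s": self.config.duration,
                "n_orientations": self.config.n_orientations,
                "seed": self.config.seed,
                "templated_fraction": self.config.templated_fraction,
            },
        }
        Path(path).write_text(json.dumps(payload, indent=1))


def simulate_tracks(
    config: SimulationConfig,
    trajectory: CountTrajectory | None = None,
) -> tuple[list[MicrotubuleTrack], GroundTruth]:
    """Spawn microtubule tracks from the nucleation recursion.

    The recursion's real-valued count is integerized by floor-with-carry:
    at each simulation step, as many tracks are spawned as the floored
    count has gained whole units.  Placement and orientation draw from a
    seeded generator, so output is deterministic given the config.

    A precomputed ``trajectory`` (e.g. a two-phase one) may be supplied;
    it must be sampled on the simulation time step.
    """
    if trajectory is None:
        trajectory = eq2_trajectory(
            config.kinetics, duration=config.duration, dt=config.dt_sim
        )
    rng = np.random.default_rng(config.seed)
    w, h = config.plane_size
    tracks: list[MicrotubuleTrack] = []
    born = 0
    for t, n in zip(trajectory.times, trajectory.counts):
        # counts within 1e-6 of the next integer round up: the recursion
        # approaches integers (and N_max) from below with accumulated
        # floating-point drift, which plain floor would turn into missed
        # or indefinitely delayed births
        target = int(math.floor(n + 1e-6))
        while born < target:
            x = rng.uniform(0.0, w)
            y = rng.uniform(0.0, h)
            ori = rng.integers(0, config.n_orientations) * (360.0 / config.n_orientations)
            anchored = bool(rng.random() < config.templated_fraction)
            tracks.append(
                MicrotubuleTrack(
                    id=born,
                    birth_time=float(t),
                    origin=(float(x), float(y)),
                    orientation_deg=float(ori),
                    anchored=anchored,
                )
            )
            born += 1
    return tracks, GroundTruth(tracks=tracks, trajectory=trajectory, config=config)


def grow_tracks(
    tracks: Sequence[MicrotubuleTrack], t: float, config: SimulationConfig
) -> list[TrackSegment]:
    """Per-track segment endpoints at time t, clipped to the plane.

    Tracks not yet born are omitted; the true (unclipped) length is kept
    alongside so ground truth survives clipping.
    """
    if t < 0:
        raise ValueError("time must be >= 0")
    w, h = config.plane_size
    segments = []
    for trk in tracks:
        if trk.birth_time > t:
            continue
        minus, plus = trk.endpoints_px(t, config)
        clip = _clip_segment(minus, plus, w, h)
        if clip is None:
            continue
        q0, q1, was_clipped = clip
        segments.append(
            TrackSegment(
                track_id=trk.id,
                p0=(float(q0[0]), float(q0[1])),
                p1=(float(q1[0]), float(q1[1])),
                clipped=was_clipped,
                true_length_um=trk.length_um(t, config),
            )
        )
    return segments


def _deposit_line(canvas: np.ndarray, p0, p1, intensity_per_um: float,
                  pixel_size: float) -> None:
    """Integrate a constant line density onto the canvas (bilinear splat)."""
    x0, y0 = p0
    x1, y1 = p1
    length_px = math.hypot(x1 - x0, y1 - y0)
    length_um = length_px * pixel_size
    if length_um == 0.0:
        return
    n = max(2, int(math.ceil(length_px / 0.25)) + 1)
    ts = np.linspace(0.0, 1.0, n)
    xs = x0 + ts * (x1 - x0)
    ys = y0 + ts * (y1 - y0)
    _deposit_points(canvas, xs, ys, np.full(n, intensity_per_um * length_um / n))


def _deposit_points(canvas: np.ndarray, xs, ys, weights) -> None:
    """Bilinear deposition of point masses at sub-pixel positions."""
    h, w = canvas.shape
    xs = np.asarray(xs, float)
    ys = np.asarray(ys, float)
    weights = np.asarray(weights, float)
    ix = np.floor(xs).astype(int)
    iy = np.floor(ys).astype(int)
    fx = xs - ix
    fy = ys - iy
    for dx, dy, wgt in (
        (0, 0, (1 - fx) * (1 - fy)),
        (1, 0, fx * (1 - fy)),
        (0, 1, (1 - fx) * fy),
        (1, 1, fx * fy),
    ):
        cx = ix + dx
        cy = iy + dy
        ok = (cx >= 0) & (cx < w) & (cy >= 0) & (cy < h)
        np.add.at(canvas, (cy[ok], cx[ok]), weights[ok] * wgt[ok])


def render_movie(
    tracks: Sequence[MicrotubuleTrack],
    config: SimulationConfig,
    render: RenderSettings = RenderSettings(),
) -> MovieStack | tuple[MovieStack, MovieStack]:
    """Render tracks into a TIRF-like stack.

    Each frame is ``background + blurred line signal (+ noise) + offset``.
    With ``render.eb1_channel`` a second stack is returned carrying a
    Gaussian comet at each live plus end (plus ends outside the plane are
    not rendered).  Identical config + settings produce bit-identical
    stacks.
    """
    w, h = config.plane_size
    frame_times = np.arange(0.0, config.duration + 1e-9, config.frame_interval)
    psf_px = render.psf_sigma / config.pixel_size
    comet_px = render.comet_sigma / config.pixel_size
    # independent noise streams per channel, derived from the placement seed
    ss = np.random.SeedSequence(config.seed)
    noise_rng, eb1_noise_rng = (np.random.default_rng(s) for s in ss.spawn(2))

    frames = np.empty((frame_times.size, h, w), dtype=np.float32)
    eb1_frames = (
        np.empty_like(frames) if render.eb1_channel else None
    )
    for fi, t in enumerate(frame_times):
        canvas = np.zeros((h, w), dtype=float)
        segments = grow_tracks(tracks, t, config)
        for seg in segments:
            _deposit_line(canvas, seg.p0, seg.p1, render.mt_intensity,
                          config.pixel_size)
        canvas = ndimage.gaussian_filter(canvas, psf_px)
        frames[fi] = _camera(canvas, render, noise_rng)
        if eb1_frames is not None:
            comet = np.zeros((h, w), dtype=float)
            live = {s.track_id for s in segments}
            for trk in tracks:
                if trk.id not in live or trk.birth_time > t:
                    continue
                _, plus = trk.endpoints_px(t, config)
                if 0 <= plus[0] <= w - 1 and 0 <= plus[1] <= h - 1:
                    _deposit_points(
                        comet, [plus[0]], [plus[1]], [render.comet_intensity]
                    )
            comet = ndimage.gaussian_filter(comet, comet_px)
            eb1_frames[fi] = _camera(comet, render, eb1_noise_rng)

    movie = MovieStack(
        data=frames,
        pixel_size_um=config.pixel_size,
        frame_interval_s=config.frame_interval,
    )
    if eb1_frames is None:
        return movie
    eb1 = MovieStack(
        data=eb1_frames,
        pixel_size_um=config.pixel_size,
        frame_interval_s=config.frame_interval,
    )
    return movie, eb1


def _camera(signal: np.ndarray, render: RenderSettings,
            rng: np.random.Generator) -> np.ndarray:
    """Apply background, noise model and offset; clip to sensor range."""
    expected = signal + render.background
    if render.noise_model == "none":
        out = expected
    elif render.noise_model == "gaussian":
        out = expected + rng.normal(0.0, render.read_noise_sigma, expected.shape)
    else:  # poisson-gaussian
        out = rng.poisson(expected).astype(float)
        out += rng.normal(0.0, render.read_noise_sigma, expected.shape)
    out = out + render.camera_offset
    return np.clip(out, 0.0, 2.0 ** render.bit_depth - 1).astype(np.float32)
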