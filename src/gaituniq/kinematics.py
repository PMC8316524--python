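"""From marker trajectories to fixed-length gait vectors.

The pipeline implemented here:

1. derive mid-hip / mid-shoulder auxiliary points,
2. rotate the trial into the laboratory frame (+X = direction of progression,
   +Z = up),
3. detect heel strikes as prominent minima of the heel's vertical coordinate,
4. cut the trial into heel-strike-to-heel-strike cycles and express each of
   the 16 body segments as a unit direction-cosine triple per frame,
5. temporally normalise every cycle to 101 frames (0..100% of the cycle), and
6. flatten the 101 x 16 x 3 orientation block into a 4848-component gait
   vector (segment-major, then axis x/y/z, then frame).

Spatiotemporal gait parameters (cadence, step length, walking velocity) are
computed per cycle from the mid-hip trajectory.
"""
from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import NamedTuple, Sequence

import numpy as np
from scipy.signal import find_peaks

from .anatomy import (
    AUGMENTED_INDEX,
    POINT_INDEX,
    POINT_LABELS,
    SegmentSet,
)

N_FRAMES_NORM = 101  #: frames per temporally normalised cycle
N_SEGMENTS = 16
GAIT_VECTOR_LEN = N_SEGMENTS * 3 * N_FRAMES_NORM  # 4848

UNIT_NORM_TOL = 1e-9


class KinematicsError(ValueError):
    """Raised for malformed trajectories or failed event extraction."""


@dataclass
class PointFrameSeries:
    """One trial's time-stamped 3-D positions of the 17 anatomical points.

    Attributes
    ----------
    frame_rate:
        Nominal capture rate in frames/s.
    times:
        ``(F,)`` array of strictly increasing sample times in s.
    positions:
        ``(F, 17, 3)`` array of positions in m, point axis ordered as
        :data:`gaituniq.anatomy.POINT_LABELS`.
    """

    frame_rate: float
    times: np.ndarray
    positions: np.ndarray
    labels: tuple = field(default=POINT_LABELS)

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        self.positions = np.asarray(self.positions, dtype=float)
        if self.frame_rate <= 0:
            raise KinematicsError("frame_rate must be positive")
        if self.positions.ndim != 3 or self.positions.shape[1:] != (17, 3):
            raise KinematicsError(
                f"positions must be (F, 17, 3), got {self.positions.shape}")
        if self.times.shape != (self.positions.shape[0],):
            raise KinematicsError("times and positions disagree on frame count")
        if len(self.times) > 1 and not np.all(np.diff(self.times) > 0):
            raise KinematicsError("times must be strictly increasing")
        if tuple(self.labels) != POINT_LABELS:
            raise KinematicsError("labels must be the canonical 17-point set")

    @property
    def n_frames(self) -> int:
        return self.positions.shape[0]

    def point(self, label: str) -> np.ndarray:
        """``(F, 3)`` trajectory of one labeled point."""
        return self.positions[:, POINT_INDEX[label], :]


class Spatiotemporal(NamedTuple):
    cadence: float      # steps/min
    step_length: float  # m
    velocity: float     # m/s


@dataclass
class GaitCycle:
    """One temporally normalised gait cycle.

    ``orientations`` is ``(101, 16, 3)``: per normalised-time frame, the unit
    direction cosines of the 16 segments in the laboratory frame.
    """

    orientations: np.ndarray
    duration: float
    spatiotemporal: Spatiotemporal
    subject_id: str = ""
    trial_id: str = ""
    cycle_index: int = 0

    def __post_init__(self):
        self.orientations = np.asarray(self.orientations, dtype=float)
        if (self.orientations.ndim != 3 or self.orientations.shape[0] < 2
                or self.orientations.shape[1:] != (N_SEGMENTS, 3)):
            raise KinematicsError(
                f"orientations must be (F, 16, 3), got {self.orientations.shape}")
        norms = np.linalg.norm(self.orientations, axis=-1)
        if not np.allclose(norms, 1.0, atol=UNIT_NORM_TOL, rtol=0):
            raise KinematicsError("direction cosines are not unit-norm")


def derive_auxiliary_points(positions: np.ndarray) -> np.ndarray:
    """Append mid-hip and mid-shoulder to a point array.

    Parameters
    ----------
    positions:
        ``(..., 17, 3)`` array in canonical label order.

    Returns
    -------
    ``(..., 19, 3)`` array ordered as :data:`gaituniq.anatomy.AUGMENTED_LABELS`;
    the midpoints are arithmetic means of the left/right hip and shoulder pairs.
    """
    positions = np.asarray(positions, dtype=float)
    if positions.shape[-2:] != (17, 3):
        raise KinematicsError(f"expected (..., 17, 3) positions, got {positions.shape}")
    l_hip, r_hip = POINT_INDEX["l_hip"], POINT_INDEX["r_hip"]
    l_sh, r_sh = POINT_INDEX["l_shoulder"], POINT_INDEX["r_shoulder"]
    mid_hip = 0.5 * (positions[..., l_hip, :] + positions[..., r_hip, :])
    mid_shoulder = 0.5 * (positions[..., l_sh, :] + positions[..., r_sh, :])
    return np.concatenate(
        [positions, mid_hip[..., None, :], mid_shoulder[..., None, :]], axis=-2)


def mid_hip_trajectory(series: PointFrameSeries) -> np.ndarray:
    """``(F, 3)`` mid-hip trajectory (midpoint of the two hips)."""
    return 0.5 * (series.point("l_hip") + series.point("r_hip"))


def align_to_lab(series: PointFrameSeries, min_progression: float = 1e-6) -> PointFrameSeries:
    """Rotate a trial about the vertical axis into the laboratory convention.

    After alignment the mid-hip net horizontal displacement points along +X
    and has zero Y component; Z coordinates are untouched.

    Raises
    ------
    KinematicsError
        If the net horizontal progression is below ``min_progression`` m.
    """
    hip = mid_hip_trajectory(series)
    disp = hip[-1] - hip[0]
    horiz = np.hypot(disp[0], disp[1])
    if horiz < min_progression:
        raise KinematicsError(
            f"net horizontal progression {horiz:.2e} m below {min_progression:g} m")
    theta = np.arctan2(disp[1], disp[0])
    c, s = np.cos(-theta), np.sin(-theta)
    rot = np.array([[c, -s, 0.0], [s, c, 0.0], [0.0, 0.0, 1.0]])
    rotated = series.positions @ rot.T
    return replace(series, positions=rotated, times=series.times.copy())


def _dominant_period(z: np.ndarray, frame_rate: float) -> float | None:
    """Cycle period in frames from the autocorrelation of the heel height.

    Returns ``None`` when no interior autocorrelation peak exists (signal
    shorter than about two cycles).
    """
    x = z - z.mean()
    ac = np.correlate(x, x, mode="full")[len(x) - 1:]
    min_lag = max(2, int(round(0.3 * frame_rate)))  # shortest plausible cycle, 0.3 s
    max_lag = len(x) - 1
    if max_lag <= min_lag:
        return None
    peaks, _ = find_peaks(ac[min_lag:max_lag])
    if len(peaks) == 0:
        return None
    seg = ac[min_lag:max_lag]
    return float(min_lag + peaks[np.argmax(seg[peaks])])


def detect_heel_strikes(
    series: PointFrameSeries,
    side: str = "right",
    prominence_frac: float = 0.05,
    min_amplitude: float = 1e-4,
) -> np.ndarray:
    """Heel-strike frame indices: periodic minima of the heel's height.

    Candidate minima need a prominence of at least ``prominence_frac`` of
    the signal range; minima closer together than roughly half the gait
    cycle are thinned, keeping the deeper one.  The cycle period is
    estimated from the autocorrelation of the heel height (falling back to
    the median candidate spacing for short signals).  Endpoint frames count
    as events when they sit at the depth of the interior minima (within 5%
    of the range), covering trials that begin or end exactly at a strike.

    Returns strictly increasing indices; K events delimit K-1 cycles.

    Raises
    ------
    KinematicsError
        For an unknown side, < 1 s of data, a flat heel trajectory, or
        fewer than two detected events.
    """
    if side not in ("left", "right"):
        raise KinematicsError(f"side must be 'left' or 'right', got {side!r}")
    if series.times[-1] - series.times[0] < 1.0:
        raise KinematicsError("need at least 1 s of data for heel-strike detection")
    z = series.point(f"{side[0]}_heel")[:, 2]
    zrange = float(z.max() - z.min())
    if zrange < min_amplitude:
        raise KinematicsError("heel height is constant; no heel strikes detectable")
    prom = prominence_frac * zrange
    idx, _ = find_peaks(-z, prominence=prom)
    events = list(idx)
    depth_tol = z.min() + 0.05 * zrange
    last = len(z) - 1
    if z[0] <= depth_tol and 0 not in events:
        events.insert(0, 0)
    if z[last] <= depth_tol and last not in events:
        events.append(last)
    period = _dominant_period(z, series.frame_rate)
    if period is None and len(events) >= 3:
        period = float(np.median(np.diff(events)))
    if period is not None and len(events) > 2:
        events = _best_periodic_comb(events, z, period)
    if len(events) < 2:
        raise KinematicsError(f"only {len(events)} heel-strike event(s) detected")
    return np.asarray(events, dtype=int)


def _best_periodic_comb(cand: list[int], z: np.ndarray, period: float,
                        window: tuple[float, float] = (0.65, 1.45)) -> list[int]:
    """Pick the chain of candidate minima whose spacings match the period.

    Dynamic programme over candidates ordered in time: a chain may step from
    one candidate to a later one when their spacing is within
    ``window x period``; the chain maximising total minimum depth wins.
    This resolves interleaved secondary minima (e.g. a split strike basin)
    into one consistent heel-strike comb.
    """
    depth = [float(z.max() - z[c]) for c in cand]
    lo, hi = window[0] * period, window[1] * period
    score = list(depth)
    parent = [-1] * len(cand)
    for i in range(len(cand)):
        for j in range(i):
            gap = cand[i] - cand[j]
            if lo <= gap <= hi and score[j] + depth[i] > score[i]:
                score[i] = score[j] + depth[i]
                parent[i] = j
    best = int(np.argmax(score))
    chain = []
    while best != -1:
        chain.append(cand[best])
        best = parent[best]
    return chain[::-1]


def segment_orientations(
    positions: np.ndarray, segments: SegmentSet, degenerate_tol: float = 1e-9
) -> np.ndarray:
    """Unit direction cosines of each segment per frame.

    Parameters
    ----------
    positions:
        ``(F, 17, 3)`` point array.

    Returns
    -------
    ``(F, 16, 3)`` array of unit vectors (distal - proximal, normalised).
    """
    aug = derive_auxiliary_points(positions)
    prox, dist = segments.endpoint_indices()
    vec = aug[:, dist, :] - aug[:, prox, :]
    norms = np.linalg.norm(vec, axis=-1)
    if np.any(norms < degenerate_tol):
        f, s = np.argwhere(norms < degenerate_tol)[0]
        raise KinematicsError(
            f"degenerate segment {segments[s].name!r} at frame {f}: coincident endpoints")
    return vec / norms[..., None]


def extract_cycles(
    series: PointFrameSeries,
    events: Sequence[int],
    segments: SegmentSet | None = None,
) -> list[np.ndarray]:
    """Cut a trial into raw orientation cycles at the given event frames.

    Each cycle spans ``[event_k, event_{k+1})``; the returned array includes
    the closing strike frame as interpolation endpoint, so cycle ``k`` has
    ``event_{k+1} - event_k + 1`` frames of shape ``(F_k, 16, 3)``.
    """
    events = np.asarray(events, dtype=int)
    if len(events) < 2:
        raise KinematicsError("need at least 2 events to extract a cycle")
    segments = segments if segments is not None else SegmentSet()
    orient = segment_orientations(series.positions, segments)
    return [orient[a:b + 1] for a, b in zip(events[:-1], events[1:])]


def resample_cycle(
    raw: np.ndarray, target_frames: int = N_FRAMES_NORM, renormalize: bool = True
) -> np.ndarray:
    """Linearly interpolate a raw cycle onto equally spaced normalised time.

    The ``F`` input frames are taken to span normalised time [0, 1]
    inclusive; each of the 48 scalar channels is interpolated independently
    onto ``target_frames`` points.  Interpolation leaves the unit sphere, so
    each interpolated cosine triple is re-normalised (``renormalize=False``
    only for diagnostic use).
    """
    raw = np.asarray(raw, dtype=float)
    if raw.ndim != 3 or raw.shape[1:] != (N_SEGMENTS, 3):
        raise KinematicsError(f"raw cycle must be (F, 16, 3), got {raw.shape}")
    F = raw.shape[0]
    if F < 2:
        raise KinematicsError("raw cycle needs at least 2 frames")
    t_src = np.linspace(0.0, 1.0, F)
    t_dst = np.linspace(0.0, 1.0, target_frames)
    flat = raw.reshape(F, -1)
    out = np.empty((target_frames, flat.shape[1]))
    for ch in range(flat.shape[1]):
        out[:, ch] = np.interp(t_dst, t_src, flat[:, ch])
    out = out.reshape(target_frames, N_SEGMENTS, 3)
    if renormalize:
        norms = np.linalg.norm(out, axis=-1)
        if np.any(norms < 1e-12):
            raise KinematicsError("interpolated triple collapsed to zero")
        out = out / norms[..., None]
    return out


def build_gait_vector(orientations: np.ndarray) -> np.ndarray:
    """Flatten a ``(F, 16, 3)`` cycle into a ``48*F``-component gait vector.

    With the standard 101-frame normalisation this is the 4848-component
    gait vector.  Order: segment-major, then axis (x, y, z), then frame,
    i.e. component ``s*3*F + a*F + f`` is segment ``s``, axis ``a``,
    frame ``f``.
    """
    orientations = np.asarray(orientations, dtype=float)
    if orientations.ndim != 3 or orientations.shape[1:] != (N_SEGMENTS, 3):
        raise KinematicsError(
            f"expected (F, 16, 3) orientations, got {orientations.shape}")
    n = orientations.shape[0] * N_SEGMENTS * 3
    return np.transpose(orientations, (1, 2, 0)).reshape(n).copy()


def unflatten_gait_vector(vector: np.ndarray) -> np.ndarray:
    """Inverse of :func:`build_gait_vector`: ``(48*F,)`` → ``(F, 16, 3)``."""
    vector = np.asarray(vector, dtype=float)
    if vector.ndim != 1 or vector.size % (N_SEGMENTS * 3) != 0:
        raise KinematicsError(
            f"gait vector length must be a multiple of 48, got {vector.shape}")
    frames = vector.size // (N_SEGMENTS * 3)
    return np.transpose(vector.reshape(N_SEGMENTS, 3, frames), (2, 0, 1)).copy()


def spatiotemporal_params(
    series: PointFrameSeries, events: Sequence[int]
) -> Spatiotemporal:
    """Cadence, step length and walking velocity over an event span.

    velocity = mid-hip horizontal displacement / elapsed time;
    cadence   = 2 steps per cycle, in steps/min;
    step_length = velocity x (cycle duration / 2).
    """
    events = np.asarray(events, dtype=int)
    if len(events) < 2:
        raise KinematicsError("need at least 2 events for spatiotemporal parameters")
    t0, t1 = series.times[events[0]], series.times[events[-1]]
    duration = float(t1 - t0)
    if duration <= 0:
        raise KinematicsError("zero-duration event span")
    n_cycles = len(events) - 1
    hip = mid_hip_trajectory(series)
    disp = hip[events[-1]] - hip[events[0]]
    velocity = float(np.hypot(disp[0], disp[1])) / duration
    cycle_duration = duration / n_cycles
    cadence = 2.0 / cycle_duration * 60.0
    step_length = velocity * cycle_duration / 2.0
    return Spatiotemporal(cadence=cadence, step_length=step_length, velocity=velocity)


def trial_to_cycles(
    series: PointFrameSeries,
    segments: SegmentSet | None = None,
    side: str = "right",
    max_cycles: int | None = None,
    target_frames: int = N_FRAMES_NORM,
) -> list[GaitCycle]:
    """Full per-trial pipeline: align, detect, cut, resample.

    Returns the first ``max_cycles`` complete cycles (all, if ``None``),
    each with its spatiotemporal parameters.
    """
    segments = segments if segments is not None else SegmentSet()
    aligned = align_to_lab(series)
    events = detect_heel_strikes(aligned, side=side)
    raws = extract_cycles(aligned, events, segments)
    if max_cycles is not None:
        raws = raws[:max_cycles]
    cycles = []
    for k, raw in enumerate(raws):
        e0, e1 = events[k], events[k + 1]
        orient = resample_cycle(raw, target_frames=target_frames)
        st = spatiotemporal_params(aligned, [e0, e1])
        duration = float(aligned.times[e1] - aligned.times[e0])
        cycles.append(GaitCycle(orientations=orient, duration=duration,
                                spatiotemporal=st, cycle_index=k))
    return cycles
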