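"""Synthetic gait cohorts with controlled inter-/intra-subject variance.

Two generators:

* :func:`generate_marker_cohort` emits marker-level trials (17 labeled 3-D
  points per frame) by forward-integrating per-subject periodic
  segment-orientation templates along the body tree, so the whole
  kinematics pipeline (alignment, heel-strike detection, cycle cutting,
  resampling) can be exercised without any recorded data.

* :func:`generate_feature_cohort` draws PCA-score-like feature matrices
  directly, for testing the variance accounting and verification stages in
  isolation with known per-component between/within-subject spread.

The orientation model: every segment's direction curve over the gait cycle
phase ``phi`` is a truncated Fourier series per axis, normalised to the unit
sphere per frame.  A subject is a draw of all Fourier coefficients around a
fixed built-in population mean gait (spread ``inter_subject_sd``); every
cycle re-perturbs the coefficients (spread ``intra_subject_sd``) and jitters
its duration lognormally.  The mid-hip root advances at the subject's
walking speed, so spatiotemporal parameters have known ground truth.
"""
from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .anatomy import POINT_INDEX
from .kinematics import PointFrameSeries

__all__ = [
    "CohortParams",
    "generate_marker_cohort",
    "generate_feature_cohort",
    "mean_template",
    "CURVE_NAMES",
]


class SimulationError(ValueError):
    """Raised for degenerate cohort parameters."""


@dataclass
class CohortParams:
    """Parameters of the synthetic marker-level cohort.

    Defaults reproduce the emulated study conditions: 2 trials x 2 cycles
    per subject at 120 frames/s with a mean cycle duration of 1.03 s.
    """

    n_subjects: int = 488
    n_trials_per_subject: int = 2
    n_cycles_per_trial: int = 2
    frame_rate: float = 120.0
    cycle_duration_mean: float = 1.03   # s
    cycle_duration_sd: float = 0.06     # s, between-subject spread
    cycle_jitter_sd: float = 0.015      # s, cycle-to-cycle spread
    n_harmonics: int = 3
    inter_subject_sd: float = 0.06      # sigma_b, Fourier-coefficient scale
    intra_subject_sd: float = 0.015     # sigma_w, same scale
    walking_speed_mean: float = 1.25    # m/s
    walking_speed_sd: float = 0.15      # m/s, between-subject spread
    seed: int = 0

    def validate(self) -> None:
        counts = dict(n_subjects=self.n_subjects,
                      n_trials_per_subject=self.n_trials_per_subject,
                      n_cycles_per_trial=self.n_cycles_per_trial,
                      n_harmonics=self.n_harmonics)
        for name, v in counts.items():
            if int(v) != v or v < 1:
                raise SimulationError(f"{name} must be an integer >= 1, got {v}")
        sds = dict(cycle_duration_sd=self.cycle_duration_sd,
                   cycle_jitter_sd=self.cycle_jitter_sd,
                   inter_subject_sd=self.inter_subject_sd,
                   intra_subject_sd=self.intra_subject_sd,
                   walking_speed_sd=self.walking_speed_sd)
        for name, v in sds.items():
            if v < 0:
                raise SimulationError(f"{name} must be >= 0, got {v}")
        if self.frame_rate <= 0:
            raise SimulationError("frame_rate must be > 0")
        if self.cycle_duration_mean <= 0:
            raise SimulationError("cycle_duration_mean must be > 0")
        if self.walking_speed_mean <= 0:
            raise SimulationError("walking_speed_mean must be > 0")

    def to_dict(self) -> dict:
        return asdict(self)


# --- population mean gait template -----------------------------------------
#
# 16 independent orientation curves; the right clavicle is the exact mirror
# of the left (so the shoulder midpoint is consistent with the emitted
# shoulder points) and the pelvis axis generates the two hip points.
# Coefficient layout per axis: [a0, a1, b1, a2, b2, a3, b3] with
# value(phi) = a0 + sum_k (a_k cos k*phi + b_k sin k*phi); phi = 0 at right
# heel strike, left-side curves are the right-side ones shifted by half a
# cycle with the Y axis mirrored.

CURVE_NAMES = (
    "trunk", "neck", "l_clavicle", "pelvis",
    "l_upper_arm", "r_upper_arm", "l_forearm", "r_forearm",
    "l_thigh", "r_thigh", "l_shank", "r_shank",
    "l_foot", "r_foot", "l_heel_link", "r_heel_link",
)
N_COEFF_TEMPLATE = 7  # constant + 3 harmonics


def _coeffs(x, y, z):
    c = np.zeros((3, N_COEFF_TEMPLATE))
    for row, vals in zip(c, (x, y, z)):
        row[:len(vals)] = vals
    return c


def _mirror(c):
    """Half-cycle phase shift (odd harmonics negated) + Y-axis mirror."""
    m = c.copy()
    m[:, [1, 2, 5, 6]] *= -1.0   # cos/sin of harmonics 1 and 3
    m[1] *= -1.0                 # y axis
    return m


def _base_template() -> dict[str, np.ndarray]:
    t = {}
    t["trunk"] = _coeffs([0.08, 0, 0, 0.02], [0, 0, 0.03], [1.0])
    t["neck"] = _coeffs([0.10], [0, 0, -0.02], [1.0])
    t["l_clavicle"] = _coeffs([0, 0, -0.04], [1.0], [0.05])
    t["pelvis"] = _coeffs([0, 0, -0.06], [1.0], [0.0])  # points toward left hip
    t["r_upper_arm"] = _coeffs([0, 0, -0.28], [-0.06], [-1.0, 0.03])
    t["l_upper_arm"] = _mirror(t["r_upper_arm"])
    t["r_forearm"] = _coeffs([0.30, 0, -0.25], [-0.04], [-0.90, 0.04])
    t["l_forearm"] = _mirror(t["r_forearm"])
    # Legs: the shank's horizontal excursion 0.5*(1 - cos phi) vanishes only
    # at the strike, so after normalisation its vertical share is maximal
    # exactly once per cycle — the heel is lowest at phi = 0 and lifts
    # through swing, giving event detection one clear minimum per cycle.
    t["r_thigh"] = _coeffs([0.0, 0.18, 0, 0, 0.02], [-0.03], [-1.0])
    t["l_thigh"] = _mirror(t["r_thigh"])
    t["r_shank"] = _coeffs([0.50, -0.50], [-0.03], [-0.95])
    t["l_shank"] = _mirror(t["r_shank"])
    t["r_foot"] = _coeffs([0.85, -0.10], [-0.10], [-0.15, 0.25])
    t["l_foot"] = _mirror(t["r_foot"])
    t["r_heel_link"] = _coeffs([0.40, 0.10], [-0.02], [0.55, 0.30])
    t["l_heel_link"] = _mirror(t["r_heel_link"])
    return t


def mean_template(n_harmonics: int = 3) -> np.ndarray:
    """Population mean gait as a ``(16, 3, 1 + 2*n_harmonics)`` coefficient array.

    Curve order follows :data:`CURVE_NAMES`.  The built-in constants define
    harmonics up to order 2; requesting more harmonics pads with zeros,
    fewer truncates.
    """
    if n_harmonics < 1:
        raise SimulationError("n_harmonics must be >= 1")
    n_coeff = 1 + 2 * n_harmonics
    base = _base_template()
    out = np.zeros((len(CURVE_NAMES), 3, n_coeff))
    for i, name in enumerate(CURVE_NAMES):
        c = base[name]
        k = min(n_coeff, N_COEFF_TEMPLATE)
        out[i, :, :k] = c[:, :k]
    return out


#: Segment lengths in m (scaled per subject by a stature factor).
SEGMENT_LENGTHS = {
    "trunk": 0.50, "neck": 0.25, "clavicle": 0.20, "pelvis_half": 0.10,
    "upper_arm": 0.30, "forearm": 0.26,
    "thigh": 0.42, "shank": 0.41, "foot": 0.18, "heel_link": 0.07,
}
ROOT_HEIGHT = 0.92       # m, mid-hip height
ROOT_BOB = -0.012        # m, at twice the cycle frequency; lowest at double support
ROOT_SWAY = 0.02         # m, lateral excursion at the cycle frequency
PHASE_MARGIN = 0.5       # cycles simulated before the first / after the last strike


def _harmonic_basis(phi: np.ndarray, n_harmonics: int) -> np.ndarray:
    """``(1 + 2H, F)`` basis rows [1, cos phi, sin phi, cos 2phi, ...]."""
    rows = [np.ones_like(phi)]
    for k in range(1, n_harmonics + 1):
        rows.append(np.cos(k * phi))
        rows.append(np.sin(k * phi))
    return np.stack(rows)


def _unit(v: np.ndarray) -> np.ndarray:
    return v / np.linalg.norm(v, axis=-1, keepdims=True)


def _trial_series(params: CohortParams, coeff_subj, scale, speed, subj_duration,
                  rng) -> PointFrameSeries:
    """Forward-integrate one trial from the subject's coefficient template."""
    H = params.n_harmonics
    n_cyc = params.n_cycles_per_trial
    # Cycles -1 .. n_cyc cover the margins before the first and after the
    # last heel strike; strikes sit at phi = 0, 2*pi, ..., 2*pi*n_cyc.
    n_cycles_total = n_cyc + 2
    jitter_rel = params.cycle_jitter_sd / params.cycle_duration_mean
    durations = subj_duration * np.exp(
        jitter_rel * rng.standard_normal(n_cycles_total) - 0.5 * jitter_rel**2)
    coeff_noise = params.intra_subject_sd * rng.standard_normal(
        (n_cycles_total, len(CURVE_NAMES), 3, 1 + 2 * H))
    heading = rng.uniform(0.0, 2.0 * np.pi)

    # piecewise-linear phase: segment c covers phi in [2*pi*(c-1), 2*pi*c)
    seg_spans = np.full(n_cycles_total, 2.0 * np.pi)
    seg_spans[0] = PHASE_MARGIN * 2.0 * np.pi      # tail of the pre-cycle
    seg_spans[-1] = PHASE_MARGIN * 2.0 * np.pi     # head of the post-cycle
    seg_times = durations * seg_spans / (2.0 * np.pi)
    bounds = np.concatenate([[0.0], np.cumsum(seg_times)])
    total = bounds[-1]
    n_frames = int(np.floor(total * params.frame_rate)) + 1
    times = np.arange(n_frames) / params.frame_rate
    seg_idx = np.clip(np.searchsorted(bounds, times, side="right") - 1,
                      0, n_cycles_total - 1)
    phi_start = np.concatenate([[-PHASE_MARGIN * 2.0 * np.pi],
                                2.0 * np.pi * np.arange(n_cycles_total - 1)])
    phi = phi_start[seg_idx] + (times - bounds[seg_idx]) / seg_times[seg_idx] * seg_spans[seg_idx]

    basis = _harmonic_basis(phi, H)                      # (C, F)
    coeff = coeff_subj[None] + coeff_noise[seg_idx]      # (F, 16, 3, C)
    values = np.einsum("fijc,cf->fij", coeff, basis)     # (F, 16, 3)
    curves = {name: _unit(values[:, i, :]) for i, name in enumerate(CURVE_NAMES)}

    L = {k: v * scale for k, v in SEGMENT_LENGTHS.items()}
    root = np.stack([
        speed * times,
        ROOT_SWAY * scale * np.sin(phi),
        ROOT_HEIGHT * scale + ROOT_BOB * scale * np.cos(2.0 * phi),
    ], axis=-1)

    pos = np.empty((n_frames, 17, 3))

    def put(label, xyz):
        pos[:, POINT_INDEX[label], :] = xyz

    mid_shoulder = root + L["trunk"] * curves["trunk"]
    put("head", mid_shoulder + L["neck"] * curves["neck"])
    l_sh = mid_shoulder + L["clavicle"] * curves["l_clavicle"]
    r_sh = mid_shoulder - L["clavicle"] * curves["l_clavicle"]
    put("l_shoulder", l_sh)
    put("r_shoulder", r_sh)
    l_el = l_sh + L["upper_arm"] * curves["l_upper_arm"]
    r_el = r_sh + L["upper_arm"] * curves["r_upper_arm"]
    put("l_elbow", l_el)
    put("r_elbow", r_el)
    put("l_wrist", l_el + L["forearm"] * curves["l_forearm"])
    put("r_wrist", r_el + L["forearm"] * curves["r_forearm"])
    l_hip = root + L["pelvis_half"] * curves["pelvis"]
    r_hip = root - L["pelvis_half"] * curves["pelvis"]
    put("l_hip", l_hip)
    put("r_hip", r_hip)
    l_kn = l_hip + L["thigh"] * curves["l_thigh"]
    r_kn = r_hip + L["thigh"] * curves["r_thigh"]
    put("l_knee", l_kn)
    put("r_knee", r_kn)
    l_ank = l_kn + L["shank"] * curves["l_shank"]
    r_ank = r_kn + L["shank"] * curves["r_shank"]
    put("l_ankle", l_ank)
    put("r_ankle", r_ank)
    put("l_toe", l_ank + L["foot"] * curves["l_foot"])
    put("r_toe", r_ank + L["foot"] * curves["r_foot"])
    put("l_heel", l_ank - L["heel_link"] * curves["l_heel_link"])
    put("r_heel", r_ank - L["heel_link"] * curves["r_heel_link"])

    c, s = np.cos(heading), np.sin(heading)
    rot = np.array([[c, -s, 0.0], [s, c, 0.0], [0.0, 0.0, 1.0]])
    pos = pos @ rot.T
    return PointFrameSeries(frame_rate=params.frame_rate, times=times, positions=pos)


def generate_marker_cohort(
    params: CohortParams,
) -> tuple[dict[tuple[str, str], PointFrameSeries], pd.DataFrame]:
    """Simulate marker-level walking trials for a whole cohort.

    Returns
    -------
    trials:
        Mapping ``(subject_id, trial_id) -> PointFrameSeries``.  Trials walk
        in a random heading, so :func:`gaituniq.kinematics.align_to_lab` is
        exercised downstream.
    registry:
        One row per trial: subject_id, trial_id, sex (placeholder ``NA``),
        walking speed (m/s), subject mean cycle duration (s).

    Deterministic for a fixed ``params.seed``.
    """
    params.validate()
    rng = np.random.default_rng(params.seed)
    mean = mean_template(params.n_harmonics)
    dur_rel = params.cycle_duration_sd / params.cycle_duration_mean

    trials: dict[tuple[str, str], PointFrameSeries] = {}
    rows = []
    for s in range(params.n_subjects):
        subject_id = f"S{s + 1:04d}"
        coeff_subj = mean + params.inter_subject_sd * rng.standard_normal(mean.shape)
        scale = float(np.clip(1.0 + 0.04 * rng.standard_normal(), 0.85, 1.15))
        speed = float(max(0.5, params.walking_speed_mean
                          + params.walking_speed_sd * rng.standard_normal()))
        subj_duration = params.cycle_duration_mean * float(
            np.exp(dur_rel * rng.standard_normal() - 0.5 * dur_rel**2))
        for t in range(params.n_trials_per_subject):
            trial_id = f"T{t + 1}"
            series = _trial_series(params, coeff_subj, scale, speed,
                                   subj_duration, rng)
            trials[(subject_id, trial_id)] = series
            rows.append(dict(subject_id=subject_id, trial_id=trial_id,
                             sex="NA", speed=speed,
                             cycle_duration=subj_duration))
    registry = pd.DataFrame(rows)
    return trials, registry


def generate_feature_cohort(
    n_subjects: int,
    n_per_subject: int,
    n_components: int,
    between_sd_per_component,
    within_sd_per_component,
    seed: int,
) -> tuple[np.ndarray, np.ndarray]:
    """Draw a PCA-score-like feature cohort with known variance structure.

    Subject means are drawn ``N(0, between_sd**2)`` per component;
    observations around each mean with ``N(0, within_sd**2)``.

    Returns
    -------
    scores:
        ``(n_subjects * n_per_subject, n_components)`` feature matrix.
    labels:
        subject-id string per row.
    """
    if n_subjects < 1 or n_per_subject < 1 or n_components < 1:
        raise SimulationError("counts must be >= 1")
    between = np.asarray(between_sd_per_component, dtype=float)
    within = np.asarray(within_sd_per_component, dtype=float)
    if between.shape != (n_components,) or within.shape != (n_components,):
        raise SimulationError("SD vectors must have length n_components")
    if np.any(between < 0) or np.any(within < 0):
        raise SimulationError("SDs must be >= 0")
    rng = np.random.default_rng(seed)
    means = between * rng.standard_normal((n_subjects, n_components))
    obs = means[:, None, :] + within * rng.standard_normal(
        (n_subjects, n_per_subject, n_components))
    labels = np.repeat([f"S{s + 1:04d}" for s in range(n_subjects)], n_per_subject)
    return obs.reshape(n_subjects * n_per_subject, n_components), labels
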