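"""Anatomical point labels and the canonical 16-segment body model.

Full-body gait capture is reduced to 17 labeled anatomical points (7 in the
upper body, 10 in the lower body).  Two auxiliary points — mid-hip and
mid-shoulder — are derived as left/right midpoints so that the trunk, neck
and clavicle segments can be defined.  Sixteen segments connect the points;
each segment is oriented proximal → distal.
"""
from __future__ import annotations

from typing import NamedTuple

#: Canonical label order used by every array with a point axis.
POINT_LABELS: tuple[str, ...] = (
    "head",
    "l_shoulder", "r_shoulder",
    "l_elbow", "r_elbow",
    "l_wrist", "r_wrist",
    "l_hip", "r_hip",
    "l_knee", "r_knee",
    "l_ankle", "r_ankle",
    "l_toe", "r_toe",
    "l_heel", "r_heel",
)

MID_HIP = "mid_hip"
MID_SHOULDER = "mid_shoulder"

#: 17 measured points followed by the two derived midpoints.
AUGMENTED_LABELS: tuple[str, ...] = POINT_LABELS + (MID_HIP, MID_SHOULDER)

POINT_INDEX = {label: i for i, label in enumerate(POINT_LABELS)}
AUGMENTED_INDEX = {label: i for i, label in enumerate(AUGMENTED_LABELS)}


class Segment(NamedTuple):
    """A rigid body segment oriented from its proximal to its distal point."""

    name: str
    proximal: str
    distal: str


#: The canonical 16 segments.  The heel links point heel → ankle so that the
#: foot region contributes two distinct orientations (ankle→toe, heel→ankle).
DEFAULT_SEGMENTS: tuple[Segment, ...] = (
    Segment("trunk", MID_HIP, MID_SHOULDER),
    Segment("neck", MID_SHOULDER, "head"),
    Segment("l_clavicle", MID_SHOULDER, "l_shoulder"),
    Segment("r_clavicle", MID_SHOULDER, "r_shoulder"),
    Segment("l_upper_arm", "l_shoulder", "l_elbow"),
    Segment("r_upper_arm", "r_shoulder", "r_elbow"),
    Segment("l_forearm", "l_elbow", "l_wrist"),
    Segment("r_forearm", "r_elbow", "r_wrist"),
    Segment("l_thigh", "l_hip", "l_knee"),
    Segment("r_thigh", "r_hip", "r_knee"),
    Segment("l_shank", "l_knee", "l_ankle"),
    Segment("r_shank", "r_knee", "r_ankle"),
    Segment("l_foot", "l_ankle", "l_toe"),
    Segment("r_foot", "r_ankle", "r_toe"),
    Segment("l_heel_link", "l_heel", "l_ankle"),
    Segment("r_heel_link", "r_heel", "r_ankle"),
)


class SegmentSet:
    """An ordered, validated collection of exactly 16 body segments.

    Parameters
    ----------
    segments:
        Iterable of :class:`Segment`.  Defaults to the canonical list.

    Raises
    ------
    ValueError
        If the count is not 16, a label is unknown, or some measured
        anatomical point participates in no segment.
    """

    def __init__(self, segments=DEFAULT_SEGMENTS):
        segments = tuple(Segment(*s) for s in segments)
        if len(segments) != 16:
            raise ValueError(f"expected 16 segments, got {len(segments)}")
        used = set()
        for seg in segments:
            for label in (seg.proximal, seg.distal):
                if label not in AUGMENTED_INDEX:
                    raise ValueError(f"unknown point label {label!r} in segment {seg.name!r}")
                used.add(label)
        missing = set(POINT_LABELS) - used
        if missing:
            raise ValueError(f"anatomical points in no segment: {sorted(missing)}")
        self.segments = segments
        self.names = tuple(s.name for s in segments)

    def __len__(self) -> int:
        return 16

    def __iter__(self):
        return iter(self.segments)

    def __getitem__(self, i) -> Segment:
        return self.segments[i]

    def endpoint_indices(self) -> tuple[list[int], list[int]]:
        """Proximal and distal indices into the augmented (19-point) array."""
        prox = [AUGMENTED_INDEX[s.proximal] for s in self.segments]
        dist = [AUGMENTED_INDEX[s.distal] for s in self.segments]
        return prox, dist
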