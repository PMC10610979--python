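"""Joint-angle geometry.

For a triplet of landmarks A, B, C (B the vertex) the joint angle is the
angle between the two limb vectors AB = B - A and BC = C - B,

    theta = acos( (AB . BC) / (|AB| |BC|) ) * 180 / pi ,

computed in pixel space after rescaling the normalized coordinates by the
frame dimensions. Under this convention a perfectly straight limb scores
0 deg (the vectors are parallel); the familiar interior angle at the
vertex is 180 - theta. Angles are invariant to translation, rotation and
uniform scaling of the three points, but not to anisotropic rescaling —
which is why pixel- and normalized-space angles differ whenever the frame
is not square.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .errors import DegenerateGeometryError, DomainError
from .pose_topology import ANGLE_ORDER, Landmark, PoseFrame, Topology, default_topology, validate_frame

__all__ = [
    "PixelPoint",
    "LimbVector",
    "AngleSample",
    "to_pixels",
    "limb_vectors",
    "joint_angle",
    "frame_angles",
]

PixelPoint = tuple[float, float]
LimbVector = tuple[float, float]


@dataclass(frozen=True)
class AngleSample:
    """One angle measurement at one time point; ``theta_deg`` is None when
    the triplet could not be measured (missing/occluded/degenerate)."""

    angle: Landmark
    time_s: float
    theta_deg: float | None

    @property
    def missing(self) -> bool:
        return self.theta_deg is None


def to_pixels(point: tuple[float, float], width_px: int, height_px: int) -> PixelPoint:
    """Map a normalized (x, y) in [0,1]^2 to pixel coordinates."""
    x, y = point
    if not (0.0 <= x <= 1.0 and 0.0 <= y <= 1.0):
        raise DomainError(f"normalized coordinates must lie in [0,1]: {(x, y)!r}")
    if width_px <= 0 or height_px <= 0:
        raise DomainError(f"frame dimensions must be positive: {(width_px, height_px)!r}")
    return (x * width_px, y * height_px)


def limb_vectors(a: PixelPoint, b: PixelPoint, c: PixelPoint) -> tuple[LimbVector, LimbVector]:
    """The two limb vectors AB = B - A and BC = C - B."""
    ab = (b[0] - a[0], b[1] - a[1])
    bc = (c[0] - b[0], c[1] - b[1])
    return ab, bc


def joint_angle(a: PixelPoint, b: PixelPoint, c: PixelPoint) -> float:
    """Angle in degrees between limb vectors AB and BC, in [0, 180].

    Raises :class:`DegenerateGeometryError` when either vector has zero
    length (coincident points); the cosine argument is clamped to [-1, 1]
    to absorb floating-point overshoot.
    """
    ab, bc = limb_vectors(a, b, c)
    norm_ab = math.hypot(*ab)
    norm_bc = math.hypot(*bc)
    if norm_ab == 0.0:
        raise DegenerateGeometryError("limb vector AB collapsed: A and B coincide")
    if norm_bc == 0.0:
        raise DegenerateGeometryError("limb vector BC collapsed: B and C coincide")
    dot = ab[0] * bc[0] + ab[1] * bc[1]
    cos_theta = dot / (norm_ab * norm_bc)
    cos_theta = max(-1.0, min(1.0, cos_theta))
    return math.degrees(math.acos(cos_theta))


def frame_angles(
    frame: PoseFrame,
    topology: Topology | None = None,
    min_visibility: float | None = None,
) -> list[AngleSample]:
    """Measure all 12 angles of one frame, in canonical reporting order.

    An angle whose triplet is not fully usable (a landmark absent, below
    the visibility threshold, or geometrically degenerate) yields a
    missing sample rather than an error.
    """
    topo = topology or default_topology()
    from .pose_topology import DEFAULT_MIN_VISIBILITY

    vis = DEFAULT_MIN_VISIBILITY if min_visibility is None else min_visibility
    report = validate_frame(frame, vis)
    usable = report.present
    samples: list[AngleSample] = []
    for name in ANGLE_ORDER:
        t = topo.triplet_for(name)
        if {t.first, t.vertex, t.last} <= usable:
            pts = [
                to_pixels(frame.points[lm], frame.width_px, frame.height_px)
                for lm in (t.first, t.vertex, t.last)
            ]
            try:
                theta = joint_angle(*pts)
            except DegenerateGeometryError:
                theta = None
        else:
            theta = None
        samples.append(AngleSample(angle=name, time_s=frame.time_s, theta_deg=theta))
    return samples
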