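"""The 12-landmark body topology and per-angle vertex triplets.

A pose frame carries up to 12 named 2D landmarks (shoulders, elbows,
wrists, hips, knees, ankles; both sides) in normalized image coordinates.
Each monitored joint angle is defined by a triplet of landmarks
(A, B, C) whose vertex B gives the angle its name; the default triplet
table ships as package data (``data/topology.yaml``) and can be replaced
by the user.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from importlib import resources
from pathlib import Path

import yaml

from .errors import DomainError, TopologyError

__all__ = [
    "Landmark",
    "ANGLE_ORDER",
    "SKELETON_EDGES",
    "MEASUREMENT_EDGES",
    "AngleTriplet",
    "Topology",
    "default_topology",
    "PoseFrame",
    "VisibilityReport",
    "validate_frame",
    "DEFAULT_MIN_VISIBILITY",
]

DEFAULT_MIN_VISIBILITY = 0.5


class Landmark(str, Enum):
    """The 12 monitored body landmarks.

    Values are the field's standard abbreviations (SH=shoulder, EL=elbow,
    W=wrist, H=hip, K=knee, AN=ankle; trailing L/R = body side).
    """

    SHL = "SHL"
    SHR = "SHR"
    ELL = "ELL"
    ELR = "ELR"
    WL = "WL"
    WR = "WR"
    HL = "HL"
    HR = "HR"
    KL = "KL"
    KR = "KR"
    ANL = "ANL"
    ANR = "ANR"

    @property
    def side(self) -> str:
        """'L' or 'R'."""
        return self.value[-1]

    @property
    def mirror(self) -> "Landmark":
        """The contralateral landmark (total left/right pairing)."""
        other = self.value[:-1] + ("R" if self.side == "L" else "L")
        return Landmark(other)

    @property
    def display_index(self) -> int:
        """1-based index used in user-facing output (left shoulder = 1 ...)."""
        return _DISPLAY_INDEX[self]

    @classmethod
    def parse(cls, name: str) -> "Landmark":
        try:
            return cls(name)
        except ValueError:
            raise TopologyError(
                f"unknown landmark/angle identifier {name!r}; "
                f"expected one of {[m.value for m in cls]}"
            ) from None


# User-facing numbering: left/right alternating, proximal to distal
# (1 left shoulder, 2 right shoulder, ... 11 left ankle, 12 right ankle).
_DISPLAY_INDEX = {
    Landmark.SHL: 1, Landmark.SHR: 2,
    Landmark.ELL: 3, Landmark.ELR: 4,
    Landmark.WL: 5, Landmark.WR: 6,
    Landmark.HL: 7, Landmark.HR: 8,
    Landmark.KL: 9, Landmark.KR: 10,
    Landmark.ANL: 11, Landmark.ANR: 12,
}

#: Canonical reporting order for the 12 angles; fixes the angle-CSV column order.
ANGLE_ORDER: tuple[Landmark, ...] = (
    Landmark.KR, Landmark.KL, Landmark.ANR, Landmark.ANL,
    Landmark.HR, Landmark.HL, Landmark.ELR, Landmark.ELL,
    Landmark.SHR, Landmark.SHL, Landmark.WR, Landmark.WL,
)


def _edge(a: Landmark, b: Landmark) -> frozenset[Landmark]:
    return frozenset((a, b))


#: Anatomical skeleton adjacency within the 12-point set.
SKELETON_EDGES: frozenset[frozenset[Landmark]] = frozenset(
    _edge(*pair)
    for pair in [
        (Landmark.SHL, Landmark.ELL), (Landmark.ELL, Landmark.WL),
        (Landmark.SHR, Landmark.ELR), (Landmark.ELR, Landmark.WR),
        (Landmark.SHL, Landmark.HL), (Landmark.SHR, Landmark.HR),
        (Landmark.HL, Landmark.KL), (Landmark.KL, Landmark.ANL),
        (Landmark.HR, Landmark.KR), (Landmark.KR, Landmark.ANR),
        (Landmark.SHL, Landmark.SHR), (Landmark.HL, Landmark.HR),
    ]
)

#: Auxiliary measurement edges used by the default wrist/ankle triplets
#: (those vertices have a single skeletal neighbour, so their angle closes
#: against the same-side hip).
MEASUREMENT_EDGES: frozenset[frozenset[Landmark]] = SKELETON_EDGES | frozenset(
    _edge(*pair)
    for pair in [
        (Landmark.WL, Landmark.HL), (Landmark.WR, Landmark.HR),
        (Landmark.ANL, Landmark.HL), (Landmark.ANR, Landmark.HR),
    ]
)


@dataclass(frozen=True)
class AngleTriplet:
    """Three landmarks (A=first, B=vertex, C=last) defining one named angle."""

    name: Landmark
    first: Landmark
    vertex: Landmark
    last: Landmark

    def __post_init__(self):
        if len({self.first, self.vertex, self.last}) != 3:
            raise TopologyError(
                f"triplet for {self.name.value} must have three distinct "
                f"landmarks, got ({self.first.value}, {self.vertex.value}, "
                f"{self.last.value})"
            )
        if self.vertex is not self.name:
            raise TopologyError(
                f"angle {self.name.value} must be labelled by its vertex; "
                f"got vertex {self.vertex.value}"
            )


@dataclass(frozen=True)
class Topology:
    """A full triplet table: one :class:`AngleTriplet` per monitored angle."""

    triplets: dict[Landmark, AngleTriplet]

    def __post_init__(self):
        missing = set(Landmark) - set(self.triplets)
        if missing:
            raise TopologyError(
                "triplet table must cover all 12 angles; missing "
                f"{sorted(m.value for m in missing)}"
            )
        extra = set(self.triplets) - set(Landmark)
        if extra:
            raise TopologyError(f"unexpected triplet keys: {sorted(extra)}")
        for name, t in self.triplets.items():
            if t.name is not name:
                raise TopologyError(
                    f"triplet stored under {name.value} is labelled {t.name.value}"
                )
            for a, b in ((t.first, t.vertex), (t.vertex, t.last)):
                if _edge(a, b) not in MEASUREMENT_EDGES:
                    raise TopologyError(
                        f"triplet for {name.value}: ({a.value}, {b.value}) is not "
                        "a declared skeleton/measurement edge"
                    )

    def triplet_for(self, name: "Landmark | str") -> AngleTriplet:
        """Return the fixed triplet measuring the named angle."""
        key = name if isinstance(name, Landmark) else Landmark.parse(name)
        return self.triplets[key]

    @classmethod
    def from_mapping(cls, mapping: dict) -> "Topology":
        triplets = {}
        for name, abc in mapping.items():
            key = Landmark.parse(str(name))
            if len(abc) != 3:
                raise TopologyError(
                    f"triplet for {key.value} must list exactly three landmarks"
                )
            a, b, c = (Landmark.parse(str(x)) for x in abc)
            triplets[key] = AngleTriplet(name=key, first=a, vertex=b, last=c)
        return cls(triplets)

    @classmethod
    def from_yaml(cls, path: "str | Path") -> "Topology":
        with open(path, "r", encoding="utf-8") as fh:
            mapping = yaml.safe_load(fh)
        if not isinstance(mapping, dict):
            raise TopologyError(f"topology file {path} must map angle -> [A, B, C]")
        return cls.from_mapping(mapping)


_DEFAULT_TOPOLOGY: Topology | None = None


def default_topology() -> Topology:
    """The packaged triplet table (cached)."""
    global _DEFAULT_TOPOLOGY
    if _DEFAULT_TOPOLOGY is None:
        text = resources.files("napscope").joinpath("data/topology.yaml").read_text()
        _DEFAULT_TOPOLOGY = Topology.from_mapping(yaml.safe_load(text))
    return _DEFAULT_TOPOLOGY


@dataclass
class PoseFrame:
    """One timestamped set of normalized landmarks.

    ``points`` maps landmark -> (x, y) with both coordinates normalized to
    [0, 1] relative to the frame; absent landmarks are simply missing keys.
    ``visibility`` defaults to 1.0 for landmarks the backend does not score.
    """

    frame_index: int
    time_s: float
    width_px: int
    height_px: int
    points: dict[Landmark, tuple[float, float]]
    visibility: dict[Landmark, float] = field(default_factory=dict)

    def __post_init__(self):
        if self.frame_index < 0:
            raise DomainError(f"frame_index out of domain: {self.frame_index!r}")
        if self.time_s < 0:
            raise DomainError(f"time_s out of domain: {self.time_s!r}")
        if self.width_px <= 0 or self.height_px <= 0:
            raise DomainError(
                f"frame dimensions out of domain: {(self.width_px, self.height_px)!r}"
            )
        for lm, (x, y) in self.points.items():
            if not (0.0 <= x <= 1.0 and 0.0 <= y <= 1.0):
                raise DomainError(f"points[{lm.value}] out of domain: {(x, y)!r}")

    def visibility_of(self, lm: Landmark) -> float:
        return self.visibility.get(lm, 1.0)


@dataclass(frozen=True)
class VisibilityReport:
    """Per-landmark presence report for one frame (report-only; never raises)."""

    present: frozenset[Landmark]
    missing: frozenset[Landmark]
    below_threshold: frozenset[Landmark]
    min_visibility: float

    @property
    def complete(self) -> bool:
        """True iff all 12 landmarks are present with sufficient visibility."""
        return not self.missing and not self.below_threshold


def validate_frame(
    frame: PoseFrame, min_visibility: float = DEFAULT_MIN_VISIBILITY
) -> VisibilityReport:
    """Check which of the 12 required landmarks a frame actually provides.

    A landmark counts as usable when it is present and its visibility score
    is at least ``min_visibility``. Raising the threshold can only shrink
    the usable set (monotone).
    """
    missing, below, present = set(), set(), set()
    for lm in Landmark:
        if lm not in frame.points:
            missing.add(lm)
        elif frame.visibility_of(lm) < min_visibility:
            below.add(lm)
        else:
            present.add(lm)
    return VisibilityReport(
        present=frozenset(present),
        missing=frozenset(missing),
        below_threshold=frozenset(below),
        min_visibility=min_visibility,
    )
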