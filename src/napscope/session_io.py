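"""File formats and pose-backend adaptation.

Three plain-text formats flow through the pipeline:

* **landmark JSON Lines** — one pose frame per line with keys ``frame``,
  ``time_s``, ``width``, ``height`` and ``points`` mapping landmark name
  to ``[x, y, visibility]`` (normalized coordinates);
* **angle CSV** — one row per frame (``frame``, ``time_s``, then the 12
  angle columns in the fixed order KR, KL, ANR, ANL, HR, HL, ELR, ELL,
  SHR, SHL, WR, WL); empty cells mark missing angles. Append mode is
  supported for incremental sessions;
* **indices / design CSVs** — flat tables written with pandas.

Pose estimation itself is delegated to a pluggable backend satisfying
:class:`PoseEstimatorContract`: any callable mapping an image frame to
named normalized landmarks (or ``None`` on failure). Video decoding is
likewise the backend's concern; the package consumes any iterable of
decodable frames, so it never links against a codec library.
"""

from __future__ import annotations

import json
import math
from pathlib import Path
from typing import Callable, Iterable, Iterator, Protocol

import numpy as np
import pandas as pd

from .angle_engine import AngleSample, frame_angles
from .errors import FormatError, InputError, ParseError
from .movement_indices import AngleSeries, DEFAULT_FPS
from .pose_topology import ANGLE_ORDER, Landmark, PoseFrame, Topology

__all__ = [
    "ANGLE_CSV_COLUMNS",
    "PoseEstimatorContract",
    "angle_table",
    "write_angle_csv",
    "read_angle_csv",
    "write_pose_jsonl",
    "read_pose_jsonl",
    "extract_from_stream",
    "extract_from_video",
]

#: Exact angle-CSV header.
ANGLE_CSV_COLUMNS = ["frame", "time_s"] + [a.value for a in ANGLE_ORDER]


class PoseEstimatorContract(Protocol):
    """A pose backend: image frame -> named normalized landmarks.

    Returns a mapping ``name -> (x, y, visibility)`` with x, y in [0, 1],
    or ``None`` when no pose was found. Color-space conversion (e.g. to
    RGB) is the adapter's responsibility.
    """

    def __call__(self, image) -> dict | None: ...


def angle_table(samples_per_frame: Iterable[list[AngleSample]], fps: float = DEFAULT_FPS) -> pd.DataFrame:
    """Stack per-frame angle samples into an angle-CSV-shaped DataFrame."""
    rows = []
    for i, samples in enumerate(samples_per_frame):
        row: dict = {"frame": i, "time_s": samples[0].time_s if samples else i / fps}
        for s in samples:
            row[s.angle.value] = np.nan if s.theta_deg is None else s.theta_deg
        rows.append(row)
    return pd.DataFrame(rows, columns=ANGLE_CSV_COLUMNS)


def write_angle_csv(table: pd.DataFrame, path, append: bool = False) -> None:
    """Write an angle table as UTF-8 CSV ('.' decimal, %.6f floats).

    ``append=True`` adds rows to an existing file without repeating the
    header (the incremental-session mode); by default the file is
    truncated.
    """
    missing = [c for c in ANGLE_CSV_COLUMNS if c not in table.columns]
    if missing:
        raise FormatError(f"angle table missing columns: {missing}")
    path = Path(path)
    exists = append and path.exists() and path.stat().st_size > 0
    table[ANGLE_CSV_COLUMNS].to_csv(
        path,
        mode="a" if exists else "w",
        header=not exists,
        index=False,
        float_format="%.6f",
        encoding="utf-8",
    )


def read_angle_csv(path, fps: float | None = None) -> dict[Landmark, AngleSeries]:
    """Read an angle CSV back into one :class:`AngleSeries` per angle.

    The header must match the documented schema exactly (first mismatched
    column is named); a non-numeric cell raises :class:`ParseError` with
    its 1-based line number. Empty cells become missing samples.
    """
    path = Path(path)
    if not path.exists():
        raise InputError(f"no such file: {path}")
    with open(path, "r", encoding="utf-8") as fh:
        header_line = fh.readline().rstrip("\n\r")
        header = header_line.split(",")
        for i, (got, want) in enumerate(zip(header, ANGLE_CSV_COLUMNS)):
            if got != want:
                raise FormatError(
                    f"{path}: header column {i + 1} is {got!r}, expected {want!r}"
                )
        if len(header) != len(ANGLE_CSV_COLUMNS):
            raise FormatError(
                f"{path}: expected {len(ANGLE_CSV_COLUMNS)} columns, got {len(header)}"
            )
        times, values = [], []
        for lineno, line in enumerate(fh, start=2):
            line = line.rstrip("\n\r")
            if not line:
                continue
            cells = line.split(",")
            if len(cells) != len(ANGLE_CSV_COLUMNS):
                raise ParseError(
                    f"{path}: line {lineno}: expected {len(ANGLE_CSV_COLUMNS)} cells, "
                    f"got {len(cells)}", line=lineno,
                )
            row = []
            for col, cell in zip(ANGLE_CSV_COLUMNS, cells):
                if cell == "":
                    row.append(math.nan)
                    continue
                try:
                    row.append(float(cell))
                except ValueError:
                    raise ParseError(
                        f"{path}: line {lineno}: non-numeric cell {cell!r} "
                        f"in column {col!r}", line=lineno,
                    ) from None
            times.append(row[1])
            values.append(row[2:])
    if not times:
        raise InputError(f"{path}: no data rows")
    t = np.array(times)
    v = np.array(values)
    if fps is None:
        dts = np.diff(t)
        fps = float(1.0 / np.median(dts)) if dts.size else DEFAULT_FPS
    return {
        angle: AngleSeries(angle=angle, times_s=t, values_deg=v[:, j], fps=fps)
        for j, angle in enumerate(ANGLE_ORDER)
    }


def write_pose_jsonl(frames: Iterable[PoseFrame], path) -> None:
    """Write a landmark stream as JSON Lines."""
    with open(path, "w", encoding="utf-8") as fh:
        for f in frames:
            rec = {
                "frame": f.frame_index,
                "time_s": round(f.time_s, 6),
                "width": f.width_px,
                "height": f.height_px,
                "points": {
                    lm.value: [xy[0], xy[1], f.visibility_of(lm)]
                    for lm, xy in f.points.items()
                },
            }
            fh.write(json.dumps(rec) + "\n")


def read_pose_jsonl(path) -> Iterator[PoseFrame]:
    """Stream pose frames back from a JSON Lines file."""
    path = Path(path)
    if not path.exists():
        raise InputError(f"no such file: {path}")
    with open(path, "r", encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            try:
                rec = json.loads(line)
            except json.JSONDecodeError as e:
                raise ParseError(f"{path}: line {lineno}: invalid JSON ({e})", line=lineno) from None
            try:
                points, visibility = {}, {}
                for name, xyv in rec["points"].items():
                    lm = Landmark.parse(name)
                    points[lm] = (float(xyv[0]), float(xyv[1]))
                    visibility[lm] = float(xyv[2]) if len(xyv) > 2 else 1.0
                yield PoseFrame(
                    frame_index=int(rec["frame"]),
                    time_s=float(rec["time_s"]),
                    width_px=int(rec["width"]),
                    height_px=int(rec["height"]),
                    points=points,
                    visibility=visibility,
                )
            except (KeyError, TypeError, ValueError) as e:
                raise ParseError(f"{path}: line {lineno}: malformed frame ({e})", line=lineno) from None


def extract_from_stream(
    frames: Iterable[PoseFrame],
    topology: Topology | None = None,
    min_visibility: float | None = None,
) -> pd.DataFrame:
    """Measure all angles over a landmark stream -> angle table.

    Incomplete frames contribute rows with missing cells; nothing is
    fabricated. Raises :class:`InputError` on an empty stream.
    """
    rows = []
    for frame in frames:
        samples = frame_angles(frame, topology=topology, min_visibility=min_visibility)
        row: dict = {"frame": frame.frame_index, "time_s": frame.time_s}
        for s in samples:
            row[s.angle.value] = np.nan if s.theta_deg is None else s.theta_deg
        rows.append(row)
    if not rows:
        raise InputError("empty landmark stream: no frames to process")
    return pd.DataFrame(rows, columns=ANGLE_CSV_COLUMNS)


def extract_from_video(
    source: Iterable,
    estimator: PoseEstimatorContract,
    fps: float = DEFAULT_FPS,
    width_px: int = 640,
    height_px: int = 480,
    topology: Topology | None = None,
    min_visibility: float | None = None,
    on_error: Callable[[int, Exception], None] | None = None,
) -> pd.DataFrame:
    """Run a pose backend over decoded video frames and measure angles.

    ``source`` is any iterable of image frames (decoding is the caller's
    or adapter's concern); the estimator maps each image to named
    landmarks. A frame on which the estimator fails (returns ``None`` or
    raises) is recorded with all angles missing — and reported through
    ``on_error`` — never fabricated. Raises :class:`InputError` if the
    source yields no frames.
    """
    def stream() -> Iterator[PoseFrame]:
        for i, image in enumerate(source):
            points: dict[Landmark, tuple[float, float]] = {}
            visibility: dict[Landmark, float] = {}
            try:
                result = estimator(image)
            except Exception as e:  # backend failure: log, mark missing
                if on_error is not None:
                    on_error(i, e)
                result = None
            if result:
                for name, xyv in result.items():
                    lm = Landmark.parse(str(name))
                    points[lm] = (float(xyv[0]), float(xyv[1]))
                    visibility[lm] = float(xyv[2]) if len(xyv) > 2 else 1.0
            yield PoseFrame(
                frame_index=i, time_s=i / fps,
                width_px=width_px, height_px=height_px,
                points=points, visibility=visibility,
            )

    return extract_from_stream(stream(), topology=topology, min_visibility=min_visibility)
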