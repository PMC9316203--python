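"""Outline containers and the file formats the pipeline reads and writes.

An :class:`Outline` is one digitized specimen: an ordered, implicitly closed
sequence of 2D coordinates (the last point is *not* a repeat of the first)
plus specimen/group metadata.  Outlines are always stored counterclockwise;
clockwise input is silently reversed and the reversal recorded in
``provenance``.

Supported interchange formats:

``xy_csv``
    Long-format CSV with columns ``specimen_id, point_index, x, y`` and an
    optional ``group`` column.  Comma-separated, header required, decimal
    point.
``tps``
    TPS outline records (``OUTLINES=``/``POINTS=`` blocks, ``ID=`` field).
    Unknown keys are ignored with a logged warning.
``chc``
    Freeman 8-direction chain codes, one specimen per line:
    ``name x0 y0 n_codes code code ...``.  Lossy for off-grid coordinates
    (quantized to an integer grid); exact for outlines already on the grid.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "Outline",
    "ChainCode",
    "OutlineError",
    "ParseError",
    "signed_area",
    "read_outlines",
    "write_outlines",
    "read_labels",
    "write_labels",
]

# Freeman 8-direction step vectors: 0=E, counterclockwise.
FREEMAN_STEPS = np.array(
    [(1, 0), (1, 1), (0, 1), (-1, 1), (-1, 0), (-1, -1), (0, -1), (1, -1)],
    dtype=int,
)
_STEP_TO_CODE = {tuple(v): i for i, v in enumerate(FREEMAN_STEPS)}


class OutlineError(ValueError):
    """An outline violates a structural invariant."""


class ParseError(OutlineError):
    """A file could not be parsed; carries the offending line number."""

    def __init__(self, message: str, line: int | None = None):
        self.line = line
        if line is not None:
            message = f"line {line}: {message}"
        super().__init__(message)


def signed_area(points: np.ndarray) -> float:
    """Shoelace signed area of an implicitly closed polygon (positive = CCW)."""
    x, y = points[:, 0], points[:, 1]
    return 0.5 * float(np.sum(x * np.roll(y, -1) - np.roll(x, -1) * y))


@dataclass
class Outline:
    """One specimen's closed contour with metadata.

    Validation on construction enforces: at least 3 points, no two
    consecutive identical points, nonzero signed area, counterclockwise
    traversal (clockwise input is reversed, noted in ``provenance``).
    """

    specimen_id: str
    points: np.ndarray
    group: str = ""
    provenance: str = ""

    def __post_init__(self) -> None:
        pts = np.asarray(self.points, dtype=float)
        if pts.ndim != 2 or pts.shape[1] != 2:
            raise OutlineError(
                f"{self.specimen_id}: points must be an (n, 2) array, got {pts.shape}"
            )
        if len(pts) < 3:
            raise OutlineError(f"{self.specimen_id}: outline needs >= 3 points, got {len(pts)}")
        # implicit closure: drop a duplicated terminal point
        if np.allclose(pts[0], pts[-1]):
            pts = pts[:-1]
        if len(pts) < 3:
            raise OutlineError(f"{self.specimen_id}: outline needs >= 3 distinct points")
        deltas = np.diff(pts, axis=0)
        if np.any(np.all(deltas == 0.0, axis=1)):
            raise OutlineError(f"{self.specimen_id}: consecutive duplicate points")
        area = signed_area(pts)
        if area == 0.0:
            raise OutlineError(f"{self.specimen_id}: degenerate outline (zero signed area)")
        if area < 0.0:
            pts = pts[::-1].copy()
            note = "reversed-to-ccw"
            self.provenance = f"{self.provenance};{note}" if self.provenance else note
        self.points = np.ascontiguousarray(pts)

    @property
    def n_points(self) -> int:
        return len(self.points)

    @property
    def area(self) -> float:
        return signed_area(self.points)

    def perimeter(self) -> float:
        closed = np.vstack([self.points, self.points[:1]])
        return float(np.sum(np.hypot(*np.diff(closed, axis=0).T)))

    def closed_points(self) -> np.ndarray:
        """Points with the first vertex repeated at the end."""
        return np.vstack([self.points, self.points[:1]])

    def centroid(self) -> np.ndarray:
        return self.points.mean(axis=0)


@dataclass
class ChainCode:
    """Freeman 8-direction chain code of a closed grid contour."""

    start: tuple[int, int]
    codes: list[int] = field(default_factory=list)

    def __post_init__(self) -> None:
        codes = [int(c) for c in self.codes]
        if any(c < 0 or c > 7 for c in codes):
            raise OutlineError("chain codes must be in 0..7")
        net = FREEMAN_STEPS[codes].sum(axis=0) if codes else np.zeros(2, int)
        if not np.array_equal(net, [0, 0]):
            raise OutlineError(f"chain code not closed: net displacement {tuple(net)}")
        self.codes = codes

    def to_points(self) -> np.ndarray:
        steps = FREEMAN_STEPS[self.codes]
        pts = np.vstack([np.array(self.start, int), np.array(self.start, int) + np.cumsum(steps, axis=0)])
        return pts[:-1].astype(float)  # last point == start


# ---------------------------------------------------------------------------
# readers
# ---------------------------------------------------------------------------


def read_outlines(path: str | Path, format: str) -> list[Outline]:
    """Read outlines from *path* in the named *format* (xy_csv | tps | chc)."""
    path = Path(path)
    if format == "xy_csv":
        outlines = _read_xy_csv(path)
    elif format == "tps":
        outlines = _read_tps(path)
    elif format == "chc":
        outlines = _read_chc(path)
    else:
        raise ValueError(f"unknown outline format: {format!r}")
    seen: set[str] = set()
    for o in outlines:
        if o.specimen_id in seen:
            raise ParseError(f"duplicate specimen_id {o.specimen_id!r} in {path}")
        seen.add(o.specimen_id)
    return outlines


def _read_xy_csv(path: Path) -> list[Outline]:
    df = pd.read_csv(path)
    required = {"specimen_id", "point_index", "x", "y"}
    missing = required - set(df.columns)
    if missing:
        raise ParseError(f"xy_csv missing columns {sorted(missing)} in {path}", line=1)
    has_group = "group" in df.columns
    outlines = []
    for sid, block in df.groupby("specimen_id", sort=False):
        block = block.sort_values("point_index")
        group = str(block["group"].iloc[0]) if has_group else ""
        try:
            outlines.append(
                Outline(str(sid), block[["x", "y"]].to_numpy(float), group=group)
            )
        except OutlineError as exc:
            raise ParseError(f"{path}: {exc}", line=int(block.index[0]) + 2) from exc
    return outlines


def _read_tps(path: Path) -> list[Outline]:
    outlines: list[Outline] = []
    lines = Path(path).read_text().splitlines()
    i = 0
    while i < len(lines):
        line = lines[i].strip()
        i += 1
        if not line:
            continue
        key, _, value = line.partition("=")
        key = key.strip().upper()
        if key != "OUTLINES":
            logger.warning("tps: ignoring unknown key %r at line %d", key, i)
            continue
        n_outlines = int(value)
        for _ in range(n_outlines):
            while i < len(lines) and not lines[i].strip().upper().startswith("POINTS"):
                i += 1
            if i >= len(lines):
                raise ParseError("OUTLINES block without POINTS record", line=i)
            n_pts = int(lines[i].split("=")[1])
            i += 1
            pts = []
            for _ in range(n_pts):
                if i >= len(lines):
                    raise ParseError("truncated POINTS block", line=i)
                xy = lines[i].split()
                if len(xy) != 2:
                    raise ParseError(f"expected 'x y', got {lines[i]!r}", line=i + 1)
                pts.append((float(xy[0]), float(xy[1])))
                i += 1
            sid = f"outline_{len(outlines)}"
            # trailing metadata lines until next OUTLINES= or EOF
            while i < len(lines):
                nxt = lines[i].strip()
                if not nxt:
                    i += 1
                    continue
                k, _, v = nxt.partition("=")
                if k.strip().upper() == "OUTLINES":
                    break
                if k.strip().upper() == "ID":
                    sid = v.strip()
                else:
                    logger.warning("tps: ignoring unknown key %r at line %d", k, i + 1)
                i += 1
            try:
                outlines.append(Outline(sid, np.array(pts)))
            except OutlineError as exc:
                raise ParseError(f"{path}: {exc}", line=i) from exc
    return outlines


def _read_chc(path: Path) -> list[Outline]:
    outlines = []
    for lineno, raw in enumerate(Path(path).read_text().splitlines(), start=1):
        tokens = raw.split()
        if not tokens:
            continue
        if len(tokens) < 4:
            raise ParseError(f"chc record too short: {raw!r}", line=lineno)
        name = tokens[0]
        try:
            x0, y0, n = int(tokens[1]), int(tokens[2]), int(tokens[3])
            codes = [int(t) for t in tokens[4:]]
        except ValueError as exc:
            raise ParseError(f"chc record not numeric: {raw!r}", line=lineno) from exc
        if len(codes) != n:
            raise ParseError(
                f"chc record declares {n} codes but carries {len(codes)}", line=lineno
            )
        try:
            chain = ChainCode((x0, y0), codes)
            outlines.append(Outline(name, chain.to_points()))
        except OutlineError as exc:
            raise ParseError(f"{path}: {exc}", line=lineno) from exc
    return outlines


def read_labels(path: str | Path) -> dict[str, str]:
    """Read a ``specimen_id, group`` labels CSV into a dict."""
    df = pd.read_csv(path)
    return dict(zip(df["specimen_id"].astype(str), df["group"].astype(str)))


# ---------------------------------------------------------------------------
# writers
# ---------------------------------------------------------------------------


def write_outlines(outlines: Sequence[Outline], path: str | Path, format: str,
                   grid: float | None = None) -> Path:
    """Write *outlines* to *path*.

    xy_csv and tps round-trip coordinates losslessly (to 1e-9); chc quantizes
    to an integer grid of spacing *grid* (default: bounding-box max dimension
    / 256) and is therefore lossy for off-grid input.
    """
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    if format == "xy_csv":
        frames = []
        for o in outlines:
            frames.append(
                pd.DataFrame(
                    {
                        "specimen_id": o.specimen_id,
                        "point_index": np.arange(o.n_points),
                        "x": o.points[:, 0],
                        "y": o.points[:, 1],
                        "group": o.group,
                    }
                )
            )
        pd.concat(frames, ignore_index=True).to_csv(path, index=False, float_format="%.12g")
    elif format == "tps":
        with open(path, "w") as fh:
            for o in outlines:
                fh.write("OUTLINES=1\n")
                fh.write(f"POINTS={o.n_points}\n")
                for x, y in o.points:
                    fh.write(f"{x:.12g} {y:.12g}\n")
                fh.write(f"ID={o.specimen_id}\n")
    elif format == "chc":
        with open(path, "w") as fh:
            for o in outlines:
                chain = outline_to_chain(o, grid=grid)
                codes = " ".join(str(c) for c in chain.codes)
                fh.write(
                    f"{o.specimen_id} {chain.start[0]} {chain.start[1]} "
                    f"{len(chain.codes)} {codes}\n"
                )
    else:
        raise ValueError(f"unknown outline format: {format!r}")
    return path


def write_labels(outlines: Sequence[Outline], path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    pd.DataFrame(
        {"specimen_id": [o.specimen_id for o in outlines], "group": [o.group for o in outlines]}
    ).to_csv(path, index=False)
    return path


def _is_on_unit_grid(o: Outline) -> bool:
    if not np.allclose(o.points, np.round(o.points)):
        return False
    deltas = np.diff(np.round(o.closed_points()).astype(int), axis=0)
    return all(tuple(d) in _STEP_TO_CODE for d in deltas)


def outline_to_chain(o: Outline, grid: float | None = None) -> ChainCode:
    """Encode an outline as a Freeman chain code.

    Outlines already on the integer grid with unit Freeman steps are encoded
    exactly.  Otherwise the outline is densely resampled, quantized to a grid
    of spacing *grid*, and connected with single Freeman moves; the chain path
    then stays within about one grid unit of the source curve.
    """
    if grid is None and _is_on_unit_grid(o):
        pts = np.round(o.closed_points()).astype(int)
        deltas = np.diff(pts, axis=0)
        codes = [_STEP_TO_CODE[tuple(d)] for d in deltas]
        return ChainCode((int(pts[0, 0]), int(pts[0, 1])), codes)

    if grid is None:
        span = np.ptp(o.points, axis=0).max()
        grid = span / 256.0
    # dense resample so consecutive quantized points are <= 1 grid step apart
    from .preprocess import resample_equal_arclength  # local import avoids cycle

    m = max(64, int(np.ceil(o.perimeter() / (0.4 * grid))))
    dense = resample_equal_arclength(o, m).closed_points()
    q = np.round(dense / grid).astype(int)
    codes: list[int] = []
    pos = q[0]
    for nxt in q[1:]:
        while not np.array_equal(pos, nxt):
            step = np.clip(nxt - pos, -1, 1)
            codes.append(_STEP_TO_CODE[tuple(step)])
            pos = pos + step
    return ChainCode((int(q[0, 0]), int(q[0, 1])), codes)
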