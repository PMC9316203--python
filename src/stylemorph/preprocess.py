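"""Outline standardization before Fourier coding.

The digitization protocol this module mirrors: only the better-accessible
body half of each specimen is drawn as an open polyline from the posterior
midline point to the anterior midline point; the stylet (the piercing
mandible+maxilla blade) is artificially rotated rigidly about its base so
that the line through its innermost proximal and innermost distal points is
parallel to the anterior-posterior midline; the half is then mirrored across
the midline to form one closed, bilaterally symmetric contour; finally the
contour is resampled at equal arc-length steps starting from the anterior
pole so that downstream Fourier coefficients share a common starting-point
convention.

Coordinate convention: the anterior-posterior midline is the y axis, y
increasing anterior (toward the stylets).
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Optional

import numpy as np

from .outlines import Outline, OutlineError

__all__ = [
    "HalfOutline",
    "straighten_stylet",
    "mirror_half",
    "resample_equal_arclength",
    "detect_landmarks",
]

MIDLINE_TOL = 1e-7


@dataclass
class HalfOutline:
    """Open polyline along one body side, posterior midline point first.

    ``proximal`` and ``distal`` index the stylet's innermost proximal point
    (blade base on the inner margin) and innermost distal point (inner margin
    near the tip).  ``stylet_start`` is the first index of the blade (the
    outer-margin base attachment); if None it is auto-detected as the
    pre-distal point closest to the proximal landmark.
    """

    points: np.ndarray
    side: str
    proximal: int
    distal: int
    stylet_start: Optional[int] = None

    def __post_init__(self) -> None:
        pts = np.asarray(self.points, dtype=float)
        if pts.ndim != 2 or pts.shape[1] != 2 or len(pts) < 4:
            raise OutlineError("half outline must be an (n>=4, 2) array")
        if self.side not in ("left", "right"):
            raise OutlineError(f"side must be 'left' or 'right', got {self.side!r}")
        for name in ("proximal", "distal"):
            idx = getattr(self, name)
            if not (0 <= idx < len(pts)):
                raise OutlineError(f"{name} landmark index {idx} out of range")
        if self.proximal == self.distal:
            raise OutlineError("proximal and distal landmarks coincide")
        if abs(pts[0, 0]) > MIDLINE_TOL * _scale(pts) or abs(pts[-1, 0]) > MIDLINE_TOL * _scale(pts):
            raise OutlineError(
                "half outline endpoints must lie on the midline "
                f"(|x| = {abs(pts[0, 0]):.3g}, {abs(pts[-1, 0]):.3g})"
            )
        self.points = np.ascontiguousarray(pts)


def _scale(pts: np.ndarray) -> float:
    return float(max(np.ptp(pts, axis=0).max(), 1.0))


def _blade_range(half: HalfOutline) -> tuple[int, int]:
    """Contiguous index range [start, stop] of the stylet blade."""
    lo, hi = sorted((half.proximal, half.distal))
    if half.stylet_start is not None:
        start = half.stylet_start
        return (min(start, lo), max(start, hi))
    # auto: the outer-margin base attachment is the point outside the inner
    # margin closest to the proximal landmark
    prox = half.points[half.proximal]
    candidates = [i for i in range(len(half.points)) if not lo <= i <= hi]
    if not candidates:
        return lo, hi
    d = np.linalg.norm(half.points[candidates] - prox, axis=1)
    start = candidates[int(np.argmin(d))]
    return (min(start, lo), max(start, hi))


def straighten_stylet(half: HalfOutline) -> HalfOutline:
    """Rigidly rotate the stylet blade so its landmark axis is parallel
    to the anterior-posterior midline.

    The rotation is about the innermost proximal landmark (the blade's
    articulation end), so head-capsule geometry is untouched and pairwise
    distances within the blade are preserved exactly.  Of the two rotations
    that align the landmark segment with the midline, the one that keeps the
    distal point anterior (larger y) is chosen.
    """
    pts = half.points.copy()
    prox = pts[half.proximal]
    dist = pts[half.distal]
    v = dist - prox
    if np.hypot(*v) == 0.0:
        raise OutlineError("coincident stylet landmarks")
    # angle from +y axis; rotating counterclockwise by that angle makes the
    # segment vertical with the distal point anterior
    angle = np.arctan2(v[0], v[1])  # 0 when already parallel, tip anterior
    c, s = np.cos(angle), np.sin(angle)
    rot = np.array([[c, -s], [s, c]])
    start, stop = _blade_range(half)
    blade = pts[start : stop + 1]
    pts[start : stop + 1] = (blade - prox) @ rot.T + prox
    return replace(half, points=pts)


def mirror_half(half: HalfOutline, specimen_id: str = "mirrored", group: str = "") -> Outline:
    """Reflect the half outline across the midline into one closed contour.

    The mirrored copy is appended in reverse traversal order; the duplicate
    midline endpoints are dropped.  The result is closed, simple,
    mirror-symmetric and counterclockwise.
    """
    pts = half.points.copy()
    # snap midline endpoints exactly so the mirror is numerically exact
    pts[0, 0] = 0.0
    pts[-1, 0] = 0.0
    mirrored = pts[::-1].copy()
    mirrored[:, 0] *= -1.0
    full = np.vstack([pts, mirrored[1:-1]])
    out = Outline(specimen_id, full, group=group, provenance=f"mirrored-{half.side}-half")
    _check_simple(out)
    return out


def _check_simple(outline: Outline) -> None:
    import shapely

    ring = shapely.LinearRing(outline.closed_points())
    if not ring.is_simple:
        i, j = _first_crossing(outline.closed_points())
        raise OutlineError(
            f"{outline.specimen_id}: self-intersecting contour "
            f"(segments {i} and {j} cross)"
        )


def _first_crossing(closed: np.ndarray) -> tuple[int, int]:
    """Brute-force search for the first pair of crossing segments (error path)."""
    from shapely import LineString

    n = len(closed) - 1
    segs = [LineString(closed[i : i + 2]) for i in range(n)]
    for i in range(n):
        for j in range(i + 2, n):
            if i == 0 and j == n - 1:
                continue  # adjacent through closure
            if segs[i].crosses(segs[j]) or (
                segs[i].intersects(segs[j]) and not segs[i].touches(segs[j])
            ):
                return i, j
    return -1, -1


def resample_equal_arclength(outline: Outline, m: int, tol: float = 1e-6,
                             max_iter: int = 30) -> Outline:
    """Resample a closed outline at *m* equal arc-length steps.

    The first output point is the intersection of the outline with the
    positive midline (the anterior pole), so the starting point is consistent
    across specimens and starting-point normalization downstream is a
    verification rather than a load-bearing step.  Falls back to the
    northernmost vertex if the outline never crosses the midline.

    A single pass equalizes spacing along the *source* polygon, whose chords
    are not themselves equal wherever curvature varies; the pass is therefore
    iterated to its fixed point, so the returned polygon has consecutive
    spacing uniform to ``tol`` relative and the operation is idempotent at
    the same tolerance.
    """
    if m < 64:
        raise ValueError(f"m must be >= 64, got {m}")
    result = _resample_once(outline, m)
    for _ in range(max_iter):
        chords = np.linalg.norm(np.diff(result.closed_points(), axis=0), axis=1)
        if np.ptp(chords) <= tol * chords.mean():
            break
        result = _resample_once(result, m)
    return result


def _resample_once(outline: Outline, m: int) -> Outline:
    closed = outline.closed_points()
    seg = np.diff(closed, axis=0)
    seglen = np.hypot(seg[:, 0], seg[:, 1])
    perim = float(seglen.sum())
    if perim <= 0.0:
        raise OutlineError(f"{outline.specimen_id}: zero-perimeter outline")
    cum = np.concatenate([[0.0], np.cumsum(seglen)])

    s0 = _anterior_pole_arcpos(closed, seg, cum)
    targets = (s0 + np.arange(m) * (perim / m)) % perim
    x = np.interp(targets, cum, closed[:, 0])
    y = np.interp(targets, cum, closed[:, 1])
    prov = outline.provenance
    if not prov.endswith("resampled"):
        prov = (prov + ";resampled").lstrip(";")
    return Outline(
        outline.specimen_id,
        np.column_stack([x, y]),
        group=outline.group,
        provenance=prov,
    )


def _anterior_pole_arcpos(closed: np.ndarray, seg: np.ndarray, cum: np.ndarray) -> float:
    """Arc position of the topmost crossing of the outline with x = 0."""
    x0, x1 = closed[:-1, 0], closed[1:, 0]
    best_y, best_s = -np.inf, None
    # vertex exactly on the midline
    on = np.flatnonzero(np.abs(x0) == 0.0)
    for i in on:
        if closed[i, 1] > best_y:
            best_y, best_s = closed[i, 1], cum[i]
    # edge straddling the midline
    straddle = np.flatnonzero((x0 * x1) < 0.0)
    for i in straddle:
        t = -x0[i] / (x1[i] - x0[i])
        ycross = closed[i, 1] + t * seg[i, 1]
        if ycross > best_y:
            best_y = ycross
            best_s = cum[i] + t * (cum[i + 1] - cum[i])
    if best_s is None:
        best_s = cum[int(np.argmax(closed[:-1, 1]))]
    return float(best_s)


def detect_landmarks(half: HalfOutline) -> HalfOutline:
    """Auto-detect the stylet landmarks on a half outline.

    Heuristic: the stylet tip is the point farthest from the posterior
    endpoint; the innermost proximal point is the sharpest corner (maximum
    turning angle) on the post-tip, midline-facing margin.  Explicitly
    supplied indices always take precedence over this detector.
    """
    pts = half.points
    tip = int(np.argmax(np.linalg.norm(pts - pts[0], axis=1)))
    if tip + 2 >= len(pts) - 1:
        raise OutlineError("cannot auto-detect landmarks: tip at traversal end")
    post = pts[tip:-1]
    v1 = post[1:-1] - post[:-2]
    v2 = post[2:] - post[1:-1]
    cross = v1[:, 0] * v2[:, 1] - v1[:, 1] * v2[:, 0]
    dot = (v1 * v2).sum(axis=1)
    turn = np.abs(np.arctan2(cross, dot))
    proximal = tip + 1 + int(np.argmax(turn))
    distal = tip + 1 if tip + 1 < proximal else proximal - 1
    return replace(half, proximal=proximal, distal=distal)
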