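"""Elliptic Fourier analysis of closed outlines.

A closed contour traversed at parameter t in [0, T) (T = perimeter, arc-length
parametrization over the polygon) has coordinate projections

    x(t) = A0 + sum_n a_n cos(2 pi n t / T) + b_n sin(2 pi n t / T)
    y(t) = C0 + sum_n c_n cos(2 pi n t / T) + d_n sin(2 pi n t / T)

The coefficients are computed with the exact piecewise-linear closed form
(the classical chain/polygon formulation), i.e. the Fourier integrals of the
polygonal x(t), y(t) are evaluated analytically segment by segment -- no FFT
and no quadrature error.

Normalization follows the standard first-harmonic procedure: the starting
point is shifted to the first-harmonic ellipse's semi-major axis, the shape
is rotated so that axis lies along +x, and all coefficients are divided by
the semi-major axis length.  After normalization a1 = 1, b1 = c1 = 0, and
d1 carries the first-ellipse aspect ratio (positive for counterclockwise
traversal).  The remaining 180-degree ambiguity (which end of the major axis
is "first") is resolved shape-intrinsically by comparing the two candidate
coefficient vectors and keeping the lexicographically larger one, which makes
the canonical form invariant to translation, rotation, scale and starting
point.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .outlines import Outline

__all__ = [
    "EFACoefficients",
    "compute_efa",
    "normalize",
    "reconstruct",
    "harmonic_power",
]


@dataclass
class EFACoefficients:
    """Per-harmonic elliptic Fourier coefficients for one outline.

    ``a``/``b`` describe the x projection, ``c``/``d`` the y projection;
    ``A0``/``C0`` are the centroid offsets.  ``size_scalar`` records the
    divisor removed during size normalization (in the input length units) so
    shape and size stay jointly recoverable.
    """

    a: np.ndarray
    b: np.ndarray
    c: np.ndarray
    d: np.ndarray
    A0: float = 0.0
    C0: float = 0.0
    normalized: bool = False
    size_scalar: float = 1.0
    specimen_id: str = ""
    group: str = ""

    def __post_init__(self) -> None:
        self.a, self.b, self.c, self.d = (
            np.asarray(v, dtype=float) for v in (self.a, self.b, self.c, self.d)
        )
        n = len(self.a)
        if not (len(self.b) == len(self.c) == len(self.d) == n):
            raise ValueError("coefficient vectors must share one length")
        if self.normalized:
            if abs(self.a[0] - 1.0) > 1e-9 or abs(self.b[0]) > 1e-9 or abs(self.c[0]) > 1e-9:
                raise ValueError(
                    "normalized coefficients must satisfy a1=1, b1=c1=0 "
                    f"(got a1={self.a[0]:.3g}, b1={self.b[0]:.3g}, c1={self.c[0]:.3g})"
                )

    @property
    def n_harmonics(self) -> int:
        return len(self.a)

    def as_matrix(self) -> np.ndarray:
        """(n_harmonics, 4) array with columns a, b, c, d."""
        return np.column_stack([self.a, self.b, self.c, self.d])


def compute_efa(outline: Outline, n_harmonics: int) -> EFACoefficients:
    """Exact elliptic Fourier coefficients of a polygonal outline.

    Raises if ``n_harmonics`` exceeds half the point count (aliasing guard:
    beyond that the polygon cannot support independent harmonic content).
    """
    if n_harmonics < 1:
        raise ValueError("n_harmonics must be >= 1")
    if n_harmonics > outline.n_points / 2:
        raise ValueError(
            f"n_harmonics={n_harmonics} exceeds n_points/2={outline.n_points / 2:.0f} "
            "(aliasing guard)"
        )
    closed = outline.closed_points()
    seg = np.diff(closed, axis=0)
    dt = np.hypot(seg[:, 0], seg[:, 1])
    keep = dt > 0.0
    seg, dt = seg[keep], dt[keep]
    T = float(dt.sum())
    t = np.concatenate([[0.0], np.cumsum(dt)])  # t[p-1], t[p] bracket segment p

    n = np.arange(1, n_harmonics + 1)[:, None]  # (H, 1)
    w = 2.0 * np.pi / T
    cos_t = np.cos(w * n * t[None, :])  # (H, P+1)
    sin_t = np.sin(w * n * t[None, :])
    dcos = cos_t[:, 1:] - cos_t[:, :-1]
    dsin = sin_t[:, 1:] - sin_t[:, :-1]
    slope = seg / dt[:, None]  # dx/dt, dy/dt per segment (constant)

    pref = T / (2.0 * np.pi**2 * n[:, 0] ** 2)
    a = pref * (dcos @ slope[:, 0])
    b = pref * (dsin @ slope[:, 0])
    c = pref * (dcos @ slope[:, 1])
    d = pref * (dsin @ slope[:, 1])

    # centroid offsets: exact integral of the piecewise-linear coordinate
    x0 = closed[:-1][keep]
    mid = x0 + 0.5 * seg
    A0 = float((mid[:, 0] * dt).sum() / T)
    C0 = float((mid[:, 1] * dt).sum() / T)
    return EFACoefficients(
        a, b, c, d, A0=A0, C0=C0, normalized=False,
        specimen_id=outline.specimen_id, group=outline.group,
    )


def _phase_shift(M: np.ndarray, theta: float) -> np.ndarray:
    """Shift the starting point by theta (first-harmonic phase units).

    Harmonic n picks up a rotation by n*theta in its (cos, sin) basis.
    """
    H = len(M)
    n = np.arange(1, H + 1)
    cn, sn = np.cos(n * theta), np.sin(n * theta)
    out = np.empty_like(M)
    out[:, 0] = M[:, 0] * cn + M[:, 1] * sn
    out[:, 1] = -M[:, 0] * sn + M[:, 1] * cn
    out[:, 2] = M[:, 2] * cn + M[:, 3] * sn
    out[:, 3] = -M[:, 2] * sn + M[:, 3] * cn
    return out


def _spatial_rotate(M: np.ndarray, psi: float) -> np.ndarray:
    """Rotate the shape by -psi in the plane (applied to all harmonics)."""
    cp, sp = np.cos(psi), np.sin(psi)
    out = np.empty_like(M)
    out[:, 0] = cp * M[:, 0] + sp * M[:, 2]
    out[:, 1] = cp * M[:, 1] + sp * M[:, 3]
    out[:, 2] = -sp * M[:, 0] + cp * M[:, 2]
    out[:, 3] = -sp * M[:, 1] + cp * M[:, 3]
    return out


def _candidate(M: np.ndarray, theta: float) -> np.ndarray:
    shifted = _phase_shift(M, theta)
    psi = np.arctan2(shifted[0, 2], shifted[0, 0])
    rotated = _spatial_rotate(shifted, psi)
    return rotated


def normalize(coeffs: EFACoefficients) -> EFACoefficients:
    """First-harmonic normalization: remove translation, scale, rotation
    and starting point.

    Raises on a degenerate first harmonic (zero magnitude), for which no
    orientation is defined.
    """
    if coeffs.normalized:
        return coeffs
    M = coeffs.as_matrix()
    a1, b1, c1, d1 = M[0]
    mag = np.sqrt(a1**2 + b1**2 + c1**2 + d1**2)
    if mag < 1e-12:
        raise ValueError("degenerate first harmonic: cannot normalize")

    theta = 0.5 * np.arctan2(2.0 * (a1 * b1 + c1 * d1), a1**2 + c1**2 - b1**2 - d1**2)
    # candidate phases place t=0 on either axis end; keep the two on the
    # MAJOR axis (larger first-harmonic radius), then break the remaining
    # 180-degree tie shape-intrinsically.
    cands = [_candidate(M, theta + k * np.pi / 2.0) for k in range(4)]
    radii = [abs(c[0, 0]) for c in cands]
    major = max(radii)
    cands = [c for c, r in zip(cands, radii) if r > major - 1e-12 * major]
    # enforce a1 > 0 (rotate by 180 degrees if needed: negates all rows)
    cands = [c if c[0, 0] > 0 else -c for c in cands]
    best = cands[0]
    for other in cands[1:]:
        if _lex_greater(other, best):
            best = other
    size = best[0, 0]
    best = best / size
    return EFACoefficients(
        best[:, 0], best[:, 1], best[:, 2], best[:, 3],
        A0=0.0, C0=0.0, normalized=True, size_scalar=coeffs.size_scalar * size,
        specimen_id=coeffs.specimen_id, group=coeffs.group,
    )


def _lex_greater(u: np.ndarray, v: np.ndarray, tol: float = 1e-12) -> bool:
    """Lexicographic comparison of coefficient matrices, ignoring sub-tol ties."""
    du = u.ravel() - v.ravel()
    idx = np.flatnonzero(np.abs(du) > tol)
    return bool(len(idx)) and du[idx[0]] > 0


def reconstruct(coeffs: EFACoefficients, n_points: int = 256, k: int | None = None,
                specimen_id: str | None = None) -> Outline:
    """Inverse Fourier sum truncated at *k* harmonics (default: all)."""
    H = coeffs.n_harmonics
    if k is None:
        k = H
    if not 1 <= k <= H:
        raise ValueError(f"k must be in 1..{H}, got {k}")
    t = np.linspace(0.0, 2.0 * np.pi, n_points, endpoint=False)
    n = np.arange(1, k + 1)[:, None]
    cos_nt = np.cos(n * t[None, :])
    sin_nt = np.sin(n * t[None, :])
    x = coeffs.A0 + coeffs.a[:k] @ cos_nt + coeffs.b[:k] @ sin_nt
    y = coeffs.C0 + coeffs.c[:k] @ cos_nt + coeffs.d[:k] @ sin_nt
    sid = specimen_id if specimen_id is not None else (coeffs.specimen_id or "reconstruction")
    return Outline(sid, np.column_stack([x, y]), group=coeffs.group,
                   provenance=f"reconstructed-k{k}")


def harmonic_power(coeffs: EFACoefficients) -> tuple[np.ndarray, np.ndarray]:
    """Per-harmonic power fractions and their cumulative sum.

    Power of harmonic n is (a_n^2 + b_n^2 + c_n^2 + d_n^2) / 2; fractions are
    relative to the total over all harmonics, so the cumulative vector is
    nondecreasing and ends at 1.
    """
    power = (coeffs.a**2 + coeffs.b**2 + coeffs.c**2 + coeffs.d**2) / 2.0
    total = power.sum()
    if total == 0.0:
        raise ValueError("all-zero coefficients have no harmonic power")
    frac = power / total
    return frac, np.cumsum(frac)
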