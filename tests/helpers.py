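"""Shared test utilities: independent oracles and fixture shape factories."""

from __future__ import annotations

import numpy as np

from stylemorph.outlines import Outline


def random_star_polygon(rng: np.random.Generator, n_vertices: int = 40,
                        r_low: float = 0.5, r_high: float = 1.5) -> Outline:
    """Random star-shaped (hence simple) polygon around a random center."""
    ang = np.sort(rng.uniform(0.0, 2.0 * np.pi, n_vertices))
    # guard against duplicate angles
    ang += np.arange(n_vertices) * 1e-9
    r = rng.uniform(r_low, r_high, n_vertices)
    center = rng.uniform(-2.0, 2.0, 2)
    pts = center + np.column_stack([r * np.cos(ang), r * np.sin(ang)])
    return Outline("star", pts)


def circle_outline(n: int = 512, r: float = 1.0, cx: float = 0.0, cy: float = 0.0) -> Outline:
    t = np.linspace(0.0, 2.0 * np.pi, n, endpoint=False)
    return Outline("circle", np.column_stack([cx + r * np.cos(t), cy + r * np.sin(t)]))


def quadrature_efa(outline: Outline, n_harmonics: int, n_steps: int = 1_000_000):
    """Brute-force elliptic Fourier coefficients by dense trapezoid quadrature.

    Independent of the closed-form implementation: builds the arc-length
    parametrization of the polygon, interpolates x(t), y(t) on a dense grid
    and integrates a_n = (2/T) int x(t) cos(2 pi n t / T) dt directly
    (likewise b, c, d with sin and y).
    """
    closed = outline.closed_points()
    seg = np.diff(closed, axis=0)
    dt = np.hypot(seg[:, 0], seg[:, 1])
    T = dt.sum()
    tk = np.concatenate([[0.0], np.cumsum(dt)])
    t = np.linspace(0.0, T, n_steps + 1)
    x = np.interp(t, tk, closed[:, 0])
    y = np.interp(t, tk, closed[:, 1])
    w = 2.0 * np.pi / T
    a = np.empty(n_harmonics)
    b = np.empty(n_harmonics)
    c = np.empty(n_harmonics)
    d = np.empty(n_harmonics)
    for i, n in enumerate(range(1, n_harmonics + 1)):
        cos_nt = np.cos(w * n * t)
        sin_nt = np.sin(w * n * t)
        a[i] = (2.0 / T) * np.trapezoid(x * cos_nt, t)
        b[i] = (2.0 / T) * np.trapezoid(x * sin_nt, t)
        c[i] = (2.0 / T) * np.trapezoid(y * cos_nt, t)
        d[i] = (2.0 / T) * np.trapezoid(y * sin_nt, t)
    A0 = np.trapezoid(x, t) / T
    C0 = np.trapezoid(y, t) / T
    return a, b, c, d, A0, C0


def brute_force_permanova_f(X: np.ndarray, labels) -> float:
    """Pseudo-F computed the slow, explicit way (independent oracle)."""
    labels = np.asarray(labels)
    N = len(X)
    D2 = np.array([[np.sum((X[i] - X[j]) ** 2) for j in range(N)] for i in range(N)])
    sst = D2[np.triu_indices(N, 1)].sum() / N
    ssw = 0.0
    names = sorted(set(labels))
    for g in names:
        idx = np.flatnonzero(labels == g)
        sub = D2[np.ix_(idx, idx)]
        ssw += sub[np.triu_indices(len(idx), 1)].sum() / len(idx)
    ssb = sst - ssw
    g = len(names)
    return (ssb / (g - 1)) / (ssw / (N - g))
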