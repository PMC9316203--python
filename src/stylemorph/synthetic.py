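"""Parametric generator of larval head-capsule + stylet outlines.

Real outlines for this study system (antlion- and owlfly-type lacewing
larvae, extant and in amber) exist only as hand drawings, so every
downstream stage is exercised against a synthetic family of shapes built to
span the same qualitative axes of variation that the head outlines of these
larvae show: concavity/convexity of the posterior rim of the head capsule,
stylet length relative to the head capsule, and stylet thickness.

Construction (all in arbitrary length units, midline = y axis, anterior up):

* head capsule: a superellipse of half-width ``head_width / 2`` and height
  ``head_length`` (exponent 2.5 gives the roughly square-with-rounded-
  corners look of these head capsules);
* posterior rim: a circular arc whose signed sagitta is
  ``posterior_rim_curvature * head_width`` (negative = concave rim);
* stylets: a pair of tapered quadratic-Bezier blades fused to the anterior
  rim, of length ``stylet_rel_length * head_length`` and basal width
  ``stylet_thickness * head_width``, optionally bowed outward
  (``stylet_curvature``) and with cosmetic tooth bumps on the inner margin.

The right half is built as an open polyline with stylet landmarks, mirrored
across the midline into ONE closed contour (elliptic Fourier analysis needs
a single closed curve), and resampled at equal arc length.  Specimen-level
variation is injected into the *parameters* (Gaussian around group means),
not into vertices, so the truth behind every specimen is recoverable;
optional per-vertex jitter exists for robustness experiments only.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np

from .outlines import Outline, OutlineError
from .preprocess import HalfOutline, mirror_half, resample_equal_arclength

__all__ = [
    "ShapeParams",
    "GroupSpec",
    "SyntheticDataset",
    "generate_half_outline",
    "generate_outline",
    "generate_dataset",
    "default_study_groups",
]

_SUPERELLIPSE_EXP = 2.5
_STYLET_GAP = 0.08  # inner stylet-base offset from midline, x head_width
_RETRY_CAP = 100

# parameter order used by dispersion vectors
PARAM_NAMES = (
    "head_length",
    "head_width",
    "posterior_rim_curvature",
    "stylet_rel_length",
    "stylet_thickness",
    "stylet_curvature",
)


@dataclass(frozen=True)
class ShapeParams:
    """Interpretable shape parameters for one specimen.

    ``posterior_rim_curvature`` is the signed sagitta of the posterior rim
    as a fraction of head width (negative = concave rim, positive = convex);
    ``stylet_rel_length`` is stylet length / head length;
    ``stylet_thickness`` is stylet basal width / head width;
    ``stylet_curvature`` bows the blade outward (0 = straight);
    ``tooth_count`` adds cosmetic bumps on the inner stylet margin.
    """

    head_length: float = 1.0
    head_width: float = 1.0
    posterior_rim_curvature: float = 0.0
    stylet_rel_length: float = 1.0
    stylet_thickness: float = 0.12
    stylet_curvature: float = 0.0
    tooth_count: int = 0

    def validate(self) -> None:
        problems = []
        if self.head_length <= 0:
            problems.append(f"head_length={self.head_length}")
        if self.head_width <= 0:
            problems.append(f"head_width={self.head_width}")
        if not 0.2 < self.stylet_rel_length < 3.0:
            problems.append(f"stylet_rel_length={self.stylet_rel_length} not in (0.2, 3.0)")
        if not 0.01 < self.stylet_thickness < 0.5:
            problems.append(f"stylet_thickness={self.stylet_thickness} not in (0.01, 0.5)")
        if self.tooth_count < 0:
            problems.append(f"tooth_count={self.tooth_count}")
        if abs(self.posterior_rim_curvature) >= 0.6:
            problems.append(
                f"posterior_rim_curvature={self.posterior_rim_curvature} too extreme"
            )
        if problems:
            raise OutlineError("invalid shape parameters: " + ", ".join(problems))

    def to_array(self) -> np.ndarray:
        return np.array([getattr(self, k) for k in PARAM_NAMES])


@dataclass(frozen=True)
class GroupSpec:
    """One labelled group of the synthetic design."""

    name: str
    n: int
    mean_params: ShapeParams
    dispersion: dict[str, float] = field(default_factory=dict)
    seed_offset: int = 0

    def validate(self) -> None:
        if self.n < 1:
            raise ValueError(f"group {self.name!r}: n must be >= 1")
        for k, v in self.dispersion.items():
            if k not in PARAM_NAMES:
                raise ValueError(f"group {self.name!r}: unknown dispersion key {k!r}")
            if v < 0:
                raise ValueError(f"group {self.name!r}: negative dispersion for {k}")


@dataclass
class SyntheticDataset:
    outlines: list[Outline]
    truth: list[ShapeParams]
    config: list[GroupSpec]
    seed: int


def _superellipse_y(x: np.ndarray, half_w: float, length: float) -> np.ndarray:
    u = np.clip(np.abs(x) / half_w, 0.0, 1.0)
    return length * (1.0 - u**_SUPERELLIPSE_EXP) ** (1.0 / _SUPERELLIPSE_EXP)


def _superellipse_arc(half_w: float, length: float, x_from: float, x_to: float,
                      n: int) -> np.ndarray:
    """Arc of the head superellipse sampled by angle between two x stations."""
    th_from = np.arccos(np.clip(x_from / half_w, -1, 1) ** (_SUPERELLIPSE_EXP / 2.0)
                        if x_from >= 0 else 0.0)
    # parametrize x = half_w * cos(t)^(2/p), y = length * sin(t)^(2/p)
    p = _SUPERELLIPSE_EXP

    def t_of_x(x):
        return np.arccos(np.clip((x / half_w) ** (p / 2.0), -1.0, 1.0))

    t = np.linspace(t_of_x(x_from), t_of_x(x_to), n)
    x = half_w * np.cos(t) ** (2.0 / p)
    y = length * np.sin(t) ** (2.0 / p)
    return np.column_stack([x, y])


def _posterior_arc(half_w: float, sagitta: float, n: int) -> np.ndarray:
    """Right half of the posterior rim, from (0, -sagitta) to (half_w, 0).

    Circular arc through (-half_w, 0), (0, -sagitta), (half_w, 0); a straight
    segment when the sagitta is negligible.
    """
    if abs(sagitta) < 1e-9 * half_w:
        t = np.linspace(0.0, 1.0, n)
        return np.column_stack([t * half_w, np.zeros(n)])
    R = (half_w**2 + sagitta**2) / (2.0 * abs(sagitta))
    yc = -sagitta + np.sign(sagitta) * R  # center on the midline
    # angles of the two arc endpoints about (0, yc)
    a0 = np.arctan2(-sagitta - yc, 0.0)
    a1 = np.arctan2(0.0 - yc, half_w)
    ang = np.linspace(a0, a1, n)
    return np.column_stack([R * np.cos(ang), yc + R * np.sin(ang)])


def _bezier(p0: np.ndarray, p1: np.ndarray, p2: np.ndarray, t: np.ndarray) -> np.ndarray:
    t = t[:, None]
    return (1 - t) ** 2 * p0 + 2 * (1 - t) * t * p1 + t**2 * p2


def generate_half_outline(params: ShapeParams, bend_angle: float = 0.0,
                          n_arc: int = 48, n_blade: int = 48) -> HalfOutline:
    """Right half outline, posterior midline point -> anterior midline point.

    ``bend_angle`` (radians) rigidly rotates the stylet blade about its
    proximal landmark away from the straightened pose, emulating a drawn
    specimen whose stylet has not yet been artificially straightened --
    :func:`stylemorph.preprocess.straighten_stylet` undoes it exactly.
    """
    params.validate()
    L, W = params.head_length, params.head_width
    half_w = W / 2.0
    x_in = _STYLET_GAP * W
    x_out = x_in + params.stylet_thickness * W
    if x_out > 0.9 * half_w:
        raise OutlineError(
            "self-intersecting parameter combination: stylet_thickness="
            f"{params.stylet_thickness} with head_width={W} pushes the stylet "
            "base beyond the head capsule flank"
        )

    post = _posterior_arc(half_w, params.posterior_rim_curvature * W, n_arc)
    lateral = _superellipse_arc(half_w, L, half_w, x_out, n_arc)[1:]
    A_out = lateral[-1]
    A_in = np.array([x_in, _superellipse_y(np.array([x_in]), half_w, L)[0]])

    # stylet centerline: quadratic Bezier from base midpoint toward the tip
    B = 0.5 * (A_out + A_in)
    S = params.stylet_rel_length * L
    kappa = params.stylet_curvature
    phi = np.arctan(0.5 * kappa)
    u = np.array([np.sin(phi), np.cos(phi)])          # tip direction
    nvec = np.array([np.cos(phi), -np.sin(phi)])      # outward normal
    P2 = B + S * u
    P1 = B + 0.5 * S * u + 0.25 * kappa * S * nvec
    t = np.linspace(0.0, 1.0, n_blade)
    center = _bezier(B, P1, P2, t)
    tangent = 2 * (1 - t)[:, None] * (P1 - B) + 2 * t[:, None] * (P2 - P1)
    tnorm = np.linalg.norm(tangent, axis=1, keepdims=True)
    normal = np.column_stack([tangent[:, 1], -tangent[:, 0]]) / tnorm
    base_n = A_out - A_in
    base_n = base_n / np.linalg.norm(base_n)
    blend = (1 - t)[:, None] * base_n + t[:, None] * normal
    blend /= np.linalg.norm(blend, axis=1, keepdims=True)
    width = np.linalg.norm(A_out - A_in) * (1.0 - t) * (1.0 + 0.25 * t)
    outer = center + 0.5 * width[:, None] * blend
    inner = center - 0.5 * width[:, None] * blend
    if params.tooth_count > 0:
        amp = 0.12 * params.stylet_thickness * W
        window = np.clip(np.sin(np.pi * np.clip((t - 0.25) / 0.6, 0, 1)), 0, 1)
        bumps = amp * np.abs(np.sin(np.pi * params.tooth_count * t)) * window
        inner = inner + bumps[:, None] * blend  # teeth point toward the midline

    anterior = _superellipse_arc(half_w, L, x_in, 0.0, n_arc)[1:]
    anterior[-1, 0] = 0.0

    # assemble: posterior arc, lateral flank, outer blade margin (base->tip),
    # inner margin (tip->base), anterior rim to the pole
    pieces = [post, lateral, outer[1:], inner[::-1][1:], anterior]
    pts = np.vstack(pieces)
    idx_outer_base = len(post) + len(lateral) - 1
    idx_tip = idx_outer_base + n_blade - 1
    idx_distal = idx_tip + 1                      # first inner-margin point below the tip
    idx_proximal = idx_tip + n_blade - 1          # inner-margin base (A_in)
    half = HalfOutline(
        points=pts, side="right",
        proximal=idx_proximal, distal=idx_distal, stylet_start=idx_outer_base,
    )
    if bend_angle != 0.0:
        prox = pts[idx_proximal]
        c, s = np.cos(bend_angle), np.sin(bend_angle)
        rot = np.array([[c, -s], [s, c]])
        blade = pts[idx_outer_base: idx_proximal + 1]
        pts = pts.copy()
        pts[idx_outer_base: idx_proximal + 1] = (blade - prox) @ rot.T + prox
        half = replace(half, points=pts)
    return half


def generate_outline(
    params: ShapeParams,
    n_points: int = 256,
    rng: Optional[np.random.Generator] = None,
    specimen_id: str = "synthetic",
    group: str = "",
    jitter: float = 0.0,
) -> Outline:
    """One closed, simple, counterclockwise head+stylet contour.

    The contour is bilaterally symmetric about the midline (before optional
    per-vertex ``jitter``) and sampled at equal arc length, starting at the
    anterior pole.  A parameter combination that self-intersects raises an
    error naming the offending parameters.
    """
    if n_points < 64:
        raise ValueError(f"n_points must be >= 64, got {n_points}")
    half = generate_half_outline(params)
    full = mirror_half(half, specimen_id=specimen_id, group=group)
    out = resample_equal_arclength(full, n_points)
    if jitter > 0.0:
        if rng is None:
            raise ValueError("jitter requires an rng")
        pts = out.points + rng.normal(0.0, jitter, size=out.points.shape)
        out = Outline(specimen_id, pts, group=group, provenance=out.provenance + ";jittered")
    return out


def _draw_params(mean: ShapeParams, dispersion: dict[str, float],
                 rng: np.random.Generator) -> ShapeParams:
    values = {k: getattr(mean, k) for k in PARAM_NAMES}
    for k in PARAM_NAMES:
        sd = dispersion.get(k, 0.0)
        if sd > 0.0:
            values[k] = values[k] + rng.normal(0.0, sd)
    return ShapeParams(tooth_count=mean.tooth_count, **values)


def generate_dataset(
    groups: Sequence[GroupSpec],
    n_points: int = 256,
    seed: int = 0,
    jitter: float = 0.0,
) -> SyntheticDataset:
    """Draw a labelled dataset: per-specimen parameters are the group means
    plus Gaussian noise with the group's per-parameter dispersions.

    Parameter draws that violate the shape invariants (or produce a
    self-intersecting contour) are redrawn, up to 100 retries per specimen.
    Reproducible: identical (groups, n_points, seed) give identical data.
    """
    names = [g.name for g in groups]
    if len(set(names)) != len(names):
        raise ValueError("group names must be unique")
    outlines: list[Outline] = []
    truth: list[ShapeParams] = []
    for gi, spec in enumerate(groups):
        spec.validate()
        rng = np.random.default_rng(np.random.SeedSequence([seed, gi + spec.seed_offset]))
        for si in range(spec.n):
            sid = f"{spec.name}_{si:04d}"
            for attempt in range(_RETRY_CAP + 1):
                p = _draw_params(spec.mean_params, spec.dispersion, rng)
                try:
                    p.validate()
                    out = generate_outline(
                        p, n_points=n_points, rng=rng, specimen_id=sid,
                        group=spec.name, jitter=jitter,
                    )
                    break
                except (OutlineError, ValueError):
                    if attempt == _RETRY_CAP:
                        raise OutlineError(
                            f"group {spec.name!r}, specimen {si}: no valid outline "
                            f"after {_RETRY_CAP} retries"
                        )
            outlines.append(out)
            truth.append(p)
    return SyntheticDataset(outlines=outlines, truth=truth, config=list(groups), seed=seed)


def default_study_groups() -> list[GroupSpec]:
    """The study-shaped design: 243 extant, 46 Cretaceous, 9 Miocene and 2
    Eocene specimens.

    Three dominant variation axes of decreasing magnitude -- relative stylet
    length, posterior-rim curvature, stylet thickness -- give the
    morphospace three effective PCs with interpretations matching those
    shape factors.  The extant fauna is twice as dispersed as the Cretaceous
    slice; the Cretaceous mean is offset toward thicker stylets (the
    low-variance thickness factor, so many Cretaceous specimens fall outside
    the extant range on that axis); Miocene larvae sit inside the extant
    cloud; and the two Eocene larvae are outliers even further out on the
    thickness axis, with slightly longer stylets.
    """
    extant_disp = {
        "posterior_rim_curvature": 0.10,
        "stylet_rel_length": 0.16,
        "stylet_thickness": 0.020,
        "stylet_curvature": 0.03,
        "head_width": 0.03,
    }
    cret_disp = {k: v / 2.0 for k, v in extant_disp.items()}
    extant_mean = ShapeParams(
        head_length=1.0, head_width=1.0, posterior_rim_curvature=0.0,
        stylet_rel_length=1.0, stylet_thickness=0.12, stylet_curvature=0.15,
        tooth_count=2,
    )
    cret_mean = replace(extant_mean, stylet_thickness=0.19,
                        posterior_rim_curvature=-0.02)
    eocene_mean = replace(extant_mean, stylet_thickness=0.24,
                          stylet_rel_length=1.1)
    return [
        GroupSpec("extant", 243, extant_mean, extant_disp, seed_offset=0),
        GroupSpec("Cretaceous", 46, cret_mean, cret_disp, seed_offset=100),
        GroupSpec("Miocene", 9, extant_mean, cret_disp, seed_offset=200),
        GroupSpec("Eocene", 2, eocene_mean, {k: v / 4 for k, v in extant_disp.items()},
                  seed_offset=300),
    ]
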