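"""Reporting helpers: explained-variance summaries, rounding-consistency
checks against published percentages, morphospace-occupation overlap, and
score scatter plots."""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np

from .morphospace import MorphospaceEmbedding

__all__ = [
    "VarianceReport",
    "variance_report",
    "within_rounding",
    "hull_overlap",
    "occupation_summary",
    "plot_morphospace",
]


@dataclass
class VarianceReport:
    proportions_pct: list[float]
    cumulative_pct: float
    stated_total_pct: float | None
    within_rounding: bool | None
    lines: list[str]

    def __str__(self) -> str:
        return "\n".join(self.lines)


def within_rounding(values_pct: Sequence[float], stated_total_pct: float,
                    tol_pp: float = 0.15) -> bool:
    """Whether individually rounded percentages are consistent with a
    separately rounded total.

    Percentages printed to one decimal each carry up to 0.05 points of
    rounding error, so a sum of three and an independently rounded total may
    legitimately disagree by as much as 0.2 points; agreement is asserted
    within ``tol_pp`` percentage points, never as equality.
    """
    return bool(abs(sum(values_pct) - stated_total_pct) <= tol_pp)


def variance_report(
    proportions: Sequence[float],
    k: int | None = None,
    stated_total_pct: float | None = None,
    tol_pp: float = 0.15,
) -> VarianceReport:
    """Format explained-variance proportions (fractions or percentages).

    If ``stated_total_pct`` is given (e.g. a published cumulative figure),
    the report flags whether the per-component percentages are consistent
    with it under independent rounding.
    """
    props = np.asarray(proportions, dtype=float)
    pct = props * 100.0 if props.max() <= 1.0 + 1e-9 else props.copy()
    if k is not None:
        pct = pct[:k]
    cum = float(pct.sum())
    lines = [f"PC{i + 1}: {p:.1f}% of overall variation" for i, p in enumerate(pct)]
    lines.append(f"cumulative over {len(pct)} components: {cum:.1f}%")
    ok = None
    if stated_total_pct is not None:
        ok = within_rounding(pct, stated_total_pct, tol_pp)
        verdict = "within rounding of" if ok else "INCONSISTENT with"
        lines.append(f"sum {cum:.1f}% is {verdict} stated total {stated_total_pct:.1f}%")
    return VarianceReport(list(map(float, pct)), cum, stated_total_pct, ok, lines)


def hull_overlap(points_a: np.ndarray, points_b: np.ndarray) -> dict[str, float]:
    """Convex-hull occupation overlap of two 2D point clouds.

    Returns hull areas, intersection area, and the fraction of each hull
    covered by the other -- the quantities behind statements like "all
    Miocene larvae plot inside the extant area".
    """
    from shapely import MultiPoint

    ha = MultiPoint(np.asarray(points_a)).convex_hull
    hb = MultiPoint(np.asarray(points_b)).convex_hull
    inter = ha.intersection(hb).area
    return {
        "area_a": ha.area,
        "area_b": hb.area,
        "intersection": inter,
        "frac_a_in_b": inter / ha.area if ha.area > 0 else np.nan,
        "frac_b_in_a": inter / hb.area if hb.area > 0 else np.nan,
    }


def occupation_summary(
    embedding: MorphospaceEmbedding,
    reference_group: str,
    pc_pairs: Sequence[tuple[int, int]] = ((1, 2), (1, 3)),
) -> dict[str, dict[str, float]]:
    """Per-group hull overlap with a reference group in each PC plane.

    Also reports, per group, the fraction of its specimens falling inside
    the reference group's convex hull (requires >= 3 reference points).
    """
    from shapely import MultiPoint, Point

    out: dict[str, dict[str, float]] = {}
    ref_rows = embedding.group_rows(reference_group)
    groups = sorted(set(embedding.groups) - {reference_group})
    for i, j in pc_pairs:
        cols = [i - 1, j - 1]
        ref_pts = embedding.scores[np.ix_(ref_rows, cols)]
        ref_hull = MultiPoint(ref_pts).convex_hull
        for g in groups:
            rows = embedding.group_rows(g)
            pts = embedding.scores[np.ix_(rows, cols)]
            key = f"PC{i}-PC{j}:{g}"
            entry: dict[str, float] = {
                "n": float(len(rows)),
                "frac_inside_reference": float(
                    np.mean([ref_hull.covers(Point(p)) for p in pts])
                ),
            }
            if len(rows) >= 3:
                entry.update(hull_overlap(pts, ref_pts))
            out[key] = entry
    return out


def plot_morphospace(
    embedding: MorphospaceEmbedding,
    path: str | Path,
    pc_pairs: Sequence[tuple[int, int]] = ((1, 2), (1, 3)),
    hull_group: str | None = None,
) -> Path:
    """Scatter panels of PC planes with group glyphs; optionally overlay the
    convex hull of one group (typically the extant fauna's occupied area)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    groups = sorted(set(embedding.groups))
    fig, axes = plt.subplots(1, len(pc_pairs), figsize=(6 * len(pc_pairs), 5))
    axes = np.atleast_1d(axes)
    for ax, (i, j) in zip(axes, pc_pairs):
        for g in groups:
            rows = embedding.group_rows(g)
            ax.scatter(
                embedding.scores[rows, i - 1], embedding.scores[rows, j - 1],
                s=18, alpha=0.7, label=f"{g} (n={len(rows)})",
            )
        if hull_group is not None:
            rows = embedding.group_rows(hull_group)
            if len(rows) >= 3:
                from shapely import MultiPoint

                hull = MultiPoint(
                    embedding.scores[np.ix_(rows, [i - 1, j - 1])]
                ).convex_hull
                hx, hy = hull.exterior.xy
                ax.fill(hx, hy, alpha=0.12, color="grey", zorder=0)
        ax.set_xlabel(f"PC{i} ({embedding.proportions[i - 1] * 100:.1f}%)")
        ax.set_ylabel(f"PC{j} ({embedding.proportions[j - 1] * 100:.1f}%)")
        ax.legend(fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
    return path
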