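"""Group disparity in morphospace: occupied size and position.

Two metrics, both computed on the scores restricted to the effective PCs:

* **sum of variances** -- total sample variance (n-1 denominator) of a
  group's scores across the retained components; measures the *size* of the
  occupied region and equals the trace of the group covariance matrix.
* **average displacement** -- mean over group members of the ratio
  (distance from the morphospace origin) / (distance from the group
  centroid); measures the *position* of the group relative to the overall
  mean shape (the origin of a centered PCA).

Because the study groups are wildly unequal in size (hundreds of extant
specimens against handfuls of fossils), estimates come with bootstrap
confidence intervals and optional rarefaction: every bootstrap replicate
draws a fixed number of specimens with replacement so groups are compared
at a common sample size.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

__all__ = [
    "DisparityEstimate",
    "sum_of_variances",
    "average_displacement",
    "bootstrap_disparity",
    "MIN_GROUP_SIZE",
]

METRICS = {}
MIN_GROUP_SIZE = 3


def _register(fn):
    METRICS[fn.__name__] = fn
    return fn


@dataclass
class DisparityEstimate:
    metric: str
    group: str
    observed: float
    bootstrap_values: np.ndarray
    n: int
    rarefied_n: Optional[int]
    ci95: tuple[float, float]
    seed: int
    flags: list[str] = field(default_factory=list)

    @property
    def n_boot(self) -> int:
        return len(self.bootstrap_values)


@_register
def sum_of_variances(scores: np.ndarray, group_rows: np.ndarray | None = None) -> float:
    """Sum over retained components of the group's sample variance (ddof=1)."""
    X = _group_scores(scores, group_rows)
    if len(X) < 2:
        raise ValueError("sum of variances undefined for fewer than 2 specimens")
    return float(np.var(X, axis=0, ddof=1).sum())


@_register
def average_displacement(scores: np.ndarray, group_rows: np.ndarray | None = None) -> float:
    """Mean ratio of origin distance to centroid distance over group members.

    A group centered on the origin scores exactly 1; groups shifted away
    from the overall mean shape score above 1.  Members lying exactly at the
    group centroid have an undefined ratio and are excluded with a warning.
    """
    X = _group_scores(scores, group_rows)
    if len(X) < 2:
        raise ValueError("average displacement undefined for fewer than 2 specimens")
    centroid = X.mean(axis=0)
    from_origin = np.linalg.norm(X, axis=1)
    from_centroid = np.linalg.norm(X - centroid, axis=1)
    ok = from_centroid > 0.0
    if not ok.any():
        raise ValueError("all group members at the centroid: displacement undefined")
    if not ok.all():
        warnings.warn(
            f"excluding {int((~ok).sum())} member(s) exactly at the group centroid",
            stacklevel=2,
        )
    return float(np.mean(from_origin[ok] / from_centroid[ok]))


def _group_scores(scores: np.ndarray, group_rows: np.ndarray | None) -> np.ndarray:
    X = np.asarray(scores, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    if group_rows is not None:
        X = X[np.asarray(group_rows)]
    return X


def bootstrap_disparity(
    scores: np.ndarray,
    group_rows: np.ndarray | None,
    metric: str = "sum_of_variances",
    n_boot: int = 1000,
    rarefy_to: Optional[int] = None,
    seed: int = 0,
    group: str = "",
) -> DisparityEstimate:
    """Bootstrap (optionally rarefied) distribution of a disparity metric.

    Each replicate draws ``rarefy_to`` rows (default: the full group size)
    with replacement and recomputes the metric; the 95% CI is the 2.5/97.5
    percentile band.  Groups below 3 specimens are flagged "too small for
    disparity" -- their observed value is still reported, but replicates of
    size < 2 cannot support a variance, so rarefaction below 3 is refused.
    """
    X = _group_scores(scores, group_rows)
    n = len(X)
    if n_boot < 100:
        raise ValueError("n_boot must be >= 100 for stable percentile CIs")
    if rarefy_to is not None:
        if rarefy_to < MIN_GROUP_SIZE:
            raise ValueError(
                f"rarefy_to={rarefy_to} below minimum {MIN_GROUP_SIZE}: "
                "metric unstable at that size"
            )
        if rarefy_to > n:
            raise ValueError(f"rarefy_to={rarefy_to} exceeds group size {n}")
    fn = METRICS[metric]
    flags = []
    if n < MIN_GROUP_SIZE:
        flags.append("too small for disparity")
    observed = fn(X)
    m = rarefy_to if rarefy_to is not None else n
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, n, size=(n_boot, m))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        boot = np.array([_safe_metric(fn, X[row]) for row in idx])
    valid = boot[~np.isnan(boot)]
    if len(valid) == 0:
        raise ValueError(f"group {group!r}: no valid bootstrap replicate")
    lo, hi = np.percentile(valid, [2.5, 97.5])
    return DisparityEstimate(
        metric=metric, group=group, observed=observed, bootstrap_values=boot,
        n=n, rarefied_n=rarefy_to, ci95=(float(lo), float(hi)), seed=seed,
        flags=flags,
    )


def _safe_metric(fn, X: np.ndarray) -> float:
    try:
        return fn(X)
    except ValueError:
        return np.nan
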