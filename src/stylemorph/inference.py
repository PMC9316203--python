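"""Permutation and resampling tests on the morphospace.

* :func:`permanova` -- one-way PERMANOVA: a pseudo-F statistic computed from
  the matrix of (squared) Euclidean distances between specimens' effective-PC
  scores, with a null distribution obtained by freely permuting the group
  labels.  Tests whether groups occupy different *positions* in morphospace.
* :func:`pairwise_size_position_tests` -- bootstrapped random-sampling tests
  for group differences in a disparity metric (occupied size, or position as
  average displacement).  The null resamples both pseudo-groups from the
  pooled pair, each rarefied to the smaller group's size, which is valid
  under the exchangeability hypothesis of no group difference.  Raw p-values
  are Bonferroni-corrected over the number of pairs tested.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .disparity import MIN_GROUP_SIZE, METRICS

__all__ = [
    "PermanovaResult",
    "PairwiseTestResult",
    "permanova",
    "pairwise_size_position_tests",
    "make_grouping",
]


@dataclass
class PermanovaResult:
    pseudo_F: float
    p_value: float
    n_permutations: int
    permutation_Fs: np.ndarray
    seed: int
    grouping: list[str]
    exact: bool = False


@dataclass
class PairwiseTestResult:
    pair: tuple[str, str]
    metric: str
    observed_diff: float
    null_values: np.ndarray
    p_raw: float
    p_bonferroni: float
    n_resamples: int
    seed: int
    testable: bool = True
    note: str = ""


def make_grouping(labels: Sequence[str], scheme: str, extant: str = "extant") -> list[str]:
    """Map time-slice labels onto a grouping scheme.

    ``coarse`` pools every non-extant slice into "fossil" (the headline
    fossil-vs-extant comparison); ``slices`` keeps the labels as given.
    """
    if scheme == "slices":
        return list(labels)
    if scheme == "coarse":
        return [lab if lab == extant else "fossil" for lab in labels]
    raise ValueError(f"unknown grouping scheme {scheme!r}")


def _group_codes(labels: Sequence[str]) -> tuple[np.ndarray, list[str]]:
    names = sorted(set(labels))
    lookup = {g: i for i, g in enumerate(names)}
    return np.array([lookup[lab] for lab in labels]), names


def _ssw(D2: np.ndarray, perm_labels: np.ndarray, n_groups: int,
         counts: np.ndarray) -> np.ndarray:
    """Within-group sum of squared distances for a batch of labelings.

    ``perm_labels`` is (B, N); returns (B,).  Uses the identity
    SSW = sum_g (z_g' D2 z_g) / (2 n_g) with indicator vectors z_g.
    """
    B = perm_labels.shape[0]
    ssw = np.zeros(B)
    for g in range(n_groups):
        Z = (perm_labels == g).T.astype(float)  # (N, B)
        ssw += np.einsum("nb,nb->b", D2 @ Z, Z) / (2.0 * counts[g])
    return ssw


def permanova(
    scores: np.ndarray,
    labels: Sequence[str],
    n_permutations: int = 9999,
    seed: int = 0,
) -> PermanovaResult:
    """One-way PERMANOVA on Euclidean distances between score rows.

    pseudo-F = (SSB / (g-1)) / (SSW / (N-g)) from the squared-distance
    partition.  When the number of distinct label rearrangements is at most
    ``n_permutations`` the null is enumerated exhaustively and the p-value is
    exact; otherwise ``n_permutations`` random permutations are drawn and
    p = (1 + #{F_perm >= F_obs}) / (1 + n_permutations), which can never be 0.
    """
    X = np.asarray(scores, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    codes, names = _group_codes(labels)
    counts = np.bincount(codes)
    if len(names) < 2:
        raise ValueError("need at least 2 groups")
    if counts.min() < 2:
        small = names[int(np.argmin(counts))]
        raise ValueError(f"group {small!r} has fewer than 2 members")
    N, g = len(X), len(names)

    sq = np.sum(X**2, axis=1)
    D2 = sq[:, None] + sq[None, :] - 2.0 * (X @ X.T)
    np.clip(D2, 0.0, None, out=D2)
    np.fill_diagonal(D2, 0.0)
    sst = D2.sum() / (2.0 * N)

    def f_stat(ssw: np.ndarray) -> np.ndarray:
        ssb = sst - ssw
        return (ssb / (g - 1)) / (ssw / (N - g))

    F_obs = float(f_stat(_ssw(D2, codes[None, :], g, counts))[0])

    n_distinct = math.factorial(N) // math.prod(math.factorial(int(c)) for c in counts)
    if n_distinct <= n_permutations:
        perms = np.array(list(_multiset_permutations(codes)), dtype=int)
        Fs = f_stat(_ssw(D2, perms, g, counts))
        p = float(np.sum(Fs >= F_obs - 1e-12) / len(Fs))
        return PermanovaResult(F_obs, p, len(Fs), Fs, seed, names, exact=True)

    rng = np.random.default_rng(seed)
    perms = np.array([rng.permutation(codes) for _ in range(n_permutations)])
    Fs = f_stat(_ssw(D2, perms, g, counts))
    p = float((1 + np.sum(Fs >= F_obs - 1e-12)) / (1 + n_permutations))
    return PermanovaResult(F_obs, p, n_permutations, Fs, seed, names, exact=False)


def _multiset_permutations(codes: np.ndarray):
    """All distinct orderings of a label multiset (exhaustive-null mode)."""
    counts = {c: int(n) for c, n in zip(*np.unique(codes, return_counts=True))}
    n = len(codes)

    def rec(prefix: list[int]):
        if len(prefix) == n:
            yield tuple(prefix)
            return
        for c in sorted(counts):
            if counts[c] > 0:
                counts[c] -= 1
                prefix.append(c)
                yield from rec(prefix)
                prefix.pop()
                counts[c] += 1

    yield from rec([])


def pairwise_size_position_tests(
    scores: np.ndarray,
    labels: Sequence[str],
    metric: str = "sum_of_variances",
    n_resamples: int = 999,
    seed: int = 0,
    min_group_size: int = MIN_GROUP_SIZE,
) -> list[PairwiseTestResult]:
    """Bootstrapped pairwise tests of a disparity metric between groups.

    For each pair: observed = |metric(A) - metric(B)|; the null draws two
    bootstrap samples from the pooled pair, each of the smaller group's size
    (rarefaction inside the bootstrap), and records their absolute metric
    difference.  Pairs with a group below ``min_group_size`` are reported as
    untestable rather than silently dropped.
    """
    if metric not in METRICS:
        raise ValueError(f"unknown metric {metric!r}")
    X = np.asarray(scores, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    labels = np.asarray(list(labels))
    names = sorted(set(labels))
    pairs = list(itertools.combinations(names, 2))
    rng = np.random.default_rng(seed)

    results: list[PairwiseTestResult] = []
    testable_pairs = []
    for a, b in pairs:
        na = int(np.sum(labels == a))
        nb = int(np.sum(labels == b))
        if min(na, nb) < min_group_size:
            results.append(
                PairwiseTestResult(
                    (a, b), metric, np.nan, np.array([]), np.nan, np.nan,
                    n_resamples, seed, testable=False,
                    note=f"group below minimum size {min_group_size} "
                         f"(n={na} vs n={nb})",
                )
            )
            continue
        testable_pairs.append((a, b, na, nb))

    n_comparisons = len(testable_pairs)
    fn = METRICS[metric]
    for a, b, na, nb in testable_pairs:
        Xa, Xb = X[labels == a], X[labels == b]
        observed = abs(fn(Xa) - fn(Xb))
        pooled = np.vstack([Xa, Xb])
        m = min(na, nb)
        null = _pooled_null(pooled, m, n_resamples, metric, rng)
        p_raw = float((1 + np.sum(null >= observed - 1e-12)) / (1 + n_resamples))
        results.append(
            PairwiseTestResult(
                (a, b), metric, float(observed), null, p_raw,
                min(1.0, p_raw * n_comparisons), n_resamples, seed,
            )
        )
    return results


def _pooled_null(pooled: np.ndarray, m: int, R: int, metric: str,
                 rng: np.random.Generator) -> np.ndarray:
    N = len(pooled)
    i1 = rng.integers(0, N, size=(R, m))
    i2 = rng.integers(0, N, size=(R, m))
    v1 = _metric_batch(pooled, i1, metric)
    v2 = _metric_batch(pooled, i2, metric)
    return np.abs(v1 - v2)


def _metric_batch(pooled: np.ndarray, idx: np.ndarray, metric: str) -> np.ndarray:
    """Vectorized metric over bootstrap index matrix (R, m)."""
    S = pooled[idx]  # (R, m, k)
    if metric == "sum_of_variances":
        return S.var(axis=1, ddof=1).sum(axis=1)
    if metric == "average_displacement":
        centroid = S.mean(axis=1, keepdims=True)
        from_origin = np.linalg.norm(S, axis=2)
        from_centroid = np.linalg.norm(S - centroid, axis=2)
        ratio = np.where(from_centroid > 0.0, from_origin / np.where(from_centroid > 0, from_centroid, 1.0), np.nan)
        with np.errstate(invalid="ignore"):
            return np.nanmean(ratio, axis=1)
    raise ValueError(f"unknown metric {metric!r}")
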