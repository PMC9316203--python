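"""PCA morphospace over normalized Fourier coefficients.

Each specimen becomes one row of a coefficient matrix (the normalized
harmonic coefficients with the three constants fixed by normalization --
a1, b1, c1 -- dropped; d1 is retained because it still varies between
shapes).  A centered, unstandardized covariance PCA turns the matrix into a
morphospace; the number of "effective" components is the count of
eigenvalues above the mean eigenvalue, the conventional broken-mean rule of
outline-morphometrics software.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .efa import EFACoefficients, reconstruct
from .outlines import Outline

logger = logging.getLogger(__name__)

__all__ = [
    "MorphospaceEmbedding",
    "assemble_matrix",
    "pca",
    "effective_components",
    "shape_along_pc",
]


@dataclass
class MorphospaceEmbedding:
    """PC scores and spectrum of a coefficient-matrix PCA."""

    scores: np.ndarray          # (n_specimens, n_components)
    eigenvalues: np.ndarray     # nonincreasing
    proportions: np.ndarray     # explained-variance fractions, sum 1
    loadings: np.ndarray        # (n_columns, n_components), orthonormal columns
    mean_vector: np.ndarray     # column means of the input matrix
    columns: list[str]
    specimen_ids: list[str]
    groups: list[str]
    effective_k: int = 0
    n_harmonics: int = 0

    def group_rows(self, group: str) -> np.ndarray:
        return np.flatnonzero(np.asarray(self.groups) == group)


def assemble_matrix(
    coeff_list: Sequence[EFACoefficients],
) -> tuple[np.ndarray, list[str]]:
    """Stack normalized coefficients into a specimen x coefficient matrix.

    Columns are every harmonic coefficient except a1, b1, c1 (fixed to 1, 0,
    0 by normalization); with H harmonics that is 4H - 3 columns.  Returns
    the matrix and a manifest naming each column (e.g. ``d1``, ``a2`` ...).
    """
    if not coeff_list:
        raise ValueError("empty coefficient list")
    H = coeff_list[0].n_harmonics
    rows = []
    for cf in coeff_list:
        if not cf.normalized:
            raise ValueError(f"{cf.specimen_id or 'specimen'}: coefficients not normalized")
        if cf.n_harmonics != H:
            raise ValueError(
                f"mixed harmonic counts: {cf.n_harmonics} vs {H} "
                f"({cf.specimen_id or 'specimen'})"
            )
        rows.append(np.concatenate([[cf.d[0]], cf.a[1:], cf.b[1:], cf.c[1:], cf.d[1:]]))
    columns = (
        ["d1"]
        + [f"a{n}" for n in range(2, H + 1)]
        + [f"b{n}" for n in range(2, H + 1)]
        + [f"c{n}" for n in range(2, H + 1)]
        + [f"d{n}" for n in range(2, H + 1)]
    )
    return np.vstack(rows), columns


def pca(
    matrix: np.ndarray,
    columns: Sequence[str] | None = None,
    specimen_ids: Sequence[str] | None = None,
    groups: Sequence[str] | None = None,
    n_harmonics: int = 0,
) -> MorphospaceEmbedding:
    """Centered, unstandardized PCA of the coefficient matrix.

    Eigendecomposition of the sample covariance matrix (n-1 denominator);
    scores are the centered rows projected on the eigenvectors.  Each
    loading's sign is fixed so its largest-magnitude entry is positive, for
    reproducible score plots.
    """
    X = np.asarray(matrix, dtype=float)
    if X.ndim != 2 or X.shape[0] < 3:
        raise ValueError("need a 2D matrix with at least 3 rows")
    if np.isnan(X).any():
        raise ValueError("matrix contains missing values")
    mean = X.mean(axis=0)
    Xc = X - mean
    # SVD route: numerically stabler than forming the covariance matrix
    U, s, Vt = np.linalg.svd(Xc, full_matrices=False)
    n = X.shape[0]
    eigenvalues = s**2 / (n - 1)
    total = eigenvalues.sum()
    if total <= 0.0:
        raise ValueError("rank-0 matrix: no variation to decompose")
    r = int(np.sum(s > s[0] * 1e-12)) if s[0] > 0 else 0
    eigenvalues = eigenvalues[:r]
    loadings = Vt[:r].T.copy()
    # deterministic sign: largest-|entry| of each loading positive
    for j in range(r):
        i = int(np.argmax(np.abs(loadings[:, j])))
        if loadings[i, j] < 0:
            loadings[:, j] *= -1.0
    scores = Xc @ loadings
    emb = MorphospaceEmbedding(
        scores=scores,
        eigenvalues=eigenvalues,
        proportions=eigenvalues / total,
        loadings=loadings,
        mean_vector=mean,
        columns=list(columns) if columns is not None else [f"col{i}" for i in range(X.shape[1])],
        specimen_ids=list(specimen_ids) if specimen_ids is not None else [str(i) for i in range(n)],
        groups=list(groups) if groups is not None else [""] * n,
        n_harmonics=n_harmonics,
    )
    emb.effective_k = effective_components(emb)
    return emb


def effective_components(embedding: MorphospaceEmbedding) -> int:
    """Number of effective PCs: eigenvalues strictly above the mean eigenvalue.

    If no eigenvalue exceeds the mean (all equal -- an isotropic cloud), the
    rule is uninformative; fall back to k = 2 with a warning so downstream
    plots and disparity still have a plane to work in.
    """
    lam = embedding.eigenvalues
    k = int(np.sum(lam > lam.mean()))
    if k == 0:
        warnings.warn(
            "all eigenvalues equal: effective-component rule degenerate, "
            "falling back to k=2",
            stacklevel=2,
        )
        k = min(2, len(lam))
    embedding.effective_k = k
    return k


def shape_along_pc(
    embedding: MorphospaceEmbedding,
    pc_index: int,
    multiplier: float,
    n_points: int = 256,
) -> Outline:
    """Render the outline at ``mean + multiplier * SD(pc) * loading``.

    ``pc_index`` is 1-based.  ``multiplier`` is in standard-deviation units
    of the chosen component's scores; 0 returns the mean shape.  Used to
    visualize what each PC encodes (rim concavity, relative stylet length,
    stylet thickness ... ).
    """
    if not 1 <= pc_index <= len(embedding.eigenvalues):
        raise ValueError(f"pc_index {pc_index} out of range")
    j = pc_index - 1
    sd = float(np.sqrt(embedding.eigenvalues[j]))
    vec = embedding.mean_vector + multiplier * sd * embedding.loadings[:, j]
    coeffs = _vector_to_coeffs(vec, embedding.columns)
    return reconstruct(coeffs, n_points=n_points,
                       specimen_id=f"PC{pc_index}{multiplier:+g}SD")


def _vector_to_coeffs(vec: np.ndarray, columns: Sequence[str]) -> EFACoefficients:
    """Rebuild an EFACoefficients from a coefficient-matrix row, restoring
    the constants dropped by :func:`assemble_matrix` (a1=1, b1=c1=0)."""
    by_name = dict(zip(columns, vec))
    H = max(int(name[1:]) for name in columns)
    a = np.array([1.0] + [by_name[f"a{n}"] for n in range(2, H + 1)])
    b = np.array([0.0] + [by_name[f"b{n}"] for n in range(2, H + 1)])
    c = np.array([0.0] + [by_name[f"c{n}"] for n in range(2, H + 1)])
    d = np.array([by_name["d1"]] + [by_name[f"d{n}"] for n in range(2, H + 1)])
    return EFACoefficients(a, b, c, d, normalized=True)
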