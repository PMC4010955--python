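"""Representation, validation and partitioning of the general linear model.

The model is ``Y = M @ psi + eps`` with a full-rank N x r design ``M`` and an
r x s contrast ``C`` (1 <= s <= r) expressing the null hypothesis
``C' psi = 0``.  For permutation methods the design is re-expressed in the
partitioned form ``Y = X @ beta + Z @ gamma + eps`` where ``X`` carries the
effects of interest and ``Z`` the nuisance.  The partition is not unique; the
scheme used here is contrast-driven,

    X = M (M'M)^{-1} C (C' (M'M)^{-1} C)^{-1},      Z = M Cv,

with ``Cv`` an orthonormal basis of the null space of ``C'``.  With this
choice ``beta = C' psi`` exactly, so testing ``beta = 0`` in the partitioned
model is the same hypothesis, and the F statistic computed from either form
is identical for any data vector.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import linalg


__all__ = [
    "DesignMatrix",
    "Contrast",
    "PartitionedModel",
    "GlmFit",
    "residual_forming",
    "partition_model",
    "fit_glm",
]


def _as_2d(a, name: str) -> np.ndarray:
    a = np.asarray(a, dtype=float)
    if a.ndim == 1:
        a = a[:, None]
    if a.ndim != 2:
        raise ValueError(f"{name} must be a 2-D array, got ndim={a.ndim}")
    if not np.all(np.isfinite(a)):
        raise ValueError(f"{name} contains non-finite entries")
    return a


def matrix_rank(a: np.ndarray) -> int:
    """Numerical rank with the standard tolerance N * eps * sigma_max."""
    if a.size == 0:
        return 0
    return int(np.linalg.matrix_rank(a))


@dataclass(frozen=True)
class DesignMatrix:
    """Full design matrix M (N observations x r regressors), full column rank."""

    M: np.ndarray
    N: int = field(init=False)
    r: int = field(init=False)

    def __post_init__(self):
        M = _as_2d(self.M, "design matrix")
        object.__setattr__(self, "M", M)
        N, r = M.shape
        if N <= r:
            raise ValueError(f"need more observations than regressors (N={N}, r={r})")
        if matrix_rank(M) < r:
            raise ValueError("design matrix is rank deficient")
        object.__setattr__(self, "N", N)
        object.__setattr__(self, "r", r)


@dataclass(frozen=True)
class Contrast:
    """Contrast matrix C (r x s), full column rank, testing C' psi = 0."""

    C: np.ndarray
    s: int = field(init=False)

    def __post_init__(self):
        C = _as_2d(self.C, "contrast")
        object.__setattr__(self, "C", C)
        r, s = C.shape
        if s > r:
            raise ValueError(f"contrast rank s={s} exceeds regressor count r={r}")
        if matrix_rank(C) < s:
            raise ValueError("contrast matrix is rank deficient")
        object.__setattr__(self, "s", s)


@dataclass(frozen=True)
class PartitionedModel:
    """Design split into interest X (N x s) and nuisance Z (N x (r-s))."""

    X: np.ndarray
    Z: np.ndarray
    H_M: np.ndarray
    R_M: np.ndarray
    H_Z: np.ndarray
    R_Z: np.ndarray

    @property
    def N(self) -> int:
        return self.X.shape[0]

    @property
    def s(self) -> int:
        return self.X.shape[1]

    @property
    def design(self) -> np.ndarray:
        """The recombined design [X Z], spanning the same space as M."""
        return np.column_stack([self.X, self.Z])


@dataclass(frozen=True)
class GlmFit:
    """Least-squares fit: coefficients psi_hat (r x V) and residuals (N x V)."""

    psi_hat: np.ndarray
    residuals: np.ndarray
    rank_M: int


def residual_forming(A) -> tuple[np.ndarray, np.ndarray]:
    """Hat matrix H = A A^+ and residual-forming matrix R = I - H.

    A zero-width ``A`` (no columns) yields H = 0, R = I.
    """
    A = np.asarray(A, dtype=float)
    if A.ndim == 1:
        A = A[:, None]
    N = A.shape[0]
    if A.shape[1] == 0:
        H = np.zeros((N, N))
        return H, np.eye(N)
    if not np.all(np.isfinite(A)):
        raise ValueError("matrix contains non-finite entries")
    H = A @ np.linalg.pinv(A)
    H = (H + H.T) / 2.0  # enforce exact symmetry
    return H, np.eye(N) - H


def partition_model(
    design: DesignMatrix | np.ndarray,
    contrast: Contrast | np.ndarray,
    scheme: str = "contrast",
) -> PartitionedModel:
    """Split the design into interest and nuisance partitions for a contrast.

    Parameters
    ----------
    design, contrast
        The full model and the hypothesis.  Arrays are validated and wrapped.
    scheme
        ``"contrast"`` (default) uses the contrast-driven construction in the
        module docstring, valid for any full-rank C.  ``"columns"`` selects
        design columns directly and requires every contrast column to be an
        elementary vector (one +/-1 and zeros); it reproduces the naive,
        unpartitioned reading of a column-selecting contrast.

    Inference on beta in the partitioned model is equivalent to inference on
    C' psi in the original one under either scheme.
    """
    if not isinstance(design, DesignMatrix):
        design = DesignMatrix(design)
    if not isinstance(contrast, Contrast):
        contrast = Contrast(contrast)
    M, C = design.M, contrast.C
    if C.shape[0] != design.r:
        raise ValueError(
            f"contrast has {C.shape[0]} rows but design has {design.r} regressors"
        )

    if scheme == "columns":
        nz = np.abs(C) > 0
        if np.any(nz.sum(axis=0) != 1):
            raise ValueError(
                "scheme='columns' needs elementary contrast columns "
                "(exactly one nonzero entry each)"
            )
        sel = np.where(nz.any(axis=1))[0]
        rest = np.setdiff1d(np.arange(design.r), sel)
        X = M[:, sel] * np.sign(C[sel].sum(axis=0))
        Z = M[:, rest]
    elif scheme == "contrast":
        MtM = M.T @ M
        A = np.linalg.solve(MtM, C)  # (M'M)^{-1} C
        X = M @ A @ np.linalg.inv(C.T @ A)
        Cv = linalg.null_space(C.T)  # r x (r-s), orthonormal
        Z = M @ Cv
    else:
        raise ValueError(f"unknown partitioning scheme {scheme!r}")

    H_M, R_M = residual_forming(M)
    H_Z, R_Z = residual_forming(Z)
    # Z spanning X would make the interest partition untestable
    if np.allclose(H_Z @ X, X, atol=1e-8 * max(1.0, np.abs(X).max())):
        raise ValueError("nuisance partition spans the effects of interest")
    return PartitionedModel(X=X, Z=Z, H_M=H_M, R_M=R_M, H_Z=H_Z, R_Z=R_Z)


def fit_glm(Y, design: DesignMatrix | np.ndarray) -> GlmFit:
    """Least-squares fit of ``Y = M psi + eps``, vectorised over columns of Y.

    psi_hat = M^+ Y and residuals = R_M Y; Y may be a vector (one test) or an
    N x V matrix of V simultaneous tests.
    """
    if not isinstance(design, DesignMatrix):
        design = DesignMatrix(design)
    Y = np.asarray(Y, dtype=float)
    squeeze = Y.ndim == 1
    if squeeze:
        Y = Y[:, None]
    if Y.shape[0] != design.N:
        raise ValueError(
            f"data has {Y.shape[0]} rows but design has {design.N} observations"
        )
    if not np.all(np.isfinite(Y)):
        raise ValueError("data contains non-finite entries")
    pinv = np.linalg.pinv(design.M)
    psi = pinv @ Y
    resid = Y - design.M @ psi
    if squeeze:
        psi, resid = psi[:, 0], resid[:, 0]
    return GlmFit(psi_hat=psi, residuals=resid, rank_M=design.r)
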