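"""Test statistics for GLM contrasts: F, t, and the heteroscedasticity-robust G.

F pools the residual variance across all observations and is pivotal only
when the errors are identically distributed.  When *variance groups* (VGs)
are present -- subsets of observations assumed to share an error variance --
the generalised statistic

    G = psi' C (C' (M' W M)^{-1} C)^{-1} C' psi / (Lambda * rank(C))

uses a diagonal weight matrix W whose entries are the reciprocal of the
estimated within-group variance,

    W_nn = (sum_{n' in g_n} R_{n'n'}) / (eps_g' eps_g),

with R the residual-forming matrix of the model, and a Welch-type correction

    Lambda = 1 + [2(s-1) / (s(s+2))] *
             sum_g (1 / sum_{n in g} R_nn) (1 - sum_{n in g} W_nn / tr W)^2.

With a single VG, Lambda = 1 and G = F.  For rank-1 contrasts,
sign(beta) sqrt(G) is the Aspin-Welch v (Behrens-Fisher problem); with one VG
it is Student's t.  For several groups and an all-means-equal contrast, G is
Welch's v^2 statistic.

All routines are vectorised over V simultaneous tests (columns of the data).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "VarianceGroups",
    "WeightMatrix",
    "StatisticValue",
    "compute_F",
    "compute_t",
    "compute_weights",
    "compute_lambda",
    "compute_G",
    "StatContext",
    "glm_statistic",
]


@dataclass(frozen=True)
class VarianceGroups:
    """Partition of the N observations into groups of presumed equal variance."""

    labels: np.ndarray
    groups: np.ndarray = field(init=False)
    indices: tuple = field(init=False)

    def __post_init__(self):
        lab = np.asarray(self.labels)
        if lab.ndim != 1:
            raise ValueError("variance-group labels must be a 1-D vector")
        object.__setattr__(self, "labels", lab)
        groups, inv = np.unique(lab, return_inverse=True)
        object.__setattr__(self, "groups", groups)
        object.__setattr__(
            self, "indices", tuple(np.where(inv == k)[0] for k in range(len(groups)))
        )
        sizes = np.array([len(ix) for ix in self.indices])
        if np.any(sizes == 1):
            warnings.warn(
                "variance group of size 1: its variance is estimated from a "
                "single residual",
                stacklevel=2,
            )

    @property
    def n_groups(self) -> int:
        return len(self.groups)

    @property
    def sizes(self) -> np.ndarray:
        return np.array([len(ix) for ix in self.indices])

    @classmethod
    def single(cls, N: int) -> "VarianceGroups":
        return cls(np.zeros(N, dtype=int))


@dataclass(frozen=True)
class WeightMatrix:
    """Diagonal of W (per observation) plus the per-group pieces it is built from.

    ``group_weights`` has shape (n_groups, V): within a group every
    observation shares the same weight.
    """

    W_diag: np.ndarray
    group_weights: np.ndarray
    group_rdiag_sums: np.ndarray
    group_indices: tuple

    @property
    def trace(self) -> np.ndarray:
        return self.W_diag.sum(axis=0)


@dataclass(frozen=True)
class StatisticValue:
    value: np.ndarray
    kind: str  # one of {"F", "t", "G", "v"}
    s: int
    lam: np.ndarray | float = 1.0


def _interest_gram_inverse(D: np.ndarray, s: int) -> np.ndarray:
    """(Top-left s x s block of (D'D)^{-1})^{-1}, the numerator metric for F."""
    Q = np.linalg.inv(D.T @ D)[:s, :s]
    return np.linalg.inv(Q)


def compute_F(psi_hat, D, s, residuals, rank_D=None, dof=None):
    """F statistic for the first ``s`` columns (interest block) of design D.

    F = [beta' (block of (D'D)^{-1})^{-1} beta / s] / [rss / dof], where
    ``beta`` is the first-s-rows block of ``psi_hat`` and dof defaults to
    N - rank(D).  Vectorised over the columns of psi_hat/residuals.
    Perfect fits (zero residual variance, nonzero numerator) yield +inf with
    a warning rather than an error.
    """
    D = np.asarray(D, dtype=float)
    psi_hat = np.atleast_2d(np.asarray(psi_hat, dtype=float).T).T
    residuals = np.atleast_2d(np.asarray(residuals, dtype=float).T).T
    N = D.shape[0]
    if rank_D is None:
        rank_D = int(np.linalg.matrix_rank(D))
    if dof is None:
        dof = N - rank_D
    if dof <= 0:
        raise ValueError("no residual degrees of freedom")
    beta = psi_hat[:s, :]
    K = _interest_gram_inverse(D, s)
    num = np.einsum("sv,st,tv->v", beta, K, beta) / s
    rss = np.einsum("nv,nv->v", residuals, residuals)
    with np.errstate(divide="ignore", invalid="ignore"):
        F = num / (rss / dof)
    F = np.where(np.isnan(F), 0.0, F)  # 0/0: no effect, no noise
    # F is scale-free, so an enormous ratio can only mean a degenerate fit
    # (residual variance at rounding-error level)
    degenerate = F > 1e12
    if np.any(degenerate):
        warnings.warn("zero residual variance: F set to +inf", stacklevel=2)
        F = np.where(degenerate, np.inf, F)
    return StatisticValue(value=F, kind="F", s=s)


def compute_t(F_value: StatisticValue, beta_hat) -> StatisticValue:
    """Signed square root t = sign(beta) sqrt(F) for rank-1 contrasts.

    Applied to G instead of F this yields the Aspin-Welch v.
    """
    if F_value.s != 1:
        raise ValueError("t statistic requires a rank-1 contrast")
    beta = np.atleast_1d(np.asarray(beta_hat, dtype=float))
    t = np.sign(beta) * np.sqrt(F_value.value)
    kind = "v" if F_value.kind == "G" else "t"
    return StatisticValue(value=t, kind=kind, s=1, lam=F_value.lam)


def compute_weights(residuals, vg: VarianceGroups, R_diag) -> WeightMatrix:
    """Per-observation weights: group effective dof over group residual sum
    of squares.  ``R_diag`` is the diagonal of the residual-forming matrix of
    the fitted model.  Vectorised over residual columns.
    """
    residuals = np.atleast_2d(np.asarray(residuals, dtype=float).T).T
    R_diag = np.asarray(R_diag, dtype=float)
    N, V = residuals.shape
    nG = vg.n_groups
    rho = np.array([R_diag[ix].sum() for ix in vg.indices])  # effective dof per group
    rss = np.empty((nG, V))
    for k, ix in enumerate(vg.indices):
        rss[k] = np.einsum("nv,nv->v", residuals[ix], residuals[ix])
    if np.any(rss == 0):
        bad = [str(vg.groups[k]) for k in range(nG) if np.any(rss[k] == 0)]
        raise ValueError(f"zero residual sum of squares in variance group(s) {bad}")
    gw = rho[:, None] / rss  # (nG, V)
    W = np.empty((N, V))
    for k, ix in enumerate(vg.indices):
        W[ix] = gw[k]
    return WeightMatrix(
        W_diag=W, group_weights=gw, group_rdiag_sums=rho, group_indices=vg.indices
    )


def compute_lambda(W: WeightMatrix, vg: VarianceGroups, s: int):
    """Welch-type correction Lambda (vector over tests; 1.0 when forced).

    Lambda = 1 + [2(s-1)/(s(s+2))] sum_g (1/rho_g)(1 - S_g / tr W)^2 where
    S_g is the summed weight of group g and rho_g its summed R_nn.
    """
    if s < 1:
        raise ValueError("contrast rank must be >= 1")
    if s == 1 or vg.n_groups == 1:
        V = W.group_weights.shape[1]
        return np.ones(V)
    sizes = vg.sizes[:, None]
    Sg = sizes * W.group_weights  # (nG, V) summed weights per group
    trW = Sg.sum(axis=0)
    rho = W.group_rdiag_sums[:, None]
    term = ((1.0 - Sg / trW) ** 2 / rho).sum(axis=0)
    return 1.0 + 2.0 * (s - 1) / (s * (s + 2)) * term


def compute_G(psi_hat, D, s, W: WeightMatrix, lam) -> StatisticValue:
    """Heteroscedasticity-robust statistic on the interest block of design D.

    G = beta' (block of (D' W D)^{-1})^{-1} beta / (Lambda * s), with W the
    diagonal weight matrix.  With one variance group G equals F exactly.
    Vectorised: W (and hence the weighted Gram matrix) differs per test, so
    the r x r inverses are batched over the V columns.
    """
    D = np.asarray(D, dtype=float)
    psi_hat = np.atleast_2d(np.asarray(psi_hat, dtype=float).T).T
    lam = np.atleast_1d(np.asarray(lam, dtype=float))
    r = D.shape[1]
    V = psi_hat.shape[1]
    beta = psi_hat[:s, :]

    # D' W D = sum_g w_g(v) * D_g' D_g ; the per-group Gram matrices are
    # constant across tests, only the weights vary.
    nG = W.group_weights.shape[0]
    grams = np.empty((nG, r, r))
    for k, ix in enumerate(W.group_indices):
        grams[k] = D[ix].T @ D[ix]
    A = np.einsum("gv,gij->vij", W.group_weights, grams)  # (V, r, r)
    Ainv = np.linalg.inv(A)
    Q = Ainv[:, :s, :s]  # (V, s, s) block of (D'WD)^{-1}
    Kb = np.linalg.solve(Q, beta.T[:, :, None])[:, :, 0]  # (V, s)
    num = np.einsum("vs,sv->v", Kb, beta)
    G = num / (lam * s)
    return StatisticValue(value=G, kind="G", s=s, lam=lam)


class StatContext:
    """Precomputed pieces for repeatedly evaluating a statistic on one design.

    The permutation engine fits thousands of data matrices against the same
    design, so the pseudo-inverse, numerical rank, residual-forming diagonal
    and variance-group bookkeeping are computed once here.

    ``kind='auto'`` picks G (signed v for s=1) when multiple variance groups
    are present, F (signed t for s=1) otherwise.  ``lambda_one`` replaces the
    Welch correction by 1 (James's variant), kept as a diagnostic toggle.
    """

    def __init__(
        self,
        D,
        s: int,
        vg: VarianceGroups | None = None,
        kind: str = "auto",
        dof: int | None = None,
        lambda_one: bool = False,
    ):
        D = np.asarray(D, dtype=float)
        N = D.shape[0]
        if vg is None:
            vg = VarianceGroups.single(N)
        multi = vg.n_groups > 1
        if kind == "auto":
            kind = ("v" if s == 1 else "G") if multi else ("t" if s == 1 else "F")
        if kind in ("t", "v") and s != 1:
            raise ValueError("t/v statistics require a rank-1 contrast")
        self.D, self.s, self.vg, self.kind, self.dof = D, s, vg, kind, dof
        self.lambda_one = lambda_one
        self.pinv = np.linalg.pinv(D)
        self.rank_D = int(np.linalg.matrix_rank(D))
        self.R_diag = 1.0 - np.einsum("ij,ji->i", D, self.pinv)
        self.use_G = kind in ("G", "v") and multi

    def compute(self, Y) -> StatisticValue:
        """Fit the data columns and return the statistic per column."""
        Y = np.atleast_2d(np.asarray(Y, dtype=float).T).T
        if Y.shape[0] != self.D.shape[0]:
            raise ValueError("data and design row counts differ")
        theta = self.pinv @ Y
        resid = Y - self.D @ theta
        if self.use_G:
            W = compute_weights(resid, self.vg, self.R_diag)
            lam = 1.0 if self.lambda_one else compute_lambda(W, self.vg, self.s)
            stat = compute_G(theta, self.D, self.s, W, lam)
        else:
            stat = compute_F(
                theta, self.D, self.s, resid, rank_D=self.rank_D, dof=self.dof
            )
            if self.kind in ("G", "v"):
                # single VG: G coincides with F
                stat = StatisticValue(value=stat.value, kind="G", s=self.s)
        if self.kind in ("t", "v"):
            stat = compute_t(stat, theta[0])
        return stat


def glm_statistic(
    Y,
    D,
    s,
    vg: VarianceGroups | None = None,
    kind: str = "auto",
    dof: int | None = None,
    lambda_one: bool = False,
):
    """Fit ``Y = D theta + eps`` and compute the requested statistic for the
    first ``s`` columns of D.  One-shot convenience over :class:`StatContext`;
    returns a :class:`StatisticValue` whose ``value`` has one entry per data
    column.
    """
    ctx = StatContext(D, s, vg=vg, kind=kind, dof=dof, lambda_one=lambda_one)
    return ctx.compute(Y)
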