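"""Nuisance-handling strategies and the vectorised permutation test.

With nuisance regressors present the data are not pure error under the null,
so there is no single exact way to shuffle; a family of approximate
strategies exists, each defining how a shuffling ``P`` enters the regression
problem:

===============  ==========================================================
draper_stoneman  Y            on  [P X, Z]
still_white      P R_Z Y      on  X alone
freedman_lane    (P R_Z + H_Z) Y  on  [X, Z]
manly            P Y          on  [X, Z]
ter_braak        (P R_M + H_M) Y  on  [X, Z]
kennedy          P R_Z Y      on  R_Z X alone
huh_jhun         P Q' R_Z Y   on  Q' R_Z X  (reduced dimension N - rank Z)
smith            Y            on  [P R_Z X, Z]
parametric       no shuffling; p-values from the F/t reference distribution
===============  ==========================================================

Freedman--Lane is the default: it permutes the residuals of the
nuisance-only fit, equivalent to the literal six-step procedure (fit reduced
model, permute its residuals, add back the nuisance effects, refit), and has
the best type-I-error behaviour across simulation conditions together with
the Smith method.

All strategies are evaluated for V data columns at once: the shuffled
transformation is formed once per shuffling and applied to the whole N x V
matrix.  Per-shuffle maxima across columns are recorded for max-statistic
FWER correction.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .design import Contrast, DesignMatrix, PartitionedModel, partition_model
from .shuffling import (
    ExchangeabilityBlocks,
    Shuffling,
    ShufflingSet,
    apply_shuffling,
    enumerate_shufflings,
)
from .statistic import StatContext, VarianceGroups

__all__ = [
    "STRATEGIES",
    "PermutationDistribution",
    "transform_model",
    "run_permutation_test",
    "parametric_pvalues",
    "round_significant",
]

STRATEGIES = (
    "draper_stoneman",
    "still_white",
    "freedman_lane",
    "manly",
    "ter_braak",
    "kennedy",
    "huh_jhun",
    "smith",
    "parametric",
)

_EMPTY_DESIGN_METHODS = ("still_white", "kennedy", "huh_jhun")


@dataclass(frozen=True)
class PermutationDistribution:
    """Observed statistics plus the permutation reference distribution.

    ``count_ge[v]`` is the number of shufflings (identity included) whose
    statistic was >= the observed one for test v; ``Tmax[j]`` is the maximum
    across tests at shuffling j.  ``Tstar`` (J x V) is kept only on request.
    """

    T0: np.ndarray
    Tmax: np.ndarray
    count_ge: np.ndarray
    J: int
    stat_kind: str
    Tstar: np.ndarray | None = None


def round_significant(x, digits: int = 12) -> np.ndarray:
    """Round to ``digits`` significant figures (elementwise, inf/0 safe).

    Permuted statistics that are genuinely tied with the observed one can
    split by floating-point noise; both sides of the >= comparison are put
    through this rounding first.
    """
    x = np.asarray(x, dtype=float)
    out = x.copy()
    mask = np.isfinite(x) & (x != 0)
    vals = x[mask]
    scale = 10.0 ** (digits - 1 - np.floor(np.log10(np.abs(vals))))
    out[mask] = np.round(vals * scale) / scale
    return out


def _huh_jhun_basis(R_Z: np.ndarray, rank_Z: int) -> np.ndarray:
    """Orthonormal basis Q of the column space of R_Z (N x (N - rank Z)),
    with a deterministic sign convention (largest-magnitude entry positive).
    """
    N = R_Z.shape[0]
    U, svals, _ = np.linalg.svd(R_Z)
    Q = U[:, : N - rank_Z]
    for k in range(Q.shape[1]):
        i = np.argmax(np.abs(Q[:, k]))
        if Q[i, k] < 0:
            Q[:, k] = -Q[:, k]
    return Q


def transform_model(method: str, sh: Shuffling, Y, part: PartitionedModel):
    """Return the shuffled regression problem (Y', X', Z', dof) for one
    strategy and one shuffling.

    ``dof`` is None when the natural residual degrees of freedom of the
    returned model apply.  This is the literal, one-shuffling form; the
    engine uses algebraically identical precomputed paths.
    """
    if method not in STRATEGIES:
        raise ValueError(f"unknown strategy {method!r}")
    Y = np.atleast_2d(np.asarray(Y, dtype=float).T).T
    X, Z = part.X, part.Z
    empty = np.empty((part.N, 0))
    if method == "parametric":
        return Y, X, Z, None
    if method == "draper_stoneman":
        return Y, apply_shuffling(sh, X), Z, None
    if method == "still_white":
        return apply_shuffling(sh, part.R_Z @ Y), X, empty, None
    if method == "freedman_lane":
        return apply_shuffling(sh, part.R_Z @ Y) + part.H_Z @ Y, X, Z, None
    if method == "manly":
        return apply_shuffling(sh, Y), X, Z, None
    if method == "ter_braak":
        return apply_shuffling(sh, part.R_M @ Y) + part.H_M @ Y, X, Z, None
    if method == "kennedy":
        return apply_shuffling(sh, part.R_Z @ Y), part.R_Z @ X, empty, None
    if method == "smith":
        return Y, apply_shuffling(sh, part.R_Z @ X), Z, None
    # huh_jhun: project into the residual space of Z and shuffle there
    rank_Z = Z.shape[1]
    Q = _huh_jhun_basis(part.R_Z, rank_Z)
    QRZ = Q.T @ part.R_Z
    if sh.N != QRZ.shape[0]:
        raise ValueError(
            "Huh-Jhun shuffles the reduced space: the shuffling must have "
            f"{QRZ.shape[0]} elements, got {sh.N}"
        )
    return apply_shuffling(sh, QRZ @ Y), QRZ @ X, np.empty((QRZ.shape[0], 0)), None


def _default_vg(blocks: ExchangeabilityBlocks | None, N: int) -> VarianceGroups:
    """Variance groups implied by the block structure: one per within-block
    EB; for whole-block, the k-th observation of every block forms group k."""
    if blocks is None or blocks.mode == "unrestricted":
        return VarianceGroups.single(N)
    if blocks.mode == "within":
        return VarianceGroups(blocks.labels)
    lab = np.empty(N, dtype=int)
    for ix in blocks.block_indices:
        lab[ix] = np.arange(len(ix))
    return VarianceGroups(lab)


def run_permutation_test(
    Y,
    M,
    C,
    *,
    blocks: ExchangeabilityBlocks | None = None,
    vg: VarianceGroups | None = None,
    method: str = "freedman_lane",
    stat: str = "auto",
    regime: str = "ee",
    n_shufflings: int = 1000,
    seed=None,
    shuffles: ShufflingSet | None = None,
    partition_scheme: str = "contrast",
    sw_full_dof: bool = False,
    dedup_cmc: bool = False,
    return_tstar: bool = False,
) -> PermutationDistribution:
    """Run the full permutation test, vectorised over the V columns of Y.

    The observed statistic T0 is the first row of the reference distribution
    (the identity shuffling comes first), so p-values computed from the
    returned counts can never be smaller than 1/J.  Shufflings are
    enumerated exhaustively when the unique count fits within
    ``n_shufflings`` and drawn by conditional Monte Carlo otherwise; repeated
    design rows in the relevant partition (X for most strategies, the full
    design for Manly and ter Braak) are detected automatically.
    """
    if method not in STRATEGIES:
        raise ValueError(f"unknown strategy {method!r}")
    if method == "parametric":
        raise ValueError(
            "the parametric strategy performs no shuffling; use "
            "parametric_pvalues instead"
        )
    design = M if isinstance(M, DesignMatrix) else DesignMatrix(M)
    contrast = C if isinstance(C, Contrast) else Contrast(C)
    Y = np.atleast_2d(np.asarray(Y, dtype=float).T).T
    N, V = Y.shape
    if N != design.N:
        raise ValueError("data and design row counts differ")
    part = partition_model(design, contrast, scheme=partition_scheme)
    s = part.s

    if method == "huh_jhun" and blocks is not None and blocks.mode != "unrestricted":
        raise ValueError("the Huh-Jhun strategy cannot honour exchangeability blocks")
    if vg is None:
        vg = _default_vg(blocks, N)

    # fixed design and shuffled-data precomputations per strategy
    rank_Z = part.Z.shape[1]
    if method == "huh_jhun":
        Q = _huh_jhun_basis(part.R_Z, rank_Z)
        QRZ = Q.T @ part.R_Z
        D = QRZ @ part.X
        base = QRZ @ Y  # shuffled part
        add = None
        eff_N = D.shape[0]
        if vg.n_groups > 1:
            raise ValueError("Huh-Jhun operates in a reduced space; variance "
                             "groups are not supported")
        vg_eff = VarianceGroups.single(eff_N)
    else:
        eff_N = N
        vg_eff = vg
        if method in ("freedman_lane",):
            D, base, add = part.design, part.R_Z @ Y, part.H_Z @ Y
        elif method == "manly":
            D, base, add = part.design, Y, None
        elif method == "ter_braak":
            D, base, add = part.design, part.R_M @ Y, part.H_M @ Y
        elif method == "still_white":
            D, base, add = part.X, part.R_Z @ Y, None
        elif method == "kennedy":
            D, base, add = part.R_Z @ part.X, part.R_Z @ Y, None
        elif method in ("draper_stoneman", "smith"):
            D, base, add = None, Y, None  # design side is shuffled instead
        else:  # pragma: no cover
            raise AssertionError(method)

    dof = None
    if method == "still_white" and sw_full_dof:
        dof = N - design.r

    if shuffles is None:
        if method in ("manly", "ter_braak"):
            X_rows = design.M
        elif method == "huh_jhun":
            X_rows = None
        else:
            X_rows = part.X
        eff_blocks = blocks
        if eff_blocks is None or method == "huh_jhun":
            eff_blocks = ExchangeabilityBlocks.unrestricted(eff_N)
        shuffles = enumerate_shufflings(
            eff_blocks,
            regime=regime,
            J_max=n_shufflings,
            seed=seed,
            X_rows=X_rows,
            dedup_cmc=dedup_cmc,
            side="design" if method in ("draper_stoneman", "smith") else "data",
        )
    if shuffles[0].N != eff_N:
        raise ValueError("shuffling size does not match the (effective) model")

    if D is not None:
        ctx = StatContext(D, s, vg=vg_eff, kind=stat, dof=dof)
        stat_kind = ctx.kind
    else:
        stat_kind = None

    J = len(shuffles)
    counts = np.zeros(V)
    Tmax = np.empty(J)
    Tstar = np.empty((J, V)) if return_tstar else None
    T0 = T0r = None
    nonfinite: list[int] = []
    for j, sh in enumerate(shuffles):
        if D is not None:
            Yj = apply_shuffling(sh, base)
            if add is not None:
                Yj = Yj + add
            vals = ctx.compute(Yj).value
        else:
            Xj = apply_shuffling(
                sh, part.X if method == "draper_stoneman" else part.R_Z @ part.X
            )
            ctx_j = StatContext(
                np.column_stack([Xj, part.Z]), s, vg=vg_eff, kind=stat, dof=dof
            )
            stat_kind = ctx_j.kind
            vals = ctx_j.compute(base).value
        if np.any(~np.isfinite(vals)):
            nonfinite.append(j)
        valsr = round_significant(vals)
        if j == 0:
            T0, T0r = vals, valsr
        counts += valsr >= T0r
        Tmax[j] = np.max(vals)
        if return_tstar:
            Tstar[j] = vals
    if nonfinite:
        warnings.warn(
            f"non-finite statistics at shuffling indices {nonfinite[:10]}"
            + ("..." if len(nonfinite) > 10 else ""),
            stacklevel=2,
        )
    return PermutationDistribution(
        T0=T0, Tmax=Tmax, count_ge=counts, J=J, stat_kind=stat_kind, Tstar=Tstar
    )


def parametric_pvalues(Y, M, C, *, stat: str = "auto", partition_scheme="contrast"):
    """Observed F or t statistics with their parametric tail-area p-values.

    Only the single-variance-group statistics have a standard reference
    distribution: F(s, N - r), or Student's t with N - r degrees of freedom
    for rank-1 contrasts (one-sided, matching the permutation convention).
    Returns ``(T0, p)`` arrays over the data columns.
    """
    from scipy import stats as sps

    design = M if isinstance(M, DesignMatrix) else DesignMatrix(M)
    contrast = C if isinstance(C, Contrast) else Contrast(C)
    Y = np.atleast_2d(np.asarray(Y, dtype=float).T).T
    part = partition_model(design, contrast, scheme=partition_scheme)
    s = part.s
    kind = ("t" if s == 1 else "F") if stat == "auto" else stat
    if kind not in ("t", "F"):
        raise ValueError("parametric p-values are available for F and t only")
    ctx = StatContext(part.design, s, kind=kind)
    T0 = ctx.compute(Y).value
    dof = design.N - design.r
    if kind == "t":
        p = sps.t.sf(T0, dof)
    else:
        p = sps.f.sf(T0, s, dof)
    return T0, p
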