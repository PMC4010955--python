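"""From permutation distributions to uncorrected, FWER and FDR p-values.

Uncorrected p-values count shufflings with a statistic at least as large as
the observed one; with the identity included, the smallest possible value is
1/J.  Familywise error is controlled with the distribution of the
per-shuffle maximum statistic across tests: thresholding the observed map at
its (1 - alpha) quantile controls the probability of any false positive.
False-discovery rate uses step-up Benjamini-Hochberg adjustment of the
uncorrected p-values.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from statsmodels.stats.multitest import multipletests

from .engine import PermutationDistribution, round_significant

__all__ = [
    "InferenceResult",
    "pvalues_uncorrected",
    "fwer_pvalues",
    "fdr_adjust",
    "fwer_threshold",
    "infer",
]


@dataclass(frozen=True)
class InferenceResult:
    """Per-test observed statistic and the three p-value flavours."""

    T0: np.ndarray
    p_unc: np.ndarray
    p_fwer: np.ndarray
    p_fdr: np.ndarray
    J: int
    fwer_thresholds: dict | None = None


def pvalues_uncorrected(dist: PermutationDistribution) -> np.ndarray:
    """p_v = (1/J) * #{j : T*_jv >= T0_v}; values lie in {1/J, ..., 1}."""
    return dist.count_ge / dist.J


def fwer_pvalues(dist: PermutationDistribution) -> np.ndarray:
    """FWER-corrected p-values from the per-shuffle maximum statistic."""
    Tmax = round_significant(dist.Tmax)
    T0 = round_significant(dist.T0)
    # count Tmax_j >= T0_v for every test v
    return (Tmax[:, None] >= T0[None, :]).sum(axis=0) / dist.J


def fwer_threshold(dist: PermutationDistribution, alpha: float = 0.05) -> float:
    """Single map threshold: the (1 - alpha) quantile of the Tmax distribution."""
    return float(np.quantile(dist.Tmax, 1.0 - alpha, method="higher"))


def fdr_adjust(p_unc) -> np.ndarray:
    """Step-up Benjamini-Hochberg adjusted p-values (monotone, in (0, 1])."""
    p = np.asarray(p_unc, dtype=float)
    if p.size == 1:
        return p.copy()
    return multipletests(p, method="fdr_bh")[1]


def infer(dist: PermutationDistribution, alpha: float = 0.05) -> InferenceResult:
    """Bundle all p-value flavours plus the single FWER map threshold."""
    p_unc = pvalues_uncorrected(dist)
    p_fwer = fwer_pvalues(dist)
    return InferenceResult(
        T0=dist.T0,
        p_unc=p_unc,
        p_fwer=p_fwer,
        p_fdr=fdr_adjust(p_unc),
        J=dist.J,
        fwer_thresholds={alpha: fwer_threshold(dist, alpha)},
    )
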