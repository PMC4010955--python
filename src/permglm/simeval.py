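"""Synthetic data generation and the two simulation studies.

Two families of scenarios are covered:

* **Group scenarios** — cell-means designs with 2 or 4 variance groups of
  specified sizes and variances (the eight canonical scenarios in
  :data:`GROUP_SCENARIOS`), testing equality of group means.  Used both for
  the statistic-robustness study (pairwise Kolmogorov-Smirnov comparison of
  null distributions across variance configurations) and for type-I-error /
  power estimation.  Under signal the true group means are [0, -1] for two
  groups and [0, -0.33, -0.67, -1] for four.

* **Regression scenarios** — one regressor of interest x1 (linear trend on
  [-1, +1], or a +/-1 split), one nuisance z1 (the mean-centred squared
  trend, or a discrete pattern orthogonal to x1), plus an intercept, with
  nuisance coefficients gamma = (0.5, 1).  Correlation between x1 and z1 is
  induced through a Cholesky factor of the target 2 x 2 correlation matrix,
  and errors are drawn from normal, uniform, exponential or Weibull laws
  standardised to zero mean and unit variance.  Used to compare the
  nuisance-handling strategies.

Proportions are reported with 95% Wilson score intervals.  Randomness is
seeded through a counter-based ladder (`numpy` SeedSequence spawning), so
any single replicate is reproducible in isolation.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
from scipy import stats as sps
from statsmodels.stats.proportion import proportion_confint

from .engine import parametric_pvalues, run_permutation_test
from .inference import pvalues_uncorrected
from .statistic import VarianceGroups, glm_statistic

__all__ = [
    "ScenarioSpec",
    "EvaluationResult",
    "KsComparison",
    "GROUP_SCENARIOS",
    "group_scenario",
    "make_scenario_design",
    "induce_correlation",
    "draw_errors",
    "simulate_group_dataset",
    "simulate_regression_dataset",
    "wilson_ci",
    "ks_two_sample",
    "run_error_power_study",
    "run_distribution_comparison",
]


#: The canonical group scenarios: sizes per variance group, and the lettered
#: variance configurations examined for each.
GROUP_SCENARIOS: dict[int, tuple[tuple[int, ...], dict[str, tuple[float, ...]]]] = {
    1: ((8, 4), {"a": (5, 1), "b": (1.2, 1), "c": (1, 1), "d": (1, 1.2), "e": (1, 5)}),
    2: ((20, 5), {"a": (5, 1), "b": (1.2, 1), "c": (1, 1), "d": (1, 1.2), "e": (1, 5)}),
    3: ((80, 30), {"a": (5, 1), "b": (1.2, 1), "c": (1, 1), "d": (1, 1.2), "e": (1, 5)}),
    4: (
        (40, 30, 20, 10),
        {
            "a": (15, 10, 5, 1),
            "b": (3.6, 2.4, 1.2, 1),
            "c": (1, 1, 1, 1),
            "d": (1, 1.2, 2.4, 3.6),
            "e": (1, 5, 10, 15),
        },
    ),
    5: ((4, 4), {"a": (1, 1), "b": (1, 1.2), "c": (1, 5)}),
    6: ((20, 20), {"a": (1, 1), "b": (1, 1.2), "c": (1, 5)}),
    7: ((4, 4, 4, 4), {"a": (1, 1, 1, 1), "b": (1, 1.2, 2.4, 3.6), "c": (1, 5, 10, 15)}),
    8: (
        (20, 20, 20, 20),
        {"a": (1, 1, 1, 1), "b": (1, 1.2, 2.4, 3.6), "c": (1, 5, 10, 15)},
    ),
}

#: True group-mean vectors under signal.
SIGNAL_PSI = {2: (0.0, -1.0), 4: (0.0, -0.33, -0.67, -1.0)}

ERROR_LAWS = ("normal", "uniform", "exponential", "weibull")


@dataclass(frozen=True)
class ScenarioSpec:
    """One simulation configuration (group study or regression study)."""

    group_sizes: tuple | None = None
    group_variances: tuple | None = None
    signal: bool = False
    N: int | None = None
    x1_kind: str = "continuous"
    z1_kind: str = "continuous"
    rho: float = 0.0
    beta1: float = 0.0
    error_law: str = "normal"
    include_partitioning: bool = False
    regime: str = "ee"

    def __post_init__(self):
        if self.group_sizes is not None:
            if self.group_variances is None or len(self.group_sizes) != len(
                self.group_variances
            ):
                raise ValueError("group sizes and variances must align")
            if any(v <= 0 for v in self.group_variances):
                raise ValueError("group variances must be positive")
        if not 0 <= abs(self.rho) < 1:
            raise ValueError("correlation must satisfy |rho| < 1")
        if self.error_law not in ERROR_LAWS:
            raise ValueError(f"unknown error law {self.error_law!r}")
        if self.regime not in ("ee", "ise", "both"):
            raise ValueError(f"unknown regime {self.regime!r}")

    @property
    def is_group_study(self) -> bool:
        return self.group_sizes is not None


@dataclass(frozen=True)
class EvaluationResult:
    """A rejection proportion (percent) with its 95% Wilson interval."""

    proportion: float
    ci_lo: float
    ci_hi: float
    n_reps: int

    def __post_init__(self):
        tol = 1e-9  # the score interval can overshoot 0/100 by rounding error
        if not self.ci_lo - tol <= self.proportion <= self.ci_hi + tol:
            raise ValueError("interval does not bracket the proportion")


@dataclass(frozen=True)
class KsComparison:
    """Pairwise distribution-equality rejection fractions for one scenario."""

    scenario: int
    alpha: float
    n_pairs: int
    n_reps: int
    rejection_fraction: dict = field(default_factory=dict)


def group_scenario(scenario: int, config: str, signal: bool = False) -> ScenarioSpec:
    """Build the ScenarioSpec for a canonical scenario/configuration pair.

    Group-mean scenarios shuffle by permutation (exchangeable-errors
    regime); the G statistic, not the shuffling scheme, carries the burden
    of heteroscedasticity in these designs.
    """
    sizes, variants = GROUP_SCENARIOS[scenario]
    return ScenarioSpec(
        group_sizes=sizes, group_variances=variants[config], signal=signal
    )


def make_scenario_design(x1_kind: str, z1_kind: str, N: int):
    """Regressor of interest, nuisance regressor and intercept column.

    Continuous: x1 is a linear trend from -1 to +1 and z1 its mean-centred
    square (orthogonal by symmetry).  Discrete: x1 is +1 for the first N/2
    observations and -1 after; z1 is -1 on the outer quarters and +1 on the
    middle half.  Returns ``(x1, z1, intercept)``.
    """
    if x1_kind == "continuous":
        x1 = np.linspace(-1.0, 1.0, N)
    elif x1_kind == "discrete":
        if N % 2:
            raise ValueError("discrete x1 needs N divisible by 2")
        x1 = np.repeat([1.0, -1.0], N // 2)
    else:
        raise ValueError(f"unknown regressor kind {x1_kind!r}")
    if z1_kind == "continuous":
        base = np.linspace(-1.0, 1.0, N)
        z1 = base**2
        z1 = z1 - z1.mean()
    elif z1_kind == "discrete":
        if N % 4:
            raise ValueError("discrete z1 needs N divisible by 4")
        z1 = np.concatenate(
            [-np.ones(N // 4), np.ones(N // 2), -np.ones(N - 3 * (N // 4))]
        )
    else:
        raise ValueError(f"unknown regressor kind {z1_kind!r}")
    return x1, z1, np.ones(N)


def induce_correlation(x1, z1, rho: float):
    """Correlate two regressors via the Cholesky factor of K = [[1, rho], [rho, 1]].

    With K = L'L the transformed pair is [x1 z1] L; rho = 0 returns the
    inputs unchanged, and the map is invertible for |rho| < 1.
    """
    if not abs(rho) < 1:
        raise ValueError("|rho| must be < 1")
    x1 = np.asarray(x1, dtype=float)
    z1 = np.asarray(z1, dtype=float)
    if rho == 0:
        return x1.copy(), z1.copy()
    K = np.array([[1.0, rho], [rho, 1.0]])
    L = np.linalg.cholesky(K).T  # upper triangular, K = L'L
    out = np.column_stack([x1, z1]) @ L
    return out[:, 0], out[:, 1]


def draw_errors(law: str, size, seed=None) -> np.ndarray:
    """Draw errors standardised to zero mean and unit variance.

    normal(0,1); uniform(-sqrt(3), +sqrt(3)); exponential(lambda=1) shifted
    by -1; Weibull(scale 1, shape 1/3) centred at Gamma(4) and scaled by
    sqrt(Gamma(7) - Gamma(4)^2), the exact first two moments.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if law == "normal":
        return rng.standard_normal(size)
    if law == "uniform":
        return rng.uniform(-math.sqrt(3.0), math.sqrt(3.0), size)
    if law == "exponential":
        return rng.exponential(1.0, size) - 1.0
    if law == "weibull":
        k = 1.0 / 3.0
        mean = math.gamma(1.0 + 1.0 / k)
        std = math.sqrt(math.gamma(1.0 + 2.0 / k) - mean**2)
        return (rng.weibull(k, size) - mean) / std
    raise ValueError(f"unknown error law {law!r}")


def _successive_difference_contrast(k: int) -> np.ndarray:
    """k x (k-1) contrast testing equality of all k group means."""
    C = np.zeros((k, k - 1))
    for j in range(k - 1):
        C[j, j], C[j + 1, j] = 1.0, -1.0
    return C


def simulate_group_dataset(spec: ScenarioSpec, n_tests: int, seed=None):
    """Simulate ``n_tests`` independent data vectors for a group scenario.

    Returns ``(Y, M, C, vg)``: N x n_tests data, the cell-means design, the
    all-means-equal contrast and the per-group variance labels.  Errors are
    normal with the per-group variances; under signal the true group means
    are the canonical psi pattern.
    """
    if not spec.is_group_study:
        raise ValueError("spec does not describe a group scenario")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    sizes = np.asarray(spec.group_sizes, dtype=int)
    k = len(sizes)
    N = int(sizes.sum())
    labels = np.repeat(np.arange(k), sizes)
    M = np.zeros((N, k))
    M[np.arange(N), labels] = 1.0
    C = _successive_difference_contrast(k)
    sd = np.sqrt(np.asarray(spec.group_variances, dtype=float))[labels]
    Y = sd[:, None] * rng.standard_normal((N, n_tests))
    if spec.signal:
        psi = SIGNAL_PSI.get(k)
        if psi is None:
            psi = tuple(np.round(np.linspace(0.0, -1.0, k), 2))
        Y = Y + np.asarray(psi)[labels][:, None]
    return Y, M, C, VarianceGroups(labels)


def simulate_regression_dataset(spec: ScenarioSpec, n_tests: int, seed=None):
    """Simulate ``n_tests`` data vectors for a regression scenario.

    Y = beta1 * x1 + 0.5 * z1 + 1 + eps with the correlated regressors and
    the requested error law.  Returns ``(Y, M, C)`` with M = [x1 z1 1] and
    C = [1 0 0]' testing beta1 = 0.
    """
    if spec.is_group_study:
        raise ValueError("spec describes a group scenario")
    if spec.N is None:
        raise ValueError("regression scenarios need N")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    x1, z1, ones = make_scenario_design(spec.x1_kind, spec.z1_kind, spec.N)
    x1r, z1r = induce_correlation(x1, z1, spec.rho)
    M = np.column_stack([x1r, z1r, ones])
    C = np.array([[1.0], [0.0], [0.0]])
    truth = M @ np.array([spec.beta1, 0.5, 1.0])
    eps = draw_errors(spec.error_law, (spec.N, n_tests), rng)
    Y = truth[:, None] + eps
    return Y, M, C


def wilson_ci(k: int, n: int, level: float = 0.95):
    """Wilson score interval for a binomial proportion (returned as fractions)."""
    if n <= 0:
        raise ValueError("need at least one trial")
    if not 0 <= k <= n:
        raise ValueError("successes must lie in [0, n]")
    lo, hi = proportion_confint(k, n, alpha=1.0 - level, method="wilson")
    return float(lo), float(hi)


def ks_two_sample(a, b):
    """Two-sample Kolmogorov-Smirnov statistic and asymptotic p-value."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both samples must be nonempty")
    res = sps.ks_2samp(a, b, method="asymp")
    return float(res.statistic), float(res.pvalue)


def _evaluation(k: int, n: int) -> EvaluationResult:
    lo, hi = wilson_ci(k, n)
    return EvaluationResult(
        proportion=100.0 * k / n, ci_lo=100.0 * lo, ci_hi=100.0 * hi, n_reps=n
    )


def _effective_kind(stat: str, s: int) -> str:
    """Map the requested statistic family to the rank-aware kind: rank-1
    contrasts use the signed one-sided t (F family) or v (G family)."""
    if stat in ("F", "G"):
        if s == 1:
            return "t" if stat == "F" else "v"
        return stat
    return stat


def run_error_power_study(
    spec: ScenarioSpec,
    n_reps: int = 1000,
    J: int = 1000,
    alpha: float = 0.05,
    seed=None,
    methods=("freedman_lane",),
    statistics=("G",),
    n_chunks: int = 10,
) -> dict:
    """Estimate the rejection rate of the permutation test under a scenario.

    Simulates ``n_reps`` independent datasets and runs the test on many of
    them at once (the datasets form the columns of one data matrix, sharing
    a shuffling set exactly as voxels of one image would).  So that the
    proportion does not hinge on any single randomly drawn shuffling set,
    the replicates are split into ``n_chunks`` batches with independently
    seeded sets.  The fraction of replicates with p <= alpha estimates the
    type-I error rate when the scenario is null and the power when it
    carries signal.  Returns a dict keyed by ``(method, statistic)`` with
    :class:`EvaluationResult` values.
    """
    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    n_chunks = max(1, min(n_chunks, n_reps))
    bounds = np.linspace(0, n_reps, n_chunks + 1).astype(int)
    rejections = {(m, st): 0 for m in methods for st in statistics}
    for chunk_ss, n_chunk in zip(ss.spawn(n_chunks), np.diff(bounds)):
        data_seed, perm_seed = chunk_ss.spawn(2)
        rng = np.random.default_rng(data_seed)
        if spec.is_group_study:
            Y, M, C, vg = simulate_group_dataset(spec, int(n_chunk), rng)
            s = C.shape[1]
            scheme = "contrast"
        else:
            Y, M, C = simulate_regression_dataset(spec, int(n_chunk), rng)
            vg, s = None, 1
            scheme = "contrast" if spec.include_partitioning else "columns"
        for method in methods:
            for stat in statistics:
                kind = _effective_kind(stat, s)
                vg_use = (
                    vg
                    if (spec.is_group_study and stat == "G")
                    else VarianceGroups.single(Y.shape[0])
                )
                if method == "parametric":
                    _, p = parametric_pvalues(
                        Y, M, C, stat="t" if s == 1 else "F", partition_scheme=scheme
                    )
                else:
                    dist = run_permutation_test(
                        Y,
                        M,
                        C,
                        vg=vg_use,
                        method=method,
                        stat=kind,
                        regime=spec.regime,
                        n_shufflings=J,
                        seed=perm_seed,
                        partition_scheme=scheme,
                    )
                    p = pvalues_uncorrected(dist)
                rejections[(method, stat)] += int((p <= alpha + 1e-12).sum())
    return {key: _evaluation(k, n_reps) for key, k in rejections.items()}


def run_distribution_comparison(
    scenario: int,
    n_voxels: int = 1000,
    n_reps: int = 1000,
    alpha: float = 0.05,
    seed=None,
    statistics=("F", "G"),
    configs=None,
) -> KsComparison:
    """Pairwise KS comparison of null statistic distributions across the
    variance configurations of one scenario.

    Per repeat and configuration, ``n_voxels`` null datasets are simulated
    and the observed statistic pooled into an empirical distribution; every
    configuration pair is KS-tested at ``alpha`` with Bonferroni correction
    over the pairs.  A statistic robust to heteroscedasticity keeps the
    rejection fraction near the corrected alpha; a non-pivotal one rejects
    far more often.
    """
    if n_voxels < 2:
        warnings.warn("fewer than two voxels per configuration is degenerate")
    sizes, variants = GROUP_SCENARIOS[scenario]
    letters = list(configs) if configs is not None else sorted(variants)
    pairs = list(combinations(letters, 2))
    n_pairs = len(pairs)
    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    rejections = {(stat, pair): 0 for stat in statistics for pair in pairs}
    for child in ss.spawn(n_reps):
        rng = np.random.default_rng(child)
        samples: dict = {}
        for letter in letters:
            spec = group_scenario(scenario, letter)
            Y, M, C, vg = simulate_group_dataset(spec, n_voxels, rng)
            s = C.shape[1]
            for stat in statistics:
                vg_use = vg if stat == "G" else VarianceGroups.single(Y.shape[0])
                kind = "G" if stat == "G" else "F"
                samples[(stat, letter)] = _observed_statistic(Y, M, C, vg_use, kind)
        for stat in statistics:
            for pair in pairs:
                _, p = ks_two_sample(samples[(stat, pair[0])], samples[(stat, pair[1])])
                if p < alpha / n_pairs:
                    rejections[(stat, pair)] += 1
    fractions = {key: count / n_reps for key, count in rejections.items()}
    return KsComparison(
        scenario=scenario,
        alpha=alpha,
        n_pairs=n_pairs,
        n_reps=n_reps,
        rejection_fraction=fractions,
    )


def _observed_statistic(Y, M, C, vg, kind):
    """Observed (unshuffled) statistic per data column for a contrast on M."""
    from .design import partition_model

    part = partition_model(M, C)
    return glm_statistic(Y, part.design, part.s, vg=vg, kind=kind).value
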