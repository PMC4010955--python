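"""Nuisance-handling strategies and the permutation engine."""

import numpy as np
import pytest
from scipy import stats

from permglm.design import partition_model
from permglm.engine import (
    STRATEGIES,
    parametric_pvalues,
    run_permutation_test,
    transform_model,
)
from permglm.inference import pvalues_uncorrected
from permglm.shuffling import (
    ExchangeabilityBlocks,
    Shuffling,
    enumerate_shufflings,
    apply_shuffling,
)
from permglm.statistic import glm_statistic


def random_shuffling(rng, N, signs=False):
    return Shuffling(
        perm=rng.permutation(N),
        signs=rng.choice(np.array([1, -1], dtype=np.int8), N)
        if signs
        else np.ones(N, dtype=np.int8),
    )


class TestTransformModel:
    def test_freedman_lane_fast_form_equals_six_steps(self, rng):
        """(P R_Z + H_Z) Y must equal: fit the nuisance-only model, permute
        its residuals, add the nuisance fit back."""
        N, V = 12, 4
        M = np.column_stack(
            [rng.standard_normal(N), rng.standard_normal(N), np.ones(N)]
        )
        C = np.array([[1.0], [0.0], [0.0]])
        Y = rng.standard_normal((N, V))
        part = partition_model(M, C)
        for _ in range(5):
            sh = random_shuffling(rng, N)
            Yfast, X, Z, _ = transform_model("freedman_lane", sh, Y, part)
            gamma = np.linalg.pinv(part.Z) @ Y
            resid_Z = Y - part.Z @ gamma
            Ylit = apply_shuffling(sh, resid_Z) + part.Z @ gamma
            np.testing.assert_allclose(Yfast, Ylit, atol=1e-10)

    def test_empty_nuisance_makes_freedman_lane_manly(self, rng):
        N = 10
        M = rng.standard_normal((N, 2))
        Y = rng.standard_normal((N, 3))
        part = partition_model(M, np.eye(2))
        sh = random_shuffling(rng, N, signs=True)
        Yfl, *_ = transform_model("freedman_lane", sh, Y, part)
        Yma, *_ = transform_model("manly", sh, Y, part)
        np.testing.assert_allclose(Yfl, Yma, atol=1e-12)

    def test_huh_jhun_reduces_dimension(self, rng):
        N = 12
        M = np.column_stack(
            [rng.standard_normal(N), rng.standard_normal(N), np.ones(N)]
        )
        part = partition_model(M, np.array([[1.0], [0.0], [0.0]]))
        sh = Shuffling.identity(N - 2)
        Yp, X, Z, _ = transform_model(
            "huh_jhun", sh, rng.standard_normal(N), part
        )
        assert Yp.shape[0] == N - 2 and X.shape == (N - 2, 1) and Z.shape[1] == 0

    def test_unknown_method_rejected(self, rng):
        part = partition_model(rng.standard_normal((8, 2)), np.eye(2))
        with pytest.raises(ValueError, match="unknown strategy"):
            transform_model("bootstrap", Shuffling.identity(8), np.zeros(8), part)


class TestRunPermutationTest:
    @pytest.mark.parametrize(
        "method", [m for m in STRATEGIES if m != "parametric"]
    )
    def test_identity_shuffling_reproduces_T0(self, rng, method):
        """Row 1 of the reference distribution is the observed statistic for
        every strategy, so p can never fall below 1/J."""
        N = 12
        M = np.column_stack(
            [rng.standard_normal(N), rng.standard_normal(N), np.ones(N)]
        )
        C = np.array([[1.0], [0.0], [0.0]])
        Y = rng.standard_normal((N, 3))
        dist = run_permutation_test(
            Y, M, C, method=method, n_shufflings=16, seed=0, return_tstar=True
        )
        np.testing.assert_allclose(dist.Tstar[0], dist.T0, rtol=1e-12)
        assert np.all(dist.count_ge >= 1)

    def test_draper_stoneman_equals_smith_when_orthogonal(self, rng):
        """With X orthogonal to Z, R_Z X = X so the two design-shuffling
        strategies coincide shuffle for shuffle."""
        N = 16
        X = rng.standard_normal((N, 1))
        Z = np.linalg.qr(rng.standard_normal((N, 2)))[0]
        X = X - Z @ (Z.T @ X)  # orthogonalise
        M = np.column_stack([X, Z])
        C = np.array([[1.0], [0.0], [0.0]])
        Y = rng.standard_normal((N, 2))
        shuffles = enumerate_shufflings(
            ExchangeabilityBlocks.unrestricted(N), "ee", 30, seed=5, side="design"
        )
        ds = run_permutation_test(
            Y, M, C, method="draper_stoneman", shuffles=shuffles,
            partition_scheme="columns", return_tstar=True,
        )
        sm = run_permutation_test(
            Y, M, C, method="smith", shuffles=shuffles,
            partition_scheme="columns", return_tstar=True,
        )
        np.testing.assert_allclose(ds.Tstar, sm.Tstar, rtol=1e-8)

    def test_exhaustive_null_pvalues_are_uniform(self, rng):
        """Exhaustive two-group permutation p-values take each value k/J
        with equal probability under the null (exactness)."""
        labels = np.repeat([0, 1], 3)
        M = np.column_stack([labels == 0, labels == 1]).astype(float)
        C = np.array([[1.0], [-1.0]])
        Y = rng.standard_normal((6, 4000))
        dist = run_permutation_test(Y, M, C, stat="t", n_shufflings=100, seed=1)
        assert dist.J == 20  # C(6,3)
        p = pvalues_uncorrected(dist)
        for k in (1, 5, 10, 19):
            frac = (p <= k / 20 + 1e-12).mean()
            assert frac == pytest.approx(k / 20, abs=0.03)

    def test_strong_signal_attains_minimum_p(self, rng):
        labels = np.repeat([0, 1], 4)
        M = np.column_stack([labels == 0, labels == 1]).astype(float)
        C = np.array([[1.0], [-1.0]])
        Y = (labels == 0) * 50.0 + rng.standard_normal(8)
        dist = run_permutation_test(Y, M, C, stat="t", n_shufflings=1000, seed=2)
        assert pvalues_uncorrected(dist)[0] == pytest.approx(1 / dist.J)

    def test_parametric_matches_reference_distribution(self, rng):
        N = 20
        M = np.column_stack([rng.standard_normal(N), np.ones(N)])
        C = np.array([[1.0], [0.0]])
        Y = rng.standard_normal((N, 5))
        T0, p = parametric_pvalues(Y, M, C, stat="t")
        oracle = stats.t.sf(T0, N - 2)
        np.testing.assert_allclose(p, oracle, rtol=1e-12)
        T0f, pf = parametric_pvalues(Y, M, C, stat="F")
        np.testing.assert_allclose(pf, stats.f.sf(T0f, 1, N - 2), rtol=1e-12)
        with pytest.raises(ValueError, match="no shuffling"):
            run_permutation_test(Y, M, C, method="parametric")

    def test_huh_jhun_rejects_blocks(self, rng):
        N = 12
        M = np.column_stack([rng.standard_normal(N), np.ones(N)])
        C = np.array([[1.0], [0.0]])
        blocks = ExchangeabilityBlocks(np.repeat([1, 2], 6), mode="within")
        with pytest.raises(ValueError, match="Huh-Jhun"):
            run_permutation_test(
                rng.standard_normal(N), M, C, blocks=blocks, method="huh_jhun"
            )

    def test_still_white_dof_flag(self, rng):
        N = 12
        M = np.column_stack(
            [rng.standard_normal(N), rng.standard_normal(N), np.ones(N)]
        )
        C = np.array([[1.0], [0.0], [0.0]])
        Y = rng.standard_normal(N)
        lo = run_permutation_test(
            Y, M, C, method="still_white", n_shufflings=8, seed=0
        )
        hi = run_permutation_test(
            Y, M, C, method="still_white", n_shufflings=8, seed=0, sw_full_dof=True
        )
        # same numerator, smaller dof scales the statistic down
        assert hi.T0[0] < lo.T0[0]

    def test_within_block_respects_blocks_end_to_end(self, rng):
        labels = np.repeat([1, 2], 4)
        blocks = ExchangeabilityBlocks(labels, mode="within")
        M = np.column_stack([rng.standard_normal(8), np.ones(8)])
        C = np.array([[1.0], [0.0]])
        dist = run_permutation_test(
            rng.standard_normal(8), M, C, blocks=blocks, n_shufflings=10_000, seed=0
        )
        assert dist.J == 4 * 3 * 2 * 1 * 24  # (4!)^2 = 576
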