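"""Effort valuation: observable mappings, shared-k fit, sign test."""

import itertools

import numpy as np
import pytest

from exertvalue import effort
from exertvalue.errors import ValidationError


def _observations(M, C, vp):
    return [
        effort.EffortObservation(f"p{i}", "T0", float(vp[i]), float(C[i]), float(M[i]))
        for i in range(len(M))
    ]


def _cohort_mc(seed=0, n=30):
    rng = np.random.default_rng(seed)
    hps = rng.normal(22.0, 3.0, n)
    C = np.round(rng.uniform(8, 15, n))
    M = np.array([effort.map_reward(h, 22.0) for h in hps])
    return M, C


class TestNormalizeFs:
    @pytest.mark.parametrize("fs,vp", [(4.27, 0.854), (5, 1.0), (0, 0.0), (-5, -1.0)])
    def test_scale_division(self, fs, vp):
        assert effort.normalize_fs(fs) == pytest.approx(vp)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValidationError):
            effort.normalize_fs(5.5)


class TestMapReward:
    @pytest.mark.parametrize(
        "hps,ref,dm,expected", [(20, 20, 0, 1.0), (20, 22, 0, 1.1), (20, 20, 0.2, 1.2)]
    )
    def test_default_mapping(self, hps, ref, dm, expected):
        assert effort.map_reward(hps, ref, dm) == pytest.approx(expected)

    def test_non_positive_rejected(self):
        with pytest.raises(ValidationError):
            effort.map_reward(0, 22)


class TestFitSharedK:
    def test_recovers_generating_constant_exactly(self):
        """Noise-free data generated at k = 0.204 is recovered to 1e-4."""
        M, C = _cohort_mc(0)
        res = effort.fit_shared_k(_observations(M, C, M / (1 + 0.204 * C)))
        assert res.k == pytest.approx(0.204, abs=1e-4)
        assert res.residual_ss < 1e-12

    def test_prediction_identity(self):
        M, C = _cohort_mc(1)
        res = effort.fit_shared_k(_observations(M, C, M / (1 + 0.15 * C)))
        assert np.max(np.abs(res.vp_model - M / (1 + res.k * C))) < 1e-12

    def test_k_zero_limit_returns_reward(self):
        M, C = _cohort_mc(2)
        m = np.clip(M, None, 1.0)
        res = effort.fit_shared_k(_observations(m, C, m))
        # with vp == reward the best k is 0 and the model predicts M itself
        assert res.k == 0.0
        assert np.allclose(res.vp_model, m)

    def test_unmodeled_reward_surplus_deflates_k(self):
        """An additive reward the fitter's M omits is absorbed as lower k —
        the training-vs-conditioning contrast, direction only."""
        M, C = _cohort_mc(3)
        vp = np.clip((M + 0.4) / (1 + 0.204 * C), -1, 1)
        res = effort.fit_shared_k(_observations(M, C, vp))
        assert res.k < 0.204

    def test_k_strictly_decreasing_in_surplus(self):
        M, C = _cohort_mc(4)
        ks = []
        for dm in (0.0, 0.1, 0.2, 0.3, 0.4, 0.5):
            vp = np.clip((M + dm) / (1 + 0.204 * C), -1, 1)
            ks.append(effort.fit_shared_k(_observations(M, C, vp)).k)
        assert all(b < a for a, b in zip(ks, ks[1:]))

    def test_matches_dense_grid_oracle(self):
        """Seeded noisy cohorts: shared k within 1e-3 of brute force over
        k in [0, 2] at 1e-4 resolution."""
        rng = np.random.default_rng(5)
        for trial in range(10):
            M, C = _cohort_mc(trial)
            vp = np.clip(M / (1 + 0.204 * C) + rng.normal(0, 0.05, len(M)), -1, 1)
            res = effort.fit_shared_k(_observations(M, C, vp))
            ks = np.arange(0.0, 2.0001, 1e-4)
            obj = ((vp[None, :] - M[None, :] / (1 + ks[:, None] * C[None, :])) ** 2).sum(1)
            k_grid = float(ks[np.argmin(obj)])
            assert abs(res.k - k_grid) < 1e-3

    def test_degenerate_inputs_flagged(self):
        obs = _observations([1.0] * 5, [10.0] * 5, [0.5] * 5)
        assert effort.fit_shared_k(obs).flat_objective

    def test_too_few_observations_rejected(self):
        with pytest.raises(ValidationError):
            effort.fit_shared_k(_observations([1.0], [10.0], [0.5]))


def _enumeration_p(diffs):
    """Full enumeration oracle: two-sided exact sign test via all 2^n
    equally likely sign patterns of the non-zero differences."""
    nz = [d for d in diffs if d != 0]
    n = len(nz)
    if n == 0:
        return 1.0
    observed = sum(d > 0 for d in nz)
    from math import comb

    p_obs = comb(n, observed)
    count = sum(
        1
        for pattern in itertools.product([0, 1], repeat=n)
        if comb(n, sum(pattern)) <= p_obs
    )
    return count / 2**n


class TestSignTest:
    def test_all_zero_differences(self):
        res = effort.sign_test([0.0, 0.0, 0.0])
        assert res["p_value"] == 1.0 and res["n"] == 0 and res["n_zero"] == 3

    def test_six_positive_no_negative(self):
        res = effort.sign_test([1, 2, 3, 4, 5, 6])
        assert res["p_value"] == pytest.approx(0.03125)

    @pytest.mark.parametrize("seed", range(8))
    def test_matches_full_enumeration(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(1, 11))
        diffs = rng.normal(0, 1, n)
        diffs[rng.random(n) < 0.2] = 0.0
        assert effort.sign_test(diffs)["p_value"] == pytest.approx(_enumeration_p(diffs))

    def test_empty_rejected(self):
        with pytest.raises(ValidationError):
            effort.sign_test([])
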