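"""Similarity regression, TFCE, and sign-flip permutation inference."""

from itertools import product

import numpy as np
import pytest

from adaptune import (
    TFCEParams,
    permutation_one_sample,
    positive_slope_mask,
    tfce,
    voxelwise_release_regression,
)
from adaptune.glm import BetaMaps


def beta_maps(curves: np.ndarray) -> BetaMaps:
    """Wrap a (4, x, y, z) array of condition maps as an HRF-model fit."""
    mask = np.ones(curves.shape[1:], bool)
    names = ("SC", "C", "D", "SD")
    return BetaMaps(betas={n: curves[i] for i, n in enumerate(names)},
                    resid_var=np.zeros(curves.shape[1:]), dof=10, mask=mask)


class TestReleaseRegression:
    @pytest.mark.parametrize("betas, slope, r2", [
        ((1.0, 2.0, 3.0, 4.0), 1.0, 1.0),
        ((2.5, 2.5, 2.5, 2.5), 0.0, 0.0),   # flat voxel: SST = 0 -> R2 = 0
        ((0.0, 1.0, 1.0, 2.0), 0.6, 0.9),
    ])
    def test_hand_ols_examples(self, betas, slope, r2):
        curves = np.array(betas).reshape(4, 1, 1, 1)
        rel = voxelwise_release_regression(beta_maps(curves), np.ones((1, 1, 1), bool))
        assert rel.slope[0, 0, 0] == pytest.approx(slope, abs=1e-12)
        assert rel.r2[0, 0, 0] == pytest.approx(r2, abs=1e-12)

    def test_identity_condition_rejected(self):
        curves = np.zeros((4, 1, 1, 1))
        with pytest.raises(ValueError, match="Identity"):
            voxelwise_release_regression(beta_maps(curves), np.ones((1, 1, 1), bool),
                                         conditions=("SC", "C", "D", "I"))

    def test_empty_mask_rejected(self):
        curves = np.zeros((4, 2, 2, 2))
        with pytest.raises(ValueError, match="mask"):
            voxelwise_release_regression(beta_maps(curves), np.zeros((2, 2, 2), bool))

    def test_measured_similarity_predictor(self):
        curves = np.array([0.9, 0.6, 0.4, 0.1])[::-1].reshape(4, 1, 1, 1)
        x = np.array([0.9, 0.6, 0.4, 0.1])  # cosine similarities, SC..SD
        rel = voxelwise_release_regression(beta_maps(curves),
                                           np.ones((1, 1, 1), bool), similarity_x=x)
        assert rel.slope[0, 0, 0] == pytest.approx(-1.0, abs=1e-12)
        assert rel.r2[0, 0, 0] == pytest.approx(1.0, abs=1e-12)


def brute_force_tfce(vals, params: TFCEParams):
    """Per-voxel flood-fill reimplementation of the TFCE integral."""
    vals = np.where(vals > 0, vals, 0.0)
    shape = vals.shape
    limit = {6: 1, 18: 2, 26: 3}[params.connectivity]
    offsets = [o for o in product((-1, 0, 1), repeat=3)
               if o != (0, 0, 0) and sum(map(abs, o)) <= limit]
    hmax = vals.max()
    out = np.zeros(shape)
    if hmax == 0:
        return out
    dh = params.dh if params.dh is not None else hmax / params.n_steps
    n_steps = int(np.floor(hmax / dh + 1e-9))
    for i in range(1, n_steps + 1):
        h = i * dh
        supra = vals >= h
        seen = np.zeros(shape, bool)
        for start in np.ndindex(shape):
            if supra[start] and not seen[start]:
                comp, queue = [], [start]
                seen[start] = True
                while queue:
                    v = queue.pop()
                    comp.append(v)
                    for o in offsets:
                        w = tuple(np.add(v, o))
                        if all(0 <= w[d] < shape[d] for d in range(3)) \
                                and supra[w] and not seen[w]:
                            seen[w] = True
                            queue.append(w)
                for v in comp:
                    out[v] += len(comp) ** params.E * h ** params.H * dh
    return out


class TestTfce:
    def test_zero_map_stays_zero(self):
        out = tfce(np.zeros((4, 4, 4)), TFCEParams())
        assert not out.values.any()

    def test_single_voxel_discrete_integral(self):
        """Height-1 voxel, dh=0.1: sum over k of 1^0.5 * (0.1 k)^2 * 0.1."""
        vals = np.zeros((3, 3, 3))
        vals[1, 1, 1] = 1.0
        out = tfce(vals, TFCEParams(dh=0.1))
        expected = sum(1 ** 0.5 * (0.1 * k) ** 2 * 0.1 for k in range(1, 11))
        assert expected == pytest.approx(0.385)
        assert out.values[1, 1, 1] == pytest.approx(expected, abs=1e-12)

    @pytest.mark.parametrize("connectivity", [6, 26])
    def test_matches_brute_force_on_random_maps(self, connectivity):
        rng = np.random.default_rng(connectivity)
        for _ in range(3):
            vals = rng.normal(0, 1, (6, 6, 6))
            params = TFCEParams(connectivity=connectivity, n_steps=20)
            got = tfce(vals, params).values
            np.testing.assert_allclose(got, brute_force_tfce(vals, params), atol=1e-10)

    def test_monotone_in_voxel_height(self):
        rng = np.random.default_rng(9)
        vals = np.abs(rng.normal(0, 1, (5, 5, 5)))
        params = TFCEParams(dh=0.05)
        base = tfce(vals, params).values
        for _ in range(5):
            bumped = vals.copy()
            idx = tuple(rng.integers(0, 5, 3))
            bumped[idx] += 0.5
            higher = tfce(bumped, params).values
            assert (higher >= base - 1e-12).all()

    def test_nonpositive_dh_is_error(self):
        with pytest.raises(ValueError, match="dh"):
            TFCEParams(dh=0.0)


class TestPermutation:
    def _maps(self, n_subj=12, seed=0, effect=1.0, shape=(8, 8, 4)):
        rng = np.random.default_rng(seed)
        maps = rng.normal(0, 0.5, (n_subj,) + shape)
        region = np.zeros(shape, bool)
        region[2:6, 2:6, 1:3] = True
        maps[:, region] += effect
        return maps, region

    def test_reproducible_under_seed(self):
        maps, _ = self._maps()
        mask = np.ones(maps.shape[1:], bool)
        a = permutation_one_sample(list(maps), mask, n_perm=200, alpha=0.05, seed=3)
        b = permutation_one_sample(list(maps), mask, n_perm=200, alpha=0.05, seed=3)
        np.testing.assert_array_equal(a.null_max, b.null_max)
        np.testing.assert_array_equal(a.p_map[mask], b.p_map[mask])

    def test_zero_maps_nothing_significant(self):
        shape = (5, 5, 5)
        maps = [np.zeros(shape)] * 10
        res = permutation_one_sample(maps, np.ones(shape, bool), n_perm=100,
                                     alpha=0.05, seed=0)
        assert not res.significant.any()

    def test_planted_region_detected(self):
        """Strong planted effect: >= 90% of region voxels significant."""
        sens = []
        for seed in range(3):
            maps, region = self._maps(n_subj=20, seed=seed)
            res = permutation_one_sample(list(maps), np.ones(maps.shape[1:], bool),
                                         n_perm=1000, alpha=0.05, seed=seed)
            sens.append(res.significant[region].mean())
        assert np.mean(sens) >= 0.9

    def test_observed_stats_invariant_to_subject_order(self):
        maps, _ = self._maps(seed=5)
        mask = np.ones(maps.shape[1:], bool)
        a = permutation_one_sample(list(maps), mask, n_perm=100, alpha=0.05, seed=1)
        b = permutation_one_sample(list(maps[::-1]), mask, n_perm=100, alpha=0.05, seed=1)
        np.testing.assert_allclose(a.t_map[mask], b.t_map[mask], atol=1e-10)
        np.testing.assert_allclose(a.tfce_map[mask], b.tfce_map[mask], atol=1e-10)

    def test_unresolvable_level_is_error(self):
        maps = [np.zeros((3, 3, 3))] * 10
        with pytest.raises(ValueError, match="n_perm"):
            permutation_one_sample(maps, np.ones((3, 3, 3), bool),
                                   n_perm=100, alpha=0.001)

    def test_few_subjects_warns(self):
        maps = [np.random.default_rng(i).normal(size=(3, 3, 3)) for i in range(5)]
        with pytest.warns(UserWarning, match="subjects"):
            permutation_one_sample(maps, np.ones((3, 3, 3), bool),
                                   n_perm=100, alpha=0.05, seed=0)


class TestPositiveSlopeMask:
    def test_sign_filtering(self):
        sig = np.array([[[True, True, False]]])
        slope = np.array([[[0.2, -0.2, 0.5]]])
        out = positive_slope_mask(sig, slope)
        assert out.tolist() == [[[True, False, False]]]

    def test_identity_when_all_positive(self):
        sig = np.random.default_rng(0).random((4, 4, 4)) > 0.5
        slope = np.full((4, 4, 4), 0.3)
        assert (positive_slope_mask(sig, slope) == sig).all()
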