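"""Tensor-based morphometry: group maps, pooled permutation null, correlation maps."""

import math

import numpy as np
import pytest

from strokemap import (
    TBMConfig,
    required_permutations,
    tbm_behaviour_correlation,
    tbm_group_map,
    tbm_pooled_inference,
)
from strokemap.stats import FDRConfig, PermutationConfig

SHAPE = (8, 8, 8)
BRAIN = np.ones(SHAPE, dtype=bool)


def _null_logjac(rng, n):
    """iid noise 'log-Jacobian' stacks for null-behaviour checks."""
    return rng.normal(0.0, 0.05, size=(n,) + SHAPE)


class TestRequiredPermutations:
    @pytest.mark.parametrize(
        "n_voxels, q, expected",
        [(42000, 0.05, 840_000), (100, 1.0, 100), (1000, 0.01, 100_000),
         (101, 0.3, math.ceil(101 / 0.3))],
    )
    def test_values(self, n_voxels, q, expected):
        assert required_permutations(n_voxels, q) == expected

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            required_permutations(0, 0.05)
        with pytest.raises(ValueError):
            required_permutations(100, 0.0)


class TestGroupMap:
    def test_label_swap_flips_sign(self, rng):
        X = _null_logjac(rng, 12)
        labels = np.array(["lesion"] * 6 + ["sham"] * 6)
        a = tbm_group_map(X, labels, BRAIN, group1="lesion").stat_map
        b = tbm_group_map(X, labels, BRAIN, group1="sham").stat_map
        assert np.allclose(a, -b, atol=1e-12, equal_nan=True)

    def test_null_groups_give_centred_t(self, rng):
        X = _null_logjac(rng, 30)
        labels = np.array(["lesion"] * 15 + ["sham"] * 15)
        t = tbm_group_map(X, labels, BRAIN).stat_map
        df = 28
        assert abs(np.nanmean(t)) < 0.05
        assert np.nanvar(t) == pytest.approx(df / (df - 2), rel=0.15)

    def test_global_rescaling_of_jacobians_leaves_t_unchanged(self, cohort):
        lj = cohort.log_jacobians()
        labels = np.where(cohort.groups() == "sham", "sham", "lesion")
        base = tbm_group_map(lj, labels, cohort.brain_mask).stat_map
        scaled = tbm_group_map(lj + np.log(2.0), labels, cohort.brain_mask).stat_map
        assert np.allclose(base, scaled, atol=1e-8, equal_nan=True)

    def test_lesion_expansion_detected_positive(self, cohort):
        """Apparent volume increase at the lesion and enlarged ventricle."""
        lj = cohort.log_jacobians()
        labels = np.where(cohort.groups() == "sham", "sham", "lesion")
        res = tbm_group_map(lj, labels, cohort.brain_mask)
        lesion_region = cohort.ground_truth["template_striatal"]
        vent = cohort.ground_truth["ventricle_mask"]
        assert np.nanmean(res.stat_map[lesion_region]) > 2.0
        assert np.nanmean(res.stat_map[vent]) > 1.0

    def test_invalid_jacobian_voxels_excluded(self, rng):
        X = _null_logjac(rng, 8)
        X[3, 2, 2, 2] = np.nan              # folded voxel in one subject
        labels = np.array(["lesion"] * 4 + ["sham"] * 4)
        res = tbm_group_map(X, labels, BRAIN)
        assert not res.tested[2, 2, 2]
        assert np.isnan(res.stat_map[2, 2, 2])


class TestPooledInference:
    def test_pooled_null_size_is_permutations_times_voxels(self, rng):
        X = _null_logjac(rng, 12)
        labels = np.array(["lesion"] * 6 + ["sham"] * 6)
        cfg = TBMConfig(permutation=PermutationConfig(
            n_permutations=50, seed=0, pool_across_voxels=True))
        res = tbm_group_map(X, labels, BRAIN, cfg=cfg)
        out = tbm_pooled_inference(res, X, labels, cfg=cfg)
        assert out.pooled_null_size == 50 * int(res.tested.sum())

    def test_small_design_switches_to_exhaustive(self, rng):
        X = _null_logjac(rng, 6)
        labels = np.array(["lesion"] * 3 + ["sham"] * 3)
        cfg = TBMConfig(permutation=PermutationConfig(
            n_permutations=10_000, seed=0, pool_across_voxels=True))
        res = tbm_group_map(X, labels, BRAIN, cfg=cfg)
        out = tbm_pooled_inference(res, X, labels, cfg=cfg)
        assert out.exhaustive
        assert out.n_permutations_used == math.comb(6, 3)

    def test_pooled_and_pervoxel_p_agree_on_exchangeable_null(self, rng):
        X = _null_logjac(rng, 16)
        labels = np.array(["lesion"] * 8 + ["sham"] * 8)
        pooled_cfg = TBMConfig(permutation=PermutationConfig(
            n_permutations=300, seed=3, pool_across_voxels=True))
        voxel_cfg = TBMConfig(permutation=PermutationConfig(
            n_permutations=300, seed=3, pool_across_voxels=False))
        base = tbm_group_map(X, labels, BRAIN)
        p_pool = tbm_pooled_inference(base, X, labels, cfg=pooled_cfg).p_map
        p_vox = tbm_pooled_inference(base, X, labels, cfg=voxel_cfg).p_map
        ok = np.isfinite(p_pool) & np.isfinite(p_vox)
        # Monte-Carlo agreement: matched on average, loose per voxel
        assert abs(np.mean(p_pool[ok] - p_vox[ok])) < 0.02
        assert np.mean(np.abs(p_pool[ok] - p_vox[ok])) < 0.08

    def test_null_cohort_yields_almost_no_significance(self, rng):
        X = _null_logjac(rng, 20)
        labels = np.array(["lesion"] * 10 + ["sham"] * 10)
        cfg = TBMConfig(permutation=PermutationConfig(
            n_permutations=300, seed=1, pool_across_voxels=True))
        base = tbm_group_map(X, labels, BRAIN, cfg=cfg)
        out = tbm_pooled_inference(base, X, labels, cfg=cfg)
        assert out.significant.mean() <= 0.05


class TestBehaviourCorrelation:
    def test_score_equal_to_logjac_gives_rho_one(self, rng):
        X = _null_logjac(rng, 10)
        scores = X[:, 4, 4, 4].copy()
        cfg = TBMConfig(permutation=PermutationConfig(n_permutations=50, seed=0))
        res = tbm_behaviour_correlation(X, scores, BRAIN, cfg)
        assert res.stat_map[4, 4, 4] == pytest.approx(1.0)

    def test_invariant_under_monotone_score_transform(self, rng):
        X = _null_logjac(rng, 12)
        scores = rng.normal(size=12)
        cfg = TBMConfig(permutation=PermutationConfig(n_permutations=20, seed=0))
        a = tbm_behaviour_correlation(X, scores, BRAIN, cfg).stat_map
        b = tbm_behaviour_correlation(X, np.exp(scores), BRAIN, cfg).stat_map
        assert np.allclose(a, b, atol=1e-12, equal_nan=True)

    def test_constant_logjac_voxel_untested(self, rng):
        X = _null_logjac(rng, 10)
        X[:, 1, 1, 1] = 0.2
        cfg = TBMConfig(permutation=PermutationConfig(n_permutations=20, seed=0))
        res = tbm_behaviour_correlation(X, rng.normal(size=10), BRAIN, cfg)
        assert not res.tested[1, 1, 1]
        assert np.isnan(res.stat_map[1, 1, 1])

    def test_max_null_correlation_near_detection_scale(self):
        """Across ~10k voxels at n=30, the largest null |rho| sits near the
        0.5 detectability scale of the model power analysis."""
        from strokemap import SyntheticConfig, generate_cohort, BehaviourModel

        models = {
            k: BehaviourModel(m.intercept, 0.0, m.sd)
            for k, m in SyntheticConfig(seed=0).behaviour_models.items()
        }
        cfg = SyntheticConfig(
            seed=21, n_sham=10, n_striatal=10, n_striatal_cortical=10,
            behaviour_models=models,
        )
        c = generate_cohort(cfg)
        tcfg = TBMConfig(permutation=PermutationConfig(n_permutations=20, seed=0))
        res = tbm_behaviour_correlation(
            c.log_jacobians(), c.scores("ffl"), c.brain_mask, tcfg
        )
        max_rho = np.nanmax(np.abs(res.stat_map))
        assert 0.35 < max_rho < 0.7

    def test_fdr_set_shrinks_as_q_decreases(self, cohort):
        lj = cohort.log_jacobians()
        scores = cohort.scores("ffl")
        sets = {}
        for q in (0.1, 0.05, 0.01):
            cfg = TBMConfig(
                permutation=PermutationConfig(n_permutations=200, seed=5),
                fdr=FDRConfig(q=q),
            )
            res = tbm_behaviour_correlation(lj, scores, cohort.brain_mask, cfg)
            sets[q] = res.significant
        assert (sets[0.01] <= sets[0.05]).all()
        assert (sets[0.05] <= sets[0.1]).all()
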