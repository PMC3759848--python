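"""Phantom-cohort generator: determinism, geometry, couplings, field calibration."""

import numpy as np
import pytest

from strokemap import (
    BehaviourModel,
    SyntheticConfig,
    generate_behaviour,
    generate_cohort,
    make_lesion_displacement_field,
)
from strokemap.deformation import jacobian_determinant, roi_volume
from strokemap.synthetic import _sphere_mm


def _small(seed=0, **kw):
    kw.setdefault("n_sham", 3)
    kw.setdefault("n_striatal", 3)
    kw.setdefault("n_striatal_cortical", 3)
    kw.setdefault("make_images", False)
    return SyntheticConfig(seed=seed, **kw)


class TestDeterminismAndStructure:
    def test_all_sham_cohort_has_empty_masks(self):
        cfg = SyntheticConfig(seed=1, n_sham=4, n_striatal=0,
                              n_striatal_cortical=0, make_fields=False,
                              make_images=False)
        cohort = generate_cohort(cfg)
        assert all(not s.lesion_mask.any() for s in cohort.subjects)
        assert all(s.lesion_volume_mm3 <= 5.0 for s in cohort.subjects)

    def test_same_seed_reproduces_different_seed_differs(self):
        a = generate_cohort(_small(seed=1))
        b = generate_cohort(_small(seed=1))
        c = generate_cohort(_small(seed=2))
        for sa, sb in zip(a.subjects, b.subjects):
            assert np.array_equal(sa.lesion_mask, sb.lesion_mask)
            assert np.array_equal(sa.field, sb.field)
            assert sa.scores == sb.scores
        assert any(
            not np.array_equal(sa.lesion_mask, sc.lesion_mask)
            for sa, sc in zip(a.subjects[3:], c.subjects[3:])
        )

    def test_earlier_subjects_unchanged_when_cohort_grows(self):
        """Per-subject streams make data independent of cohort composition."""
        a = generate_cohort(_small(seed=5))
        b = generate_cohort(_small(seed=5, n_striatal_cortical=6))
        for sa, sb in zip(a.subjects, b.subjects[: len(a.subjects)]):
            assert np.array_equal(sa.lesion_mask, sb.lesion_mask)

    def test_masks_confined_to_brain_and_hemisphere(self):
        cohort = generate_cohort(_small(seed=3, make_fields=False))
        mid = cohort.config.midline
        for s in cohort.subjects:
            if s.group == "sham":
                continue
            assert (s.lesion_mask <= cohort.brain_mask).all()
            assert not s.lesion_mask[:mid].any()

    def test_combined_template_strictly_contains_striatal_template(self):
        cohort = generate_cohort(_small(seed=3, make_fields=False))
        tmpl_s = cohort.ground_truth["template_striatal"]
        tmpl_sc = cohort.ground_truth["template_striatal_cortical"]
        assert (tmpl_s <= tmpl_sc).all()
        assert tmpl_sc.sum() > tmpl_s.sum()

    def test_unplaceable_lesion_fails_clearly(self):
        cfg = _small(seed=0, make_fields=False)
        cfg.striatal_radius_mm = (6.0, 0.0)   # cannot fit one hemisphere
        with pytest.raises(ValueError, match="hemisphere"):
            generate_cohort(cfg)


class TestDisplacementFields:
    def test_empty_mask_no_ventricle_gives_zero_field(self):
        cfg = SyntheticConfig(seed=0, ventricle_enlargement=0.0)
        field = make_lesion_displacement_field(
            np.zeros(cfg.grid_shape, bool), cfg
        )
        assert not field.any()

    def test_jacobian_positive_for_generated_subjects(self, cohort):
        for s in cohort.subjects:
            assert s.jacobian.j.min() > 0

    def test_spherical_source_volume_integral(self):
        """Integral of (J - 1) over the brain matches the requested volume
        change within 10% (numerical-integration oracle)."""
        cfg = SyntheticConfig(
            seed=0, ventricle_enlargement=0.0, field_noise_vox=0.0,
            deformation_magnitude=0.3,
        )
        mask = _sphere_mm(cfg.grid_shape, cfg.voxel_dims_mm, (22, 16, 16), 1.2)
        field = make_lesion_displacement_field(mask, cfg)
        jac = jacobian_determinant(field, cfg.voxel_dims_mm)
        voxvol = float(np.prod(cfg.voxel_dims_mm))
        achieved = jac.dv[cfg.brain_mask()].sum() * voxvol
        expected = cfg.deformation_magnitude * mask.sum() * voxvol
        assert achieved == pytest.approx(expected, rel=0.10)

    def test_excessive_magnitude_scaled_down_with_warning(self):
        cfg = SyntheticConfig(
            seed=0, ventricle_enlargement=0.0, field_noise_vox=0.0,
            deformation_magnitude=60.0,
        )
        mask = _sphere_mm(cfg.grid_shape, cfg.voxel_dims_mm, (22, 16, 16), 1.2)
        with pytest.warns(UserWarning, match="folds the grid"):
            field = make_lesion_displacement_field(mask, cfg)
        assert jacobian_determinant(field, cfg.voxel_dims_mm).j.min() > 0


class TestBehaviour:
    def test_noise_free_linear_model_is_exact(self):
        cfg = SyntheticConfig(
            seed=0,
            behaviour_models={
                "ffl": BehaviourModel(10.0, 0.5, 0.0),
                "ffr": BehaviourModel(10.0, 0.5, 0.0),
                "gsl": BehaviourModel(10.0, 0.5, 0.0),
                "gsr": BehaviourModel(10.0, 0.5, 0.0),
            },
        )
        table = generate_behaviour([20.0], cfg, seed=0)
        assert table.loc[0, "ffl"] == pytest.approx(20.0)

    def test_default_directions_match_motor_deficit(self):
        models = SyntheticConfig(seed=0).behaviour_models
        assert models["ffl"].slope > 0       # contralateral foot-faults rise
        assert models["gsl"].slope < 0       # contralateral grip strength falls

    def test_foot_faults_clamped_to_percentage_range(self):
        cfg = SyntheticConfig(
            seed=0,
            behaviour_models={
                "ffl": BehaviourModel(90.0, 10.0, 0.0),
                "ffr": BehaviourModel(-5.0, 0.0, 0.0),
                "gsl": BehaviourModel(-50.0, 0.0, 0.0),
                "gsr": BehaviourModel(100.0, 0.0, 0.0),
            },
        )
        table = generate_behaviour([50.0], cfg, seed=0)
        assert table.loc[0, "ffl"] == 100.0
        assert table.loc[0, "ffr"] == 0.0
        assert table.loc[0, "gsl"] == 0.0   # grip strength floored at zero

    def test_negative_volume_rejected(self):
        with pytest.raises(ValueError):
            generate_behaviour([-1.0], SyntheticConfig(seed=0), seed=0)

    def test_negative_residual_sd_rejected(self):
        with pytest.raises(ValueError):
            SyntheticConfig(
                seed=0,
                behaviour_models={
                    "ffl": BehaviourModel(0, 0, -1.0),
                    "ffr": BehaviourModel(0, 0, 1.0),
                    "gsl": BehaviourModel(0, 0, 1.0),
                    "gsr": BehaviourModel(0, 0, 1.0),
                },
            )

    def test_configured_slope_recovered_by_regression(self, rng):
        """Least squares on n=200 subjects recovers the slope within 2 SE."""
        cfg = SyntheticConfig(seed=0)
        volumes = rng.uniform(0.0, 15.0, size=200)
        table = generate_behaviour(volumes, cfg, seed=99)
        y = table["ffl"].to_numpy()
        X = np.column_stack([np.ones_like(volumes), volumes])
        beta, res, *_ = np.linalg.lstsq(X, y, rcond=None)
        resid = y - X @ beta
        sigma2 = resid @ resid / (len(y) - 2)
        se = np.sqrt(sigma2 * np.linalg.inv(X.T @ X)[1, 1])
        assert abs(beta[1] - cfg.behaviour_models["ffl"].slope) < 2 * se

    def test_zero_slopes_leave_scores_uncorrelated_with_volume(self):
        """Monte-Carlo over 100 seeds: |r| exceeds 3/sqrt(n) only rarely."""
        models = {
            k: BehaviourModel(m.intercept, 0.0, m.sd)
            for k, m in SyntheticConfig(seed=0).behaviour_models.items()
        }
        n = 30
        exceed = 0
        rs = []
        for seed in range(100):
            cfg = SyntheticConfig(
                seed=seed, n_sham=10, n_striatal=10, n_striatal_cortical=10,
                behaviour_models=models, make_fields=False, make_images=False,
            )
            cohort = generate_cohort(cfg)
            vols = np.array([s.lesion_volume_mm3 for s in cohort.subjects])
            r = np.corrcoef(vols, cohort.scores("ffl"))[0, 1]
            rs.append(r)
            if abs(r) >= 3 / np.sqrt(n):
                exceed += 1
        assert exceed <= 3          # ~0.3% expected per seed
        assert abs(np.mean(rs)) < 0.06
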