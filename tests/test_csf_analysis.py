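"""CSF compartment separation, Monte-Carlo sampling, offset measurement,
normality testing and the sample-size derivation."""

import dataclasses

import numpy as np
import pytest

from rbmicv import csf_analysis as ca
from rbmicv import phantom as ph
from rbmicv import segmentation as seg
from rbmicv.metrics import dice
from tests.conftest import make_volume


@pytest.fixture(scope="module")
def noiseless_pipeline():
    """Noiseless half-scale 3T phantom segmented with exact priors."""
    spec = dataclasses.replace(ph.PhantomSpec(field_mode="3T").scaled(0.5),
                               noise_sd=0.0)
    assets = ph.make_template(spec)
    img, truth = ph.synthesize_subject(spec, seed=9)
    native = seg.warp_priors(assets.priors, truth.subject_affine, img)
    _, post = seg.fit_tissue_model(img, native)
    return spec, assets, img, truth, native, post


class TestGmwmMap:
    def test_union_and_dominance(self, rng):
        gm = rng.random((5, 5, 5)) * 0.6
        wm = rng.random((5, 5, 5)) * 0.6
        out = ca.gmwm_map(make_volume(gm), make_volume(wm))
        assert (out.voxels <= 1.0).all()
        assert (out.voxels >= gm - 1e-12).all()
        assert (out.voxels >= wm - 1e-12).all()

    def test_zero_maps(self):
        z = make_volume(np.zeros((4, 4, 4)))
        assert ca.gmwm_map(z, z.like(z.voxels.copy())).voxels.sum() == 0.0


class TestBrainCSFMask:
    def test_zero_gmwm_returns_icv(self, rng):
        icv = make_volume((rng.random((6, 6, 6)) > 0.4).astype(np.uint8))
        z = icv.like(np.zeros((6, 6, 6)))
        out = ca.brain_csf_mask(icv, z)
        np.testing.assert_array_equal(out.voxels, icv.voxels)

    def test_full_gmwm_empties_mask(self, rng):
        icv = make_volume(np.ones((5, 5, 5), dtype=np.uint8))
        out = ca.brain_csf_mask(icv, icv.like(np.ones((5, 5, 5))))
        assert out.voxels.sum() == 0

    def test_phantom_confusion_rates(self, noiseless_pipeline):
        """On noiseless input the derived CSF mask covers >= 95% of the
        truth CSF and <= 5% of the truth GM/WM voxels."""
        _, _, _, truth, _, post = noiseless_pipeline
        gmwm = ca.gmwm_map(post["gm"], post["wm"])
        out = ca.brain_csf_mask(truth.icv_mask, gmwm, 0.90)
        m = out.voxels.astype(bool)
        labels = truth.tissue_labels.voxels
        csf_true = (labels == ph.CISTERNAL_CSF) | (labels == ph.VENTRICULAR_CSF)
        tissue_true = (labels == ph.GM) | (labels == ph.WM)
        assert m[csf_true].mean() >= 0.95
        assert m[tissue_true].mean() <= 0.05


class TestSplitCompartments:
    def test_ventricular_dice_against_truth(self, noiseless_pipeline):
        spec, assets, img, truth, native, post = noiseless_pipeline
        gmwm = ca.gmwm_map(post["gm"], post["wm"])
        csf_mask = ca.brain_csf_mask(truth.icv_mask, gmwm, 0.90)
        brain_std = assets.standard_brain_mask
        from rbmicv.core_image import resample
        brain_native = resample(brain_std, truth.subject_affine, img,
                                mode="nearest")
        comp = ca.split_compartments(csf_mask, brain_native, native["csf"],
                                     erosion_mm=6.0, prior_floor=0.5)
        assert dice(comp.ventricular_mask, truth.ventricular_mask) >= 0.9

    def test_partition_is_exact(self, noiseless_pipeline):
        spec, assets, img, truth, native, post = noiseless_pipeline
        gmwm = ca.gmwm_map(post["gm"], post["wm"])
        csf_mask = ca.brain_csf_mask(truth.icv_mask, gmwm, 0.90)
        comp = ca.split_compartments(csf_mask, truth.icv_mask,
                                     native["csf"])
        vent = comp.ventricular_mask.voxels.astype(bool)
        cist = comp.cisternal_mask.voxels.astype(bool)
        assert not (vent & cist).any()
        np.testing.assert_array_equal(vent | cist,
                                      csf_mask.voxels.astype(bool))
        assert comp.total_csf_cm3 == pytest.approx(
            comp.ventricular_cm3 + comp.cisternal_cm3, abs=1e-6)

    def test_degenerate_parameters_take_everything(self, rng):
        csf = make_volume((rng.random((8, 8, 8)) > 0.6).astype(np.uint8),
                          voxel=2.0)
        everything = csf.like(np.ones((8, 8, 8), dtype=np.uint8))
        prior = csf.like(np.ones((8, 8, 8)))
        comp = ca.split_compartments(csf, everything, prior,
                                     erosion_mm=0.0, prior_floor=0.0)
        np.testing.assert_array_equal(comp.ventricular_mask.voxels,
                                      csf.voxels)
        assert comp.cisternal_cm3 == 0.0

    def test_empty_mask_warns(self):
        z = make_volume(np.zeros((5, 5, 5), dtype=np.uint8))
        with pytest.warns(UserWarning, match="empty"):
            comp = ca.split_compartments(z, z, z.like(np.zeros((5, 5, 5))))
        assert comp.total_csf_cm3 == 0.0


class TestSampling:
    def test_constant_mask_gives_constant_means(self):
        vol = make_volume(np.full((8, 8, 8), 42.0))
        mask = make_volume(np.ones((8, 8, 8), dtype=np.uint8))
        out = ca.sample_csf_intensity(vol, mask,
                                      ca.SamplingPlan(50, 5, seed=1))
        np.testing.assert_allclose(out["trial_means"], 42.0)
        assert out["pooled_sd"] == 0.0

    def test_same_seed_identical(self, rng):
        vol = make_volume(rng.random((8, 8, 8)))
        mask = make_volume(np.ones((8, 8, 8), dtype=np.uint8))
        plan = ca.SamplingPlan(100, 10, seed=7)
        a = ca.sample_csf_intensity(vol, mask, plan)
        b = ca.sample_csf_intensity(vol, mask, plan)
        np.testing.assert_array_equal(a["samples"], b["samples"])

    def test_trials_use_independent_streams(self, rng):
        vol = make_volume(rng.random((10, 10, 10)))
        mask = make_volume(np.ones((10, 10, 10), dtype=np.uint8))
        out = ca.sample_csf_intensity(vol, mask,
                                      ca.SamplingPlan(200, 2, seed=3))
        assert not np.array_equal(out["samples"][0], out["samples"][1])

    def test_pooled_mean_clt_bound(self):
        rng = np.random.default_rng(0)
        vol = make_volume(rng.normal(100.0, 10.0, size=(20, 20, 20)))
        mask = make_volume(np.ones((20, 20, 20), dtype=np.uint8))
        out = ca.sample_csf_intensity(vol, mask,
                                      ca.SamplingPlan(270, 10, seed=5))
        se = 10.0 / np.sqrt(2700.0)
        assert abs(out["pooled_mean"] - 100.0) <= 3.0 * se + 3 * se

    def test_small_mask_samples_with_replacement(self, rng):
        vol = make_volume(rng.random((4, 4, 4)))
        mask = vol.like(np.zeros((4, 4, 4), dtype=np.uint8))
        mask.voxels[0, 0, :3] = 1
        out = ca.sample_csf_intensity(vol, mask, ca.SamplingPlan(10, 2, 1))
        assert out["with_replacement"] is True

    def test_empty_mask_raises(self, rng):
        vol = make_volume(rng.random((4, 4, 4)))
        with pytest.raises(ca.CSFDataError):
            ca.sample_csf_intensity(vol,
                                    vol.like(np.zeros((4, 4, 4))),
                                    ca.SamplingPlan(5, 2, 1))


class TestIntensityRelDiff:
    def test_equal_means_zero(self):
        assert ca.intensity_rel_diff(10.0, 10.0) == 0.0

    def test_ratio_132_gives_2759(self):
        assert ca.intensity_rel_diff(1.32, 1.0) == pytest.approx(27.586,
                                                                 abs=1e-2)

    def test_antisymmetry(self):
        assert ca.intensity_rel_diff(3.0, 5.0) == -ca.intensity_rel_diff(
            5.0, 3.0)

    def test_nonpositive_denominator(self):
        with pytest.raises(ca.CSFDataError):
            ca.intensity_rel_diff(-5.0, 2.0)


class TestKSNormality:
    def test_gaussian_samples_mostly_pass(self):
        hits = 0
        for sd in range(20):
            x = np.random.default_rng(sd).normal(50.0, 5.0, size=1000)
            _, p = ca.ks_normality(x)
            hits += p > 0.05
        assert hits >= 18

    def test_bimodal_rejected(self):
        rng = np.random.default_rng(1)
        x = np.concatenate([rng.normal(0, 1, 500), rng.normal(12, 1, 500)])
        _, p = ca.ks_normality(x)
        assert p < 0.01

    def test_outlier_increases_D(self):
        from scipy import stats

        x = stats.norm.ppf(np.linspace(0.01, 0.99, 99))
        d0, _ = ca.ks_normality(x)
        x_out = np.append(x[:-1], 25.0)
        d1, _ = ca.ks_normality(x_out)
        assert d0 <= d1

    def test_log_transform_requires_positive(self):
        with pytest.raises(ca.CSFDataError):
            ca.ks_normality(np.linspace(-1, 1, 50), log_transform=True)

    def test_too_few_samples(self):
        with pytest.raises(ca.CSFDataError):
            ca.ks_normality([1.0, 2.0, 3.0])


class TestSampleSizeForSD:
    def test_reference_configuration(self):
        """90% confidence, 10% relative SD error -> n ≈ 136 per region
        (normal approximation 0.5 * (z_0.95 / 0.1)^2 ≈ 135.3)."""
        n = ca.sample_size_for_sd(0.90, 0.10)
        assert 130 <= n <= 142

    def test_monotone_in_rel_error(self):
        assert ca.sample_size_for_sd(0.90, 0.30) < ca.sample_size_for_sd(
            0.90, 0.10)

    def test_monotone_in_confidence(self):
        assert ca.sample_size_for_sd(0.99, 0.10) > ca.sample_size_for_sd(
            0.90, 0.10)


class TestOffsetRecovery:
    def test_sampled_offset_near_configured(self):
        """Sampled symmetric difference on an uncorrected 3T phantom lies
        within 3 SE of the configured 32%."""
        spec = ph.PhantomSpec(field_mode="3T")
        img, truth = ph.synthesize_subject(spec, seed=4)
        plan = ca.SamplingPlan(270, 10, seed=4)
        sv = ca.sample_csf_intensity(img, truth.ventricular_mask, plan)
        sc = ca.sample_csf_intensity(img, truth.cisternal_mask, plan)
        rd = ca.intensity_rel_diff(sv["pooled_mean"], sc["pooled_mean"])
        # propagate the per-compartment SEs through the symmetric diff
        n = plan.n_voxels * plan.n_trials
        se = 100.0 * np.hypot(sv["pooled_sd"], sc["pooled_sd"]) / (
            0.5 * (sv["pooled_mean"] + sc["pooled_mean"])) / np.sqrt(n)
        assert abs(rd - 32.0) <= max(3 * se, 1.0)
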