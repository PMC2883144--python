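"""Ventricular vs. cisternal CSF separation and intensity analysis.

The CSF inside the ventricles and the CSF in the subarachnoid space
(cisterns) should share one intensity distribution on a T1-weighted
image; at higher field strength the central-brightening artifact breaks
this, and the resulting offset is what drives tissue-class ICV methods to
drop peripheral CSF.  This module reproduces the measurement machinery:

1. a brain-CSF mask obtained by subtracting the thresholded GM+WM
   probability map from the ICV mask,
2. a morphological split of that mask into intraventricular and cisternal
   compartments, guided by an eroded standard-space brain mask warped to
   native space and by the CSF prior,
3. Monte-Carlo intensity sampling (by default 10 trials of 270 voxels) in
   each compartment, the symmetric percent intensity difference between
   the compartment means, and a Lilliefors-style Kolmogorov–Smirnov
   normality check of the sampled (optionally log-transformed) values.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage, stats
from statsmodels.stats.diagnostic import lilliefors

from .core_image import Volume3D, check_same_grid, voxel_volume


class CSFDataError(ValueError):
    """Invalid input for CSF analysis (empty masks, bad intensities)."""


@dataclass
class CSFCompartments:
    """Disjoint ventricular / cisternal partition of the brain CSF mask."""

    ventricular_mask: Volume3D
    cisternal_mask: Volume3D
    ventricular_cm3: float
    cisternal_cm3: float
    total_csf_cm3: float
    provenance: dict


@dataclass(frozen=True)
class SamplingPlan:
    """Monte-Carlo CSF sampling configuration."""

    n_voxels: int = 270
    n_trials: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_voxels < 1 or self.n_trials < 1:
            raise ValueError("n_voxels and n_trials must be >= 1")


def gmwm_map(gm_post: Volume3D, wm_post: Volume3D) -> Volume3D:
    """Sum of the GM and WM probability maps, clipped to [0, 1]."""
    check_same_grid(gm_post, wm_post, what="GM/WM maps")
    total = np.asarray(gm_post.voxels, float) + np.asarray(wm_post.voxels,
                                                           float)
    return gm_post.like(np.clip(total, 0.0, 1.0))


def brain_csf_mask(icv_mask: Volume3D, gmwm: Volume3D,
                   gmwm_threshold: float = 0.90) -> Volume3D:
    """ICV mask minus the thresholded GM+WM map: the brain's CSF space."""
    check_same_grid(icv_mask, gmwm, what="ICV mask and GMWM map")
    out = (np.asarray(icv_mask.voxels) > 0.5) & ~(
        np.asarray(gmwm.voxels, float) >= gmwm_threshold)
    return icv_mask.like(out.astype(np.uint8))


def _ball(radius_mm: float, voxel_mm: float) -> np.ndarray:
    r_vox = max(0, int(round(radius_mm / voxel_mm)))
    if r_vox == 0:
        return np.ones((1, 1, 1), dtype=bool)
    span = np.arange(-r_vox, r_vox + 1)
    xx, yy, zz = np.meshgrid(span, span, span, indexing="ij")
    return xx ** 2 + yy ** 2 + zz ** 2 <= r_vox ** 2


def split_compartments(
    csf_mask: Volume3D,
    warped_brain_mask: Volume3D,
    csf_prior_native: Volume3D,
    erosion_mm: float = 6.0,
    prior_floor: float = 0.5,
) -> CSFCompartments:
    """Split a brain-CSF mask into ventricular and cisternal compartments.

    The warped standard-space brain mask is eroded by a ball of radius
    ``erosion_mm`` to form a conservative core that cannot reach the
    subarachnoid rim; CSF voxels inside the core whose CSF prior is at
    least ``prior_floor`` are ventricular candidates, connected components
    of the candidates are kept when their centroid lies inside a
    once-more-eroded core, and everything else in the CSF mask is
    cisternal.  The two compartments tile the input mask exactly.
    """
    check_same_grid(csf_mask, warped_brain_mask, csf_prior_native,
                    what="CSF split inputs")
    csf = np.asarray(csf_mask.voxels) > 0.5
    vox_mm = float(np.cbrt(voxel_volume(csf_mask)))
    prov = {"erosion_mm": erosion_mm, "prior_floor": prior_floor,
            "voxel_mm": vox_mm}
    if not csf.any():
        import warnings

        warnings.warn("empty CSF mask; returning empty compartments",
                      stacklevel=2)
        empty = csf_mask.like(np.zeros_like(csf, dtype=np.uint8))
        return CSFCompartments(empty, empty.like(empty.voxels.copy()),
                               0.0, 0.0, 0.0, prov)

    brain = np.asarray(warped_brain_mask.voxels) > 0.5
    ball = _ball(erosion_mm, vox_mm)
    core = ndimage.binary_erosion(brain, structure=ball) if erosion_mm > 0 \
        else brain
    candidate = csf & core & (
        np.asarray(csf_prior_native.voxels, float) >= prior_floor)

    inner = ndimage.binary_erosion(core, structure=ball) if erosion_mm > 0 \
        else core
    labels, n_comp = ndimage.label(candidate)
    vent = np.zeros_like(csf)
    if n_comp:
        centroids = ndimage.center_of_mass(candidate, labels,
                                           range(1, n_comp + 1))
        for lab, com in enumerate(centroids, start=1):
            idx = tuple(int(round(c)) for c in com)
            if inner[idx]:
                vent |= labels == lab
    cist = csf & ~vent

    vv_cm3 = voxel_volume(csf_mask) / 1000.0
    return CSFCompartments(
        ventricular_mask=csf_mask.like(vent.astype(np.uint8)),
        cisternal_mask=csf_mask.like(cist.astype(np.uint8)),
        ventricular_cm3=float(vent.sum()) * vv_cm3,
        cisternal_cm3=float(cist.sum()) * vv_cm3,
        total_csf_cm3=float(csf.sum()) * vv_cm3,
        provenance=prov,
    )


def sample_csf_intensity(
    vol: Volume3D,
    mask: Volume3D,
    plan: SamplingPlan = SamplingPlan(),
) -> dict:
    """Monte-Carlo intensity sampling within a mask.

    Each trial draws ``plan.n_voxels`` voxels uniformly without
    replacement from an independent substream of the seed (with
    replacement, logged in the output, if the mask is smaller than a
    trial).  Deterministic given the plan.
    """
    check_same_grid(vol, mask, what="image and mask")
    m = np.asarray(mask.voxels) > 0.5
    values = np.asarray(vol.voxels, dtype=float)[m]
    if values.size == 0:
        raise CSFDataError("empty sampling mask")
    replace = values.size < plan.n_voxels
    streams = np.random.SeedSequence(plan.seed).spawn(plan.n_trials)
    samples = []
    for ss in streams:
        rng = np.random.default_rng(ss)
        samples.append(rng.choice(values, size=plan.n_voxels,
                                  replace=replace))
    samples = np.asarray(samples)
    return {
        "trial_means": samples.mean(axis=1),
        "pooled_mean": float(samples.mean()),
        "pooled_sd": float(samples.std(ddof=1)),
        "samples": samples,
        "with_replacement": replace,
    }


def intensity_rel_diff(ventricular_mean: float, cisternal_mean: float) -> float:
    """Symmetric percent difference of the two compartment means.

    100 · (V2 − V1) / ((V2 + V1)/2) with V2 the ventricular and V1 the
    cisternal mean; positive values mean brighter ventricular CSF.
    """
    denom = (ventricular_mean + cisternal_mean) / 2.0
    if denom <= 0:
        raise CSFDataError("mean intensities must be positive")
    return 100.0 * (ventricular_mean - cisternal_mean) / denom


def ks_normality(samples, log_transform: bool = False) -> tuple[float, float]:
    """Kolmogorov–Smirnov normality test with plug-in parameters.

    One-sample KS of the (optionally log-transformed) values against a
    Gaussian with the sample mean and SD — the Lilliefors variant, since
    the reference distribution's parameters are estimated from the same
    sample.  Returns (D, p).
    """
    x = np.asarray(samples, dtype=float).ravel()
    if x.size < 8:
        raise CSFDataError("need at least 8 samples")
    if log_transform:
        if (x <= 0).any():
            raise CSFDataError("log transform requires positive samples")
        x = np.log(x)
    d, p = lilliefors(x, dist="norm", pvalmethod="table")
    return float(d), float(p)


def sample_size_for_sd(confidence: float = 0.90,
                       rel_error: float = 0.10) -> int:
    """Smallest n whose chi-square CI for an SD has half-width ≤ rel_error·σ.

    For a Gaussian sample of size n, the equal-tail confidence interval
    for σ is σ̂·[√((n−1)/χ²_{1−α/2}), √((n−1)/χ²_{α/2})]; the half-width
    shrinks like 1/√(2n), giving ≈ 0.5·(z_{1−α/2}/rel_error)² for small
    relative errors.
    """
    if not (0 < confidence < 1):
        raise ValueError("confidence must lie in (0, 1)")
    if rel_error <= 0:
        raise ValueError("rel_error must be > 0")
    alpha = 1.0 - confidence
    for n in range(2, 1_000_000):
        df = n - 1
        lo = np.sqrt(df / stats.chi2.ppf(1 - alpha / 2, df))
        hi = np.sqrt(df / stats.chi2.ppf(alpha / 2, df))
        if (hi - lo) / 2.0 <= rel_error:
            return n
    raise RuntimeError("no sample size found")  # pragma: no cover
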