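"""Synthetic digital head phantom with ground truth.

The phantom emulates a T1-weighted head acquisition as a set of nested
ellipsoids — scalp, skull, dura, subarachnoid (cisternal) CSF, a cortical
grey-matter shell, a white-matter core and two intraventricular CSF
ellipsoids — painted with class mean intensities and degraded by the two
field-strength artifacts this toolkit studies:

* a smooth multiplicative *central brightening* field (Gaussian bump,
  ≈5% amplitude in the "1.5T" mode, ≈30% in the "3T" mode), and
* a net intensity offset between ventricular and cisternal CSF
  (16% at "1.5T", 32% at "3T", expressed as the symmetric two-mean
  percentage difference measured on the noiseless image).

The same geometry, rendered artifact-free on a fixed standard grid, serves
as the standard-space template from which Gaussian-blurred tissue
probability maps (GM / WM / CSF) and a conservative standard-space brain
mask are derived — synthetic counterparts of population tissue priors and
of a linearly generated template brain mask.  Each synthetic subject is
related to the standard space by a random affine, so reverse normalization
can be exercised exactly.

Intensity scale: arbitrary units on a T1-like ordering
(CSF ≈ bone < dura < GM < WM < scalp fat).  The dura and inner-table bone
defaults sit close to the CSF band — the tissue ambiguity that drives
peripheral-CSF misclassification in tissue-class ICV estimation.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .core_image import (
    AffineTransform,
    Volume3D,
    gaussian_blur_mm,
    invert_affine,
    voxel_volume,
    world_coordinates,
)

# tissue label codes
BACKGROUND, SCALP, SKULL, DURA, CISTERNAL_CSF, GM, WM, VENTRICULAR_CSF = range(8)

LABEL_NAMES = {
    BACKGROUND: "background",
    SCALP: "scalp",
    SKULL: "skull",
    DURA: "dura",
    CISTERNAL_CSF: "cisternal_csf",
    GM: "gm",
    WM: "wm",
    VENTRICULAR_CSF: "ventricular_csf",
}

_Z90 = 1.2815515655446004  # standard normal 90% quantile


@dataclass(frozen=True)
class PhantomSpec:
    """Geometry, intensity and artifact parameters of the head phantom.

    Semi-axes are in mm about the head centre; structures must be strictly
    nested (scalp ⊃ skull ⊃ inner table ⊃ CSF ⊃ GM shell ⊃ WM core, with
    both ventricles strictly inside the WM core).  ``dura_thickness_mm``
    carves the dura as a thin shell immediately inside the inner table.
    """

    grid_shape: tuple[int, int, int] = (96, 96, 96)
    voxel_size: float = 2.0
    # nested semi-axes (x, y, z) in mm
    scalp_axes: tuple[float, float, float] = (72.0, 84.0, 75.0)
    skull_axes: tuple[float, float, float] = (67.0, 79.0, 70.0)
    inner_table_axes: tuple[float, float, float] = (62.0, 74.0, 65.0)
    gm_axes: tuple[float, float, float] = (57.0, 69.0, 60.0)
    wm_axes: tuple[float, float, float] = (48.0, 60.0, 51.0)
    dura_thickness_mm: float = 1.0
    ventricle_centres: tuple[tuple[float, float, float], ...] = (
        (-13.0, -8.0, 2.0),
        (13.0, -8.0, 2.0),
    )
    ventricle_axes: tuple[float, float, float] = (16.0, 32.0, 18.0)
    # class mean intensities, arbitrary units
    mean_background: float = 4.0
    mean_scalp: float = 180.0
    mean_skull: float = 58.0
    mean_dura: float = 58.0
    mean_csf: float = 50.0
    mean_gm: float = 110.0
    mean_wm: float = 160.0
    noise_sd: float = 4.0
    # field-strength artifact configuration
    field_mode: str = "3T"
    brightening_amplitude: float | None = None  # 0.05 @1.5T, 0.30 @3T
    brightening_fwhm: float = 140.0
    ventricular_offset_pct: float | None = None  # 16 @1.5T, 32 @3T
    # subject-to-standard affine sampling ranges
    scale_range: tuple[float, float] = (0.95, 1.05)
    rotation_deg: float = 8.0
    translation_mm: float = 5.0
    # prior construction
    prior_blur_fwhm: float = 2.0
    prior_margin_mm: float = 0.3
    seed: int = 0

    _MODE_DEFAULTS = {"1.5T": (0.05, 16.0), "3T": (0.30, 32.0)}

    def __post_init__(self) -> None:
        if self.field_mode not in ("1.5T", "3T", "custom"):
            raise ValueError(f"unknown field_mode {self.field_mode!r}")
        amp, off = self._MODE_DEFAULTS.get(self.field_mode, (0.0, 0.0))
        if self.brightening_amplitude is None:
            object.__setattr__(self, "brightening_amplitude", amp)
        if self.ventricular_offset_pct is None:
            object.__setattr__(self, "ventricular_offset_pct", off)
        self.validate()

    # -- validation -------------------------------------------------------
    def validate(self) -> None:
        nest = [self.scalp_axes, self.skull_axes, self.inner_table_axes,
                self.csf_outer_axes, self.gm_axes, self.wm_axes]
        for outer, inner in zip(nest, nest[1:]):
            if not all(i < o for i, o in zip(inner, outer)):
                raise ValueError(
                    f"phantom structures must be strictly nested: {inner} "
                    f"not inside {outer}")
        for centre in self.ventricle_centres:
            if not all(abs(c) + a < w for c, a, w in
                       zip(centre, self.ventricle_axes, self.wm_axes)):
                raise ValueError(
                    f"ventricle at {centre} not strictly inside the WM core")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.brightening_amplitude < 0:
            raise ValueError("brightening_amplitude must be >= 0")
        if self.ventricular_offset_pct <= -100:
            raise ValueError("ventricular_offset_pct must exceed -100")
        if self.dura_thickness_mm <= 0:
            raise ValueError("dura_thickness_mm must be > 0")

    # -- derived geometry -------------------------------------------------
    @property
    def csf_outer_axes(self) -> tuple[float, float, float]:
        """Outer boundary of the cisternal CSF = inner surface of the dura."""
        return tuple(a - self.dura_thickness_mm for a in self.inner_table_axes)

    @property
    def prior_extension_mm(self) -> float:
        """Outward extension of the CSF prior support beyond the inner table.

        Calibrated so that the 90% isocontour of the blurred, summed tissue
        prior tracks the inner-table surface (minus a small conservative
        margin), emulating population tissue maps whose support spreads
        slightly past the subarachnoid space.
        """
        sigma = self.prior_blur_fwhm / (2.0 * np.sqrt(2.0 * np.log(2.0)))
        return max(0.0, _Z90 * sigma - self.prior_margin_mm)

    def standard_grid(self) -> Volume3D:
        """The standard-space grid: isotropic voxels centred on the origin."""
        n = np.asarray(self.grid_shape, dtype=float)
        affine = np.eye(4)
        affine[:3, :3] *= self.voxel_size
        affine[:3, 3] = -(n - 1) / 2.0 * self.voxel_size
        return Volume3D(voxels=np.zeros(self.grid_shape), affine=affine,
                        space_tag="standard")

    def scaled(self, factor: float) -> "PhantomSpec":
        """Geometrically scaled copy (smaller grids for quick experiments)."""
        sc3 = lambda t: tuple(factor * x for x in t)  # noqa: E731
        return replace(
            self,
            grid_shape=tuple(max(8, int(round(factor * n)))
                             for n in self.grid_shape),
            scalp_axes=sc3(self.scalp_axes),
            skull_axes=sc3(self.skull_axes),
            inner_table_axes=sc3(self.inner_table_axes),
            gm_axes=sc3(self.gm_axes),
            wm_axes=sc3(self.wm_axes),
            dura_thickness_mm=max(self.voxel_size / 2,
                                  factor * self.dura_thickness_mm),
            ventricle_centres=tuple(sc3(c) for c in self.ventricle_centres),
            ventricle_axes=sc3(self.ventricle_axes),
            brightening_fwhm=factor * self.brightening_fwhm,
            translation_mm=factor * self.translation_mm,
        )

    @property
    def class_means(self) -> dict[int, float]:
        return {
            BACKGROUND: self.mean_background,
            SCALP: self.mean_scalp,
            SKULL: self.mean_skull,
            DURA: self.mean_dura,
            CISTERNAL_CSF: self.mean_csf,
            GM: self.mean_gm,
            WM: self.mean_wm,
            VENTRICULAR_CSF: self.mean_csf,  # offset applied downstream
        }


@dataclass
class PhantomTruth:
    """Ground truth accompanying one synthetic subject image."""

    icv_mask: Volume3D
    tissue_labels: Volume3D
    ventricular_mask: Volume3D
    cisternal_mask: Volume3D
    true_icv_mm3: float
    subject_affine: AffineTransform  # native world -> standard world
    bias_field: Volume3D


@dataclass
class TemplateAssets:
    """Standard-space template, tissue priors and brain mask."""

    template: Volume3D
    priors: dict[str, Volume3D]  # keys: gm, wm, csf
    standard_brain_mask: Volume3D


# ---------------------------------------------------------------------------
# geometry helpers
# ---------------------------------------------------------------------------

def _inside(points: np.ndarray, axes, centre=(0.0, 0.0, 0.0),
            grow_mm: float = 0.0) -> np.ndarray:
    """Boolean membership of world points in an (optionally grown) ellipsoid."""
    semi = np.asarray(axes, dtype=float) + grow_mm
    rel = (points - np.asarray(centre, dtype=float)) / semi
    return np.einsum("...a,...a->...", rel, rel) <= 1.0


def _template_points(spec: PhantomSpec) -> np.ndarray:
    """World coordinates of the standard grid's voxel centres."""
    return world_coordinates(spec.standard_grid())


def classify_points(spec: PhantomSpec, points: np.ndarray) -> np.ndarray:
    """Tissue label for each world point, from the analytic geometry.

    ``points`` has shape (..., 3) in the *standard* world frame (the frame
    in which the ellipsoids are defined).
    """
    labels = np.full(points.shape[:-1], BACKGROUND, dtype=np.uint8)
    labels[_inside(points, spec.scalp_axes)] = SCALP
    labels[_inside(points, spec.skull_axes)] = SKULL
    labels[_inside(points, spec.inner_table_axes)] = DURA
    labels[_inside(points, spec.csf_outer_axes)] = CISTERNAL_CSF
    labels[_inside(points, spec.gm_axes)] = GM
    labels[_inside(points, spec.wm_axes)] = WM
    for centre in spec.ventricle_centres:
        labels[_inside(points, spec.ventricle_axes, centre)] = VENTRICULAR_CSF
    return labels


# ---------------------------------------------------------------------------
# template and priors
# ---------------------------------------------------------------------------

def make_template(spec: PhantomSpec) -> TemplateAssets:
    """Build the standard-space template, tissue priors and brain mask.

    The priors are Gaussian-blurred indicators of GM, WM and CSF.  The CSF
    indicator covers everything intracranial that is not GM/WM — ventricular
    and cisternal CSF plus the thin dura shell, extended outward by
    ``spec.prior_extension_mm`` — mirroring how population CSF maps, which
    never separate dura or partial-volume rim voxels from subarachnoid
    fluid, spread beyond the brain surface.  Because the three indicators
    are disjoint, the blurred maps sum to at most 1 voxelwise by linearity;
    any floating-point overshoot is clipped.

    The standard brain mask thresholds the blurred whole-brain indicator
    (GM ∪ WM ∪ CSF proper, without dura) at 0.5 — the synthetic analogue of
    a "brain present at least 50% of the time" template mask.
    """
    grid = spec.standard_grid()
    pts = world_coordinates(grid)
    labels = classify_points(spec, pts)

    gm_ind = (labels == GM).astype(float)
    wm_ind = (labels == WM).astype(float)
    csf_ind = _inside(pts, spec.inner_table_axes,
                      grow_mm=spec.prior_extension_mm).astype(float)
    csf_ind[(labels == GM) | (labels == WM)] = 0.0
    brain_ind = ((labels == GM) | (labels == WM) |
                 (labels == CISTERNAL_CSF) |
                 (labels == VENTRICULAR_CSF)).astype(float)

    fwhm = spec.prior_blur_fwhm
    gm_p = gaussian_blur_mm(grid.like(gm_ind), fwhm)
    wm_p = gaussian_blur_mm(grid.like(wm_ind), fwhm)
    csf_p = gaussian_blur_mm(grid.like(csf_ind), fwhm)
    total = gm_p.voxels + wm_p.voxels + csf_p.voxels
    excess = np.clip(total, 1.0, None)
    # population tissue maps vanish outside the cranium: truncate the blur
    # tails at the outer skull surface so no tissue prior reaches the scalp
    cranium = _inside(pts, spec.skull_axes)
    for p in (gm_p, wm_p, csf_p):
        np.divide(p.voxels, excess, out=p.voxels)
        p.voxels[~cranium] = 0.0
        np.clip(p.voxels, 0.0, 1.0, out=p.voxels)

    brain_blur = gaussian_blur_mm(grid.like(brain_ind), fwhm)
    brain_mask = grid.like((brain_blur.voxels >= 0.5).astype(np.uint8))

    means = spec.class_means
    template = grid.like(
        np.take(np.array([means[c] for c in range(8)]), labels))
    return TemplateAssets(template=template,
                          priors={"gm": gm_p, "wm": wm_p, "csf": csf_p},
                          standard_brain_mask=brain_mask)


# ---------------------------------------------------------------------------
# bias field
# ---------------------------------------------------------------------------

def apply_bias_field(vol: Volume3D, amplitude: float, fwhm: float,
                     centre=(0.0, 0.0, 0.0)) -> tuple[Volume3D, Volume3D]:
    """Multiply a volume by a central-brightening Gaussian bump.

    field(x) = 1 + amplitude · exp(−4 ln2 ‖x−centre‖² / fwhm²); the field is
    returned alongside the biased image so it can serve as ground truth.
    """
    if fwhm <= 0:
        raise ValueError("fwhm must be > 0")
    if amplitude < 0:
        raise ValueError("amplitude must be >= 0")
    pts = world_coordinates(vol)
    d2 = np.sum((pts - np.asarray(centre, dtype=float)) ** 2, axis=-1)
    fld = 1.0 + amplitude * np.exp(-4.0 * np.log(2.0) * d2 / fwhm ** 2)
    return vol.like(np.asarray(vol.voxels, dtype=float) * fld), vol.like(fld)


# ---------------------------------------------------------------------------
# subject synthesis
# ---------------------------------------------------------------------------

def _draw_subject_affine(spec: PhantomSpec,
                         rng: np.random.Generator) -> AffineTransform:
    """Random native-to-standard affine: per-axis scale, rotation, shift."""
    scales = rng.uniform(*spec.scale_range, size=3)
    angles = np.deg2rad(rng.uniform(-spec.rotation_deg, spec.rotation_deg,
                                    size=3))
    trans = rng.uniform(-spec.translation_mm, spec.translation_mm, size=3)
    cx, cy, cz = np.cos(angles)
    sx, sy, sz = np.sin(angles)
    rx = np.array([[1, 0, 0], [0, cx, -sx], [0, sx, cx]])
    ry = np.array([[cy, 0, sy], [0, 1, 0], [-sy, 0, cy]])
    rz = np.array([[cz, -sz, 0], [sz, cz, 0], [0, 0, 1]])
    m = np.eye(4)
    m[:3, :3] = rz @ ry @ rx @ np.diag(scales)
    m[:3, 3] = trans
    return AffineTransform(m)


def synthesize_subject(spec: PhantomSpec,
                       seed: int | None = None) -> tuple[Volume3D, PhantomTruth]:
    """Render one ground-truthed subject head image in native space.

    A random native→standard affine is drawn, tissue labels are evaluated
    analytically at every native voxel centre (no resampling error in the
    ground truth), class mean intensities are painted, the central
    brightening field of the configured mode is applied, the ventricular
    CSF mean is then calibrated so that the net ventricular-vs-cisternal
    symmetric percentage difference of the noiseless image equals
    ``ventricular_offset_pct``, and Gaussian noise is added.  Identical
    spec and seed reproduce the output bit for bit.
    """
    if seed is None:
        seed = spec.seed
    rng = np.random.default_rng(seed)
    subject_affine = _draw_subject_affine(spec, rng)

    grid = spec.standard_grid()
    native_grid = Volume3D(voxels=np.zeros(spec.grid_shape),
                           affine=grid.affine.copy(), space_tag="native")
    pts_native = world_coordinates(native_grid)
    pts_standard = subject_affine.apply(
        pts_native.reshape(-1, 3)).reshape(pts_native.shape)
    labels = classify_points(spec, pts_standard)

    means = spec.class_means
    image = np.take(np.array([means[c] for c in range(8)], dtype=float),
                    labels)

    head_centre_native = invert_affine(subject_affine).apply(
        np.zeros(3)).ravel()
    if spec.brightening_amplitude > 0:
        biased, bias = apply_bias_field(native_grid.like(image),
                                        spec.brightening_amplitude,
                                        spec.brightening_fwhm,
                                        centre=head_centre_native)
        image = biased.voxels
    else:
        bias = native_grid.like(np.ones(spec.grid_shape))

    vent = labels == VENTRICULAR_CSF
    cist = labels == CISTERNAL_CSF
    q = spec.ventricular_offset_pct / 100.0
    if vent.any() and cist.any() and q != 0.0:
        target_ratio = (2.0 + q) / (2.0 - q)  # symmetric %diff -> mean ratio
        gain = target_ratio * image[cist].mean() / image[vent].mean()
        image[vent] *= gain

    if spec.noise_sd > 0:
        image = image + rng.normal(0.0, spec.noise_sd, size=image.shape)

    icv = _inside(pts_standard, spec.inner_table_axes)
    vol_mm3 = voxel_volume(native_grid)
    truth = PhantomTruth(
        icv_mask=native_grid.like(icv.astype(np.uint8)),
        tissue_labels=native_grid.like(labels),
        ventricular_mask=native_grid.like(vent.astype(np.uint8)),
        cisternal_mask=native_grid.like(cist.astype(np.uint8)),
        true_icv_mm3=float(icv.sum()) * vol_mm3,
        subject_affine=subject_affine,
        bias_field=bias,
    )
    return native_grid.like(image), truth
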