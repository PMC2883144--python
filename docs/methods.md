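# Methods

`rbmicv` implements and compares two automated estimators of intracranial
volume (ICV) on T1-weighted head MRI, together with the measurement
machinery needed to explain why they disagree across scanner field
strengths. Because no subject data ship with the package, every analysis
runs on a synthetic digital head phantom with exact ground truth; this
note records the models, the phantom's construction, the numerical
choices, and what the synthetic results do and do not show.

## The two ICV estimators

**Reverse brain mask (RBM).** The three standard-space tissue probability
maps (GM, WM, CSF) are summed voxelwise — without thresholding — into an
ICV probabilistic mask, warped into the subject's native space with the
inverse of the subject→standard affine using nearest-neighbour
interpolation, and thresholded at 90% probability. ICV is the surviving
voxel count times the voxel volume. The estimate uses only the priors and
the transform; it is provably invariant to the subject's intensity
content, which is the source of its cross-field stability.

**Tissue-class thresholding.** An atlas-prior Gaussian-mixture EM
segmentation produces GM/WM/CSF posterior maps; the ICV mask is the hard
cut-off `P(GM)+P(WM)+P(CSF) ≥ θ` with θ = 0.90 by default (0.50 is the
documented alternative pairing for deconvolution-style bias correctors).
This estimator sees the intensities, so intensity artifacts propagate
into the volume.

## Atlas-prior EM segmentation

The intensity model is a spatially weighted mixture

    p(x_v) = Σ_c π_c(v) Σ_k w_ck N(x_v; μ_ck, σ²_ck),

where the warped priors π_c(v) act as per-voxel mixing proportions over
classes (the standard probabilistic-atlas formulation), and each class
carries K_c Gaussians (defaults: GM 2, WM 2, CSF 2; CSF 4 is the variant
motivated by the broader CSF intensity distribution at 3T). EM updates
are in closed form; the observed-data log-likelihood is non-decreasing by
construction and is traced per iteration. Convergence is a relative
log-likelihood change below 1e-5 (default cap 60 iterations; a
non-converged fit is returned with a flag, never an exception).

Priors are warped with linear interpolation (probabilities are
continuous) and the background prior is completed as 1 − (GM+WM+CSF).

**Background model.** The non-brain class is intensity-heterogeneous: air
is near zero, cortical bone is dark (CSF-like), subcutaneous fat is
bright. It is modelled with three Gaussians whose mixing is *gated by
proximity to the tissue-prior support*: an air component active away from
the head, and dark/bright shell components active near it (gate: a 16-mm
blurred indicator of the prior support). With purely global weights the
air volume — roughly 70% of the field of view — drives the shell
components' weights toward zero, leaving the background class unable to
compete for any voxel of non-air intensity; the skull would then be
swallowed by the CSF class and the ICV boundary would sit at the outer
skull surface. The gate is a fixed, deterministic function of the priors,
so the EM remains a valid fixed-point iteration with a monotone
likelihood.

**Initialization** is deterministic: class moments come from voxels where
the class's prior is dominant (≥ 0.8, falling back to all prior-weighted
voxels), components start at quantiles of that distribution spread over
[0.02, 0.98], and initial variances are the class variance divided by K².
The wide quantile spread matters: the brightest CSF mode (ventricular CSF
on a strongly brightened image) can hold only a few percent of the
class's mass, and a narrower spread starts every component on the
dominant dark mode. The air component is initialized from the weighted
median/MAD of the far-field sample (the soft gate leaks a few bright
scalp voxels into it, which would wreck moment estimates), and the two
shell components by a weighted two-means split of the non-air shell
sample. A component whose variance collapses below 1e-12 of the data
variance is restarted at its class mean with the class variance and the
event logged; on noiseless inputs this fires by design and the posteriors
are then decided by the priors.

## Bias field estimation

The corrector stands in for the family of histogram/cluster-based
intensity-non-uniformity tools. It iterates: classify head voxels into
k = 8 intensity clusters of the current corrected image (deterministic,
quantile-seeded 1-D k-means; ties break toward the lower cluster); form
each voxel's log-residual from its cluster mean; least-squares fit a 3-D
polynomial (default total degree 3, ≈ 20 monomials on unit-scaled world
coordinates) to `log-field + residual`; gain-normalize (zero mean
log-field over the mask); stop when the max log-field change is below
1e-4 or after 20 iterations. Estimation runs on the full head mask
(intensity threshold at 10% of the robust maximum, largest connected
component) without skull-stripping, since removing peripheral structures
first would bias exactly the tissue a cranial-volume pipeline cares
about.

The cluster count is a genuine numerical choice: this phantom has five
distinct in-head intensity levels arranged in concentric shells, and with
k ≤ 5 each shell's cluster mean absorbs its local bias, leaving a
degenerate fit that can stall on a spurious (even anti-correlated) field.
k = 8 resolves the degeneracy and recovers the configured 30% Gaussian
brightening to within ~3% everywhere in the head mask. Order 0
degenerates, correctly, to a constant unit field.

The corrector removes *smooth* modulation. The ventricular-vs-cisternal
CSF offset is a compartment (tissue-assignment) effect, not a smooth one:
a low-order polynomial over the whole head cannot dim two localized
ventricular bodies without dragging everything at the same radius with
them. On 3T-mode phantoms the sampled offset drops from the configured
32% to roughly 21–22% after correction — reduced, never eliminated.

## The head phantom

Nested ellipsoids on a 96³ grid of 2-mm isotropic voxels (world
coordinates centred on the head): scalp (semi-axes 72/84/75 mm), skull
(67/79/70), inner skull table = ICV boundary (62/74/65, ≈ 1240 cm³), a
1-mm dura shell, cisternal (subarachnoid) CSF, a cortical GM shell
(57/69/60), a WM core (48/60/51) and two ventricular ellipsoids
(16/32/18 mm semi-axes, ≈ 78 cm³ total — an enlarged, elderly/atrophic
configuration chosen so the ventricular intensity mode carries
non-negligible mass). Class means (arbitrary units) follow T1 ordering:
air 4, CSF 50, skull 58, dura 58, GM 110, WM 160, scalp fat 180; dura and
inner-table bone sit in the CSF-like dark band, which is the anatomical
ambiguity behind peripheral segmentation errors. Additive Gaussian noise
(SD 4 ≈ WM SNR 40) stands in for thermal noise; Rician statistics are
out of scope because every analysis here concerns means and thresholds
far above the noise floor.

**Field-strength artifacts.** Two per mode:

* *Central brightening*: a multiplicative Gaussian bump
  `1 + A·exp(−4 ln2 ‖x−c‖²/FWHM²)` with FWHM 140 mm; A = 0.05 in "1.5T"
  mode, 0.30 in "3T" mode.
* *Ventricular/cisternal offset*: after the bump is applied, ventricular
  CSF is rescaled so that the symmetric two-mean percent difference
  `100·(V−C)/((V+C)/2)` of the noiseless image equals the configured
  value — 16% at 1.5T, 32% at 3T. Defining the offset as the *net
  measured* contrast (rather than a pre-bias tissue ratio) matches how
  such offsets are reported from raw images; the measured quantity then
  equals the configured one by construction, and what remains
  interesting is how much of it survives bias correction.

**Template and priors.** The same geometry, rendered artifact-free on the
standard grid, yields the template. Priors are Gaussian-blurred (FWHM
2 mm) indicators of GM, WM and CSF, where the CSF indicator covers
everything intracranial that is not GM/WM — ventricles, cisterns and the
dura shell, which population CSF maps never separate from subarachnoid
fluid — extended outward by `z₀.₉·σ_blur − 0.3 mm` beyond the inner
table and truncated at the outer skull surface. The extension calibrates
the 90% isocontour of the summed prior to track the inner table with a
small conservative margin, emulating how population maps (averaged over
anatomical variability) spread slightly past the subarachnoid space; the
0.3-mm margin leaves RBM marginally conservative, in line with its
slight reported underestimation on real data. The standard brain mask is
the blurred whole-brain indicator (without dura) thresholded at 0.5.

Each subject is a random affine away from the standard space (per-axis
scales 0.95–1.05, rotations ±8°, translations ±5 mm); truth labels are
evaluated analytically at native voxel centres, so the ground truth has
no resampling error. Identical spec and seed give bit-identical output.

**What the phantom does not have:** cortical folding, partial-volume
mixtures, Rician noise, multi-coil spatial sensitivity structure, or a
nonlinear subject-template deformation. Consequently the synthetic
results demonstrate the *mechanisms* — intensity-independence of RBM,
threshold sensitivity of tissue-class ICV to compartment offsets,
non-removability of those offsets by smooth correction — at realistic
magnitudes, but the absolute error percentages are not predictions for
real cohorts, where partial volume and registration error dominate.

## CSF compartment analysis

The brain-CSF mask is the ICV mask minus the GM+WM probability map
thresholded at 90%. The ventricular/cisternal split erodes the warped
standard-space brain mask by a 6-mm ball to form a conservative core,
keeps CSF voxels inside the core whose native CSF prior is ≥ 0.5, and
accepts connected components whose centroid lies inside a once-more
eroded core; everything else in the CSF mask is cisternal. The two
compartments tile the CSF mask exactly. The erosion/connected-component/
prior-floor scheme is this package's concrete realization of a
"morphological separation guided by a template brain mask and the CSF
prior"; all three parameters are exposed and logged.

Intensity sampling follows the reference protocol: 10 trials of 270
voxels drawn uniformly without replacement, each trial from an
independent child stream of the seed. Normality of (optionally
log-transformed) samples is assessed with a Kolmogorov–Smirnov test
against a Gaussian with plug-in sample mean/SD — the Lilliefors variant,
implemented via `statsmodels`, since the reference parameters are
estimated from the same sample.

The 270-voxel figure is documented as deriving from 90% confidence and a
10% tolerance on the CSF intensity SD. A chi-square interval search
(`sample_size_for_sd`) reproduces n ≈ 136 *per compartment* for those
settings (normal approximation `0.5·(z₀.₉₅/0.10)² ≈ 135`); 270 is
consistent with two compartments of ~135. The sampler defaults to the
literal 270 per compartment.

## Agreement metrics

Signed relative difference `%DIFF = 100·(V₂−V₁)/((V₁+V₂)/2)` with the
reference (manual/truth) as V₂, so positive values mean the automated
method underestimates; `%ADIFF` is its magnitude; Dice is
`2·N(A∩B)/(N(A)+N(B))` on voxel counts. The ICC is the two-way
random-effects, single-measure, *absolute-agreement* coefficient
(ICC(2,1)) computed from the explicit two-way mean squares — the standard
choice for method-vs-reference agreement because it penalizes systematic
offsets; the consistency form ICC(3,1) is available as an option.
Slice-wise positive/negative error profiles count false-positive /
false-negative in-plane areas per slice. The sparse-slice (Cavalieri)
estimator sums every k-th slice and multiplies by k, mirroring manual
tracing protocols; on the ellipsoidal ICV mask its error is ≈ 1% at
k = 10 across all phases.

## Reproduction scale and determinism

All validation runs at the default 96³/2-mm scale (EM ≈ 8 s, bias fit
≈ 3 s per subject on one core); the EM sanity battery and several unit
tests use geometrically halved phantoms (48³). `scripts/acceptance.py`
regenerates five subjects per field mode from a master seed and
recomputes every headline quantity from scratch; with a fixed seed all
outputs are bit-stable. The behaviours reproduced under the default
conditions: RBM |%DIFF| ≲ 0.3% with Dice ≈ 0.99 at both field
strengths and cross-field ICC ≈ 1; tissue-class ICV overestimates
slightly at 1.5T (the dark skull band is intensity-consistent with CSF)
and underestimates at 3T (the dura/bone band falls into the gap that the
ventricular offset opens between the two CSF Gaussians); the sampled CSF
offset reproduces the configured 16%/32% and survives bias correction at
~21%.
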