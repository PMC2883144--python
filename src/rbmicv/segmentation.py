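"""Atlas-prior Gaussian-mixture EM tissue classification.

Produces GM/WM/CSF posterior probability maps in subject native space from
an intensity image and warped standard-space tissue priors, in the spirit
of probabilistic-atlas tissue segmentation: the priors enter as spatially
varying mixing proportions of a per-class Gaussian mixture,

    p(x_v) = Σ_c  π_c(v) Σ_k  w_ck N(x_v ; μ_ck, σ²_ck),

and EM alternates component responsibilities (E) with closed-form updates
of means, variances and within-class weights (M).  The class posterior of
a voxel is the sum of its components' responsibilities.

Class structure
---------------
Three brain classes (GM, WM, CSF) carry the warped priors; everything else
is absorbed by a single background class with prior 1 − (GM+WM+CSF).  The
background is intensity-heterogeneous — air outside the head is near zero
while the skull/scalp shell contains both dark cortical bone and bright
subcutaneous fat — so it is modelled with three components whose mixing is
gated by proximity to the tissue-prior support: an air component active
away from the head and two shell components (dark, bright) active near it.
Without this gating the huge air volume swamps the shell components'
global weights and the background class cannot compete for any voxel of
non-air intensity, which distorts the ICV boundary behaviour the toolkit
exists to study.

The number of CSF Gaussians is the parameter that distinguishes the two
tissue-class variants compared here (2 components as the default, 4 as the
"better 3T CSF model" variant).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.special import logsumexp

from .core_image import (
    AffineTransform,
    Volume3D,
    check_same_grid,
    gaussian_blur_mm,
    resample,
)

logger = logging.getLogger(__name__)

TISSUE_CLASSES = ("gm", "wm", "csf")
BACKGROUND_CLASS = "background"

_LOG_2PI = np.log(2.0 * np.pi)


class PriorInconsistencyError(ValueError):
    """Warped priors sum to more than 1 beyond tolerance somewhere."""


def warp_priors(
    priors: dict[str, Volume3D],
    t_std_to_native: AffineTransform,
    target: Volume3D,
) -> dict[str, Volume3D]:
    """Warp standard-space tissue priors onto a native grid.

    Probabilities are continuous, so linear interpolation is used; values
    are clipped to [0, 1] and the background prior is completed as
    1 − (GM+WM+CSF).  A genuinely negative background (sum > 1 beyond 1e-6)
    raises :class:`PriorInconsistencyError`.
    """
    native: dict[str, Volume3D] = {}
    for name in TISSUE_CLASSES:
        warped = resample(priors[name], t_std_to_native, target, mode="linear")
        np.clip(warped.voxels, 0.0, 1.0, out=warped.voxels)
        native[name] = warped
    total = sum(native[c].voxels for c in TISSUE_CLASSES)
    overshoot = total.max() - 1.0
    if overshoot > 1e-6:
        raise PriorInconsistencyError(
            f"warped tissue priors sum to 1 + {overshoot:.3g} > 1")
    bg = np.clip(1.0 - total, 0.0, 1.0)
    native[BACKGROUND_CLASS] = target.like(bg)
    return native


@dataclass
class TissueModel:
    """Fitted per-class Gaussian mixture parameters."""

    means: dict[str, np.ndarray]       # class -> (K_c,)
    variances: dict[str, np.ndarray]   # class -> (K_c,)
    weights: dict[str, np.ndarray]     # class -> (K_c,), sums to 1
    priors_native: dict[str, Volume3D]
    log_likelihood_trace: list[float] = field(default_factory=list)
    converged: bool = False
    n_collapse_restarts: int = 0


@dataclass
class PosteriorMaps:
    """Per-class posterior probability volumes on the subject grid."""

    maps: dict[str, Volume3D]

    def __getitem__(self, key: str) -> Volume3D:
        return self.maps[key]

    def tissue_sum(self) -> Volume3D:
        """GM + WM + CSF posterior, the quantity thresholded for ICV."""
        ref = self.maps["gm"]
        return ref.like(sum(self.maps[c].voxels for c in TISSUE_CLASSES))


def _spread_quantiles(k: int) -> np.ndarray:
    """K quantile positions spread over [0.02, 0.98].

    The wide spread matters: the brightest CSF mode (ventricular CSF on a
    strongly brightened image) can hold only a few percent of the class's
    prior-weighted mass, and a narrower spread would start every component
    on the dominant dark mode.
    """
    if k == 1:
        return np.array([0.5])
    return np.linspace(0.02, 0.98, k)


def _weighted_two_means(x: np.ndarray, w: np.ndarray,
                        n_sweeps: int = 20) -> np.ndarray:
    """Two weighted cluster means of a 1-D sample (deterministic)."""
    centres = _weighted_quantile(x, w, np.array([0.1, 0.9]))
    for _ in range(n_sweeps):
        mid = centres.mean()
        lo = x <= mid
        new = centres.copy()
        for j, sel in enumerate((lo, ~lo)):
            if w[sel].sum() > 0:
                new[j] = np.average(x[sel], weights=w[sel])
        if np.allclose(new, centres, atol=1e-9):
            break
        centres = new
    return centres


def _weighted_quantile(x: np.ndarray, w: np.ndarray, qs: np.ndarray) -> np.ndarray:
    order = np.argsort(x)
    cw = np.cumsum(w[order])
    if cw[-1] <= 0:
        return np.full(len(qs), x.mean() if len(x) else 0.0)
    cw = cw / cw[-1]
    return np.interp(qs, cw, x[order])


def fit_tissue_model(
    vol: Volume3D,
    native_priors: dict[str, Volume3D],
    K: dict[str, int] | None = None,
    tol: float = 1e-5,
    max_iter: int = 60,
    seed: int = 0,
    init_jitter: float = 0.0,
) -> tuple[TissueModel, PosteriorMaps]:
    """Fit the spatially-weighted Gaussian mixture by EM.

    Parameters
    ----------
    vol:
        Intensity image on the native grid.
    native_priors:
        Output of :func:`warp_priors` (gm/wm/csf plus completed background).
    K:
        Gaussians per brain class, e.g. ``{"gm": 2, "wm": 2, "csf": 2}``
        (the default) or ``csf=4`` for the richer CSF model.  The
        background always uses 3 gated components (air, dark shell,
        bright shell).
    tol:
        Relative log-likelihood change at which to declare convergence.
    seed, init_jitter:
        Optional deterministic jitter of the initial component means
        (fraction of the class SD); zero by default, so initialization is
        fully deterministic from the priors.

    Returns the fitted :class:`TissueModel` (with the observed-data
    log-likelihood trace, non-decreasing up to float tolerance) and the
    class :class:`PosteriorMaps`, which sum to 1 voxelwise.  A component
    whose variance collapses is restarted at its class mean with the class
    variance; failure to converge within ``max_iter`` returns
    ``converged=False`` rather than raising.
    """
    K = dict(K or {})
    for c in TISSUE_CLASSES:
        K.setdefault(c, 2)
        if K[c] < 1:
            raise ValueError(f"K[{c!r}] must be >= 1")

    check_same_grid(vol, *[native_priors[c] for c in TISSUE_CLASSES],
                    native_priors[BACKGROUND_CLASS], what="image and priors")
    shape = vol.shape
    x = np.asarray(vol.voxels, dtype=float).ravel()
    n = x.size
    data_var = max(x.var(), 1e-12)
    var_floor = 1e-12 * data_var
    rng = np.random.default_rng(seed)

    pri = {c: np.asarray(native_priors[c].voxels, dtype=float).ravel()
           for c in (*TISSUE_CLASSES, BACKGROUND_CLASS)}

    # Proximity gate for the background components: near the tissue-prior
    # support the shell components act, far from it only air does.
    support = (1.0 - pri[BACKGROUND_CLASS]).reshape(shape) > 0.02
    gate_vol = gaussian_blur_mm(vol.like(support.astype(float)), 16.0)
    g = np.clip(gate_vol.voxels.ravel(), 0.0, 1.0)

    classes = list(TISSUE_CLASSES) + [BACKGROUND_CLASS]
    means: dict[str, np.ndarray] = {}
    variances: dict[str, np.ndarray] = {}
    weights: dict[str, np.ndarray] = {}

    for c in TISSUE_CLASSES:
        w = pri[c]
        if w.sum() <= 0:
            raise ValueError(f"prior for class {c!r} is empty")
        # initialize from voxels where the class prior dominates, so that
        # boundary partial-prior bleed (e.g. the GM rim or the skull margin
        # inside the CSF prior's support) cannot hijack a component
        w_dom = w * (w >= 0.8)
        if w_dom.sum() > 0:
            w = w_dom
        mu_c = float(np.average(x, weights=w))
        var_c = float(np.average((x - mu_c) ** 2, weights=w)) + var_floor
        qs = _weighted_quantile(x, w, _spread_quantiles(K[c]))
        if init_jitter > 0:
            qs = qs + rng.normal(0.0, init_jitter * np.sqrt(var_c), size=K[c])
        means[c] = qs
        variances[c] = np.full(K[c], max(var_c / K[c] ** 2, 1e-6 * data_var))
        weights[c] = np.full(K[c], 1.0 / K[c])

    # background: air from the far-field, two shell components near the head
    w_air = pri[BACKGROUND_CLASS] * (1.0 - g)
    w_shell = pri[BACKGROUND_CLASS] * g
    # robust air statistics (weighted median / MAD): the proximity gate is
    # soft, so bright scalp voxels leak small weights into the air sample
    # and would wreck moment-based estimates
    if w_air.sum() > 0:
        mu_air = float(_weighted_quantile(x, w_air, np.array([0.5]))[0])
        mad = float(_weighted_quantile(np.abs(x - mu_air), w_air,
                                       np.array([0.5]))[0])
        var_air = max((1.4826 * mad) ** 2, 1e-6 * data_var)
    else:
        mu_air, var_air = float(x.min()), data_var
    # initialize the two shell components on non-air intensities only (so
    # the near-head air ring cannot pull them onto the air mode), splitting
    # dark (bone) from bright (fat/scalp) with a weighted two-means pass
    non_air = x > mu_air + 4.0 * np.sqrt(var_air)
    w_shell_init = w_shell * non_air
    if w_shell_init.sum() > 0:
        q_shell = _weighted_two_means(x, w_shell_init)
        var_shell = float(np.average(
            (x - np.average(x, weights=w_shell_init)) ** 2,
            weights=w_shell_init))
    else:
        q_shell = np.array([mu_air, mu_air])
        var_shell = data_var
    means[BACKGROUND_CLASS] = np.array([mu_air, q_shell[0], q_shell[1]])
    variances[BACKGROUND_CLASS] = np.array(
        [var_air, max(var_shell / 4, 1e-6 * data_var)] * 1 +
        [max(var_shell / 4, 1e-6 * data_var)])
    weights[BACKGROUND_CLASS] = np.array([1.0, 0.5, 0.5])  # shell part only

    comp_class: list[str] = []
    for c in classes:
        comp_class += [c] * len(means[c])
    n_comp = len(comp_class)

    def component_log_weights() -> np.ndarray:
        """log(π_c(v) · w_ck(v)) for every component, shape (n_comp, n)."""
        lw = np.empty((n_comp, n))
        j = 0
        with np.errstate(divide="ignore"):
            for c in TISSUE_CLASSES:
                lp = np.log(pri[c])
                for k in range(len(means[c])):
                    lw[j] = lp + np.log(weights[c][k])
                    j += 1
            lp_bg = np.log(pri[BACKGROUND_CLASS])
            wsh = weights[BACKGROUND_CLASS][1:]
            wsh = wsh / max(wsh.sum(), 1e-300)
            lw[j] = lp_bg + np.log(1.0 - g + 1e-300)          # air (gated)
            lw[j + 1] = lp_bg + np.log(g * wsh[0] + 1e-300)   # dark shell
            lw[j + 2] = lp_bg + np.log(g * wsh[1] + 1e-300)   # bright shell
        return lw

    def gaussian_log_density() -> np.ndarray:
        out = np.empty((n_comp, n))
        j = 0
        for c in classes:
            for k in range(len(means[c])):
                v = max(variances[c][k], var_floor)
                out[j] = -0.5 * ((x - means[c][k]) ** 2 / v +
                                 np.log(v) + _LOG_2PI)
                j += 1
        return out

    trace: list[float] = []
    converged = False
    n_restarts = 0
    for _ in range(max_iter):
        log_joint = component_log_weights() + gaussian_log_density()
        log_px = logsumexp(log_joint, axis=0)
        ll = float(log_px.sum())
        trace.append(ll)

        resp = np.exp(log_joint - log_px)  # (n_comp, n)

        j = 0
        for c in classes:
            kc = len(means[c])
            r = resp[j:j + kc]
            mass = r.sum(axis=1)
            for k in range(kc):
                if mass[k] < 1e-12:
                    continue
                mu = float(r[k] @ x / mass[k])
                var = float(r[k] @ (x - mu) ** 2 / mass[k])
                if var < var_floor:
                    # collapsed component: restart at the class mean
                    w_cls = pri[c]
                    mu = float(np.average(x, weights=w_cls))
                    var = float(np.average((x - mu) ** 2, weights=w_cls))
                    var = max(var, 1e-6 * data_var)
                    n_restarts += 1
                    logger.warning("restarted collapsed component %s[%d]",
                                   c, k)
                means[c][k] = mu
                variances[c][k] = var
            if c == BACKGROUND_CLASS:
                shell_mass = mass[1:]
                tot = shell_mass.sum()
                if tot > 0:
                    weights[c][1:] = shell_mass / tot
            else:
                tot = mass.sum()
                if tot > 0:
                    weights[c] = mass / tot
            j += kc

        if len(trace) >= 2:
            prev = trace[-2]
            if abs(ll - prev) <= tol * (abs(prev) + 1e-12):
                converged = True
                break

    # final E-step posteriors with the last parameter set
    log_joint = component_log_weights() + gaussian_log_density()
    log_px = logsumexp(log_joint, axis=0)
    resp = np.exp(log_joint - log_px)
    post: dict[str, Volume3D] = {}
    j = 0
    for c in classes:
        kc = len(means[c])
        post[c] = vol.like(resp[j:j + kc].sum(axis=0).reshape(shape))
        j += kc

    model = TissueModel(means=means, variances=variances, weights=weights,
                        priors_native=native_priors,
                        log_likelihood_trace=trace, converged=converged,
                        n_collapse_restarts=n_restarts)
    return model, PosteriorMaps(maps=post)
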