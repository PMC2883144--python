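"""Polynomial log-domain bias-field estimation and correction.

MR images carry a smooth multiplicative intensity modulation (coil and
field inhomogeneity).  This module estimates such a field with a generic
iterative scheme: classify head voxels into a few intensity clusters,
take each voxel's log-residual from its cluster mean, fit a low-order 3-D
polynomial in world coordinates to those residuals by least squares,
exponentiate and gain-normalize, repeat until the log-field stabilizes.
The corrector removes smooth modulation well, but — deliberately — it
cannot remove a compartment-specific intensity offset such as the
ventricular-vs-cisternal CSF difference, because that offset is a matter
of tissue assignment, not of smoothness.

The estimation runs directly on the whole head mask without prior brain
extraction, since removing skull or meninges first would bias exactly the
peripheral structures an intracranial-volume pipeline cares about.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core_image import Volume3D, check_same_grid, world_coordinates


class BiasDataError(ValueError):
    """Invalid data for bias estimation (empty mask, non-positive values)."""


@dataclass
class BiasField:
    """A fitted multiplicative bias field.

    The field is strictly positive and gain-normalized: its mean over the
    estimation mask is 1 (within 1e-6), so correction preserves the
    overall intensity scale.
    """

    field: Volume3D
    basis_order: int
    iterations_run: int
    converged: bool


def _polynomial_basis(points: np.ndarray, order: int) -> np.ndarray:
    """Monomials x^a y^b z^c with a+b+c <= order, on unit-scaled coords."""
    cols = []
    px, py, pz = points[:, 0], points[:, 1], points[:, 2]
    for a in range(order + 1):
        for b in range(order + 1 - a):
            for c in range(order + 1 - a - b):
                cols.append(px ** a * py ** b * pz ** c)
    return np.column_stack(cols)


def _cluster_means(values: np.ndarray, k: int,
                   n_sweeps: int = 10) -> np.ndarray:
    """Deterministic k-cluster means of a 1-D sample (quantile-seeded).

    Ties in assignment are broken toward the lower-mean cluster (the
    cluster centres are kept sorted, and ``searchsorted`` on midpoints
    assigns boundary values to the left interval).
    """
    centres = np.quantile(values, (np.arange(k) + 0.5) / k)
    centres = np.sort(centres)
    for _ in range(n_sweeps):
        mids = (centres[1:] + centres[:-1]) / 2.0
        assign = np.searchsorted(mids, values, side="right")
        new = centres.copy()
        for j in range(k):
            sel = assign == j
            if sel.any():
                new[j] = values[sel].mean()
        new = np.sort(new)
        if np.allclose(new, centres, rtol=0, atol=1e-10):
            centres = new
            break
        centres = new
    return centres


def estimate_bias(
    vol: Volume3D,
    mask: Volume3D,
    order: int = 3,
    max_iter: int = 20,
    tol: float = 1e-4,
    n_clusters: int = 8,
) -> BiasField:
    """Estimate a smooth multiplicative bias field within a mask.

    Parameters follow the scheme described in the module docstring;
    ``order`` is the total degree of the 3-D polynomial fitted to the
    log-residuals (order 0 degenerates to a gain-normalized constant
    field of 1).  Intensities inside the mask must be strictly positive.
    """
    check_same_grid(vol, mask, what="image and mask")
    m = np.asarray(mask.voxels) > 0.5
    if not m.any():
        raise BiasDataError("empty estimation mask")
    x = np.asarray(vol.voxels, dtype=float)[m]
    n_bad = int((x <= 0).sum())
    if n_bad:
        raise BiasDataError(
            f"{n_bad} non-positive intensities inside the mask")

    pts = world_coordinates(vol)[m]
    scale = np.abs(pts).max(axis=0)
    scale[scale == 0] = 1.0
    basis = _polynomial_basis(pts / scale, order)

    log_x = np.log(x)
    log_field = np.zeros_like(log_x)
    converged = False
    iters = 0
    for iters in range(1, max_iter + 1):
        corrected = log_x - log_field
        centres = _cluster_means(corrected, n_clusters)
        mids = (centres[1:] + centres[:-1]) / 2.0
        assign = np.searchsorted(mids, corrected, side="right")
        residual = corrected - centres[assign]
        target = log_field + residual
        coef, *_ = np.linalg.lstsq(basis, target, rcond=None)
        new_log_field = basis @ coef
        new_log_field -= new_log_field.mean()  # gain normalization
        delta = np.abs(new_log_field - log_field).max()
        log_field = new_log_field
        if delta < tol:
            converged = True
            break

    # evaluate the fitted polynomial over the full grid
    all_pts = world_coordinates(vol).reshape(-1, 3) / scale
    full_log = _polynomial_basis(all_pts, order) @ coef
    full_log -= full_log.reshape(vol.shape)[m].mean()
    field = vol.like(np.exp(full_log.reshape(vol.shape)))
    return BiasField(field=field, basis_order=order, iterations_run=iters,
                     converged=converged)


def apply_correction(vol: Volume3D, bias: BiasField | Volume3D) -> Volume3D:
    """Divide an image by a bias field; zero voxels stay zero."""
    field = bias.field if isinstance(bias, BiasField) else bias
    check_same_grid(vol, field, what="image and bias field")
    f = np.asarray(field.voxels, dtype=float)
    v = np.asarray(vol.voxels, dtype=float)
    bad = (f <= 0) & (v != 0)
    if bad.any():
        raise BiasDataError(
            f"non-positive field under {int(bad.sum())} nonzero voxels")
    out = np.zeros_like(v)
    ok = f > 0
    out[ok] = v[ok] / f[ok]
    return vol.like(out)


def head_mask(vol: Volume3D, fraction: float = 0.1) -> Volume3D:
    """Head support: intensity threshold plus largest-component cleanup.

    Voxels above ``fraction`` of the robust (99.5th percentile) maximum are
    kept and reduced to the largest connected component, so isolated noise
    voxels in the background cannot leak into the estimation domain, where
    they would both corrupt the polynomial fit and receive wild
    extrapolated field values.
    """
    from scipy import ndimage

    v = np.asarray(vol.voxels, dtype=float)
    thresh = fraction * np.percentile(v, 99.5)
    m = v > thresh
    labels, n = ndimage.label(m)
    if n > 1:
        sizes = ndimage.sum_labels(m, labels, range(1, n + 1))
        m = labels == (1 + int(np.argmax(sizes)))
    return vol.like(m.astype(np.uint8))
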