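"""Volumetric agreement and error metrics.

Implements the standard test/retest comparison quantities for ICV
estimates: the signed relative volume difference

    %DIFF = 100 · (V2 − V1) / ((V1 + V2) / 2),

its magnitude %ADIFF (robustness without direction), the Dice overlap
2·N(A∩B)/(N(A)+N(B)), an intraclass correlation coefficient for
method-vs-reference agreement, slice-wise false-positive/negative error
profiles, and the sparse every-k-th-slice (Cavalieri-style) volume
estimator that mirrors manual tracing protocols.

Sign convention for method-vs-manual comparisons: V2 is the manual
(reference) volume and V1 the automated one, so positive differences mean
the manual estimate was larger.
"""

from __future__ import annotations

import numpy as np

from .core_image import Volume3D, check_same_grid, voxel_volume

_AXES = {"x": 0, "y": 1, "z": 2}


class UndefinedMetricError(ValueError):
    """Metric undefined for this input (e.g. Dice of two empty masks)."""


def rel_diff_pct(v1: float, v2: float) -> float:
    """Signed percent difference of v2 vs v1, relative to their mean."""
    mean = (v1 + v2) / 2.0
    if mean <= 0:
        raise ValueError("mean volume must be positive")
    return 100.0 * (v2 - v1) / mean


def abs_rel_diff_pct(v1: float, v2: float) -> float:
    """Magnitude of the relative percent difference."""
    return abs(rel_diff_pct(v1, v2))


def _as_bool(vol: Volume3D) -> np.ndarray:
    return np.asarray(vol.voxels) > 0.5


def dice(a: Volume3D, b: Volume3D) -> float:
    """Dice coefficient 2·N(A∩B) / (N(A)+N(B)) of two binary masks."""
    check_same_grid(a, b, what="masks")
    am, bm = _as_bool(a), _as_bool(b)
    na, nb = int(am.sum()), int(bm.sum())
    if na + nb == 0:
        raise UndefinedMetricError("Dice undefined for two empty masks")
    return 2.0 * int((am & bm).sum()) / (na + nb)


def icc_agreement(measurements, form: str = "absolute") -> float:
    """Intraclass correlation of an (subjects × raters/conditions) table.

    The default is the two-way random-effects, single-measure,
    absolute-agreement coefficient (commonly written ICC(2,1)),

        ICC = (MS_R − MS_E) / (MS_R + (k−1)·MS_E + k·(MS_C − MS_E)/n),

    computed from the mean squares of the two-way decomposition (rows =
    subjects, columns = raters).  ``form="consistency"`` gives the
    two-way mixed consistency coefficient ICC(3,1) instead.
    """
    x = np.asarray(measurements, dtype=float)
    if x.ndim != 2 or x.shape[0] < 2 or x.shape[1] < 2:
        raise ValueError("need a table of >= 2 subjects and >= 2 columns")
    if np.isnan(x).any():
        raise ValueError("missing cells are not supported")
    n, k = x.shape
    grand = x.mean()
    row_means = x.mean(axis=1)
    col_means = x.mean(axis=0)
    ss_rows = k * ((row_means - grand) ** 2).sum()
    ss_cols = n * ((col_means - grand) ** 2).sum()
    ss_total = ((x - grand) ** 2).sum()
    ss_err = ss_total - ss_rows - ss_cols
    ms_r = ss_rows / (n - 1)
    ms_c = ss_cols / (k - 1)
    ms_e = ss_err / ((n - 1) * (k - 1))
    if ms_r <= 0:
        import warnings

        warnings.warn("zero between-subject variance; ICC set to 0",
                      stacklevel=2)
        return 0.0
    if form == "absolute":
        denom = ms_r + (k - 1) * ms_e + k * (ms_c - ms_e) / n
    elif form == "consistency":
        denom = ms_r + (k - 1) * ms_e
    else:
        raise ValueError(f"unknown ICC form {form!r}")
    if denom <= 0:
        return 0.0
    if form == "absolute":
        return float((ms_r - ms_e) / denom)
    return float((ms_r - ms_e) / denom)


def _slice_indices(n: int, indices, step: int | None, start: int):
    if indices is not None:
        idx = list(indices)
        if any(i < 0 or i >= n for i in idx):
            raise ValueError("slice index out of range")
        return idx
    step = step or 1
    return list(range(start, n, step))


def slice_error_profile(
    auto: Volume3D,
    ref: Volume3D,
    axis: str = "z",
    indices=None,
    step: int | None = None,
    start: int = 0,
) -> list[tuple[int, float, float]]:
    """Per-slice false-positive and false-negative areas in mm².

    For each selected slice orthogonal to ``axis``: the positive error is
    the area labelled intracranial by ``auto`` but not by ``ref``; the
    negative error the converse.  In-plane voxel area is the voxel volume
    divided by the slice spacing along the chosen axis.
    """
    if axis not in _AXES:
        raise ValueError(f"axis must be one of {sorted(_AXES)}")
    check_same_grid(auto, ref, what="masks")
    ax = _AXES[axis]
    spacing = float(np.linalg.norm(auto.affine[:3, ax]))
    area = voxel_volume(auto) / spacing
    am, rm = _as_bool(auto), _as_bool(ref)
    out = []
    for i in _slice_indices(auto.shape[ax], indices, step, start):
        a = np.take(am, i, axis=ax)
        r = np.take(rm, i, axis=ax)
        pos = float((a & ~r).sum()) * area
        neg = float((r & ~a).sum()) * area
        out.append((i, pos, neg))
    return out


def sparse_slice_icv(mask: Volume3D, axis: str = "z", step: int = 10,
                     start: int = 0) -> float:
    """Every-k-th-slice volume estimate in mm³.

    Mirrors the manual tracing protocol in which every tenth slice is
    delineated and the summed slice volumes are multiplied by the step.
    """
    if axis not in _AXES:
        raise ValueError(f"axis must be one of {sorted(_AXES)}")
    if step < 1:
        raise ValueError("step must be >= 1")
    ax = _AXES[axis]
    if not (0 <= start < mask.shape[ax]):
        raise ValueError("start slice outside the volume")
    m = _as_bool(mask)
    sel = np.take(m, range(start, mask.shape[ax], step), axis=ax)
    return float(sel.sum()) * voxel_volume(mask) * step


def volume_agreement(auto: Volume3D, ref: Volume3D, axis: str = "z",
                     step: int = 1) -> dict:
    """Bundle of agreement metrics of an automated mask vs a reference.

    %DIFF follows the manual-comparison convention (V2 = reference,
    V1 = automated): positive values mean the reference was larger.
    """
    vv = voxel_volume(auto)
    v_auto = float(_as_bool(auto).sum()) * vv
    v_ref = float(_as_bool(ref).sum()) * vv
    profile = slice_error_profile(auto, ref, axis=axis, step=step)
    return {
        "diff_pct": rel_diff_pct(v_auto, v_ref),
        "adiff_pct": abs_rel_diff_pct(v_auto, v_ref),
        "dice": dice(auto, ref),
        "per_slice": profile,
    }
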