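"""Flow-contrast reconstruction from repeated complex A-lines (OMAG).

The differential algorithm contrasts moving scatterers against static tissue
by averaging magnitudes of complex differences between adjacent repeats:
static clutter (a constant phasor) cancels exactly, while a scatterer whose
phase rotates at Doppler frequency f contributes 2 A |sin(pi f dt)| per
differential pair.
"""
from __future__ import annotations

import warnings
from typing import Optional, Tuple

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage.filters import threshold_otsu
from skimage.measure import label as cc_label
from skimage.morphology import skeletonize

from .containers import AScanEnsemble, FlowVolume, QuantImage


def omag_flow(ensemble: AScanEnsemble) -> FlowVolume:
    """Inter-repeat differential flow contrast and structural magnitude.

    flow(z, x)      = mean_k | S(z, k+1, x) - S(z, k, x) |
    structure(z, x) = mean_k | S(z, k, x) |
    """
    s = ensemble.signal
    if s.shape[1] < 2:
        raise ValueError("insufficient repeats for differential OMAG")
    flow = np.mean(np.abs(np.diff(s, axis=1)), axis=1)
    structure = np.mean(np.abs(s), axis=1)
    return FlowVolume(flow=flow, structure=structure, pixel_um=ensemble.pixel_um)


def mip(volume: np.ndarray, axis: int = 0) -> np.ndarray:
    """Maximum intensity projection along ``axis``."""
    volume = np.asarray(volume)
    if not -volume.ndim <= axis < volume.ndim:
        raise ValueError(f"axis {axis} invalid for {volume.ndim}-D volume")
    return volume.max(axis=axis)


def binarize(
    image: np.ndarray,
    method: str = "otsu",
    threshold: Optional[float] = None,
    invert: bool = False,
) -> np.ndarray:
    """Threshold an image to a binary mask (fixed value or Otsu's method)."""
    image = np.asarray(image, dtype=float)
    if method == "fixed":
        if threshold is None:
            raise ValueError("fixed method requires a threshold")
        level = threshold
    elif method == "otsu":
        if np.ptp(image) == 0:
            warnings.warn("flat image: Otsu undefined, returning all-false mask",
                          stacklevel=2)
            return np.zeros(image.shape, dtype=bool)
        level = threshold_otsu(image)
    else:
        raise ValueError("method must be 'fixed' or 'otsu'")
    mask = image < level if invert else image > level
    return mask


def vessel_area_density(mask: np.ndarray, roi: Optional[np.ndarray] = None) -> float:
    """Vessel pixels as a percentage of the region of interest.

    ``roi`` is a boolean mask of the same shape (default: the whole field).
    """
    mask = np.asarray(mask, dtype=bool)
    if roi is None:
        roi = np.ones(mask.shape, dtype=bool)
    roi = np.asarray(roi, dtype=bool)
    if roi.shape != mask.shape:
        raise ValueError("roi shape must match mask")
    n_roi = int(roi.sum())
    if n_roi == 0:
        raise ValueError("empty roi")
    return 100.0 * float(mask[roi].sum()) / n_roi


def estimate_vessel_diameters(
    mask: np.ndarray, pixel_um: float | Tuple[float, ...]
) -> pd.DataFrame:
    """Per-vessel diameter from the distance transform on the medial axis.

    Each connected component (8-connectivity in 2-D, 26 in 3-D) is
    skeletonized; its diameter is twice the maximum Euclidean distance to
    background over the skeleton, in µm.  Returns columns: label,
    diameter_um, area_um2 (pixel/voxel footprint x pixel area).
    """
    mask = np.asarray(mask, dtype=bool)
    if np.isscalar(pixel_um):
        sampling = (float(pixel_um),) * mask.ndim
    else:
        sampling = tuple(float(p) for p in pixel_um)
    if mask.ndim not in (2, 3):
        raise ValueError("mask must be 2-D or 3-D")
    cols = ["label", "diameter_um", "area_um2"]
    if not mask.any():
        return pd.DataFrame(columns=cols)
    labels = cc_label(mask, connectivity=mask.ndim)
    dist = ndimage.distance_transform_edt(mask, sampling=sampling)
    skel = skeletonize(mask)
    px_area = float(np.prod(sampling[-2:]))
    rows = []
    for lab in range(1, labels.max() + 1):
        comp = labels == lab
        on_skel = comp & skel
        # tiny components may skeletonize away; fall back to the component
        ridge = dist[on_skel] if on_skel.any() else dist[comp]
        rows.append(
            dict(
                label=lab,
                diameter_um=2.0 * float(ridge.max()),
                area_um2=float(comp.sum()) * px_area,
            )
        )
    return pd.DataFrame(rows, columns=cols)


def vessel_mip_image(volume: FlowVolume, axis: int = 0) -> QuantImage:
    """En-face MIP of a flow volume as a calibrated image.

    A 2-D flow map (single B-frame) is already an image and is returned
    as-is; 3-D volumes are projected along ``axis``.
    """
    pixels = volume.flow if volume.flow.ndim == 2 else mip(volume.flow, axis=axis)
    return QuantImage(
        pixels=pixels,
        pixel_um=float(volume.pixel_um[-1]),
        channel="flow",
    )
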