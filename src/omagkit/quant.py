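"""Fluorescence-image quantification: thresholded particle analysis with a
small-object exclusion, distance-binned lumen statistics, coverage and
colocalization fractions, perfused-area measurement and bead-tracking
velocimetry."""
from __future__ import annotations

import logging
import warnings
from typing import Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage.measure import label as cc_label, regionprops

from .containers import ParticleSet, QuantImage
from .omag import binarize
from .phantoms import DEFAULT_DISTANCE_BINS

logger = logging.getLogger(__name__)


def wall_distance_map(wall_mask: np.ndarray, pixel_um: float) -> np.ndarray:
    """Distance (µm) of every pixel to the nearest vessel-wall pixel."""
    wall_mask = np.asarray(wall_mask, dtype=bool)
    if not wall_mask.any():
        raise ValueError("wall reference mask is empty")
    return ndimage.distance_transform_edt(~wall_mask, sampling=pixel_um)


def particle_analysis(
    mask: np.ndarray,
    pixel_um: float,
    min_area_um2: float = 20.0,
    wall_mask: Optional[np.ndarray] = None,
) -> ParticleSet:
    """Label connected components and drop particles below ``min_area_um2``.

    Components use 8-connectivity.  Particles smaller than the cutoff (by
    strict <, i.e. area >= cutoff survives) are excluded as background.  With
    a wall reference, each particle gets its centroid distance to the
    nearest wall pixel in µm.
    """
    mask = np.asarray(mask, dtype=bool)
    labels = cc_label(mask, connectivity=2)
    px_area = pixel_um**2
    dist_map = (
        wall_distance_map(wall_mask, pixel_um) if wall_mask is not None else None
    )
    rows = []
    keep = np.zeros(labels.max() + 1, dtype=bool)
    for rp in regionprops(labels):
        area = rp.area * px_area
        if area < min_area_um2:
            continue
        keep[rp.label] = True
        cy, cx = rp.centroid
        row = dict(
            label=rp.label,
            area_um2=area,
            equivalent_diameter_um=2.0 * np.sqrt(area / np.pi),
            centroid_x_um=cx * pixel_um,
            centroid_y_um=cy * pixel_um,
        )
        if dist_map is not None:
            row["distance_um"] = float(
                dist_map[int(round(cy)), int(round(cx))]
            )
        rows.append(row)
    cols = ["label", "area_um2", "equivalent_diameter_um", "centroid_x_um",
            "centroid_y_um"]
    if dist_map is not None:
        cols.append("distance_um")
    table = pd.DataFrame(rows, columns=cols)
    filtered = np.where(keep[labels], labels, 0)
    return ParticleSet(
        table=table, labels=filtered, pixel_um=pixel_um, min_area_um2=min_area_um2
    )


def distance_binned_stats(
    particles: ParticleSet,
    distance_map_um: np.ndarray,
    bins: Sequence[Tuple[float, float]] = DEFAULT_DISTANCE_BINS,
) -> pd.DataFrame:
    """Per-distance-bin particle count, density and mean area.

    Bins are half-open [lo, hi) on the centroid-to-wall distance; particles
    beyond the last bin land in a separate overflow row.  Density divides
    the count by the image area falling inside the bin band, in mm^2.
    """
    if "distance_um" not in particles.table.columns:
        raise ValueError("particles carry no wall-distance measurements")
    dist = particles.table["distance_um"].to_numpy()
    px_mm2 = (particles.pixel_um * 1e-3) ** 2
    rows = []
    assigned = np.zeros(len(dist), dtype=bool)
    for lo, hi in bins:
        in_bin = (dist >= lo) & (dist < hi)
        assigned |= in_bin
        band_area_mm2 = float(
            ((distance_map_um >= lo) & (distance_map_um < hi)).sum() * px_mm2
        )
        areas = particles.table.loc[in_bin, "area_um2"]
        rows.append(
            dict(
                bin_lo_um=lo,
                bin_hi_um=hi,
                count=int(in_bin.sum()),
                bin_area_mm2=band_area_mm2,
                density_per_mm2=(in_bin.sum() / band_area_mm2) if band_area_mm2 else np.nan,
                mean_area_um2=float(areas.mean()) if len(areas) else np.nan,
            )
        )
    overflow = ~assigned & (dist >= bins[-1][1])
    if np.any(~assigned):
        lo = bins[-1][1]
        band_area_mm2 = float((distance_map_um >= lo).sum() * px_mm2)
        areas = particles.table.loc[overflow, "area_um2"]
        rows.append(
            dict(
                bin_lo_um=lo,
                bin_hi_um=np.inf,
                count=int(overflow.sum()),
                bin_area_mm2=band_area_mm2,
                density_per_mm2=(overflow.sum() / band_area_mm2) if band_area_mm2 else np.nan,
                mean_area_um2=float(areas.mean()) if len(areas) else np.nan,
            )
        )
    return pd.DataFrame(rows)


def area_fraction(
    signal_mask: np.ndarray,
    reference_area_um2: Optional[float] = None,
    reference_mask: Optional[np.ndarray] = None,
    pixel_um: float = 1.0,
) -> float:
    """Signal area as a percentage of a reference area.

    Used e.g. for platelet (CD41a+) coverage normalized to the vessel-wall
    surface area.  With a reference mask the signal is clipped to it first
    and the reference area is the mask's own area.
    """
    signal_mask = np.asarray(signal_mask, dtype=bool)
    px_area = pixel_um**2
    if reference_mask is not None:
        reference_mask = np.asarray(reference_mask, dtype=bool)
        signal_mask = signal_mask & reference_mask
        reference_area_um2 = float(reference_mask.sum()) * px_area
    if not reference_area_um2 or reference_area_um2 <= 0:
        raise ValueError("reference area must be positive")
    return 100.0 * float(signal_mask.sum()) * px_area / reference_area_um2


def colocalization_fraction(
    marker_mask: np.ndarray,
    objects: ParticleSet,
    min_overlap_fraction: float = 0.0,
) -> float:
    """Percent of objects overlapping a marker mask.

    An object counts as positive when the overlapping fraction of its area
    exceeds ``min_overlap_fraction`` (default: any overlap).  Undefined
    (NaN, with a warning) for an empty object set.
    """
    if len(objects) == 0:
        warnings.warn("empty object set: colocalization undefined", stacklevel=2)
        return float("nan")
    marker_mask = np.asarray(marker_mask, dtype=bool)
    positive = 0
    for lab, area in zip(objects.table["label"], objects.table["area_um2"]):
        obj = objects.labels == lab
        overlap = float((obj & marker_mask).sum()) * objects.pixel_um**2
        if min_overlap_fraction == 0.0:
            positive += overlap > 0
        else:
            positive += (overlap / area) >= min_overlap_fraction
    return 100.0 * positive / len(objects)


def perfused_area(
    image: QuantImage,
    method: str = "otsu",
    threshold: Optional[float] = None,
    roi: Optional[np.ndarray] = None,
) -> Tuple[float, float]:
    """Total perfused-bead signal area and its percent of the field.

    ``roi`` restricts the field (e.g. twice the original pattern boundary);
    returns (area µm^2, percent of ROI area).
    """
    mask = binarize(image.pixels, method=method, threshold=threshold)
    if roi is not None:
        roi = np.asarray(roi, dtype=bool)
        mask = mask & roi
        field_px = int(roi.sum())
    else:
        field_px = mask.size
    px_area = image.pixel_um**2
    area = float(mask.sum()) * px_area
    return area, 100.0 * float(mask.sum()) / field_px


def _detect_centroids(frame: np.ndarray, pixel_um: float,
                      method: str, threshold: Optional[float]) -> np.ndarray:
    mask = binarize(frame, method=method, threshold=threshold)
    labels = cc_label(mask, connectivity=2)
    pts = [rp.centroid for rp in regionprops(labels)]
    if not pts:
        return np.empty((0, 2))
    return np.asarray(pts)[:, ::-1] * pixel_um  # (x, y) µm


def track_beads(
    frames: np.ndarray,
    frame_interval_s: float,
    pixel_um: float,
    max_displacement_um: Optional[float] = None,
    method: str = "fixed",
    threshold: Optional[float] = 0.5,
    tie_tolerance_um: float = 1e-9,
) -> pd.DataFrame:
    """Detect and link bead centroids across frames; report velocities.

    Linking is nearest-neighbor with an optional maximum-displacement gate.
    When two candidate detections are equidistant (within
    ``tie_tolerance_um``) the link is ambiguous and the track is terminated.
    Velocity is the mean inter-frame displacement divided by the frame
    interval, in µm/s.  Returns columns: bead, velocity_um_s, n_steps,
    x0_um, y0_um.
    """
    frames = np.asarray(frames)
    if frames.ndim != 3 or frames.shape[0] < 2:
        raise ValueError("need a stack of at least 2 frames")
    if frame_interval_s <= 0:
        raise ValueError("frame_interval_s must be positive")
    detections = [
        _detect_centroids(f, pixel_um, method, threshold) for f in frames
    ]
    tracks = [[tuple(p)] for p in detections[0]]
    active = list(range(len(tracks)))
    for t in range(1, len(frames)):
        pts = detections[t]
        claimed: dict[int, tuple[int, float]] = {}
        next_active = []
        for ti in active:
            last = np.asarray(tracks[ti][-1])
            if len(pts) == 0:
                continue
            d = np.linalg.norm(pts - last, axis=1)
            order = np.argsort(d)
            best = int(order[0])
            if max_displacement_um is not None and d[best] > max_displacement_um:
                continue
            if len(order) > 1 and d[int(order[1])] - d[best] <= tie_tolerance_um:
                logger.info("track %d: ambiguous link at frame %d, terminated", ti, t)
                continue
            if best in claimed:
                prev_ti, prev_d = claimed[best]
                if abs(prev_d - d[best]) <= tie_tolerance_um:
                    logger.info("tracks %d/%d: tie on detection, both terminated",
                                prev_ti, ti)
                    next_active = [x for x in next_active if x != prev_ti]
                    tracks[prev_ti].pop()
                    del claimed[best]
                    continue
                if d[best] < prev_d:
                    next_active = [x for x in next_active if x != prev_ti]
                    tracks[prev_ti].pop()
                else:
                    continue
            claimed[best] = (ti, float(d[best]))
            tracks[ti].append(tuple(pts[best]))
            next_active.append(ti)
        active = next_active
    rows = []
    for i, tr in enumerate(tracks):
        arr = np.asarray(tr)
        steps = np.linalg.norm(np.diff(arr, axis=0), axis=1)
        rows.append(
            dict(
                bead=i,
                velocity_um_s=(steps.mean() / frame_interval_s) if steps.size else 0.0,
                n_steps=int(steps.size),
                x0_um=arr[0, 0],
                y0_um=arr[0, 1],
            )
        )
    return pd.DataFrame(rows, columns=["bead", "velocity_um_s", "n_steps",
                                       "x0_um", "y0_um"])
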