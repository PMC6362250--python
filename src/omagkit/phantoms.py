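"""Synthetic phantom generators with known ground truth.

Every input the pipeline consumes can be generated here: complex A-scan
ensembles with programmed axial velocities, binary vasculature volumes,
calibrated lumen images, bead time-lapse movies and integer count matrices.
All generators are deterministic for a fixed seed.

Signal model for the flow phantom: each voxel's repeat series is

    s_k = A_static * exp(i phi_s) + sum_seg A_seg * exp(i (2 pi f_seg t_k + phi_f)) + n_k

with t_k = k / a_line_rate, f_seg = 2 n v_z / lambda0 (the axial Doppler
shift), per-voxel random initial phases (speckle) and circular complex
Gaussian noise n_k of standard deviation ``noise_sigma``.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .containers import AScanEnsemble, GroundTruth, QuantImage


class AliasingError(ValueError):
    """A programmed velocity exceeds the unambiguous Doppler range."""


@dataclass
class FlowSegment:
    """A rectangular block of moving scatterers in the ensemble.

    ``positions`` and ``depths`` are half-open pixel index ranges.
    """

    positions: Tuple[int, int]
    depths: Tuple[int, int]
    velocity_mm_s: float
    amplitude: float = 0.3


@dataclass
class PhantomSpec:
    """Scan geometry plus programmed scene for a flow phantom.

    Defaults mirror the velocimetry protocol: 50 repeated A-lines at 200
    lateral positions over a 1.5 x 1.5 mm^2 field at 20,000 A-lines/s and a
    1340 nm center wavelength.  The static clutter amplitude is set well
    above the flow amplitude (tissue backscatter dominates the intralipid
    signal in fixed hearts).
    """

    field_of_view_mm: Tuple[float, float] = (1.5, 1.5)
    n_positions: int = 200
    n_repeats: int = 50
    a_line_rate_hz: float = 20_000.0
    depth_px: int = 128
    pixel_um: Tuple[float, float] = (7.0, 7.5)
    center_wavelength_nm: float = 1340.0
    refractive_index: float = 1.35
    noise_sigma: float = 0.03
    seed: int = 0
    flow_segments: List[FlowSegment] = field(default_factory=list)
    static_amplitude: float = 1.0
    preset_name: str = ""

    @property
    def aliasing_limit_mm_s(self) -> float:
        """Largest unambiguous |axial velocity|: lambda0 * rate / (4 n)."""
        lam_m = self.center_wavelength_nm * 1e-9
        return lam_m * self.a_line_rate_hz / (4.0 * self.refractive_index) * 1e3

    def doppler_frequency_hz(self, velocity_mm_s: float) -> float:
        """Axial Doppler shift f = 2 n v / lambda0 for v in mm/s."""
        lam_m = self.center_wavelength_nm * 1e-9
        return 2.0 * self.refractive_index * (velocity_mm_s * 1e-3) / lam_m

    def validate(self) -> None:
        if self.n_repeats < 2:
            raise ValueError("n_repeats must be >= 2")
        if self.a_line_rate_hz <= 0:
            raise ValueError("a_line_rate_hz must be positive")
        if self.depth_px < 1 or self.n_positions < 1:
            raise ValueError("empty scan geometry")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be >= 0")
        limit = self.aliasing_limit_mm_s
        for seg in self.flow_segments:
            if abs(seg.velocity_mm_s) >= limit:
                raise AliasingError(
                    f"programmed velocity {seg.velocity_mm_s} mm/s exceeds the "
                    f"aliasing limit {limit:.3f} mm/s at {self.a_line_rate_hz} Hz"
                )
            p0, p1 = seg.positions
            d0, d1 = seg.depths
            if not (0 <= p0 < p1 <= self.n_positions):
                raise ValueError("segment position range outside scan")
            if not (0 <= d0 < d1 <= self.depth_px):
                raise ValueError("segment depth range outside scan")


_PRESETS = {
    # angiography protocol: 16 B-frame repetitions at 250 A-line locations,
    # 280 frames/s (the repeat interval is the inter-frame time)
    "omag": dict(n_positions=250, n_repeats=16, a_line_rate_hz=280.0),
    # velocimetry protocol: 50 repeated A-lines at 200 positions, 20 kHz
    "omag-v": dict(n_positions=200, n_repeats=50, a_line_rate_hz=20_000.0),
}


def preset(name: str, **overrides) -> PhantomSpec:
    """Return a PhantomSpec for a named scan protocol ('omag' or 'omag-v')."""
    if name not in _PRESETS:
        raise KeyError(f"unknown preset {name!r}; choose from {sorted(_PRESETS)}")
    params = dict(_PRESETS[name])
    params.update(overrides)
    spec = PhantomSpec(preset_name=name, **params)
    lateral = spec.field_of_view_mm[0] * 1e3 / spec.n_positions
    return replace(spec, pixel_um=(spec.pixel_um[0], lateral))


def make_flow_phantom(spec: PhantomSpec) -> Tuple[AScanEnsemble, GroundTruth]:
    """Simulate a repeated-A-line ensemble with programmed axial velocities."""
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    shape = (spec.depth_px, spec.n_repeats, spec.n_positions)
    t = np.arange(spec.n_repeats) / spec.a_line_rate_hz

    static_phase = rng.uniform(0.0, 2.0 * np.pi, (spec.depth_px, spec.n_positions))
    signal = (
        spec.static_amplitude
        * np.exp(1j * static_phase)[:, None, :]
        * np.ones((1, spec.n_repeats, 1))
    ).astype(np.complex128)

    velocity_true = np.zeros((spec.depth_px, spec.n_positions))
    for seg in spec.flow_segments:
        p0, p1 = seg.positions
        d0, d1 = seg.depths
        f = spec.doppler_frequency_hz(seg.velocity_mm_s)
        phase0 = rng.uniform(0.0, 2.0 * np.pi, (d1 - d0, p1 - p0))
        rot = np.exp(2j * np.pi * f * t)
        signal[d0:d1, :, p0:p1] += (
            seg.amplitude * np.exp(1j * phase0)[:, None, :] * rot[None, :, None]
        )
        velocity_true[d0:d1, p0:p1] = seg.velocity_mm_s

    if spec.noise_sigma > 0:
        noise = rng.standard_normal(shape) + 1j * rng.standard_normal(shape)
        signal += spec.noise_sigma / np.sqrt(2.0) * noise

    ensemble = AScanEnsemble(
        signal=signal,
        a_line_rate_hz=spec.a_line_rate_hz,
        pixel_um=spec.pixel_um,
        center_wavelength_nm=spec.center_wavelength_nm,
        refractive_index=spec.refractive_index,
        preset_name=spec.preset_name,
    )
    truth = GroundTruth(
        velocity_map_true=velocity_true,
        vessel_mask_true=velocity_true != 0,
        extras={"spec": spec},
    )
    return ensemble, truth


@dataclass
class Cylinder:
    """Axis-aligned cylindrical vessel spanning the volume along ``axis``."""

    axis: int  # 0, 1 or 2
    center_um: Tuple[float, float]  # coordinates in the two transverse axes
    diameter_um: float
    velocity_mm_s: float = 0.0


def make_vessel_volume(
    layout: Sequence[Cylinder],
    volume_shape: Tuple[int, int, int],
    pixel_um: float,
) -> Tuple[np.ndarray, GroundTruth]:
    """Render axis-aligned cylinders into a binary 3-D volume.

    Overlaps are allowed; an empty layout yields an empty mask.  Truth
    records per-vessel diameter and programmed velocity, and a matching
    voxelwise velocity volume (later cylinders overwrite earlier ones where
    they overlap).
    """
    mask = np.zeros(volume_shape, dtype=bool)
    velocity = np.zeros(volume_shape, dtype=float)
    rows = []
    grids = np.meshgrid(
        *[np.arange(s) * pixel_um for s in volume_shape], indexing="ij"
    )
    for i, cyl in enumerate(layout):
        transverse = [ax for ax in range(3) if ax != cyl.axis]
        r = cyl.diameter_um / 2.0
        d2 = (grids[transverse[0]] - cyl.center_um[0]) ** 2 + (
            grids[transverse[1]] - cyl.center_um[1]
        ) ** 2
        inside = d2 <= r**2
        if cyl.center_um[0] < -r or cyl.center_um[1] < -r:
            raise ValueError(f"cylinder {i} outside volume bounds")
        mask |= inside
        velocity[inside] = cyl.velocity_mm_s
        rows.append(
            dict(
                vessel=i,
                axis=cyl.axis,
                diameter_um=cyl.diameter_um,
                velocity_mm_s=cyl.velocity_mm_s,
                voxels=int(inside.sum()),
            )
        )
    truth = GroundTruth(
        vessel_mask_true=mask,
        velocity_map_true=velocity,
        vessel_table_true=pd.DataFrame(
            rows, columns=["vessel", "axis", "diameter_um", "velocity_mm_s", "voxels"]
        ),
    )
    return mask, truth


# distance bins used for lumen statistics relative to the patterned vessel
# wall, in µm; half-open [lo, hi)
DEFAULT_DISTANCE_BINS = ((0.0, 300.0), (300.0, 600.0), (600.0, 900.0))


def _disk_pixels(
    shape: Tuple[int, int], center_px: Tuple[float, float], radius_px: float
) -> np.ndarray:
    yy, xx = np.ogrid[: shape[0], : shape[1]]
    return (yy - center_px[0]) ** 2 + (xx - center_px[1]) ** 2 <= radius_px**2


def make_lumen_image(
    lumens: Sequence[Tuple[Tuple[float, float], float, float]],
    pixel_um: float,
    image_shape: Tuple[int, int],
    min_area_um2_for_truth: float = 20.0,
    bins: Sequence[Tuple[float, float]] = DEFAULT_DISTANCE_BINS,
) -> Tuple[QuantImage, GroundTruth]:
    """Render lumen cross-sections as filled disks of requested area.

    ``lumens`` is a sequence of ((x_um, y_um) centroid, area_um2,
    distance_from_wall_um).  The disk radius is refined by bisection so the
    rendered pixel count is the nearest achievable to the requested area.
    A wall reference line is painted along column 0 at the stated distances'
    origin, so downstream distance computations can be exercised; the truth
    table is authoritative regardless.
    """
    img = np.zeros(image_shape, dtype=float)
    px_area = pixel_um**2
    rows = []
    for i, (centroid_um, area_um2, distance_um) in enumerate(lumens):
        target_px = area_um2 / px_area
        center_px = (centroid_um[1] / pixel_um, centroid_um[0] / pixel_um)
        if target_px < 1.0:
            warnings.warn(
                f"lumen {i}: requested area {area_um2} um^2 is below one pixel; "
                "rendering a single pixel",
                stacklevel=2,
            )
            disk = np.zeros(image_shape, dtype=bool)
            disk[int(round(center_px[0])), int(round(center_px[1]))] = True
        else:
            # nearest achievable area: the round(target) pixels closest to
            # the center form the most circular region of that exact count
            k = int(round(target_px))
            yy, xx = np.mgrid[: image_shape[0], : image_shape[1]]
            d2 = (yy - center_px[0]) ** 2 + (xx - center_px[1]) ** 2
            order = np.argsort(d2, axis=None)[:k]
            disk = np.zeros(image_shape, dtype=bool)
            disk.flat[order] = True
        if np.any(img[disk] > 0):
            raise ValueError(f"lumen {i} overlaps a previously placed lumen")
        img[disk] = 1.0
        rendered = disk.sum() * px_area
        bin_index = -1
        for b, (lo, hi) in enumerate(bins):
            if lo <= distance_um < hi:
                bin_index = b
                break
        rows.append(
            dict(
                lumen=i,
                area_um2=area_um2,
                rendered_area_um2=rendered,
                centroid_x_um=centroid_um[0],
                centroid_y_um=centroid_um[1],
                distance_um=distance_um,
                bin=bin_index,
                survives_filter=area_um2 >= min_area_um2_for_truth,
            )
        )
    table = pd.DataFrame(
        rows,
        columns=[
            "lumen",
            "area_um2",
            "rendered_area_um2",
            "centroid_x_um",
            "centroid_y_um",
            "distance_um",
            "bin",
            "survives_filter",
        ],
    )
    wall = np.zeros(image_shape, dtype=bool)
    wall[:, 0] = True  # wall reference along the left edge (x = 0)
    image = QuantImage(pixels=img, pixel_um=pixel_um, channel="GFP", wall_mask=wall)
    return image, GroundTruth(lumen_table_true=table)


def make_bead_movie(
    tracks: Sequence[Tuple[Tuple[float, float], Tuple[float, float]]],
    frame_interval_s: float,
    n_frames: int,
    image_shape: Tuple[int, int] = (128, 128),
    pixel_um: float = 1.0,
    bead_radius_um: float = 2.0,
) -> Tuple[np.ndarray, GroundTruth]:
    """Render a time-lapse of beads moving at constant velocity.

    ``tracks`` is a sequence of ((x0_um, y0_um) start, (vx_um_s, vy_um_s)
    velocity).  Frames are float images with beads as filled disks.  Beads
    must stay within the frame for all time points.
    """
    if n_frames < 1:
        raise ValueError("need at least one frame")
    frames = np.zeros((n_frames,) + tuple(image_shape), dtype=float)
    rows = []
    extent = (image_shape[1] * pixel_um, image_shape[0] * pixel_um)
    for b, (start, vel) in enumerate(tracks):
        for k in range(n_frames):
            x = start[0] + vel[0] * frame_interval_s * k
            y = start[1] + vel[1] * frame_interval_s * k
            if not (0 <= x < extent[0] and 0 <= y < extent[1]):
                raise ValueError(f"bead {b} leaves the frame at t={k}")
            disk = _disk_pixels(
                image_shape, (y / pixel_um, x / pixel_um), bead_radius_um / pixel_um
            )
            frames[k][disk] = 1.0
            rows.append(
                dict(
                    bead=b,
                    frame=k,
                    x_um=x,
                    y_um=y,
                    speed_um_s=float(np.hypot(*vel)),
                )
            )
    truth = GroundTruth(
        bead_tracks_true=pd.DataFrame(
            rows, columns=["bead", "frame", "x_um", "y_um", "speed_um_s"]
        )
    )
    return frames, truth


def make_count_matrix(
    n_genes: int = 2000,
    n_per_group: int = 3,
    group_names: Tuple[str, str] = ("A", "B"),
    libsize: int = 1_000_000,
    n_de: int = 100,
    fold: float = 4.0,
    dispersion: float = 0.1,
    frac_silent: float = 0.1,
    seed: int = 0,
):
    """Negative-binomial count matrix with planted differential genes.

    A fraction ``frac_silent`` of genes is given near-zero expression so the
    counts-per-million keep-filter has genuine work to do.  Half the planted
    DE genes go up in the second group, half down, each by ``fold`` on the
    linear scale.  Returns (counts DataFrame genes x samples, groups Series,
    GroundTruth with per-gene truth table).
    """
    if libsize <= 0:
        raise ValueError("libsize must be positive")
    rng = np.random.default_rng(seed)
    genes = [f"g{i:05d}" for i in range(n_genes)]
    samples = [f"{g}{j+1}" for g in group_names for j in range(n_per_group)]
    groups = pd.Series(
        [g for g in group_names for _ in range(n_per_group)], index=samples, name="group"
    )

    base = rng.lognormal(mean=4.0, sigma=1.5, size=n_genes)
    silent = rng.choice(n_genes, size=int(frac_silent * n_genes), replace=False)
    base[silent] *= 1e-4

    expressed = np.setdiff1d(np.arange(n_genes), silent)
    de_idx = rng.choice(expressed, size=min(n_de, expressed.size), replace=False)
    log2fc_true = np.zeros(n_genes)
    half = de_idx.size // 2
    log2fc_true[de_idx[:half]] = np.log2(fold)
    log2fc_true[de_idx[half:]] = -np.log2(fold)

    rel = base / base.sum()
    counts = np.empty((n_genes, len(samples)), dtype=np.int64)
    for j, s in enumerate(samples):
        mult = np.where(groups.iloc[j] == group_names[1], 2.0**log2fc_true, 1.0)
        mu = rel * mult * libsize
        # NB via gamma-Poisson; dispersion = 1/size
        lam = rng.gamma(shape=1.0 / dispersion, scale=mu * dispersion)
        counts[:, j] = rng.poisson(lam)

    counts_df = pd.DataFrame(counts, index=genes, columns=samples)
    cpm = counts * 1e6 / counts.sum(axis=0, keepdims=True)
    kept = (cpm > 1.0).sum(axis=1) >= 2
    truth = GroundTruth(
        gene_truth=pd.DataFrame(
            {
                "gene": genes,
                "is_de": np.isin(np.arange(n_genes), de_idx),
                "log2fc_true": log2fc_true,
                "kept_true": kept,
            }
        ).set_index("gene")
    )
    return counts_df, groups, truth
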