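"""Core in-memory containers shared across the imaging chain.

Array axis convention: depth = axis 0, repeats = axis 1, lateral position =
axis 2; indices 0-based; physical units (µm, mm/s, Hz) carried in metadata.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Tuple

import numpy as np
import pandas as pd


@dataclass
class AScanEnsemble:
    """Complex OCT signal block of repeated A-lines.

    ``signal`` has shape (depth, repeats, positions).  The repeat interval is
    ``1 / a_line_rate_hz``: for the velocimetry protocol the repeats are
    consecutive A-lines at the full line rate, for the angiography protocol
    they are B-frame repetitions at the frame rate.
    """

    signal: np.ndarray
    a_line_rate_hz: float
    pixel_um: Tuple[float, float]  # (axial, lateral)
    center_wavelength_nm: float
    refractive_index: float
    preset_name: str = ""

    def __post_init__(self) -> None:
        self.signal = np.asarray(self.signal)
        if self.signal.ndim != 3:
            raise ValueError("signal must be (depth, repeats, positions)")
        if self.signal.shape[1] < 2:
            raise ValueError("insufficient repeats: need at least 2")
        if not np.iscomplexobj(self.signal):
            raise ValueError("signal must be complex valued")
        if not np.all(np.isfinite(self.signal)):
            raise ValueError("signal contains non-finite values")
        if self.a_line_rate_hz <= 0:
            raise ValueError("a_line_rate_hz must be positive")

    @property
    def n_depth(self) -> int:
        return self.signal.shape[0]

    @property
    def n_repeats(self) -> int:
        return self.signal.shape[1]

    @property
    def n_positions(self) -> int:
        return self.signal.shape[2]

    @property
    def repeat_interval_s(self) -> float:
        return 1.0 / self.a_line_rate_hz

    @property
    def doppler_slope_mm_s_per_hz(self) -> float:
        """Axial Doppler calibration slope v = slope * f, i.e. lambda0/(2 n)."""
        lam_mm = self.center_wavelength_nm * 1e-6
        return lam_mm / (2.0 * self.refractive_index)


@dataclass
class FlowVolume:
    """Voxelwise flow contrast and mean structural magnitude."""

    flow: np.ndarray
    structure: np.ndarray
    pixel_um: Tuple[float, float]

    def __post_init__(self) -> None:
        self.flow = np.asarray(self.flow, dtype=float)
        self.structure = np.asarray(self.structure, dtype=float)
        if self.flow.shape != self.structure.shape:
            raise ValueError("flow and structure shapes differ")
        if np.any(self.flow < -1e-12):
            raise ValueError("flow must be non-negative")


@dataclass
class VelocityField:
    """Calibrated velocity map: velocity = doppler slope x frequency, per pixel.

    Pixels that carry no detected flow hold NaN in both maps.
    """

    velocity_mm_s: np.ndarray
    frequency_hz: np.ndarray
    pixel_um: Tuple[float, float]
    nyquist_hz: float
    gate_um: Tuple[float, float] = (20.0, 40.0)

    def __post_init__(self) -> None:
        self.velocity_mm_s = np.asarray(self.velocity_mm_s, dtype=float)
        self.frequency_hz = np.asarray(self.frequency_hz, dtype=float)
        if self.velocity_mm_s.shape != self.frequency_hz.shape:
            raise ValueError("velocity and frequency shapes differ")

    @property
    def flow_mask(self) -> np.ndarray:
        return np.isfinite(self.velocity_mm_s)


@dataclass
class QuantImage:
    """Calibrated 2-D intensity image (isotropic µm/pixel)."""

    pixels: np.ndarray
    pixel_um: float
    channel: str = ""
    wall_mask: Optional[np.ndarray] = None  # binary vessel-wall reference

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim != 2:
            raise ValueError("pixels must be 2-D")
        if self.pixel_um <= 0:
            raise ValueError("pixel_um must be positive")
        if not np.all(np.isfinite(self.pixels)):
            raise ValueError("pixels contain non-finite values")
        if self.wall_mask is not None:
            self.wall_mask = np.asarray(self.wall_mask, dtype=bool)
            if self.wall_mask.shape != self.pixels.shape:
                raise ValueError("wall_mask shape mismatch")

    @property
    def field_area_um2(self) -> float:
        return self.pixels.size * self.pixel_um**2


@dataclass
class ParticleSet:
    """Connected components of a binary image with per-particle measurements.

    ``table`` columns: label, area_um2, centroid_x_um, centroid_y_um and,
    when a wall reference was available, distance_um.  ``labels`` is the
    labeled image the table was measured from (0 = background).
    """

    table: pd.DataFrame
    labels: np.ndarray
    pixel_um: float
    min_area_um2: float = 0.0

    def __len__(self) -> int:
        return len(self.table)

    @property
    def areas_um2(self) -> np.ndarray:
        return self.table["area_um2"].to_numpy()


@dataclass
class GroundTruth:
    """Known truth attached to a synthetic dataset; absent parts are None."""

    velocity_map_true: Optional[np.ndarray] = None
    vessel_mask_true: Optional[np.ndarray] = None
    vessel_table_true: Optional[pd.DataFrame] = None
    lumen_table_true: Optional[pd.DataFrame] = None
    bead_tracks_true: Optional[pd.DataFrame] = None
    gene_truth: Optional[pd.DataFrame] = None
    extras: dict = field(default_factory=dict)
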