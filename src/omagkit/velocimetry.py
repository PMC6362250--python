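"""Eigendecomposition velocimetry of repeated A-line ensembles (OMAG-V).

The repeat series at each depth within an axial window are pooled into an
ensemble covariance matrix.  Its eigendecomposition separates the dominant
static-tissue (clutter) subspace from flow components; the Doppler frequency
of the leading flow eigenvector is read off the phase of its lag-one
autocorrelation and mapped linearly to velocity.  Per-vessel velocities,
diameter-gated statistics and perfusion rates follow.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from skimage.measure import label as cc_label

from .containers import AScanEnsemble, VelocityField
from .omag import estimate_vessel_diameters


@dataclass
class EnsembleCovariance:
    """Hermitian covariance of an N-repeat ensemble pooled over depth."""

    matrix: np.ndarray
    n_samples: int
    position: int = -1

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix)
        if m.ndim != 2 or m.shape[0] != m.shape[1]:
            raise ValueError("covariance must be square")
        if not np.allclose(m, m.conj().T, atol=1e-8 * max(1.0, np.abs(m).max())):
            raise ValueError("covariance is not Hermitian")
        self.matrix = m

    @property
    def trace(self) -> float:
        return float(np.real(np.trace(self.matrix)))


@dataclass
class EigenSplit:
    """Eigenpairs of an ensemble covariance, split into clutter and flow."""

    eigenvalues: np.ndarray  # descending, real >= 0
    eigenvectors: np.ndarray  # columns matching eigenvalues
    n_clutter: int

    @property
    def clutter_values(self) -> np.ndarray:
        return self.eigenvalues[: self.n_clutter]

    @property
    def flow_values(self) -> np.ndarray:
        return self.eigenvalues[self.n_clutter :]

    @property
    def clutter_vectors(self) -> np.ndarray:
        return self.eigenvectors[:, : self.n_clutter]

    @property
    def flow_vectors(self) -> np.ndarray:
        return self.eigenvectors[:, self.n_clutter :]


@dataclass
class DopplerCalibration:
    """Linear frequency-to-velocity map v = slope * f.

    Either give ``slope_mm_s_per_hz`` directly (an empirically calibrated
    linear correlation) or the optics (lambda0, n) for the axial Doppler
    default slope lambda0 / (2 n).
    """

    slope_mm_s_per_hz: Optional[float] = None
    center_wavelength_nm: Optional[float] = None
    refractive_index: Optional[float] = None

    @property
    def slope(self) -> float:
        if self.slope_mm_s_per_hz is not None:
            return self.slope_mm_s_per_hz
        if self.center_wavelength_nm is None or self.refractive_index is None:
            raise ValueError(
                "calibration requires a slope or (center_wavelength_nm, "
                "refractive_index)"
            )
        return (self.center_wavelength_nm * 1e-6) / (2.0 * self.refractive_index)

    @classmethod
    def from_ensemble(cls, ensemble: AScanEnsemble) -> "DopplerCalibration":
        return cls(
            center_wavelength_nm=ensemble.center_wavelength_nm,
            refractive_index=ensemble.refractive_index,
        )


def ensemble_covariance(
    ensemble: AScanEnsemble,
    position: int,
    depth_window: Tuple[int, int],
) -> EnsembleCovariance:
    """Pool the repeat series over a depth window into an N x N covariance.

    C = (1/Z) sum_z x_z x_z^H with x_z the N-repeat complex series at depth z.
    """
    z0, z1 = depth_window
    if not (0 <= z0 < z1 <= ensemble.n_depth):
        raise ValueError("depth window outside volume")
    if not (0 <= position < ensemble.n_positions):
        raise ValueError("position outside volume")
    x = ensemble.signal[z0:z1, :, position]  # (Z, N)
    c = np.einsum("zi,zj->ij", x, x.conj()) / x.shape[0]
    return EnsembleCovariance(matrix=c, n_samples=x.shape[0], position=position)


def eigen_split(cov: EnsembleCovariance, n_clutter: int = 1) -> EigenSplit:
    """Diagonalize the covariance; label the top ``n_clutter`` eigenpairs as
    static-tissue clutter and the remainder as candidate flow components."""
    n = cov.matrix.shape[0]
    if not 0 <= n_clutter <= n - 1:
        raise ValueError("n_clutter must be in [0, N_rep - 1]")
    vals, vecs = np.linalg.eigh(cov.matrix)
    tol = 1e-8 * max(1.0, float(vals.max(initial=0.0)))
    if vals.min(initial=0.0) < -tol:
        raise ValueError("covariance is not positive semi-definite")
    order = np.argsort(vals)[::-1]
    return EigenSplit(
        eigenvalues=np.clip(vals[order], 0.0, None),
        eigenvectors=vecs[:, order],
        n_clutter=n_clutter,
    )


def lag_one_frequency(
    eigvec: np.ndarray,
    a_line_rate_hz: float,
    coherence_tol: float = 0.0,
) -> float:
    """Doppler frequency from the phase of the lag-one autocorrelation.

    r = sum_k e(k+1) conj(e(k)); f = arg(r) * rate / (2 pi), in
    (-rate/2, rate/2].  When |r| (normalized by its maximum (N-1)/N for a
    unit vector) falls below ``coherence_tol`` the component is broadband
    noise and the frequency is undefined (NaN).
    """
    e = np.asarray(eigvec)
    if e.size < 2:
        raise ValueError("eigenvector must have length >= 2")
    r = np.sum(e[1:] * np.conj(e[:-1]))
    norm = np.sum(np.abs(e) ** 2)
    max_r = norm * (e.size - 1) / e.size
    if max_r == 0 or np.abs(r) / max_r <= coherence_tol:
        return float("nan")
    return float(np.angle(r) * a_line_rate_hz / (2.0 * np.pi))


def frequency_to_velocity(
    frequency_hz: float | np.ndarray, calibration: DopplerCalibration
) -> float | np.ndarray:
    """Map Doppler frequency to axial velocity: v = slope * f (mm/s)."""
    slope = calibration.slope
    out = slope * np.asarray(frequency_hz, dtype=float)
    return float(out) if np.isscalar(frequency_hz) else out


def velocity_map(
    ensemble: AScanEnsemble,
    n_clutter: int = 1,
    calibration: Optional[DopplerCalibration] = None,
    depth_window: int = 16,
    noise_multiple: float = 3.0,
    coherence_min: float = 0.5,
    weighted: bool = False,
) -> VelocityField:
    """Full velocimetry chain over every position and axial window.

    Per (position, window): covariance -> eigendecomposition -> frequency of
    the leading flow component -> velocity, assigned to voxels whose
    projection energy onto the flow eigenvector exceeds ``noise_multiple``
    times the noise floor (the mean of the lower half of the eigenvalue
    spectrum).  A flow component is accepted only if its eigenvalue clears
    the same multiple of the noise floor and its lag-one autocorrelation is
    phase-coherent (|r| above ``coherence_min`` of its maximum), which
    rejects broadband noise eigenvectors.

    With ``weighted`` the frequency is the eigenvalue-weighted circular mean
    over all accepted flow components instead of the leading one.
    """
    if calibration is None:
        calibration = DopplerCalibration.from_ensemble(ensemble)
    nz, nrep, nx = ensemble.signal.shape
    velocity = np.full((nz, nx), np.nan)
    frequency = np.full((nz, nx), np.nan)
    rate = ensemble.a_line_rate_hz

    for x in range(nx):
        for z0 in range(0, nz, depth_window):
            z1 = min(z0 + depth_window, nz)
            if z1 - z0 < 2:
                continue
            cov = ensemble_covariance(ensemble, x, (z0, z1))
            split = eigen_split(cov, n_clutter=n_clutter)
            vals = split.eigenvalues
            rank = min(z1 - z0, nrep)
            tail = vals[max(n_clutter + 1, rank // 2) : rank]
            noise_floor = float(tail.mean()) if tail.size else 0.0
            flow_vals = split.flow_values
            flow_vecs = split.flow_vectors
            accepted = []
            for j in range(flow_vals.size):
                if flow_vals[j] <= noise_multiple * noise_floor or flow_vals[j] <= 0:
                    break  # eigenvalues are sorted; nothing further clears
                f = lag_one_frequency(flow_vecs[:, j], rate, coherence_tol=coherence_min)
                if np.isfinite(f):
                    accepted.append((flow_vals[j], f, flow_vecs[:, j]))
            if not accepted:
                continue
            if weighted and len(accepted) > 1:
                w = np.array([a[0] for a in accepted])
                ph = np.array([a[1] for a in accepted]) * 2 * np.pi / rate
                f_est = float(np.angle(np.sum(w * np.exp(1j * ph))) * rate / (2 * np.pi))
            else:
                f_est = accepted[0][1]
            e_lead = accepted[0][2]
            xblock = ensemble.signal[z0:z1, :, x]
            energy = np.abs(xblock @ np.conj(e_lead)) ** 2
            hot = energy > noise_multiple * max(noise_floor, 0.0)
            if noise_floor == 0.0:
                hot = energy > 0
            zz = np.arange(z0, z1)[hot]
            frequency[zz, x] = f_est
            velocity[zz, x] = calibration.slope * f_est

    return VelocityField(
        velocity_mm_s=velocity,
        frequency_hz=frequency,
        pixel_um=ensemble.pixel_um,
        nyquist_hz=rate / 2.0,
    )


def per_vessel_table(
    field: VelocityField, mask: np.ndarray, pixel_um: Optional[float] = None
) -> pd.DataFrame:
    """Per-vessel diameter, mean velocity and Poiseuille-free flow estimate.

    Vessels are the connected components of ``mask``; each row carries the
    medial-axis diameter (µm), the mean |velocity| over in-vessel voxels with
    detected flow (mm/s), and the tube flow Q = v pi (d/2)^2 in µL/min.
    """
    mask = np.asarray(mask, dtype=bool)
    px = float(pixel_um) if pixel_um is not None else float(field.pixel_um[-1])
    diam = estimate_vessel_diameters(mask, px)
    labels = cc_label(mask, connectivity=mask.ndim)
    rows = []
    for _, drow in diam.iterrows():
        lab = int(drow["label"])
        vox = labels == lab
        v = field.velocity_mm_s[vox]
        v = np.abs(v[np.isfinite(v)])
        mean_v = float(v.mean()) if v.size else np.nan
        d_mm = drow["diameter_um"] * 1e-3
        q = mean_v * np.pi * (d_mm / 2.0) ** 2 * 60.0 if v.size else 0.0
        rows.append(
            dict(
                label=lab,
                diameter_um=drow["diameter_um"],
                velocity_mm_s=mean_v,
                q_ul_min=q,
                n_flow_voxels=int(v.size),
            )
        )
    return pd.DataFrame(
        rows, columns=["label", "diameter_um", "velocity_mm_s", "q_ul_min",
                       "n_flow_voxels"]
    )


@dataclass
class GatedVelocityStats:
    mean_mm_s: float
    sd_mm_s: float
    n_vessels: int
    gate_um: Tuple[float, float]

    @property
    def empty(self) -> bool:
        return self.n_vessels == 0


def gated_velocity_stats(
    vessels: pd.DataFrame, gate_um: Tuple[float, float] = (20.0, 40.0)
) -> GatedVelocityStats:
    """Mean +/- SD velocity over vessels whose diameter falls in the gate."""
    lo, hi = gate_um
    if lo > hi:
        raise ValueError("inverted gate bounds")
    sel = vessels[
        (vessels["diameter_um"] >= lo)
        & (vessels["diameter_um"] <= hi)
        & np.isfinite(vessels["velocity_mm_s"])
    ]
    if len(sel) == 0:
        warnings.warn("no vessels within the diameter gate", stacklevel=2)
        return GatedVelocityStats(np.nan, np.nan, 0, gate_um)
    v = sel["velocity_mm_s"].to_numpy()
    return GatedVelocityStats(
        mean_mm_s=float(v.mean()),
        sd_mm_s=float(v.std(ddof=1)) if v.size > 1 else 0.0,
        n_vessels=int(v.size),
        gate_um=gate_um,
    )


@dataclass
class PerfusionRate:
    q_fov_ul_min: float
    q_volumetric_ml_min_ml: float
    fov_area_mm2: float
    tissue_depth_mm: float


# depth of the imaged tissue slab used to normalize the field-of-view
# perfusion rate to a volumetric rate, in mm; configurable and logged
DEFAULT_TISSUE_DEPTH_MM = 0.89


def perfusion_rate(
    vessels: pd.DataFrame,
    fov_area_mm2: float = 2.25,
    tissue_depth_mm: Optional[float] = DEFAULT_TISSUE_DEPTH_MM,
) -> PerfusionRate:
    """Total perfusion over the field of view and per tissue volume.

    Q_fov = sum_i v_i pi (d_i/2)^2 in µL/min; the volumetric rate divides by
    the tissue volume FOV area x depth (in mL), giving mL/min per mL tissue.
    """
    if tissue_depth_mm is None:
        raise ValueError("tissue depth configuration is required")
    if tissue_depth_mm <= 0 or fov_area_mm2 <= 0:
        raise ValueError("fov_area_mm2 and tissue_depth_mm must be positive")
    q = vessels["q_ul_min"].to_numpy() if len(vessels) else np.array([])
    q_fov = float(np.nansum(q))
    volume_ml = fov_area_mm2 * tissue_depth_mm * 1e-3  # mm^3 -> mL
    q_vol = (q_fov * 1e-3) / volume_ml  # µL -> mL
    return PerfusionRate(q_fov, q_vol, fov_area_mm2, tissue_depth_mm)


def normalize_to_healthy(q_graft: float, q_healthy: float) -> float:
    """Graft perfusion rate as a fraction of the matched healthy region."""
    if q_healthy == 0:
        raise ValueError("healthy perfusion rate must be non-zero")
    return q_graft / q_healthy
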