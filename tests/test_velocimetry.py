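"""Covariance, eigendecomposition, lag-one frequency and perfusion metrics."""
import numpy as np
import pandas as pd
import pytest
from scipy.stats import spearmanr

from omagkit import FlowSegment, phantoms
from omagkit.containers import AScanEnsemble, VelocityField
from omagkit.velocimetry import (
    DopplerCalibration,
    EnsembleCovariance,
    eigen_split,
    ensemble_covariance,
    frequency_to_velocity,
    gated_velocity_stats,
    lag_one_frequency,
    normalize_to_healthy,
    per_vessel_table,
    perfusion_rate,
    velocity_map,
)

from conftest import small_flow_spec

RATE = 20000.0


def _ens(signal):
    return AScanEnsemble(signal=signal, a_line_rate_hz=RATE, pixel_um=(7.0, 7.5),
                         center_wavelength_nm=1340.0, refractive_index=1.35)


class TestCovariance:
    def test_static_phasor_is_rank_one(self):
        a = 2.0
        sig = a * np.exp(1j * 0.3) * np.ones((16, 8, 2), dtype=complex)
        cov = ensemble_covariance(_ens(sig), position=0, depth_window=(0, 16))
        split = eigen_split(cov, n_clutter=1)
        # rank-1 outer product of the length-N constant phasor: A^2 N
        assert split.eigenvalues[0] == pytest.approx(a**2 * 8, rel=1e-12)
        assert np.allclose(split.eigenvalues[1:], 0.0, atol=1e-10)

    def test_orthogonal_components_split_powers(self):
        # a DC phasor and a full-cycle phasor are exactly orthogonal over N
        n = 8
        u = np.ones(n, dtype=complex)
        v = np.exp(2j * np.pi * np.arange(n) / n)
        sig = np.zeros((2, n, 1), dtype=complex)
        sig[0, :, 0] = 2.0 * u  # static component, power 4 per repeat
        sig[1, :, 0] = v  # flow component, power 1 per repeat
        cov = ensemble_covariance(_ens(sig), 0, (0, 2))
        vals = eigen_split(cov, 0).eigenvalues
        # C = (1/2)(4 uu^H + vv^H) with orthogonal u, v
        assert vals[0] == pytest.approx(2.0 * n, rel=1e-10)
        assert vals[1] == pytest.approx(0.5 * n, rel=1e-10)
        assert np.allclose(vals[2:], 0.0, atol=1e-9)

    def test_trace_equals_mean_signal_energy(self, rng):
        sig = rng.standard_normal((10, 6, 3)) + 1j * rng.standard_normal((10, 6, 3))
        cov = ensemble_covariance(_ens(sig), 1, (0, 10))
        energy = np.mean(np.sum(np.abs(sig[:, :, 1]) ** 2, axis=1))
        assert cov.trace == pytest.approx(energy, rel=1e-12)

    def test_window_outside_volume_rejected(self):
        sig = np.ones((4, 4, 2), dtype=complex)
        with pytest.raises(ValueError):
            ensemble_covariance(_ens(sig), 0, (0, 10))


class TestEigenSplit:
    def test_eigenvalue_sum_equals_trace(self, rng):
        x = rng.standard_normal((20, 8)) + 1j * rng.standard_normal((20, 8))
        c = np.einsum("zi,zj->ij", x, x.conj()) / 20
        cov = EnsembleCovariance(matrix=c, n_samples=20)
        split = eigen_split(cov, 1)
        assert split.eigenvalues.sum() == pytest.approx(cov.trace, rel=1e-10)
        # descending order, orthonormal vectors
        assert np.all(np.diff(split.eigenvalues) <= 1e-12)
        assert np.allclose(
            split.eigenvectors.conj().T @ split.eigenvectors, np.eye(8), atol=1e-10
        )

    def test_static_phantom_clutter_vector_is_constant_phase(self):
        ens, _ = phantoms.make_flow_phantom(
            small_flow_spec(flow_segments=[], noise_sigma=0.01)
        )
        cov = ensemble_covariance(ens, 3, (0, 32))
        split = eigen_split(cov, 1)
        e1 = split.clutter_vectors[:, 0]
        const = np.ones_like(e1) / np.sqrt(e1.size)
        # subspace angle to the constant-phase vector under 5 degrees
        cosang = np.abs(np.vdot(e1, const))
        assert np.degrees(np.arccos(min(cosang, 1.0))) < 5.0

    def test_flow_phasor_is_dominant_eigenvector(self):
        ens, _ = phantoms.make_flow_phantom(
            small_flow_spec(noise_sigma=0.0, static_amplitude=0.0)
        )
        cov = ensemble_covariance(ens, 5, (6, 10))
        split = eigen_split(cov, 0)
        f = small_flow_spec().doppler_frequency_hz(0.5)
        t = np.arange(ens.n_repeats) / RATE
        phasor = np.exp(2j * np.pi * f * t) / np.sqrt(ens.n_repeats)
        assert np.abs(np.vdot(split.eigenvectors[:, 0], phasor)) > 0.99

    def test_invalid_clutter_count(self):
        c = np.eye(4, dtype=complex)
        with pytest.raises(ValueError):
            eigen_split(EnsembleCovariance(matrix=c, n_samples=4), 4)

    def test_non_psd_rejected(self):
        c = -np.eye(4, dtype=complex)
        with pytest.raises(ValueError, match="positive semi-definite"):
            eigen_split(EnsembleCovariance(matrix=c, n_samples=4), 1)


class TestLagOneFrequency:
    def test_pure_phasor_recovers_frequency_exactly(self):
        f = 1007.5
        t = np.arange(50) / RATE
        e = np.exp(2j * np.pi * f * t) / np.sqrt(50)
        assert lag_one_frequency(e, RATE) == pytest.approx(f, rel=1e-12)

    def test_constant_vector_is_zero(self):
        assert lag_one_frequency(np.ones(10) / np.sqrt(10), RATE) == 0.0

    def test_beyond_nyquist_aliases(self):
        # 12 kHz sampled at 20 kHz wraps to -8 kHz
        t = np.arange(50) / RATE
        e = np.exp(2j * np.pi * 12000.0 * t)
        assert lag_one_frequency(e, RATE) == pytest.approx(-8000.0, rel=1e-9)

    def test_incoherent_vector_flagged(self, rng):
        e = np.exp(1j * rng.uniform(0, 2 * np.pi, 64))
        f = lag_one_frequency(e, RATE, coherence_tol=0.5)
        assert np.isnan(f)


class TestCalibration:
    def test_doppler_slope_inverts_programmed_frequency(self):
        cal = DopplerCalibration(center_wavelength_nm=1340.0, refractive_index=1.35)
        assert frequency_to_velocity(1007.46, cal) == pytest.approx(0.5, rel=1e-4)
        assert frequency_to_velocity(0.0, cal) == 0.0

    def test_explicit_slope_linearity(self):
        cal1 = DopplerCalibration(slope_mm_s_per_hz=0.001)
        cal2 = DopplerCalibration(slope_mm_s_per_hz=0.002)
        assert frequency_to_velocity(500.0, cal2) == 2 * frequency_to_velocity(500.0, cal1)

    def test_missing_calibration_rejected(self):
        with pytest.raises(ValueError, match="calibration"):
            DopplerCalibration().slope


class TestVelocityMap:
    def test_two_vessel_phantom_recovery_within_5pct(self):
        spec = small_flow_spec(
            depth_px=32, n_positions=16, seed=11,
            flow_segments=[
                FlowSegment((2, 6), (4, 12), 0.3),
                FlowSegment((10, 14), (20, 28), 1.5),
            ],
        )
        ens, truth = phantoms.make_flow_phantom(spec)
        field = velocity_map(ens, depth_window=16)
        for seg in spec.flow_segments:
            p0, p1 = seg.positions
            d0, d1 = seg.depths
            v = np.abs(field.velocity_mm_s[d0:d1, p0:p1])
            v = v[np.isfinite(v)]
            assert v.size > 0
            assert np.median(v) == pytest.approx(seg.velocity_mm_s, rel=0.05)

    def test_static_phantom_has_no_flow_voxels(self):
        ens, _ = phantoms.make_flow_phantom(
            small_flow_spec(flow_segments=[], noise_sigma=0.03)
        )
        field = velocity_map(ens, depth_window=16)
        assert not field.flow_mask.any()

    def test_velocities_monotone_in_programmed_velocity(self):
        programmed = [0.3, 0.6, 1.0, 1.8, 2.6]
        recovered = []
        for i, v in enumerate(programmed):
            ens, truth = phantoms.make_flow_phantom(
                small_flow_spec(velocity_mm_s=v, seed=100 + i)
            )
            field = velocity_map(ens, depth_window=16)
            vv = np.abs(field.velocity_mm_s[truth.vessel_mask_true])
            recovered.append(np.nanmedian(vv))
        rho, _ = spearmanr(programmed, recovered)
        assert rho > 0.99999

    def test_strong_clutter_shifts_frequency_under_1pct(self):
        freqs = {}
        for mult in (1.0, 100.0):
            ens, truth = phantoms.make_flow_phantom(
                small_flow_spec(velocity_mm_s=1.0, static_amplitude=mult, seed=5)
            )
            field = velocity_map(ens, depth_window=16)
            freqs[mult] = np.nanmedian(np.abs(field.frequency_hz[truth.vessel_mask_true]))
        assert abs(freqs[100.0] - freqs[1.0]) / freqs[1.0] < 0.01


class TestVesselMetrics:
    def _field(self, velocity):
        return VelocityField(velocity_mm_s=velocity,
                             frequency_hz=np.zeros_like(velocity),
                             pixel_um=(2.0, 2.0), nyquist_hz=RATE / 2)

    def test_gated_stats_select_small_vessel(self):
        vessels = pd.DataFrame(
            {"label": [1, 2], "diameter_um": [30.0, 60.0],
             "velocity_mm_s": [0.7, 2.0], "q_ul_min": [0.1, 0.2],
             "n_flow_voxels": [10, 20]}
        )
        g = gated_velocity_stats(vessels, (20.0, 40.0))
        assert g.mean_mm_s == pytest.approx(0.7)
        assert g.n_vessels == 1
        both = gated_velocity_stats(vessels, (0.0, np.inf))
        assert both.n_vessels == 2

    def test_inverted_gate_rejected(self):
        with pytest.raises(ValueError, match="inverted"):
            gated_velocity_stats(pd.DataFrame(columns=["diameter_um",
                                                       "velocity_mm_s"]),
                                 (40.0, 20.0))

    def test_no_gated_vessels_flagged(self):
        vessels = pd.DataFrame({"label": [1], "diameter_um": [100.0],
                                "velocity_mm_s": [1.0], "q_ul_min": [0.1],
                                "n_flow_voxels": [5]})
        with pytest.warns(UserWarning, match="no vessels"):
            g = gated_velocity_stats(vessels)
        assert g.empty

    def test_per_vessel_table_measures_in_vessel_velocity(self):
        velocity = np.full((20, 20), np.nan)
        mask = np.zeros((20, 20), bool)
        mask[5:10, 5:15] = True
        velocity[5:10, 5:15] = 0.8
        t = per_vessel_table(self._field(velocity), mask, pixel_um=2.0)
        assert len(t) == 1
        assert t["velocity_mm_s"].iloc[0] == pytest.approx(0.8)
        assert t["diameter_um"].iloc[0] == pytest.approx(10.0, abs=2.0)


class TestPerfusionRate:
    def _vessels(self, rows):
        return pd.DataFrame(rows, columns=["label", "diameter_um",
                                           "velocity_mm_s", "q_ul_min",
                                           "n_flow_voxels"])

    def test_single_vessel_unit_arithmetic(self):
        # d = 40 um, v = 1 mm/s -> Q = pi (0.02 mm)^2 mm/s = 0.0754 uL/min
        q = 1.0 * np.pi * 0.02**2 * 60.0
        vessels = self._vessels([[1, 40.0, 1.0, q, 10]])
        rate = perfusion_rate(vessels, fov_area_mm2=2.25, tissue_depth_mm=0.89)
        assert rate.q_fov_ul_min == pytest.approx(0.0754, abs=2e-4)

    def test_volumetric_normalization_matches_fov_rate(self):
        vessels = self._vessels([[1, 40.0, 1.0, 24.5, 10]])
        rate = perfusion_rate(vessels, fov_area_mm2=2.25, tissue_depth_mm=0.89)
        # 24.5 uL/min over 2.25 mm^2 x 0.89 mm is about 12.2 mL/min/mL
        assert rate.q_volumetric_ml_min_ml == pytest.approx(12.23, abs=0.05)

    def test_additivity(self):
        one = self._vessels([[1, 40.0, 1.0, 0.0754, 10]])
        two = self._vessels([[1, 40.0, 1.0, 0.0754, 10],
                             [2, 40.0, 1.0, 0.0754, 10]])
        q1 = perfusion_rate(one).q_fov_ul_min
        q2 = perfusion_rate(two).q_fov_ul_min
        assert q2 == pytest.approx(2 * q1, rel=1e-12)

    def test_zero_vessels(self):
        assert perfusion_rate(self._vessels([])).q_fov_ul_min == 0.0

    def test_missing_depth_rejected(self):
        with pytest.raises(ValueError, match="depth"):
            perfusion_rate(self._vessels([]), tissue_depth_mm=None)

    def test_invariant_to_pixel_size_at_fixed_geometry(self):
        # same vessel geometry in um on two pixel grids gives the same Q
        qs = []
        for px in (1.0, 2.0):
            n = int(60 / px)
            w = int(30 / px)
            velocity = np.full((n, n), np.nan)
            mask = np.zeros((n, n), bool)
            lo = (n - w) // 2
            mask[lo : lo + w, :] = True
            velocity[mask] = 1.0
            field = VelocityField(velocity_mm_s=velocity,
                                  frequency_hz=np.zeros_like(velocity),
                                  pixel_um=(px, px), nyquist_hz=RATE / 2)
            t = per_vessel_table(field, mask, pixel_um=px)
            qs.append(perfusion_rate(t).q_fov_ul_min)
        # the rate formula is pixel-free; residual difference comes from the
        # +/- 1 px discretization of the medial-axis diameter estimate
        assert qs[0] == pytest.approx(qs[1], rel=0.15)


class TestNormalizeToHealthy:
    def test_reported_graft_to_healthy_ratio(self):
        assert normalize_to_healthy(24.5, 117.9) == pytest.approx(0.208, abs=0.001)

    def test_identity_and_zero(self):
        assert normalize_to_healthy(5.0, 5.0) == 1.0
        assert normalize_to_healthy(0.0, 5.0) == 0.0

    def test_zero_healthy_rejected(self):
        with pytest.raises(ValueError):
            normalize_to_healthy(1.0, 0.0)
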