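import warnings

import numpy as np
import pytest

import vhqpi as v
from vhqpi.hst_demod import (
    AnalyticFringePattern,
    analytic_signal,
    congruence_repair,
    count_residues,
    ft_demodulate,
    hilbert_spiral_transform,
    lsq_unwrap,
    remove_plane,
    spiral_phase_function,
    unwrap_phase,
    wrapped_phase,
)

from conftest import carrier


class TestSpiralPhaseFunction:
    def test_axis_values(self):
        spf = spiral_phase_function((8, 8))
        # positive u axis (one column over) -> +1; positive v axis -> +i
        assert spf[0, 1] == pytest.approx(1 + 0j)
        assert spf[1, 0] == pytest.approx(0 + 1j)
        assert spf[0, 0] == 0.0

    def test_unit_modulus_off_dc(self):
        spf = spiral_phase_function((33, 64))
        mags = np.abs(spf)
        mags[0, 0] = 1.0
        assert np.allclose(mags, 1.0, atol=1e-12)

    def test_tiny_shape_rejected(self):
        with pytest.raises(ValueError):
            spiral_phase_function((1, 8))


class TestHilbertSpiralTransform:
    def test_carrier_quadrature_is_sine(self):
        n = 256
        f = carrier(n, 16, "x")
        q = hilbert_spiral_transform(f, 0.0)
        x = np.arange(n)
        true = np.sin(2 * np.pi * x / 16)[None, :].repeat(n, 0)
        mask = v.interior_mask((n, n), 16)
        assert np.sqrt(np.mean((q - true)[mask] ** 2)) < 0.05

    def test_zero_input_zero_output(self):
        assert np.all(hilbert_spiral_transform(np.zeros((32, 32)), 0.0) == 0)

    def test_half_turn_negates_quadrature(self):
        f = carrier(128, 16)
        q0 = hilbert_spiral_transform(f, 0.0)
        q1 = hilbert_spiral_transform(f, np.pi)
        assert np.max(np.abs(q0 + q1)[16:-16, 16:-16]) < 1e-6

    def test_linearity(self, rng):
        f = rng.standard_normal((64, 64))
        f -= f.mean()
        beta = np.mod(rng.standard_normal((64, 64)), 2 * np.pi)
        q1 = hilbert_spiral_transform(2.5 * f, beta)
        q2 = 2.5 * hilbert_spiral_transform(f, beta)
        assert np.max(np.abs(q1 - q2)) < 1e-10

    def test_involution_on_carrier(self):
        f = carrier(256, 16)
        q = hilbert_spiral_transform(f, 0.0)
        ff = hilbert_spiral_transform(q, 0.0)
        mask = v.interior_mask((256, 256), 16)
        assert np.sqrt(np.mean((ff + f)[mask] ** 2)) < 0.05

    def test_spiral_multiplier_preserves_energy(self, rng):
        # Parseval: unit-modulus multiplier, DC nulled, zero-mean input
        f = rng.standard_normal((64, 64))
        f -= f.mean()
        spec = np.fft.fft2(f)
        out = spiral_phase_function(f.shape) * spec
        assert np.abs(np.sum(np.abs(out) ** 2) - np.sum(np.abs(spec) ** 2)) < 1e-10 * np.sum(
            np.abs(spec) ** 2
        )

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            hilbert_spiral_transform(np.zeros((32, 32)), np.zeros((16, 16)))


class TestAnalyticSignal:
    def test_real_part_is_input_bitwise(self, rng):
        f = rng.standard_normal((64, 64))
        f -= f.mean()
        afp = analytic_signal(f, 0.0)
        assert np.array_equal(afp.real, f)

    def test_unit_carrier_envelope_flat(self):
        afp = analytic_signal(carrier(256, 16), 0.0)
        mask = v.interior_mask((256, 256), 16)
        assert np.allclose(np.abs(afp.complex)[mask], 1.0, atol=0.05)

    def test_carrier_angle_is_wrapped_ramp(self):
        n = 256
        afp = analytic_signal(carrier(n, 16), 0.0)
        x = np.arange(n)
        expected = np.angle(np.exp(1j * 2 * np.pi * x / 16))[None, :].repeat(n, 0)
        mask = v.interior_mask((n, n), 16)
        d = np.angle(np.exp(1j * (wrapped_phase(afp) - expected)))
        assert np.sqrt(np.mean(d[mask] ** 2)) < 0.05


class TestWrappedPhase:
    def test_quadrant_values(self):
        afp = AnalyticFringePattern(real=np.array([[1.0, 0.0, -1.0]]), imag=np.array([[0.0, 1.0, 0.0]]))
        phi = wrapped_phase(afp)
        assert phi[0, 0] == 0.0
        assert phi[0, 1] == pytest.approx(np.pi / 2)
        assert phi[0, 2] == pytest.approx(np.pi)  # +pi, not -pi

    def test_zero_magnitude_maps_to_zero(self):
        phi = wrapped_phase(np.zeros((4, 4), complex))
        assert np.all(phi == 0)

    def test_range(self, rng):
        z = rng.standard_normal((32, 32)) + 1j * rng.standard_normal((32, 32))
        phi = wrapped_phase(z)
        assert np.all(phi > -np.pi) and np.all(phi <= np.pi)


class TestUnwrapPhase:
    @pytest.mark.parametrize("method", ["lsq", "quality"])
    def test_clean_ramp_unwraps_exactly(self, method):
        n = 128
        xx = np.mgrid[0:n, 0:n][1].astype(float)
        ramp = 2 * np.pi * xx / 16
        wrapped = np.angle(np.exp(1j * ramp))
        u = unwrap_phase(wrapped, method=method)
        d = u - ramp
        assert np.max(np.abs(d - d.mean())) < 1e-6

    def test_constant_input_unchanged(self):
        w = np.full((32, 32), 0.7)
        assert np.allclose(unwrap_phase(w), 0.7, atol=1e-9)

    @pytest.mark.parametrize("method", ["lsq", "quality"])
    def test_rewrap_reproduces_input(self, method, rng):
        w = np.angle(np.exp(1j * rng.standard_normal((64, 64)) * 3))
        u = unwrap_phase(w, method=method)
        d = np.angle(np.exp(1j * (u - w)))
        assert np.max(np.abs(d)) < 1e-6

    def test_unknown_method_rejected(self):
        with pytest.raises(ValueError):
            unwrap_phase(np.zeros((8, 8)), method="nope")

    def test_noncongruent_lsq_smooth_on_residue_free(self):
        n = 64
        xx = np.mgrid[0:n, 0:n][1].astype(float)
        ramp = 2 * np.pi * xx / 10
        u = lsq_unwrap(np.angle(np.exp(1j * ramp)), congruent=False)
        d = u - ramp
        assert np.max(np.abs(d - d.mean())) < 1e-6

    def test_congruence_repair_fixes_sheet_outlier(self):
        u = np.zeros((64, 64))
        u[30:33, 30:33] = 2 * np.pi  # isolated sheet defect
        fixed = congruence_repair(u)
        assert np.allclose(fixed, 0.0)

    def test_residue_count(self):
        n = 64
        yy, xx = np.mgrid[0:n, 0:n].astype(float)
        vortex = np.arctan2(yy - n / 2 + 0.5, xx - n / 2 + 0.5)
        assert count_residues(np.angle(np.exp(1j * vortex))) == 1
        assert count_residues(np.zeros((16, 16))) == 0


class TestRemovePlane:
    def test_exact_plane_removed(self):
        n = 64
        yy, xx = np.mgrid[0:n, 0:n].astype(float)
        out = remove_plane(3.0 + 0.1 * xx - 0.2 * yy)
        assert np.max(np.abs(out)) < 1e-9

    def test_phantom_recovered_from_plane_contamination(self):
        spec = v.SyntheticSpec(size=128)
        ph = v.rbc_phase(128, spec)
        n = 128
        yy, xx = np.mgrid[0:n, 0:n].astype(float)
        out = remove_plane(ph + 1.0 + 0.05 * xx + 0.02 * yy)
        assert np.max(np.abs(out - remove_plane(ph))) < 1e-9

    def test_idempotent(self, rng):
        p = rng.standard_normal((48, 48))
        once = remove_plane(p)
        assert np.allclose(remove_plane(once), once, atol=1e-10)


class TestFtDemodulate:
    def test_noise_free_phantom_offaxis(self):
        spec = v.SyntheticSpec(size=512, period=8.0, noise_amp=0.0, background="gaussian", seed=1)
        ph = v.rbc_phase(512, spec)
        I, _ = v.generate_interferogram(spec, ph)
        out = ft_demodulate(I, filter_center=(64, 0), filter_radius=30)
        mask = v.interior_mask((512, 512), 16, exclude_disk=10)
        assert v.rms_error(out, ph, mask=mask) < 0.15

    def test_pure_carrier_maps_to_plane(self):
        I = carrier(256, 8)
        out = ft_demodulate(I, filter_center=(32, 0), filter_radius=10)
        mask = v.interior_mask((256, 256), 16)
        assert np.sqrt(np.mean(out[mask] ** 2)) < 0.02

    def test_dc_filter_on_carrier_free_input_fails_loudly(self):
        spec = v.SyntheticSpec(size=256, period=np.inf, noise_amp=0.0, background="gaussian")
        ph = v.rbc_phase(256, spec)
        I, _ = v.generate_interferogram(spec, ph)
        with pytest.warns(UserWarning, match="autocorrelation"):
            out = ft_demodulate(I, filter_center=(0, 0), filter_radius=20)
        mask = v.interior_mask((256, 256), 16, exclude_disk=10)
        assert v.rms_error(out, ph, mask=mask) > 1.0

    def test_mask_touching_dc_warns(self):
        I = carrier(128, 8)
        with pytest.warns(UserWarning, match="autocorrelation"):
            ft_demodulate(I, filter_center=(16, 0), filter_radius=20)

    def test_auto_center_finds_carrier_lobe(self):
        I = carrier(256, 8)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            out = ft_demodulate(I)
        mask = v.interior_mask((256, 256), 16)
        assert np.sqrt(np.mean(out[mask] ** 2)) < 0.05
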