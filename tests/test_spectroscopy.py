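import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import vibrodyn as vd
from vibrodyn.constants import HBAR_EV_FS


def lineshape_moments(spec):
    """First moment and central variance of epsilon(w)/w."""
    L = spec.epsilon / spec.omega
    m0 = np.trapezoid(L, spec.omega)
    m1 = np.trapezoid(L * spec.omega, spec.omega) / m0
    var = np.trapezoid(L * (spec.omega - m1) ** 2, spec.omega) / m0
    return m0, m1, var


def rigid_model(E0=5.0):
    return vd.LVCModel(
        basis=vd.NormalModeBasis(frequencies=np.array([0.15])),
        E0=np.array([E0]),
        lambda_diag=np.zeros((1, 1)),
        lambda_offdiag=np.zeros((1, 1, 1)),
        dipoles=np.array([[1.0, 0.0, 0.0]]),
    )


class TestBroadeningConversion:
    def test_printed_value(self):
        # 0.04^2 / (4 ln 2) = 5.7708e-4 eV^2
        assert vd.hwhm_to_gamma(0.04) == pytest.approx(5.7708e-4, rel=1e-4)

    def test_round_trip(self):
        for x in (0.01, 0.04, 0.25, 1.0):
            assert vd.gamma_to_hwhm(vd.hwhm_to_gamma(x)) == pytest.approx(x)

    def test_quadratic_scaling(self):
        assert vd.hwhm_to_gamma(0.08) == pytest.approx(4 * vd.hwhm_to_gamma(0.04))

    def test_nonpositive_rejected(self):
        with pytest.raises(ValueError):
            vd.hwhm_to_gamma(0.0)
        with pytest.raises(ValueError):
            vd.gamma_to_hwhm(-1.0)

    @settings(max_examples=30, deadline=None)
    @given(st.floats(1e-4, 10.0))
    def test_round_trip_property(self, x):
        assert vd.gamma_to_hwhm(vd.hwhm_to_gamma(x)) == pytest.approx(x, rel=1e-12)


class TestAutocorrelationToSpectrum:
    def test_rigid_transition_gaussian(self):
        """C(t) = exp(-i E0 t / hbar) yields a Gaussian at E0 with the
        HWHM implied by Gamma."""
        m = rigid_model(5.0)
        r = vd.propagate(m, vd.make_doorway(m, 0), t_final=100.0, dt=0.1)
        gamma = vd.hwhm_to_gamma(0.04)
        grid = np.linspace(4.5, 5.5, 4001)
        spec = vd.autocorrelation_to_spectrum(r, m, 0, gamma, grid)
        peak_idx = int(np.argmax(spec.epsilon))
        assert spec.omega[peak_idx] == pytest.approx(5.0, abs=spec.spacing)
        half = spec.epsilon[peak_idx] / 2
        above = spec.omega[spec.epsilon >= half]
        hwhm = (above[-1] - above[0]) / 2
        assert hwhm == pytest.approx(0.04, abs=0.001)

    def test_dipole_quadratic_weighting(self):
        m = rigid_model()
        m2 = vd.LVCModel(
            basis=m.basis, E0=m.E0, lambda_diag=m.lambda_diag,
            lambda_offdiag=m.lambda_offdiag,
            dipoles=2.0 * m.dipoles,
        )
        r = vd.propagate(m, vd.make_doorway(m, 0), t_final=100.0, dt=0.1)
        gamma = vd.hwhm_to_gamma(0.04)
        grid = np.linspace(4.5, 5.5, 501)
        s1 = vd.autocorrelation_to_spectrum(r, m, 0, gamma, grid)
        s2 = vd.autocorrelation_to_spectrum(r, m2, 0, gamma, grid)
        np.testing.assert_allclose(s2.epsilon, 4.0 * s1.epsilon, rtol=1e-12)

    def test_moment_theorem_uncoupled(self):
        """First moment E0 and variance 1/2 sum lambda^2 + Gamma part."""
        m = vd.make_toy_model(
            vd.FixtureSpec(nstates=1, nmodes=2, seed=5, diag_scale=0.1,
                           coupling_scale=0.0)
        )
        r = vd.propagate(m, vd.make_doorway(m, 0), t_final=150.0, dt=0.1)
        gamma = vd.hwhm_to_gamma(0.04)
        grid = np.linspace(m.E0[0] - 2.5, m.E0[0] + 2.5, 6001)
        spec = vd.autocorrelation_to_spectrum(r, m, 0, gamma, grid)
        sm = vd.spectral_moments(m, 0)
        _, m1, var = lineshape_moments(spec)
        assert m1 == pytest.approx(sm.m1, rel=0.01)
        # the Gamma damping is a Gaussian of variance 2*Gamma in omega
        assert var - 2 * gamma == pytest.approx(sm.var, rel=0.01)

    def test_franck_condon_progression_spacing(self, single_mode_model):
        """Peaks of the 1-mode VG spectrum are spaced by the mode frequency."""
        m = single_mode_model
        times = np.arange(0.0, 600.0, 0.1)
        C = vd.analytic_vg_autocorrelation(m, 0, times)
        r = vd.PropagationResult(
            times=times, autocorr=C,
            populations=np.ones((times.size, 1)),
            norm_trace=np.ones(times.size),
            energy_trace=np.full(times.size, m.E0[0]),
        )
        gamma = vd.hwhm_to_gamma(0.008)
        grid = np.linspace(1.8, 2.4, 12001)
        spec = vd.autocorrelation_to_spectrum(r, m, 0, gamma, grid)
        peaks = [
            i for i in range(1, grid.size - 1)
            if spec.epsilon[i] > spec.epsilon[i - 1]
            and spec.epsilon[i] > spec.epsilon[i + 1]
            and spec.epsilon[i] > 0.01 * spec.epsilon.max()
        ]
        spacings = np.diff(spec.omega[peaks])
        np.testing.assert_allclose(spacings, 0.05, atol=0.001)

    def test_intensity_redistribution_not_creation(self):
        """Total integrated epsilon/omega is invariant under coupling toggle."""
        m = vd.two_state_conical_preset()
        gamma = vd.hwhm_to_gamma(0.04)
        grid = np.linspace(3.0, 6.0, 3001)
        integrals = {}
        for tag, mm in (("on", m), ("off", vd.strip_couplings(m))):
            psi = vd.make_doorway(mm, 1, truncation=(20, 12))
            r = vd.propagate(mm, psi, t_final=100.0, dt=0.1)
            spec = vd.autocorrelation_to_spectrum(r, mm, 1, gamma, grid)
            integrals[tag] = np.trapezoid(spec.epsilon / spec.omega, grid)
        assert integrals["on"] == pytest.approx(integrals["off"], rel=1e-3)

    def test_cross_terms_require_crosscorr(self, toy_coupled_model):
        m = toy_coupled_model
        psi = vd.make_doorway(m, 0, truncation=(6, 6))
        r = vd.propagate(m, psi, t_final=10.0, dt=0.1, store_crosscorr=False)
        with pytest.raises(ValueError, match="cross"):
            vd.autocorrelation_to_spectrum(
                r, m, 0, vd.hwhm_to_gamma(0.1), cross_terms=True
            )

    def test_cross_terms_small_effect(self, toy_coupled_model):
        """Full auto + cross double sum over all doorways stays positive and
        differs little from the auto-only spectrum."""
        m = toy_coupled_model
        gamma = vd.hwhm_to_gamma(0.15)
        results = []
        for i in range(m.nstates):
            psi = vd.make_doorway(m, i, truncation=(10, 10))
            results.append(vd.propagate(m, psi, t_final=60.0, dt=0.1))
        states = list(range(m.nstates))
        auto = vd.autocorrelation_to_spectrum(results, m, states, gamma)
        both = vd.autocorrelation_to_spectrum(
            results, m, states, gamma, cross_terms=True
        )
        assert both.meta["cross_terms"] is True
        # cross terms perturb, not dominate
        assert np.max(np.abs(both.epsilon - auto.epsilon)) < 0.5 * np.max(auto.epsilon)

    def test_nonuniform_grid_rejected(self, toy_coupled_model):
        m = toy_coupled_model
        psi = vd.make_doorway(m, 0, truncation=(5, 5))
        r = vd.propagate(m, psi, t_final=5.0, dt=0.1)
        r.times = r.times**1.01
        with pytest.raises(ValueError, match="uniform"):
            vd.autocorrelation_to_spectrum(r, m, 0, vd.hwhm_to_gamma(0.1))


class TestStickSpectrum:
    # vertical energies / oscillator strengths of the published
    # five-state pyrimidine benchmark set (bright states only)
    STICKS_E = [5.50, 6.62, 6.88]
    STICKS_F = [0.190, 0.045, 0.170]

    def test_two_band_envelope(self):
        """The three-stick table yields a two-band envelope: one band at the
        first stick, and a slightly stronger overlapped band where the two
        upper sticks merge (their 0.25 eV Gaussians overlap)."""
        grid = np.linspace(4.5, 8.0, 7001)
        spec = vd.stick_spectrum(self.STICKS_E, self.STICKS_F, hwhm=0.25, grid=grid)
        maxima = [
            i for i in range(1, grid.size - 1)
            if spec.epsilon[i] > spec.epsilon[i - 1]
            and spec.epsilon[i] > spec.epsilon[i + 1]
            and spec.epsilon[i] > 0.1 * spec.epsilon.max()
        ]
        assert len(maxima) == 2
        first, second = (spec.omega[i] for i in maxima)
        assert first == pytest.approx(5.50, abs=0.01)
        assert 6.6 < second < 6.9
        # the merged upper band narrowly overtops the first one
        ratio = spec.epsilon[maxima[1]] / spec.epsilon[maxima[0]]
        assert 1.0 < ratio < 1.05

    def test_single_stick_fwhm(self):
        grid = np.linspace(4.0, 6.0, 8001)
        spec = vd.stick_spectrum([5.0], [1.0], hwhm=0.25, grid=grid)
        peak = spec.epsilon.max()
        above = spec.omega[spec.epsilon >= peak / 2]
        assert above[-1] - above[0] == pytest.approx(0.5, abs=0.001)

    def test_zero_strengths_zero_spectrum(self):
        spec = vd.stick_spectrum([5.0, 6.0], [0.0, 0.0], hwhm=0.25)
        assert np.all(spec.epsilon == 0.0)

    def test_areas_proportional_to_f(self):
        grid = np.linspace(2.0, 9.0, 20001)
        spec = vd.stick_spectrum([4.0, 7.0], [0.2, 0.6], hwhm=0.1, grid=grid)
        mid = np.searchsorted(grid, 5.5)
        a1 = np.trapezoid(spec.epsilon[:mid], grid[:mid])
        a2 = np.trapezoid(spec.epsilon[mid:], grid[mid:])
        assert a2 / a1 == pytest.approx(3.0, rel=1e-6)

    def test_matches_vibronic_limit(self):
        """Pure-electronic spectrum equals the vibronic one when all
        lambdas vanish and hwhm matches Gamma."""
        m = rigid_model(5.0)
        r = vd.propagate(m, vd.make_doorway(m, 0), t_final=100.0, dt=0.1)
        hwhm = 0.1
        grid = np.linspace(4.0, 6.0, 2001)
        vib = vd.autocorrelation_to_spectrum(
            r, m, 0, vd.hwhm_to_gamma(hwhm), grid
        )
        sticks = vd.stick_spectrum([5.0], [1.0], hwhm=hwhm, grid=grid)
        # compare omega-divided lineshapes: the omega prefactor of the
        # vibronic spectrum skews the band by a few percent otherwise
        L = vib.epsilon / grid
        L /= L.max()
        s = sticks.epsilon / sticks.epsilon.max()
        np.testing.assert_allclose(L, s, atol=2e-3)

    def test_bad_inputs(self):
        with pytest.raises(ValueError):
            vd.stick_spectrum([5.0], [1.0, 2.0], hwhm=0.25)
        with pytest.raises(ValueError):
            vd.stick_spectrum([5.0], [1.0], hwhm=0.0)


class TestShiftNormalizeCombine:
    def test_max_normalization(self):
        spec = vd.stick_spectrum([5.0], [0.3], hwhm=0.25)
        out = vd.shift_normalize_combine([spec], normalization="max")
        assert out.epsilon.max() == pytest.approx(1.0)

    def test_fifty_fifty_of_identical_inputs(self):
        spec = vd.stick_spectrum([5.0, 6.0], [0.3, 0.2], hwhm=0.25)
        out = vd.shift_normalize_combine(
            [spec, spec], weights=[0.5, 0.5], normalization="max"
        )
        ref = vd.shift_normalize_combine([spec], normalization="max")
        np.testing.assert_allclose(out.epsilon, ref.epsilon, atol=1e-12)

    def test_shift_moves_argmax(self):
        grid = np.linspace(3.0, 7.0, 4001)  # 1 meV spacing, commensurate
        spec = vd.stick_spectrum([5.0], [1.0], hwhm=0.25, grid=grid)
        out = vd.shift_normalize_combine([spec], shifts=[-0.3], grid=grid)
        old = grid[np.argmax(spec.epsilon)]
        new = grid[np.argmax(out.epsilon)]
        assert old - new == pytest.approx(0.3, abs=1e-9)

    def test_area_normalization(self):
        spec = vd.stick_spectrum([5.0], [0.3], hwhm=0.25)
        out = vd.shift_normalize_combine([spec], normalization="area")
        assert np.trapezoid(out.epsilon, out.omega) == pytest.approx(1.0)

    def test_negative_weights_rejected(self):
        spec = vd.stick_spectrum([5.0], [0.3], hwhm=0.25)
        with pytest.raises(ValueError, match="non-negative"):
            vd.shift_normalize_combine([spec], weights=[-1.0])

    def test_equal_weight_tautomer_style_combination(self):
        a = vd.stick_spectrum([4.6], [0.15], hwhm=0.2,
                              grid=np.linspace(3.5, 6.5, 3001))
        b = vd.stick_spectrum([5.15], [0.3], hwhm=0.2,
                              grid=np.linspace(3.5, 6.5, 3001))
        out = vd.shift_normalize_combine(
            [a, b], weights=[0.5, 0.5], normalization="max"
        )
        assert out.epsilon.max() == pytest.approx(1.0)
        # both bands visible
        peaks = [
            i for i in range(1, out.omega.size - 1)
            if out.epsilon[i] > out.epsilon[i - 1]
            and out.epsilon[i] > out.epsilon[i + 1]
            and out.epsilon[i] > 0.2
        ]
        assert len(peaks) == 2


class TestSpectrumValidationAndIO:
    def test_grid_must_increase(self):
        with pytest.raises(ValueError):
            vd.Spectrum(omega=np.array([2.0, 1.0]), epsilon=np.zeros(2))

    def test_negative_ripple_clipped(self):
        eps = np.array([1.0, -1e-8, 2.0])
        spec = vd.Spectrum(omega=np.array([1.0, 2.0, 3.0]), epsilon=eps)
        assert spec.epsilon[1] == 0.0

    def test_large_negative_rejected(self):
        with pytest.raises(ValueError, match="negative"):
            vd.Spectrum(
                omega=np.array([1.0, 2.0, 3.0]),
                epsilon=np.array([1.0, -0.5, 2.0]),
            )

    def test_tsv_round_trip(self, tmp_path):
        spec = vd.stick_spectrum([5.0], [0.3], hwhm=0.25)
        p = tmp_path / "spec.tsv"
        vd.write_spectrum_tsv(spec, p)
        back = vd.read_spectrum_tsv(p)
        np.testing.assert_allclose(back.omega, spec.omega)
        np.testing.assert_allclose(back.epsilon, spec.epsilon)
        assert back.meta["hwhm_ev"] == 0.25


def test_default_grid(uracil_model):
    grid = vd.default_grid(uracil_model)
    assert grid.size == 2048
    assert grid[0] == pytest.approx(5.10 - 1.0)
    assert grid[-1] == pytest.approx(6.88 + 2.0)
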