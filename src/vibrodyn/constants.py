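"""Physical constants and unit conventions.

The package works in a mixed unit system chosen for spectroscopy of
mid-sized molecules: energies in eV, time in fs, transition dipoles in
atomic units.  Nuclear coordinates are dimensionless normal coordinates of
the ground-state Hessian, with the ground vibrational Hamiltonian
``1/2 * sum_a Omega_a * (p_a^2 + q_a^2)`` so that ``<0|q_a^2|0> = 1/2`` and
the zero-point energy is ``1/2 * sum_a Omega_a``.
"""

#: Reduced Planck constant in eV*fs.
HBAR_EV_FS: float = 0.6582119569

#: Conversion bundle for absolute molar absorptivity.
#:
#: epsilon(omega) [M^-1 cm^-1] = EPSILON_PREFACTOR * omega[eV] * |mu[a.u.]|^2
#:                               * Int dt[fs] e^{i omega t/hbar - Gamma t^2/hbar^2} C(t)
#:
#: Derived from the golden-rule absorption cross section
#: sigma(omega) = omega / (6 eps0 hbar c) |mu|^2 Int dt e^{i omega t} C(t)  (SI)
#: together with epsilon = sigma * N_A / (1000 ln 10) (sigma in cm^2).
#: Evaluated once with CODATA 2018 values:
#:   e = 1.602176634e-19 C, hbar = 1.054571817e-34 J s,
#:   N_A = 6.02214076e23 1/mol, a0 = 5.29177210903e-11 m,
#:   c0 = 2.99792458e8 m/s, eps0 = 8.8541878128e-12 F/m.
EPSILON_PREFACTOR: float = 170.0574474

#: Hartree in eV, used only for oscillator-strength conversions.
HARTREE_EV: float = 27.211386245988
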