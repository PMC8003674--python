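import numpy as np
import pytest

import vibrodyn as vd


@pytest.fixture
def single_mode_model():
    """1-state, 1-mode displaced oscillator: E0=2 eV, lambda=0.1, Omega=0.05."""
    return vd.LVCModel(
        basis=vd.NormalModeBasis(frequencies=np.array([0.05])),
        E0=np.array([2.0]),
        lambda_diag=np.array([[0.1]]),
        lambda_offdiag=np.zeros((1, 1, 1)),
        dipoles=np.array([[1.0, 0.0, 0.0]]),
    )


@pytest.fixture
def uracil_E0():
    """Vertical energies of the five-state pyrimidine reference set (eV)."""
    return np.array([5.10, 5.50, 6.18, 6.62, 6.88])


@pytest.fixture
def uracil_model(uracil_E0):
    """Five uncoupled states at the reference vertical energies."""
    nmodes = 2
    return vd.LVCModel(
        basis=vd.NormalModeBasis(frequencies=np.array([0.1, 0.2])),
        E0=uracil_E0,
        lambda_diag=np.zeros((5, nmodes)),
        lambda_offdiag=np.zeros((5, 5, nmodes)),
        dipoles=np.zeros((5, 3)),
        state_labels=("nOpi1", "pipi1", "Ryd1", "pipi2", "pipi3"),
    )


@pytest.fixture
def toy_coupled_model():
    """Small seeded random coupled model for generic tests."""
    return vd.make_toy_model(vd.FixtureSpec(nstates=3, nmodes=2, seed=11))


def dense_reference_propagation(model, psi0, times):
    """Independent oracle: full dense eigendecomposition of the truncated H.

    Returns (autocorr, populations) with the same zero-point-energy
    reference convention as :func:`vibrodyn.propagate`.
    """
    H = vd.build_hamiltonian(model, psi0.truncation).toarray()
    w, U = np.linalg.eigh(H)
    c0 = U.conj().T @ psi0.flat()
    zpe = 0.5 * float(model.basis.frequencies.sum())
    hbar = vd.HBAR_EV_FS
    autocorr = np.empty(len(times), dtype=complex)
    populations = np.empty((len(times), model.nstates))
    nvib = psi0.flat().size // model.nstates
    for k, t in enumerate(times):
        psi_t = U @ (np.exp(-1j * w * t / hbar) * c0)
        autocorr[k] = np.exp(1j * zpe * t / hbar) * np.vdot(psi0.flat(), psi_t)
        populations[k] = np.sum(
            np.abs(psi_t.reshape(model.nstates, nvib)) ** 2, axis=1
        )
    return autocorr, populations
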