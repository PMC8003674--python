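"""Seeded synthetic models and mock adiabatic scans.

Every other module is testable without any electronic-structure
calculation: models are drawn from documented distributions under a fixed
integer seed, and mock scans are produced by diagonalizing a known model so
that diabatization round trips are exact.
"""

from __future__ import annotations

import dataclasses
import warnings
from typing import Sequence

import numpy as np

from .diabatization import AdiabaticScan, ScanPoint
from .lvc import LVCModel, NormalModeBasis, adiabatic_energies_at

__all__ = [
    "FixtureSpec",
    "make_toy_model",
    "mock_adiabatic_scan",
    "two_state_conical_preset",
    "nucleobase_like_preset",
]


@dataclasses.dataclass(frozen=True)
class FixtureSpec:
    """Recipe for a random LVC model.

    Frequencies are uniform in ``frequency_range`` (eV); diagonal gradients
    and couplings are Gaussian with the given scales — with the defaults
    this exercises Huang-Rhys factors roughly in [0.01, 2].  ``dark_states``
    lists state indices whose dipole rows are zeroed; energy gaps follow
    ``energy_range`` uniformly (sorted), emulating a clustered bright/dark
    onset.
    """

    nstates: int
    nmodes: int
    seed: int
    frequency_range: tuple[float, float] = (0.05, 0.4)
    energy_range: tuple[float, float] = (4.5, 7.0)
    diag_scale: float = 0.08
    coupling_scale: float = 0.04
    dark_states: tuple[int, ...] = ()

    def __post_init__(self) -> None:
        if self.nstates < 1 or self.nmodes < 1:
            raise ValueError("nstates and nmodes must be positive")
        if self.diag_scale < 0 or self.coupling_scale < 0:
            raise ValueError("scales must be non-negative")
        if any(not 0 <= i < self.nstates for i in self.dark_states):
            raise ValueError("dark_states indices out of range")


def make_toy_model(spec: FixtureSpec) -> LVCModel:
    """Deterministic random model drawn with ``numpy.random.default_rng(seed)``."""
    rng = np.random.default_rng(spec.seed)
    n, f = spec.nstates, spec.nmodes
    freq = rng.uniform(*spec.frequency_range, size=f)
    E0 = np.sort(rng.uniform(*spec.energy_range, size=n))
    lambda_diag = rng.normal(0.0, spec.diag_scale, size=(n, f))
    offdiag = np.zeros((n, n, f))
    for i in range(n):
        for j in range(i + 1, n):
            vec = rng.normal(0.0, spec.coupling_scale, size=f)
            offdiag[i, j] = vec
            offdiag[j, i] = vec
    dipoles = rng.normal(0.0, 1.0, size=(n, 3))
    for i in spec.dark_states:
        dipoles[i] = 0.0
    return LVCModel(
        basis=NormalModeBasis(frequencies=freq),
        E0=E0,
        lambda_diag=lambda_diag,
        lambda_offdiag=offdiag,
        dipoles=dipoles,
    )


def mock_adiabatic_scan(
    model: LVCModel,
    delta: float = 0.05,
    *,
    sign_flips: bool = False,
    seed: int = 0,
) -> AdiabaticScan:
    """Scan emulating displaced-geometry electronic structure on ``model``.

    At each ``+/-delta`` displacement the diabatic potential matrix is
    diagonalized; the adiabatic energies (ascending) and the eigenvector
    matrix are recorded.  Since the reference diabatic basis coincides with
    the adiabatic basis at q = 0, the eigenvector matrix *is* the overlap
    matrix ``S[k, l] = <d_k | a_l>``.  With ``sign_flips=True`` random
    eigenvector signs are injected to exercise downstream phase fixing.

    Warns (with the mode index) when an eigenvalue crossing reorders the
    states at the displaced geometry relative to q = 0; Procrustes-based
    diabatization still recovers the model in that case.
    """
    if delta <= 0:
        raise ValueError("delta must be positive")
    rng = np.random.default_rng(seed)
    points: dict[tuple[int, int], ScanPoint] = {}
    for mode in range(model.nmodes):
        for sign in (+1, -1):
            q = np.zeros(model.nmodes)
            q[mode] = sign * delta
            energies, vectors = adiabatic_energies_at(model, q, return_vectors=True)
            if np.any(np.argmax(np.abs(vectors), axis=0) != np.arange(model.nstates)):
                warnings.warn(
                    f"possible state reordering at mode {mode}, "
                    f"sign {sign:+d} (delta={delta})",
                    stacklevel=2,
                )
            S = vectors
            if sign_flips:
                S = S * rng.choice([-1.0, 1.0], size=model.nstates)
            points[(mode, sign)] = ScanPoint(energies=energies, overlap=S)
    return AdiabaticScan(
        basis=model.basis,
        delta=delta,
        points=points,
        E0=model.E0,
        dipoles=model.dipoles,
        state_labels=model.state_labels,
    )


def two_state_conical_preset() -> LVCModel:
    """Canonical two-state/two-mode conical-intersection benchmark.

    One totally symmetric tuning mode (0.0996 eV) with opposite-sign
    gradients on the two states and one coupling mode (0.0936 eV) carrying
    the inter-state coupling (0.1825 eV) — parameters in the ballpark of
    the classic two-mode azine benchmark.  The upper state is bright, the
    lower nearly dark; population leaves the upper diabatic state within
    tens of fs.
    """
    basis = NormalModeBasis(
        frequencies=np.array([0.0996, 0.0936]),
        labels=("tuning", "coupling"),
        symmetry=("in-plane", "out-of-plane"),
    )
    return LVCModel(
        basis=basis,
        E0=np.array([4.0, 4.5]),
        lambda_diag=np.array([[-0.0964, 0.0], [0.1194, 0.0]]),
        lambda_offdiag=np.array(
            [
                [[0.0, 0.0], [0.0, 0.1825]],
                [[0.0, 0.1825], [0.0, 0.0]],
            ]
        ),
        dipoles=np.array([[0.0, 0.0, 0.1], [1.0, 0.0, 0.0]]),
        state_labels=("lower", "upper"),
    )


def nucleobase_like_preset(seed: int = 7) -> LVCModel:
    """Six-state/six-mode model with a bright/dark layout typical of
    heteroaromatic chromophores: two bright states among four dark ones,
    clustered vertical energies, moderate gradients and couplings.

    Deterministic under the seed and small enough to propagate 250 fs at
    desk scale with a reduced per-mode basis.
    """
    spec = FixtureSpec(
        nstates=6,
        nmodes=6,
        seed=seed,
        frequency_range=(0.08, 0.25),
        energy_range=(4.8, 6.8),
        diag_scale=0.07,
        coupling_scale=0.035,
        dark_states=(0, 2, 4, 5),
    )
    model = make_toy_model(spec)
    labels = ("dark1", "bright1", "dark2", "bright2", "dark3", "dark4")
    return dataclasses.replace(model, state_labels=labels)


def _preset_by_name(name: str, seed: int = 7) -> LVCModel:
    presets = {
        "two-state-conical": lambda: two_state_conical_preset(),
        "nucleobase-like": lambda: nucleobase_like_preset(seed),
    }
    try:
        return presets[name]()
    except KeyError:
        raise KeyError(
            f"unknown preset {name!r}; available: {sorted(presets)}"
        ) from None
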