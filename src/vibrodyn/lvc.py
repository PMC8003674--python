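"""Linear vibronic coupling (LVC) Hamiltonian data model.

An LVC model couples ``n`` diabatic electronic states through a Hamiltonian
expressed in dimensionless ground-state normal coordinates ``q``:

* kinetic energy ``K = 1/2 p^T Omega p`` (shared by all states),
* diagonal potentials ``V_ii(q) = E0_i + lambda_ii^T q + 1/2 q^T Omega q``,
* linear inter-state couplings ``V_ij(q) = lambda_ij^T q``.

All energies are in eV; transition dipoles are in atomic units and are
treated as coordinate independent (Condon approximation).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import warnings
from pathlib import Path
from typing import Sequence

import numpy as np

logger = logging.getLogger(__name__)

SCHEMA_VERSION = 1

__all__ = [
    "NormalModeBasis",
    "LVCModel",
    "SpectralMoments",
    "diabatic_potential_at",
    "adiabatic_energies_at",
    "spectral_moments",
    "strip_couplings",
    "read_model_json",
    "write_model_json",
    "model_to_operator_text",
]


@dataclasses.dataclass(frozen=True)
class NormalModeBasis:
    """Harmonic normal-mode basis of the ground electronic state.

    Frequencies are in eV.  A negative input frequency is interpreted as an
    imaginary ground-state frequency and is replaced by its absolute value
    (with a warning), a standard pragmatic fix for shallow out-of-plane
    saddle directions.
    """

    frequencies: np.ndarray
    labels: tuple[str, ...] = ()
    symmetry: tuple[str, ...] | None = None

    def __post_init__(self) -> None:
        freq = np.atleast_1d(np.asarray(self.frequencies, dtype=float)).copy()
        if freq.ndim != 1:
            raise ValueError("frequencies must be a 1-D array")
        if np.any(freq == 0) or not np.all(np.isfinite(freq)):
            raise ValueError("frequencies must be finite and nonzero")
        if np.any(freq < 0):
            bad = np.flatnonzero(freq < 0)
            warnings.warn(
                f"imaginary (negative) frequencies at modes {bad.tolist()} "
                "replaced by their absolute values",
                stacklevel=3,
            )
            freq = np.abs(freq)
        labels = tuple(self.labels) if self.labels else tuple(
            f"mode{i}" for i in range(freq.size)
        )
        if len(labels) != freq.size:
            raise ValueError("labels length must equal number of modes")
        if self.symmetry is not None and len(self.symmetry) != freq.size:
            raise ValueError("symmetry length must equal number of modes")
        freq.setflags(write=False)
        object.__setattr__(self, "frequencies", freq)
        object.__setattr__(self, "labels", labels)
        if self.symmetry is not None:
            object.__setattr__(self, "symmetry", tuple(self.symmetry))

    @property
    def nmodes(self) -> int:
        return int(self.frequencies.size)


@dataclasses.dataclass(frozen=True)
class LVCModel:
    """Parameters of an LVC Hamiltonian.

    ``lambda_diag`` has shape (nstates, nmodes); ``lambda_offdiag`` has shape
    (nstates, nstates, nmodes), is symmetric in its first two indices and has
    zero diagonal slices (diagonal gradients live in ``lambda_diag``).
    ``dipoles`` has shape (nstates, 3); zero rows mark dark states.
    """

    basis: NormalModeBasis
    E0: np.ndarray
    lambda_diag: np.ndarray
    lambda_offdiag: np.ndarray
    dipoles: np.ndarray
    state_labels: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        E0 = np.atleast_1d(np.asarray(self.E0, dtype=float)).copy()
        n = E0.size
        f = self.basis.nmodes
        ld = np.asarray(self.lambda_diag, dtype=float).reshape(n, f).copy()
        lo = np.asarray(self.lambda_offdiag, dtype=float).reshape(n, n, f).copy()
        mu = np.asarray(self.dipoles, dtype=float).reshape(n, 3).copy()
        if not (np.all(np.isfinite(E0)) and np.all(np.isfinite(ld))
                and np.all(np.isfinite(lo)) and np.all(np.isfinite(mu))):
            raise ValueError("model parameters must be finite")
        if not np.allclose(lo, lo.swapaxes(0, 1), atol=1e-10, rtol=0.0):
            raise ValueError("lambda_offdiag must be symmetric in (i, j)")
        diag = lo[np.arange(n), np.arange(n), :]
        if not np.allclose(diag, 0.0, atol=1e-12):
            raise ValueError(
                "diagonal slices of lambda_offdiag must vanish; "
                "put diagonal gradients in lambda_diag"
            )
        # store an exactly symmetric tensor with an exactly zero diagonal
        lo = 0.5 * (lo + lo.swapaxes(0, 1))
        lo[np.arange(n), np.arange(n), :] = 0.0
        labels = tuple(self.state_labels) if self.state_labels else tuple(
            f"S{i + 1}" for i in range(n)
        )
        if len(labels) != n:
            raise ValueError("state_labels length must equal nstates")
        for arr in (E0, ld, lo, mu):
            arr.setflags(write=False)
        object.__setattr__(self, "E0", E0)
        object.__setattr__(self, "lambda_diag", ld)
        object.__setattr__(self, "lambda_offdiag", lo)
        object.__setattr__(self, "dipoles", mu)
        object.__setattr__(self, "state_labels", labels)

    @property
    def nstates(self) -> int:
        return int(self.E0.size)

    @property
    def nmodes(self) -> int:
        return self.basis.nmodes

    def state_index(self, state: int | str) -> int:
        """Resolve a state label or integer index to an integer index."""
        if isinstance(state, str):
            try:
                return self.state_labels.index(state)
            except ValueError:
                raise KeyError(
                    f"unknown state label {state!r}; known: {self.state_labels}"
                ) from None
        i = int(state)
        if not 0 <= i < self.nstates:
            raise IndexError(f"state index {i} out of range [0, {self.nstates})")
        return i

    def content_hash(self) -> str:
        """Stable hash of the model parameters (for provenance metadata)."""
        return hashlib.sha256(
            json.dumps(_model_to_dict(self), sort_keys=True).encode()
        ).hexdigest()[:16]


@dataclasses.dataclass(frozen=True)
class SpectralMoments:
    """Analytic moments of the zero-temperature one-doorway lineshape.

    ``m0`` is the |mu|^2 weight, ``m1`` the first moment (eV) and ``var`` the
    central second moment (eV^2), all referenced to the ground vibrational
    level and excluding any phenomenological broadening.
    """

    m0: float
    m1: float
    var: float

    def __post_init__(self) -> None:
        if self.var < 0:
            raise ValueError("variance must be non-negative")


def diabatic_potential_at(model: LVCModel, q: Sequence[float]) -> np.ndarray:
    """Evaluate the diabatic potential matrix V(q) in eV.

    ``V_ii = E0_i + lambda_ii.q + 1/2 sum_a Omega_a q_a^2`` and
    ``V_ij = lambda_ij.q``; the returned matrix is exactly symmetric.
    """
    q = np.atleast_1d(np.asarray(q, dtype=float))
    if q.shape != (model.nmodes,):
        raise ValueError(
            f"coordinate vector has shape {q.shape}, expected ({model.nmodes},)"
        )
    harm = 0.5 * float(np.dot(model.basis.frequencies, q * q))
    V = model.lambda_offdiag @ q
    np.fill_diagonal(V, model.E0 + model.lambda_diag @ q + harm)
    return V


def adiabatic_energies_at(
    model: LVCModel,
    q: Sequence[float],
    return_vectors: bool = False,
) -> np.ndarray | tuple[np.ndarray, np.ndarray]:
    """Eigenvalues (ascending, eV) of the diabatic potential matrix at ``q``.

    With ``return_vectors=True`` also return the eigenvector matrix whose
    columns are the adiabatic states expressed in the diabatic basis.
    """
    V = diabatic_potential_at(model, q)
    if return_vectors:
        w, U = np.linalg.eigh(V)
        return w, U
    return np.linalg.eigvalsh(V)


def spectral_moments(model: LVCModel, state: int | str) -> SpectralMoments:
    """Analytic m0/m1/variance of the lineshape for doorway state ``state``.

    For the doorway ``|d_i; 0>`` and energies referenced to the ground
    vibrational level, the first moment is ``E0_i`` and the central variance
    ``1/2 * sum_a [lambda_ii,a^2 + sum_{j != i} lambda_ij,a^2]`` (using
    ``<0|q_a^2|0> = 1/2``).
    """
    i = model.state_index(state)
    m0 = float(np.dot(model.dipoles[i], model.dipoles[i]))
    var = 0.5 * float(
        np.sum(model.lambda_diag[i] ** 2) + np.sum(model.lambda_offdiag[i] ** 2)
    )
    return SpectralMoments(m0=m0, m1=float(model.E0[i]), var=var)


def strip_couplings(model: LVCModel) -> LVCModel:
    """Return a copy with all inter-state couplings set to zero.

    The result is the vertical-gradient (VG) limit: independent displaced
    harmonic surfaces.
    """
    return LVCModel(
        basis=model.basis,
        E0=model.E0,
        lambda_diag=model.lambda_diag,
        lambda_offdiag=np.zeros_like(model.lambda_offdiag),
        dipoles=model.dipoles,
        state_labels=model.state_labels,
    )


# ---------------------------------------------------------------------------
# JSON schema (versioned, bit-exact round trip)
# ---------------------------------------------------------------------------

def _model_to_dict(model: LVCModel) -> dict:
    n = model.nstates
    offdiag = [
        [i, j, model.lambda_offdiag[i, j].tolist()]
        for i in range(n)
        for j in range(i + 1, n)
        if np.any(model.lambda_offdiag[i, j] != 0.0)
    ]
    return {
        "schema_version": SCHEMA_VERSION,
        "nstates": n,
        "nmodes": model.nmodes,
        "frequencies_ev": model.basis.frequencies.tolist(),
        "E0_ev": model.E0.tolist(),
        "lambda_diag_ev": model.lambda_diag.tolist(),
        "lambda_offdiag_ev": offdiag,
        "dipoles_au": model.dipoles.tolist(),
        "state_labels": list(model.state_labels),
        "mode_labels": list(model.basis.labels),
        "mode_symmetry": list(model.basis.symmetry) if model.basis.symmetry else None,
    }


def _model_from_dict(data: dict) -> LVCModel:
    version = data.get("schema_version")
    if version != SCHEMA_VERSION:
        raise ValueError(f"unsupported model schema version: {version!r}")
    n = int(data["nstates"])
    f = int(data["nmodes"])
    freq = np.asarray(data["frequencies_ev"], dtype=float)
    if freq.shape != (f,):
        raise ValueError("frequencies_ev length does not match nmodes")
    offdiag = np.zeros((n, n, f))
    for entry in data["lambda_offdiag_ev"]:
        i, j, vec = int(entry[0]), int(entry[1]), np.asarray(entry[2], dtype=float)
        if not (0 <= i < j < n):
            raise ValueError(f"invalid off-diagonal index pair ({i}, {j})")
        if vec.shape != (f,):
            raise ValueError(f"lambda vector for ({i}, {j}) has wrong length")
        offdiag[i, j] = vec
        offdiag[j, i] = vec
    basis = NormalModeBasis(
        frequencies=freq,
        labels=tuple(data["mode_labels"]),
        symmetry=tuple(data["mode_symmetry"]) if data.get("mode_symmetry") else None,
    )
    return LVCModel(
        basis=basis,
        E0=np.asarray(data["E0_ev"], dtype=float),
        lambda_diag=np.asarray(data["lambda_diag_ev"], dtype=float),
        lambda_offdiag=offdiag,
        dipoles=np.asarray(data["dipoles_au"], dtype=float),
        state_labels=tuple(data["state_labels"]),
    )


def write_model_json(model: LVCModel, path: str | Path) -> None:
    Path(path).write_text(json.dumps(_model_to_dict(model), indent=1) + "\n")


def read_model_json(path: str | Path) -> LVCModel:
    return _model_from_dict(json.loads(Path(path).read_text()))


# ---------------------------------------------------------------------------
# Plain-text operator export (Quantics/MCTDH flavoured, best effort)
# ---------------------------------------------------------------------------

def model_to_operator_text(model: LVCModel, title: str = "lvc model") -> str:
    """Render the model as an MCTDH-style plain-text operator section.

    Best-effort export for visual inspection and hand-off to external
    propagation codes; not validated bit-for-bit against any of them.
    """
    lines = [f"OP_DEFINE-SECTION", f"title\n{title}\nend-title", "end-op_define-section", ""]
    lines.append("PARAMETER-SECTION")
    for a, (w, lab) in enumerate(zip(model.basis.frequencies, model.basis.labels)):
        lines.append(f"omega_{a + 1} = {w:.12g}, ev   # {lab}")
    for i in range(model.nstates):
        lines.append(f"E0_{i + 1} = {model.E0[i]:.12g}, ev")
    for i in range(model.nstates):
        for a in range(model.nmodes):
            if model.lambda_diag[i, a] != 0.0:
                lines.append(f"kappa_{i + 1}_{a + 1} = {model.lambda_diag[i, a]:.12g}, ev")
    for i in range(model.nstates):
        for j in range(i + 1, model.nstates):
            for a in range(model.nmodes):
                if model.lambda_offdiag[i, j, a] != 0.0:
                    lines.append(
                        f"lambda_{i + 1}_{j + 1}_{a + 1} = "
                        f"{model.lambda_offdiag[i, j, a]:.12g}, ev"
                    )
    lines.append("end-parameter-section")
    lines.append("")
    lines.append("HAMILTONIAN-SECTION")
    header = "modes | el | " + " | ".join(model.basis.labels)
    lines.append(header)
    for a in range(model.nmodes):
        lines.append(f"omega_{a + 1}/2  |1 1  |{a + 2} dq^2")
        lines.append(f"omega_{a + 1}/2  |1 1  |{a + 2} q^2")
    for i in range(model.nstates):
        lines.append(f"E0_{i + 1}  |1 S{i + 1}&{i + 1}  |2 1")
        for a in range(model.nmodes):
            if model.lambda_diag[i, a] != 0.0:
                lines.append(f"kappa_{i + 1}_{a + 1}  |1 S{i + 1}&{i + 1}  |{a + 2} q")
    for i in range(model.nstates):
        for j in range(i + 1, model.nstates):
            for a in range(model.nmodes):
                if model.lambda_offdiag[i, j, a] != 0.0:
                    lines.append(
                        f"lambda_{i + 1}_{j + 1}_{a + 1}  |1 S{i + 1}&{j + 1}  |{a + 2} q"
                    )
    lines.append("end-hamiltonian-section")
    lines.append("")
    lines.append("end-operator")
    return "\n".join(lines) + "\n"
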