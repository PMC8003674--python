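"""Maximum-overlap diabatization and finite-difference parameter extraction.

Given adiabatic energies and wavefunction-overlap matrices at geometries
displaced by ``+/- delta`` along each normal coordinate, this module
constructs the orthogonal transformation that maps adiabatic states onto
diabatic states defined by maximal overlap with a fixed reference set (the
adiabatic states at the undisplaced geometry), rotates the adiabatic
energies into the diabatic representation, and extracts linear coupling
parameters by central differences.  The result is a complete
:class:`~vibrodyn.lvc.LVCModel`.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .lvc import LVCModel, NormalModeBasis

logger = logging.getLogger(__name__)

SCAN_SCHEMA_VERSION = 1

__all__ = [
    "ScanPoint",
    "AdiabaticScan",
    "DiabatizationResult",
    "max_overlap_transformation",
    "diabatize_point",
    "central_difference_lambda",
    "build_lvc_from_scan",
    "read_scan_json",
    "write_scan_json",
    "read_scan_text",
    "write_scan_text",
]


@dataclasses.dataclass(frozen=True)
class ScanPoint:
    """Adiabatic data at one displaced geometry.

    ``overlap[k, l]`` is the overlap of reference diabatic state ``k`` with
    the ``l``-th adiabatic state at the displaced geometry; ``energies`` are
    the adiabatic energies in ascending order (eV).
    """

    energies: np.ndarray
    overlap: np.ndarray

    def __post_init__(self) -> None:
        e = np.atleast_1d(np.asarray(self.energies, dtype=float))
        S = np.asarray(self.overlap, dtype=float)
        if S.ndim != 2 or S.shape[0] != S.shape[1]:
            raise ValueError("overlap must be a square matrix")
        if e.shape != (S.shape[0],):
            raise ValueError("energies length must match overlap dimension")
        if np.any(np.diff(e) < 0):
            raise ValueError("adiabatic energies must be ascending")
        e.setflags(write=False)
        S = S.copy()
        S.setflags(write=False)
        object.__setattr__(self, "energies", e)
        object.__setattr__(self, "overlap", S)

    def orthogonality_defect(self) -> float:
        """``max |S^T S - I|`` — how far the overlap is from orthogonal."""
        S = self.overlap
        return float(np.max(np.abs(S.T @ S - np.eye(S.shape[0]))))


@dataclasses.dataclass(frozen=True)
class AdiabaticScan:
    """Collection of ±delta scan points, one pair per normal mode.

    ``points`` maps ``(mode_index, sign)`` with sign in {+1, -1} to a
    :class:`ScanPoint`.  ``delta`` is the dimensionless displacement, a
    scalar or a per-mode array.  Reference-point data (``E0``, ``dipoles``,
    ``state_labels``) may ride along so a scan file is self-contained.
    """

    basis: NormalModeBasis
    delta: np.ndarray
    points: Mapping[tuple[int, int], ScanPoint]
    E0: np.ndarray | None = None
    dipoles: np.ndarray | None = None
    state_labels: tuple[str, ...] | None = None
    orthogonality_tol: float = 1e-2

    def __post_init__(self) -> None:
        delta = np.broadcast_to(
            np.asarray(self.delta, dtype=float), (self.basis.nmodes,)
        ).copy()
        if np.any(delta <= 0):
            raise ValueError("delta must be positive")
        delta.setflags(write=False)
        object.__setattr__(self, "delta", delta)
        object.__setattr__(self, "points", dict(self.points))
        for (mode, sign), pt in self.points.items():
            if not 0 <= mode < self.basis.nmodes or sign not in (+1, -1):
                raise ValueError(f"invalid scan point key ({mode}, {sign})")
            defect = pt.orthogonality_defect()
            if defect > self.orthogonality_tol:
                logger.warning(
                    "overlap at mode %d sign %+d deviates from orthogonality "
                    "by %.3g (tol %.3g)", mode, sign, defect, self.orthogonality_tol,
                )
        if self.E0 is not None:
            e0 = np.atleast_1d(np.asarray(self.E0, dtype=float))
            e0.setflags(write=False)
            object.__setattr__(self, "E0", e0)
        if self.dipoles is not None:
            mu = np.asarray(self.dipoles, dtype=float)
            mu.setflags(write=False)
            object.__setattr__(self, "dipoles", mu)

    @property
    def nstates(self) -> int:
        return next(iter(self.points.values())).energies.size

    def point(self, mode: int, sign: int) -> ScanPoint:
        try:
            return self.points[(mode, sign)]
        except KeyError:
            raise KeyError(f"scan is missing the point (mode={mode}, sign={sign:+d})") from None


@dataclasses.dataclass(frozen=True)
class DiabatizationResult:
    """An assembled LVC model plus per-point diagnostics.

    ``D_matrices`` maps ``(mode, sign)`` to the orthogonal transformation
    used at that point; ``residuals`` maps the same keys to a dict with the
    overlap orthogonality defect and the Frobenius diabaticity residual
    ``|D - S|_F`` (how much Procrustes had to correct the raw overlap).
    """

    model: LVCModel
    D_matrices: dict[tuple[int, int], np.ndarray]
    residuals: dict[tuple[int, int], dict[str, float]]


def max_overlap_transformation(
    S: np.ndarray,
    *,
    force_rotation: bool = False,
    rank_tol: float = 1e-8,
    label: str = "",
) -> np.ndarray:
    """Orthogonal matrix maximizing Frobenius similarity to ``S``.

    Solves the orthogonal Procrustes problem via the SVD ``S = U Sigma V^T``,
    returning ``D = U V^T`` (for near-orthogonal ``S`` this coincides with
    Loewdin symmetric orthogonalization).  A reflection (det = -1) is
    accepted by default, since the diabatic basis may legitimately pick up a
    sign; ``force_rotation=True`` flips the weakest singular direction to
    force det = +1.

    Raises ``ValueError`` when ``S`` is rank deficient (smallest singular
    value below ``rank_tol``), which signals state crossings or intruder
    states at that displacement.
    """
    S = np.asarray(S, dtype=float)
    if S.ndim != 2 or S.shape[0] != S.shape[1]:
        raise ValueError("overlap matrix must be square")
    U, sigma, Vt = np.linalg.svd(S)
    if sigma[-1] < rank_tol:
        where = f" at {label}" if label else ""
        raise ValueError(
            f"overlap matrix{where} is rank deficient "
            f"(smallest singular value {sigma[-1]:.3g} < {rank_tol:.3g}); "
            "likely state crossing or intruder state"
        )
    D = U @ Vt
    if force_rotation and np.linalg.det(D) < 0:
        U = U.copy()
        U[:, -1] *= -1.0
        D = U @ Vt
    return D


def diabatize_point(
    energies: Sequence[float],
    D: np.ndarray,
    *,
    orthogonality_tol: float = 1e-6,
) -> np.ndarray:
    """Rotate adiabatic energies into the diabatic representation.

    With ``D[k, l] = <d_k | a_l>`` the diabatic potential matrix is
    ``V_dia = D diag(E) D^T``; it is symmetric with trace equal to the sum
    of the adiabatic energies.
    """
    e = np.atleast_1d(np.asarray(energies, dtype=float))
    D = np.asarray(D, dtype=float)
    if D.shape != (e.size, e.size):
        raise ValueError("dimension mismatch between energies and D")
    defect = np.max(np.abs(D.T @ D - np.eye(e.size)))
    if defect > orthogonality_tol:
        raise ValueError(
            f"transformation is not orthogonal (defect {defect:.3g} > "
            f"{orthogonality_tol:.3g})"
        )
    V = (D * e) @ D.T
    return 0.5 * (V + V.T)


def central_difference_lambda(
    Vdia_plus: np.ndarray,
    Vdia_minus: np.ndarray,
    delta: float,
) -> np.ndarray:
    """Central-difference gradient ``(V(+d) - V(-d)) / (2 d)`` (eV per unit q).

    Exact for LVC-form potentials, whose matrix elements contain no odd
    terms in q beyond the linear one.
    """
    if delta <= 0:
        raise ValueError("delta must be positive")
    Vp = np.asarray(Vdia_plus, dtype=float)
    Vm = np.asarray(Vdia_minus, dtype=float)
    if Vp.shape != Vm.shape:
        raise ValueError("matrices must have the same shape")
    return (Vp - Vm) / (2.0 * delta)


def _fix_phases(S: np.ndarray) -> np.ndarray:
    """Flip adiabatic-state signs so diag(S) is non-negative.

    Electronic-structure eigenvectors carry arbitrary signs; this removes
    them before Procrustes.  The rotated diabatic potential is invariant
    under these flips, so the fix only stabilizes the diagnostics.
    """
    signs = np.where(np.diag(S) < 0, -1.0, 1.0)
    return S * signs


def build_lvc_from_scan(
    scan: AdiabaticScan,
    E0: Sequence[float] | None = None,
    dipoles: np.ndarray | None = None,
    *,
    state_labels: Sequence[str] | None = None,
    force_rotation: bool = False,
) -> DiabatizationResult:
    """Assemble an LVC model from a full ±delta adiabatic scan.

    ``E0`` are the reference-point adiabatic energies (the model's vertical
    energies); they and the dipoles default to the values carried by the
    scan.  Fails loudly (with mode/sign context) on missing points or
    rank-deficient overlaps.
    """
    if E0 is None:
        E0 = scan.E0
    if E0 is None:
        raise ValueError("E0 must be given or carried by the scan")
    E0 = np.atleast_1d(np.asarray(E0, dtype=float))
    n = scan.nstates
    if E0.shape != (n,):
        raise ValueError(f"E0 has shape {E0.shape}, expected ({n},)")
    if dipoles is None:
        dipoles = scan.dipoles
    if dipoles is None:
        dipoles = np.zeros((n, 3))
    if state_labels is None:
        state_labels = scan.state_labels

    f = scan.basis.nmodes
    lambda_diag = np.zeros((n, f))
    lambda_offdiag = np.zeros((n, n, f))
    D_matrices: dict[tuple[int, int], np.ndarray] = {}
    residuals: dict[tuple[int, int], dict[str, float]] = {}

    for mode in range(f):
        Vdia = {}
        for sign in (+1, -1):
            pt = scan.point(mode, sign)
            if pt.energies.size != n:
                raise ValueError(
                    f"scan point (mode={mode}, sign={sign:+d}) has "
                    f"{pt.energies.size} states, expected {n}"
                )
            S = _fix_phases(pt.overlap)
            D = max_overlap_transformation(
                S, force_rotation=force_rotation,
                label=f"mode {mode}, sign {sign:+d}",
            )
            D_matrices[(mode, sign)] = D
            residuals[(mode, sign)] = {
                "orthogonality_defect": pt.orthogonality_defect(),
                "diabaticity_residual": float(np.linalg.norm(D - S)),
            }
            Vdia[sign] = diabatize_point(pt.energies, D)
        lam = central_difference_lambda(Vdia[+1], Vdia[-1], scan.delta[mode])
        lam = 0.5 * (lam + lam.T)
        lambda_diag[:, mode] = np.diag(lam)
        off = lam.copy()
        np.fill_diagonal(off, 0.0)
        lambda_offdiag[:, :, mode] = off
        logger.debug(
            "mode %d: diabaticity residuals %+d: %.3g, %-d: %.3g",
            mode, 1, residuals[(mode, 1)]["diabaticity_residual"],
            -1, residuals[(mode, -1)]["diabaticity_residual"],
        )

    model = LVCModel(
        basis=scan.basis,
        E0=E0,
        lambda_diag=lambda_diag,
        lambda_offdiag=lambda_offdiag,
        dipoles=dipoles,
        state_labels=tuple(state_labels) if state_labels else (),
    )
    return DiabatizationResult(model=model, D_matrices=D_matrices, residuals=residuals)


# ---------------------------------------------------------------------------
# Scan file formats
# ---------------------------------------------------------------------------

def _scan_to_dict(scan: AdiabaticScan) -> dict:
    return {
        "schema_version": SCAN_SCHEMA_VERSION,
        "nstates": scan.nstates,
        "nmodes": scan.basis.nmodes,
        "frequencies_ev": scan.basis.frequencies.tolist(),
        "mode_labels": list(scan.basis.labels),
        "delta": scan.delta.tolist(),
        "points": [
            {
                "mode": mode,
                "sign": sign,
                "energies_ev": pt.energies.tolist(),
                "overlap": pt.overlap.tolist(),
            }
            for (mode, sign), pt in sorted(scan.points.items())
        ],
        "reference_E0_ev": scan.E0.tolist() if scan.E0 is not None else None,
        "reference_dipoles_au": scan.dipoles.tolist() if scan.dipoles is not None else None,
        "state_labels": list(scan.state_labels) if scan.state_labels else None,
    }


def _scan_from_dict(data: dict) -> AdiabaticScan:
    if data.get("schema_version") != SCAN_SCHEMA_VERSION:
        raise ValueError(f"unsupported scan schema version: {data.get('schema_version')!r}")
    basis = NormalModeBasis(
        frequencies=np.asarray(data["frequencies_ev"], dtype=float),
        labels=tuple(data["mode_labels"]),
    )
    points = {
        (int(p["mode"]), int(p["sign"])): ScanPoint(
            energies=np.asarray(p["energies_ev"], dtype=float),
            overlap=np.asarray(p["overlap"], dtype=float),
        )
        for p in data["points"]
    }
    return AdiabaticScan(
        basis=basis,
        delta=np.asarray(data["delta"], dtype=float),
        points=points,
        E0=np.asarray(data["reference_E0_ev"], dtype=float)
        if data.get("reference_E0_ev") is not None else None,
        dipoles=np.asarray(data["reference_dipoles_au"], dtype=float)
        if data.get("reference_dipoles_au") is not None else None,
        state_labels=tuple(data["state_labels"]) if data.get("state_labels") else None,
    )


def write_scan_json(scan: AdiabaticScan, path: str | Path) -> None:
    Path(path).write_text(json.dumps(_scan_to_dict(scan), indent=1) + "\n")


def read_scan_json(path: str | Path) -> AdiabaticScan:
    return _scan_from_dict(json.loads(Path(path).read_text()))


def write_scan_text(scan: AdiabaticScan, path: str | Path) -> None:
    """Plain-text scan variant: one block per point, for hand-made fixtures."""
    lines = [
        f"# adiabatic scan, {scan.nstates} states, {scan.basis.nmodes} modes",
        "frequencies_ev: " + " ".join(f"{w:.17g}" for w in scan.basis.frequencies),
        "delta: " + " ".join(f"{d:.17g}" for d in scan.delta),
    ]
    for (mode, sign), pt in sorted(scan.points.items()):
        lines.append(f"point mode={mode} sign={sign:+d}")
        lines.append("energies: " + " ".join(f"{e:.17g}" for e in pt.energies))
        lines.append("overlap:")
        for row in pt.overlap:
            lines.append("  " + " ".join(f"{x:.17g}" for x in row))
    Path(path).write_text("\n".join(lines) + "\n")


def read_scan_text(path: str | Path) -> AdiabaticScan:
    lines = [
        ln for ln in Path(path).read_text().splitlines()
        if ln.strip() and not ln.lstrip().startswith("#")
    ]
    freq = delta = None
    points: dict[tuple[int, int], ScanPoint] = {}
    i = 0
    while i < len(lines):
        ln = lines[i].strip()
        if ln.startswith("frequencies_ev:"):
            freq = np.array([float(x) for x in ln.split(":", 1)[1].split()])
            i += 1
        elif ln.startswith("delta:"):
            delta = np.array([float(x) for x in ln.split(":", 1)[1].split()])
            i += 1
        elif ln.startswith("point"):
            fields = dict(part.split("=") for part in ln.split()[1:])
            mode, sign = int(fields["mode"]), int(fields["sign"])
            energies = np.array(
                [float(x) for x in lines[i + 1].split(":", 1)[1].split()]
            )
            n = energies.size
            rows = [
                [float(x) for x in lines[i + 3 + k].split()] for k in range(n)
            ]
            points[(mode, sign)] = ScanPoint(energies=energies, overlap=np.array(rows))
            i += 3 + n
        else:
            raise ValueError(f"unrecognized line in scan file: {ln!r}")
    if freq is None or delta is None:
        raise ValueError("scan file is missing frequencies_ev or delta")
    return AdiabaticScan(basis=NormalModeBasis(frequencies=freq), delta=delta, points=points)
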