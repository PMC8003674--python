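"""Absorption spectra from autocorrelation functions and stick tables.

The vibronic spectrum is obtained by damped Fourier transform of the sum of
doorway-state autocorrelation functions weighted by |transition dipole|^2,
with a quadratic time-domain damping ``exp(-Gamma t^2 / hbar^2)`` that is a
Gaussian broadening of half width ``2 sqrt(Gamma ln 2)`` in the frequency
domain.  Cross-correlation terms are available behind a flag but are off by
default: their effect is usually negligible.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import math
from pathlib import Path
from typing import Sequence

import numpy as np

from .constants import EPSILON_PREFACTOR, HBAR_EV_FS
from .lvc import LVCModel
from .propagation import PropagationResult

logger = logging.getLogger(__name__)

__all__ = [
    "Spectrum",
    "hwhm_to_gamma",
    "gamma_to_hwhm",
    "default_grid",
    "autocorrelation_to_spectrum",
    "stick_spectrum",
    "shift_normalize_combine",
    "read_spectrum_tsv",
    "write_spectrum_tsv",
]

DEFAULT_NPOINTS = 2048
#: Negative ripple below this fraction of the maximum is clipped to zero.
CLIP_FRACTION = 1e-6


@dataclasses.dataclass
class Spectrum:
    """Frequency grid (eV, uniform, increasing) and intensity.

    ``epsilon`` is in M^-1 cm^-1 when produced with absolute units and
    dipoles in a.u.; arbitrary units otherwise (see ``meta['units']``).
    """

    omega: np.ndarray
    epsilon: np.ndarray
    meta: dict = dataclasses.field(default_factory=dict)

    def __post_init__(self) -> None:
        w = np.asarray(self.omega, dtype=float)
        e = np.asarray(self.epsilon, dtype=float)
        if w.shape != e.shape or w.ndim != 1:
            raise ValueError("omega and epsilon must be matching 1-D arrays")
        dw = np.diff(w)
        if np.any(dw <= 0):
            raise ValueError("frequency grid must be strictly increasing")
        if not np.allclose(dw, dw[0], rtol=1e-9, atol=0.0):
            raise ValueError("frequency grid must be uniform")
        peak = float(np.max(np.abs(e))) if e.size else 0.0
        neg = e < 0
        if np.any(neg):
            worst = float(-np.min(e))
            if worst > CLIP_FRACTION * peak:
                raise ValueError(
                    f"negative intensity {worst:.3g} exceeds the clipping "
                    f"tolerance ({CLIP_FRACTION:g} of the maximum)"
                )
            logger.debug("clipped negative ripple of %.3g (max %.3g)", worst, peak)
            e = np.where(neg, 0.0, e)
        self.omega = w
        self.epsilon = e

    @property
    def spacing(self) -> float:
        return float(self.omega[1] - self.omega[0])


def hwhm_to_gamma(hwhm: float) -> float:
    """Quadratic damping parameter (eV^2) for a Gaussian HWHM (eV).

    ``Gamma = hwhm^2 / (4 ln 2)``: damping ``exp(-Gamma t^2/hbar^2)``
    transforms to a frequency-domain Gaussian of the given half width at
    half maximum.
    """
    if hwhm <= 0:
        raise ValueError("hwhm must be positive")
    return hwhm**2 / (4.0 * math.log(2.0))


def gamma_to_hwhm(gamma: float) -> float:
    """Inverse of :func:`hwhm_to_gamma`."""
    if gamma <= 0:
        raise ValueError("gamma must be positive")
    return 2.0 * math.sqrt(gamma * math.log(2.0))


def default_grid(
    model: LVCModel,
    npoints: int = DEFAULT_NPOINTS,
    pad_below: float = 1.0,
    pad_above: float = 2.0,
) -> np.ndarray:
    """Uniform energy grid spanning [min(E0) - pad_below, max(E0) + pad_above]."""
    return np.linspace(
        float(np.min(model.E0)) - pad_below,
        float(np.max(model.E0)) + pad_above,
        npoints,
    )


def _damped_ft(
    times: np.ndarray,
    corr: np.ndarray,
    gamma: float,
    omega: np.ndarray,
) -> np.ndarray:
    """``Int_-inf^inf dt e^{i w t/hbar - Gamma t^2/hbar^2} C(t)`` in fs.

    Uses the Hermitian extension ``C(-t) = C(t)*`` so the full-line integral
    is ``2 Re Int_0^inf``; evaluated by trapezoidal quadrature directly on
    the requested (possibly incommensurate) frequency grid.
    """
    t = np.asarray(times, dtype=float)
    dt = np.diff(t)
    if t.size < 2 or np.any(dt <= 0) or not np.allclose(dt, dt[0], rtol=1e-9):
        raise ValueError("time grid must be uniform, increasing, from t = 0")
    if abs(t[0]) > 1e-12:
        raise ValueError("time grid must start at t = 0")
    weights = np.full(t.size, dt[0])
    weights[0] = weights[-1] = 0.5 * dt[0]
    g = corr * np.exp(-gamma * (t / HBAR_EV_FS) ** 2) * weights
    out = np.empty(omega.size)
    # chunked to bound the phase-matrix memory footprint
    chunk = max(1, int(4e6 // t.size))
    for lo in range(0, omega.size, chunk):
        block = omega[lo:lo + chunk]
        phases = np.exp(1j * np.outer(block, t) / HBAR_EV_FS)
        out[lo:lo + chunk] = 2.0 * np.real(phases @ g)
    return out


def autocorrelation_to_spectrum(
    results: PropagationResult | Sequence[PropagationResult],
    model: LVCModel,
    states: int | str | Sequence[int | str],
    gamma: float,
    grid: np.ndarray | None = None,
    *,
    cross_terms: bool = False,
    absolute_units: bool = True,
    shift: float = 0.0,
) -> Spectrum:
    """Fourier-transform doorway autocorrelations into an absorption spectrum.

    ``results`` and ``states`` pair each propagation with the doorway state
    it started from; the contribution of each is weighted by
    |dipole(state)|^2.  With ``cross_terms=True`` the stored doorway
    cross-correlations add the (usually negligible) interference terms
    weighted by dipole scalar products.  Output is in M^-1 cm^-1 for
    ``absolute_units=True`` and dipoles in a.u.
    """
    if isinstance(results, PropagationResult):
        results = [results]
    if isinstance(states, (int, str)):
        states = [states]
    if len(results) != len(states):
        raise ValueError("results and states must have equal length")
    if grid is None:
        grid = default_grid(model)
    grid = np.asarray(grid, dtype=float)

    total = np.zeros(grid.size)
    contributions = []
    for res, state in zip(results, states):
        i = model.state_index(state)
        mu_i = model.dipoles[i]
        w2 = float(np.dot(mu_i, mu_i))
        if w2 == 0.0:
            logger.warning("state %s has a vanishing transition dipole", state)
        total += w2 * _damped_ft(res.times, res.autocorr, gamma, grid)
        contributions.append({"state": int(i), "weight_mu2_au": w2})
        if cross_terms:
            if res.crosscorr is None:
                raise ValueError(
                    "cross_terms requested but the propagation result has no "
                    "stored cross-correlations"
                )
            for j in range(model.nstates):
                if j == i:
                    continue
                wij = float(np.dot(model.dipoles[j], mu_i))
                if wij == 0.0:
                    continue
                total += wij * _damped_ft(res.times, res.crosscorr[j], gamma, grid)

    prefactor = EPSILON_PREFACTOR if absolute_units else 1.0
    epsilon = prefactor * grid * total
    meta = {
        "gamma_ev2": gamma,
        "hwhm_ev": gamma_to_hwhm(gamma),
        "shift_ev": shift,
        "normalization": "none",
        "units": "M^-1 cm^-1" if absolute_units else "arbitrary",
        "cross_terms": cross_terms,
        "contributions": contributions,
    }
    spec = Spectrum(omega=grid, epsilon=epsilon, meta=meta)
    if shift != 0.0:
        spec = shift_normalize_combine([spec], shifts=[shift], normalization="none")
        spec.meta.update(meta)
        spec.meta["shift_ev"] = shift
    return spec


def stick_spectrum(
    E: Sequence[float],
    f: Sequence[float],
    hwhm: float,
    grid: np.ndarray | None = None,
    npoints: int = DEFAULT_NPOINTS,
) -> Spectrum:
    """Pure-electronic spectrum: Gaussians at ``E_k`` with areas ``prop. f_k``.

    The classical Franck-Condon-principle baseline: no vibrational
    structure, just phenomenologically broadened vertical transitions.
    """
    E = np.atleast_1d(np.asarray(E, dtype=float))
    f = np.atleast_1d(np.asarray(f, dtype=float))
    if E.shape != f.shape:
        raise ValueError("E and f must have equal length")
    if hwhm <= 0:
        raise ValueError("hwhm must be positive")
    if grid is None:
        grid = np.linspace(float(E.min()) - 1.0, float(E.max()) + 2.0, npoints)
    grid = np.asarray(grid, dtype=float)
    sigma = hwhm / math.sqrt(2.0 * math.log(2.0))
    eps = np.zeros(grid.size)
    for ek, fk in zip(E, f):
        eps += fk / (sigma * math.sqrt(2.0 * math.pi)) * np.exp(
            -((grid - ek) ** 2) / (2.0 * sigma**2)
        )
    meta = {
        "hwhm_ev": hwhm,
        "shift_ev": 0.0,
        "normalization": "none",
        "units": "arbitrary",
        "sticks": [{"E_ev": float(e), "f": float(x)} for e, x in zip(E, f)],
    }
    return Spectrum(omega=grid, epsilon=eps, meta=meta)


def shift_normalize_combine(
    spectra: Sequence[Spectrum],
    shifts: Sequence[float] | None = None,
    weights: Sequence[float] | None = None,
    normalization: str = "max",
    grid: np.ndarray | None = None,
) -> Spectrum:
    """Shift each spectrum along the energy axis, combine and normalize.

    A shift ``s`` moves features from ``E`` to ``E + s`` (so published
    red shifts are negative).  ``normalization`` is ``"max"`` (peak to 1,
    as in "normalised to 1" figure captions), ``"area"`` (unit integral) or
    ``"none"``.  Spectra are resampled onto ``grid`` (default: grid of the
    first spectrum) by linear interpolation, zero outside their support.
    """
    if not spectra:
        raise ValueError("need at least one spectrum")
    shifts = list(shifts) if shifts is not None else [0.0] * len(spectra)
    weights = list(weights) if weights is not None else [1.0] * len(spectra)
    if len(shifts) != len(spectra) or len(weights) != len(spectra):
        raise ValueError("shifts and weights must match the number of spectra")
    if any(w < 0 for w in weights):
        raise ValueError("weights must be non-negative")
    if grid is None:
        grid = spectra[0].omega
    grid = np.asarray(grid, dtype=float)

    total = np.zeros(grid.size)
    for spec, s, w in zip(spectra, shifts, weights):
        total += w * np.interp(grid, spec.omega + s, spec.epsilon, left=0.0, right=0.0)

    if normalization == "max":
        peak = float(np.max(total))
        if peak > 0:
            total = total / peak
    elif normalization == "area":
        area = float(np.trapezoid(total, grid))
        if area > 0:
            total = total / area
    elif normalization != "none":
        raise ValueError(f"unknown normalization mode {normalization!r}")

    meta = {
        "shifts_ev": shifts,
        "weights": weights,
        "normalization": normalization,
        "units": "normalized" if normalization != "none" else
        spectra[0].meta.get("units", "arbitrary"),
        "inputs": [dict(s.meta) for s in spectra],
    }
    return Spectrum(omega=grid, epsilon=total, meta=meta)


# ---------------------------------------------------------------------------
# TSV + JSON-sidecar I/O
# ---------------------------------------------------------------------------

def write_spectrum_tsv(spec: Spectrum, path: str | Path) -> None:
    """Two-column TSV with header comments; full metadata in a .json sidecar."""
    path = Path(path)
    header_lines = ["energy_eV\tepsilon"]
    for key in ("gamma_ev2", "hwhm_ev", "shift_ev", "normalization", "units"):
        if key in spec.meta:
            header_lines.insert(0, f"# {key} = {spec.meta[key]}")
    np.savetxt(
        path,
        np.column_stack([spec.omega, spec.epsilon]),
        delimiter="\t",
        header="\n".join(header_lines),
        comments="",
    )
    path.with_suffix(path.suffix + ".json").write_text(
        json.dumps(spec.meta, indent=1, default=str) + "\n"
    )


def read_spectrum_tsv(path: str | Path) -> Spectrum:
    path = Path(path)
    rows = []
    for line in path.read_text().splitlines():
        s = line.strip()
        if not s or s.startswith("#"):
            continue
        parts = s.split("\t")
        try:
            rows.append((float(parts[0]), float(parts[1])))
        except (ValueError, IndexError):
            continue  # column-header row
    arr = np.asarray(rows, dtype=float)
    meta: dict = {}
    sidecar = path.with_suffix(path.suffix + ".json")
    if sidecar.exists():
        meta = json.loads(sidecar.read_text())
    return Spectrum(omega=arr[:, 0], epsilon=arr[:, 1], meta=meta)
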