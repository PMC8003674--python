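"""Diabatic population analysis: decay fits and transfer timescales."""

from __future__ import annotations

import dataclasses
import math
from typing import Sequence

import numpy as np
import pandas as pd
import scipy.optimize

from .propagation import PropagationResult

__all__ = [
    "DecayFit",
    "fit_exponential_decay",
    "half_transfer_time",
    "population_report",
]

#: tau larger than this multiple of the fit window flags a non-decaying trace.
NON_DECAYING_FACTOR = 100.0


@dataclasses.dataclass(frozen=True)
class DecayFit:
    """Mono-exponential fit ``P(t) = baseline + amplitude * exp(-t / tau)``.

    ``completion`` is the percentage of the initial population lost by the
    end of the window, computed from the raw trace.  ``non_decaying`` flags
    traces where the fitted tau exceeds 100x the window (the fit parameters
    are still reported).
    """

    tau: float
    amplitude: float
    baseline: float
    completion: float
    rmse: float
    non_decaying: bool = False

    def __post_init__(self) -> None:
        if self.tau <= 0:
            raise ValueError("tau must be positive")
        if not 0.0 <= self.completion <= 100.0:
            raise ValueError("completion must be in [0, 100]")

    def evaluate(self, times: Sequence[float]) -> np.ndarray:
        t = np.asarray(times, dtype=float)
        return self.baseline + self.amplitude * np.exp(-t / self.tau)


def fit_exponential_decay(
    times: Sequence[float],
    P: Sequence[float],
    tau_starts: Sequence[float] = (10.0, 50.0, 200.0),
) -> DecayFit:
    """Least-squares mono-exponential fit of a population trace.

    Nonlinear least squares with multi-start initialization of tau to avoid
    local minima; the baseline is free, since populations need not decay to
    zero.
    """
    t = np.asarray(times, dtype=float)
    P = np.asarray(P, dtype=float)
    if t.shape != P.shape or t.ndim != 1:
        raise ValueError("times and P must be matching 1-D arrays")
    if t.size < 10:
        raise ValueError("need at least 10 samples for a decay fit")
    if np.any(P < -1e-9) or np.any(P > 1.0 + 1e-9):
        raise ValueError("populations must lie in [0, 1]")

    window = float(t[-1] - t[0])
    tau_cap = 1e4 * max(window, 1.0)

    def residuals(params: np.ndarray) -> np.ndarray:
        b, a, tau = params
        return b + a * np.exp(-t / tau) - P

    best = None
    for tau0 in tau_starts:
        p0 = np.array([P[-1], max(P[0] - P[-1], 1e-6), tau0])
        try:
            sol = scipy.optimize.least_squares(
                residuals, p0,
                bounds=([-1.0, -2.0, 1e-8], [2.0, 2.0, tau_cap]),
                xtol=1e-14, ftol=1e-14, gtol=1e-14,
            )
        except ValueError:
            continue
        if best is None or sol.cost < best.cost:
            best = sol
    if best is None:
        raise RuntimeError("exponential fit failed for all starting points")

    baseline, amplitude, tau = best.x
    rmse = float(np.sqrt(np.mean(best.fun**2)))
    p_start = float(P[0])
    completion = (
        100.0 * (p_start - float(P[-1])) / p_start if p_start > 0 else 0.0
    )
    completion = min(max(completion, 0.0), 100.0)
    non_decaying = tau > NON_DECAYING_FACTOR * window or amplitude <= 1e-6
    return DecayFit(
        tau=float(tau),
        amplitude=float(amplitude),
        baseline=float(baseline),
        completion=completion,
        rmse=rmse,
        non_decaying=bool(non_decaying),
    )


def half_transfer_time(times: Sequence[float], P: Sequence[float]) -> float | None:
    """First time at which P(t) drops to half its initial value.

    Linearly interpolated between samples; ``None`` if the trace never
    reaches P(0)/2.
    """
    t = np.asarray(times, dtype=float)
    P = np.asarray(P, dtype=float)
    if t.shape != P.shape or t.ndim != 1:
        raise ValueError("times and P must be matching 1-D arrays")
    target = 0.5 * P[0]
    below = np.flatnonzero(P <= target)
    if below.size == 0:
        return None
    k = int(below[0])
    if k == 0:
        return float(t[0])
    # linear interpolation between samples k-1 and k
    frac = (P[k - 1] - target) / (P[k - 1] - P[k])
    return float(t[k - 1] + frac * (t[k] - t[k - 1]))


def population_report(
    result: PropagationResult,
    checkpoints: Sequence[float] = (25.0, 50.0, 100.0, 250.0),
) -> pd.DataFrame:
    """Tabular summary of a propagation: per-state decay metrics.

    One row per diabatic state with initial population, populations at the
    checkpoint times (grid-interpolated, NaN beyond the stored window), the
    fitted tau (NaN when the trace is flagged non-decaying), the
    half-transfer time and the closure residual ``max_t |sum_i P_i - 1|``.
    """
    t = result.times
    labels = result.meta.get(
        "state_labels", [f"S{i + 1}" for i in range(result.nstates)]
    )
    closure = float(np.max(np.abs(result.populations.sum(axis=1) - result.norm_trace**2)))
    rows = []
    for i in range(result.nstates):
        P = result.populations[:, i]
        row: dict = {"state": labels[i], "P0": float(P[0])}
        for tc in checkpoints:
            key = f"P{int(tc) if float(tc).is_integer() else tc}fs"
            row[key] = (
                float(np.interp(tc, t, P)) if t[0] <= tc <= t[-1] else math.nan
            )
        try:
            fit = fit_exponential_decay(t, np.clip(P, 0.0, 1.0))
            row["tau_fs"] = math.nan if fit.non_decaying else fit.tau
        except (ValueError, RuntimeError):
            row["tau_fs"] = math.nan
        th = half_transfer_time(t, P)
        row["t_half_fs"] = math.nan if th is None else th
        row["closure"] = closure
        rows.append(row)
    return pd.DataFrame(rows)
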