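"""Hook-curve analysis: Σ/Δ transforms, the two-species Langmuir hook model,
hook fitting and hybridization-regime classification.

The hook method summarizes one array by plotting, per probe set, the mean
PM/MM log-intensity difference Δ against the mean log-intensity level Σ
(log ≡ log10 throughout).  With increasing Σ the smoothed curve traverses
five hybridization regimes — N (non-specific only), mix, S (specific),
sat (saturation) and as (asymptotic) — and its geometry encodes chip-level
hybridization parameters:

* ``alpha`` — height of the hook, the log10 PM/MM gap of specific binding;
* ``beta`` — width, set by the non-specific background level (logM − Σ_start);
* ``sigma_start`` — Σ of the N-regime (start point);
* ``logM`` — asymptotic saturation level (end point).

The theoretical curve is parameterized by the specific-to-non-specific
binding ratio R of a probe set:

    Δ(R) = log[(R+1)/(R·10^{-α}+1)] − log[B_PM(R)/B_MM(R)]
    Σ(R) = Σ_start + ½·log[(R+1)·(R·10^{-α}+1)] − ½·log[B_PM(R)·B_MM(R)]

with saturation terms B_PM(R) = 1 + 10^{−β+Δ_start/2}·(R+1) and
B_MM(R) = 1 + 10^{−β−Δ_start/2}·(R·10^{−α}+1).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

from .probe_model import ChipData

logger = logging.getLogger(__name__)

REGIMES = ("N", "mix", "S", "sat", "as")

#: R boundaries of the N and mix regimes (the S/sat/as boundaries follow
#: from the fitted curve, see :func:`regime_boundaries`)
R_N_MAX = 0.1
R_MIX_MAX = 1.0


class HookError(RuntimeError):
    """Raised when a hook curve cannot be fitted."""


@dataclass
class HookCurve:
    """Smoothed per-probe-set hook points, ordered by Σ."""

    sigma: np.ndarray
    delta: np.ndarray
    window_sizes: np.ndarray

    def __post_init__(self) -> None:
        if not np.all(np.isfinite(self.sigma)) or not np.all(np.isfinite(self.delta)):
            raise ValueError("hook curve contains non-finite values")
        if np.any(np.diff(self.sigma) < 0):
            raise ValueError("hook curve Σ must be non-decreasing")


@dataclass
class HookFit:
    """Fitted hook parameters and derived chip summaries."""

    alpha: float
    beta: float
    sigma_start: float
    delta_start: float = 0.0
    pct_absent: float = float("nan")
    phi: float = float("nan")
    converged: bool = True
    residual_norm: float = float("nan")
    message: str = ""

    @property
    def logM(self) -> float:
        return self.sigma_start + self.beta

    def __post_init__(self) -> None:
        if self.alpha < 0:
            raise ValueError("alpha must be >= 0")
        if self.beta <= 0:
            raise ValueError("beta must be > 0 (logM > sigma_start)")


# ---------------------------------------------------------------------- #
# transforms


def sigma_delta(pm, mm):
    """Hook coordinates of single probes: Σ = ½(log pm + log mm), Δ = log pm − log mm."""
    pm = np.asarray(pm, dtype=float)
    mm = np.asarray(mm, dtype=float)
    if np.any(pm <= 0) or np.any(mm <= 0):
        bad = int(np.argmax((pm <= 0) | (mm <= 0)))
        raise ValueError(f"non-positive intensity at probe {bad}")
    lp, lm = np.log10(pm), np.log10(mm)
    return 0.5 * (lp + lm), lp - lm


def probeset_hook_points(chip: ChipData) -> pd.DataFrame:
    """Per-probe-set (Σ, Δ) with per-set mean log PM/MM, sorted by Σ.

    Returns a DataFrame indexed by probeset_id with columns ``sigma, delta,
    log_pm, log_mm`` (set means).
    """
    df = chip.regular
    sig, dlt = sigma_delta(df["pm"].to_numpy(), df["mm"].to_numpy())
    per = pd.DataFrame(
        {
            "probeset_id": df["probeset_id"].to_numpy(),
            "sigma": sig,
            "delta": dlt,
            "log_pm": np.log10(df["pm"].to_numpy()),
            "log_mm": np.log10(df["mm"].to_numpy()),
        }
    )
    out = per.groupby("probeset_id", sort=False).mean(numeric_only=True)
    return out.sort_values("sigma", kind="stable")


def moving_average(
    sigma: np.ndarray,
    values: np.ndarray,
    base_window: int = 1000,
    shrink_tail: bool = True,
) -> HookCurve:
    """Centered moving average of ``values`` along Σ-sorted points.

    The window shrinks linearly to ``base_window/10`` over the top 5 % of Σ
    ranks when ``shrink_tail`` is on, compensating the sparse population of
    the saturation range.  Windows are clipped at the data boundaries.
    """
    sigma = np.asarray(sigma, dtype=float)
    values = np.asarray(values, dtype=float)
    n = len(sigma)
    if n == 0:
        raise ValueError("no points to smooth")
    order = np.argsort(sigma, kind="stable")
    sigma, values = sigma[order], values[order]

    win = np.full(n, min(base_window, n), dtype=float)
    if shrink_tail and n > 20:
        tail = max(int(round(0.05 * n)), 2)
        shrink = np.linspace(1.0, 0.1, tail)
        win[-tail:] = np.maximum(win[-tail:] * shrink, 3)
    half = np.maximum((win // 2).astype(int), 1)

    csum = np.concatenate([[0.0], np.cumsum(values)])
    csig = np.concatenate([[0.0], np.cumsum(sigma)])
    idx = np.arange(n)
    lo = np.maximum(idx - half, 0)
    hi = np.minimum(idx + half + 1, n)
    cnt = hi - lo
    sm_val = (csum[hi] - csum[lo]) / cnt
    sm_sig = (csig[hi] - csig[lo]) / cnt
    order2 = np.argsort(sm_sig, kind="stable")
    return HookCurve(sigma=sm_sig[order2], delta=sm_val[order2], window_sizes=cnt[order2])


# ---------------------------------------------------------------------- #
# theoretical curve


def _saturation_terms(R, alpha, beta, delta_start):
    b_pm = 1.0 + 10.0 ** (-beta + 0.5 * delta_start) * (R + 1.0)
    b_mm = 1.0 + 10.0 ** (-beta - 0.5 * delta_start) * (R * 10.0 ** (-alpha) + 1.0)
    return b_pm, b_mm


def theoretical_hook(R, alpha, beta, sigma_start, delta_start=0.0):
    """Evaluate the theoretical hook curve at S/N ratio(s) R.

    Returns ``(Σ, Δ)`` arrays.  Δ → 0 for R → 0 and R → ∞ (the saturation
    terms cancel the PM/MM gap α at full saturation); Σ rises from
    ``sigma_start`` to ``logM = sigma_start + beta``.
    """
    R = np.asarray(R, dtype=float)
    if np.any(R < 0):
        raise ValueError("R must be >= 0")
    b_pm, b_mm = _saturation_terms(R, alpha, beta, delta_start)
    spec = np.log10((R + 1.0) * (R * 10.0 ** (-alpha) + 1.0))
    delta = (
        np.log10((R + 1.0) / (R * 10.0 ** (-alpha) + 1.0))
        - np.log10(b_pm / b_mm)
        + delta_start
    )
    sigma = sigma_start + 0.5 * spec - 0.5 * np.log10(b_pm * b_mm)
    return sigma, delta


def _log_r_grid(beta: float, n: int = 2000) -> np.ndarray:
    return np.linspace(-4.0, beta + 4.0, n)


def invert_sigma(
    sigma: np.ndarray,
    alpha: float,
    beta: float,
    sigma_start: float,
    delta_start: float = 0.0,
    clip_warn: bool = False,
) -> np.ndarray:
    """Invert the monotone Σ(R) relation: map observed Σ to log10 R.

    Values outside [Σ_start, logM] are clamped to the grid ends.
    """
    grid = _log_r_grid(beta)
    sig_grid, _ = theoretical_hook(10.0**grid, alpha, beta, sigma_start, delta_start)
    sigma = np.asarray(sigma, dtype=float)
    if clip_warn and (np.any(sigma < sig_grid[0]) or np.any(sigma > sig_grid[-1])):
        warnings.warn("Σ values outside [Σ_start, logM]; clamped for R inversion", stacklevel=2)
    return np.interp(sigma, sig_grid, grid)


# ---------------------------------------------------------------------- #
# fitting


def fit_hook(curve: HookCurve, delta_start: float | None = None) -> HookFit:
    """Fit the theoretical hook to a smoothed curve by nonlinear least squares.

    The latent per-point R is eliminated by inverting Σ(R) at the current
    parameters and predicting Δ there.  Initialization: Σ_start from the 2nd
    Σ percentile, logM from the 98th percentile + 0.3, α from max Δ,
    β = logM − Σ_start.  Δ_start is not a free parameter — it trades almost
    exactly against (α, β, Σ_start) and is therefore pinned to its
    operational definition, the Δ level of the N-range (median Δ over the
    lowest 2 % of Σ), unless supplied explicitly.

    Raises
    ------
    HookError
        If the curve has no specific branch (flat Δ) or the fit diverges.
    """
    sig, dlt = curve.sigma, curve.delta
    if sig.max() - sig.min() < 0.2:
        raise HookError("Σ range too narrow to identify hook regimes")
    if dlt.max() < 0.05:
        raise HookError("no specific branch: Δ never rises above noise")

    s0 = float(np.percentile(sig, 2))
    logm0 = float(np.percentile(sig, 98)) + 0.3
    a0 = float(dlt.max())
    b0 = max(logm0 - s0, 0.5)
    if delta_start is None:
        delta_start = float(np.median(dlt[sig <= np.percentile(sig, 2)]))
    dstart = delta_start

    def resid(p):
        a, b, s_start = p
        logr = invert_sigma(sig, a, b, s_start, dstart)
        _, pred = theoretical_hook(10.0**logr, a, b, s_start, dstart)
        return pred - dlt

    p0 = np.clip([a0, b0, s0], [0.0, 0.1, s0 - 2.0], [3.0, 8.0, s0 + 2.0])
    sol = least_squares(
        resid, p0, bounds=([0.0, 0.1, s0 - 2.0], [3.0, 8.0, s0 + 2.0]),
        method="trf", x_scale="jac", xtol=1e-14, ftol=1e-14, gtol=1e-14,
    )
    if not sol.success:
        raise HookError(f"hook fit did not converge: {sol.message}; |r|={np.linalg.norm(sol.fun):.3g}")
    a, b, s_start = sol.x
    return HookFit(
        alpha=float(a),
        beta=float(b),
        sigma_start=float(s_start),
        delta_start=float(dstart),
        converged=True,
        residual_norm=float(np.linalg.norm(sol.fun) / np.sqrt(len(sig))),
        message=sol.message,
    )


# ---------------------------------------------------------------------- #
# regimes and expression index


def regime_boundaries(fit: HookFit) -> tuple[float, float, float, float]:
    """R boundaries (N|mix, mix|S, S|sat, sat|as) from the fitted curve.

    The S/sat boundary is placed at the maximum of the theoretical Δ(R)
    (beyond it saturation bends the hook down); the sat/as boundary where
    Σ(R) comes within 5 % of β below logM.
    """
    grid = _log_r_grid(fit.beta, 4000)
    sig, dlt = theoretical_hook(10.0**grid, fit.alpha, fit.beta, fit.sigma_start, fit.delta_start)
    r_sat = 10.0 ** grid[int(np.argmax(dlt))]
    near_as = sig >= fit.logM - 0.05 * fit.beta
    r_as = 10.0 ** grid[int(np.argmax(near_as))] if near_as.any() else 10.0 ** grid[-1]
    return R_N_MAX, R_MIX_MAX, max(r_sat, R_MIX_MAX), max(r_as, r_sat)


def classify_regimes(per_set_sigma: np.ndarray, fit: HookFit) -> np.ndarray:
    """Label probe sets with their hybridization regime (N/mix/S/sat/as).

    Per-set R is inferred by inverting the fitted Σ(R); Σ outside
    [Σ_start, logM] is clamped with a warning.
    """
    logr = invert_sigma(
        per_set_sigma, fit.alpha, fit.beta, fit.sigma_start, fit.delta_start, clip_warn=True
    )
    r = 10.0**logr
    b_n, b_mix, b_sat, b_as = regime_boundaries(fit)
    labels = np.full(len(r), "S", dtype=object)
    labels[r < b_n] = "N"
    labels[(r >= b_n) & (r < b_mix)] = "mix"
    labels[(r >= b_sat) & (r < b_as)] = "sat"
    labels[r >= b_as] = "as"
    return labels


def pct_absent(labels: np.ndarray) -> float:
    """Fraction of probe sets in the N regime (%N as a fraction in [0,1])."""
    labels = np.asarray(labels)
    return float(np.mean(labels == "N")) if len(labels) else float("nan")


def expression_index(per_set_sigma: np.ndarray, fit: HookFit, labels=None) -> float:
    """Mean expression index φ of present (non-N) probe sets.

    φ = ⟨log R⟩ over present sets + (Σ_start − logM); the additive offset
    pins φ to the logged specific binding strength of the chip (convention).
    """
    if labels is None:
        labels = classify_regimes(per_set_sigma, fit)
    present = np.asarray(labels) != "N"
    if not present.any():
        warnings.warn("no present probe sets: expression index undefined", stacklevel=2)
        return float("nan")
    logr = invert_sigma(
        np.asarray(per_set_sigma)[present], fit.alpha, fit.beta, fit.sigma_start, fit.delta_start
    )
    return float(np.mean(logr) + (fit.sigma_start - fit.logM))


def subtract_optical_background(chip: ChipData, quantile: float = 0.02) -> ChipData:
    """Optional constant-O subtraction: removes the 2nd-percentile intensity.

    A small floor keeps intensities positive.  Use when the input table has
    not been background-corrected upstream.
    """
    df = chip.probes.copy()
    o = float(np.percentile(np.concatenate([df["pm"], df["mm"]]), quantile * 100))
    floor = max(o * 1e-3, 1e-6)
    df["pm"] = np.maximum(df["pm"] - o, floor)
    df["mm"] = np.maximum(df["mm"] - o, floor)
    out = chip.with_probes(df)
    out.metadata["optical_background_subtracted"] = o
    return out
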