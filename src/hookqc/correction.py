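"""Positional, hybridization-mode-aware correction of probe intensities.

Each raw probe intensity is divided by a correction factor

    C(x, y) = d_S(x) · f_s(y) + 1 · (1 − f_s(y))

where ``d_S(x)`` is the fitted specific decay at the probe position
(x = probe offset k−1 or nucleotide distance L), and ``f_s(y) ∈ [0, 1]``
is the degree of specific, unsaturated hybridization of the probe set,
estimated as the relative amplitude of the degradation hook at the set's
mean log intensity ``y``.  Non-specific and fully saturated sets have
f_s ≈ 0 and pass through unchanged; specific unsaturated sets are scaled
up with increasing distance from the 3'-end.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .degradation import DecayFit, decay_profile, fit_decay, subset_sigma, window_sets
from .hook_core import moving_average
from .probe_model import ChipData

logger = logging.getLogger(__name__)


@dataclass
class CorrectionModel:
    """Tabulated f_s(y) plus fitted specific decay d_S(x).

    ``theta`` rescales the fitted decay (d_S = d_fit^θ) so that the log
    bias it spans between the 3' and 5' probe subsets equals the observed
    degradation-hook maximum: a fully specific set (f_s = 1) is then
    corrected by exactly the bias the hook attributes to it.
    """

    y_grid: np.ndarray
    fs_grid: np.ndarray
    decay: DecayFit
    scale: str  # "k" or "L"
    theta: float = 1.0

    def fs(self, y) -> np.ndarray:
        """Specific-hybridization fraction at set level y (mean log PM).

        Linear interpolation on the smoothed degradation-hook abscissa;
        nearest-endpoint extension outside the tabulated range.
        """
        return np.clip(np.interp(y, self.y_grid, self.fs_grid), 0.0, 1.0)

    def d_s(self, x) -> np.ndarray:
        return np.clip(self.decay(x) ** self.theta, 1e-6, 1.0)

    def factor(self, x, y) -> np.ndarray:
        """Correction factor C(x, y) ∈ (0, 1]."""
        fs = self.fs(y)
        c = self.d_s(x) * fs + (1.0 - fs)
        if np.any(c <= 0):
            raise RuntimeError("correction factor C <= 0: model invariant breached")
        return c

    @classmethod
    def identity(cls, scale: str = "k") -> "CorrectionModel":
        """No-op model (C ≡ 1) for chips without a detectable 3'/5' bias."""
        decay = DecayFit(
            lambda_=np.inf, d_inf=1.0, x0=0.0, scale=scale,
            fit_range=(0.0, 0.0), residual_norm=0.0,
        )
        return cls(y_grid=np.array([0.0, 1.0]), fs_grid=np.zeros(2), decay=decay, scale=scale)


#: smallest degradation-hook amplitude treated as a real positional bias;
#: below it (≈12 % intensity bias) the smoothed-curve maximum is dominated
#: by noise and the correction degrades to the identity
MIN_HOOK_AMPLITUDE = 0.05


def build_correction_model(
    chip: ChipData,
    labels: pd.Series,
    scale: str = "k",
    base_window: int = 1000,
    decay_fit: DecayFit | None = None,
    s_regimes: tuple = ("S",),
    min_amplitude: float = MIN_HOOK_AMPLITUDE,
) -> CorrectionModel:
    """Build the correction model from the chip's own degradation signature.

    f_s comes from the smoothed PM-only degradation hook tabulated against
    the per-set mean log PM intensity y and normalized by its maximum; past
    the maximum the declining branch is followed (saturated sets show no
    apparent 3'/5' bias and receive no correction).  The PM-only ordinate is
    used because the correction rescales PM (and, at its own y, MM)
    intensities: the PM/MM-averaged hook underweights the PM bias wherever
    MM probes are still background-dominated.  d_S is the decay fit of the
    specific subset on the chosen scale ("k" is the robust default, "L"
    resolves absolute positions).
    """
    if scale not in ("k", "L"):
        raise ValueError(f"unknown scale {scale!r}")
    sub = subset_sigma(chip, pm_only=True)
    curve = moving_average(
        sub["log_pm"].to_numpy(),
        (sub["sigma_3p"] - sub["sigma_5p"]).to_numpy(),
        base_window=window_sets(chip, base_window),
    )
    amp = curve.delta.max()
    if amp < min_amplitude:
        # undegraded (or non-specific) chip: no positional bias to remove
        logger.info("degradation-hook amplitude %.3f below %.3f: identity correction", amp, min_amplitude)
        return CorrectionModel.identity(scale)
    rel_grid = np.clip(curve.delta / amp, 0.0, 1.0)
    if decay_fit is None:
        try:
            fb_labels = _full_bias_sets(sub, curve, rel_grid)
            if fb_labels.size < 50:
                fb_labels = labels[labels.isin(s_regimes)].index
            sel = pd.Series("S", index=fb_labels)
            profile = decay_profile(chip, sel, subset="S", scale=scale)
            decay_fit = fit_decay(profile)
        except (ValueError, RuntimeError) as exc:
            logger.warning("no specific decay available (%s): identity correction", exc)
            return CorrectionModel.identity(scale)

    x3, x5 = _subset_positions(chip, scale)
    theta = _calibrate_theta(decay_fit, x3, x5, amp)
    fs_grid = _invert_fractions(curve.delta, decay_fit, theta, x3, x5)
    return CorrectionModel(
        y_grid=curve.sigma, fs_grid=fs_grid, decay=decay_fit, scale=scale, theta=theta
    )


def _subset_positions(chip: ChipData, scale: str) -> tuple[np.ndarray, np.ndarray]:
    """Positions of the 3' and 5' three-probe subsets on the chosen scale."""
    n = chip.n_pset_size
    if scale == "k":
        return np.arange(3, dtype=float), np.arange(n - 3, n, dtype=float)
    df = chip.regular
    k = df["k"].to_numpy()
    L = df["L"].to_numpy(dtype=float)
    return L[k <= 3].mean() + np.zeros(1), L[k > n - 3].mean() + np.zeros(1)


def _subset_gap(decay_fn, theta: float, x3: np.ndarray, x5: np.ndarray) -> float:
    """Log10 bias the rescaled decay spans between the two subsets at f_s = 1."""
    d3 = np.log10(np.clip(decay_fn(x3) ** theta, 1e-9, None)).mean()
    d5 = np.log10(np.clip(decay_fn(x5) ** theta, 1e-9, None)).mean()
    return float(d3 - d5)


def _calibrate_theta(decay_fit: DecayFit, x3, x5, amp: float) -> float:
    """Exponent θ matching the decay's subset bias to the hook amplitude."""
    base = _subset_gap(decay_fit, 1.0, x3, x5)
    if base <= 0:
        return 1.0
    return float(amp / base)


def _invert_fractions(deg_values: np.ndarray, decay_fit: DecayFit, theta, x3, x5) -> np.ndarray:
    """Map observed degradation-hook ordinates to specific fractions f_s.

    Inverts the mixture form of the correction: the apparent subset bias of
    a set with fraction f is b(f) = ⟨log C⟩_3' − ⟨log C⟩_5' with
    C = f·d_S + (1 − f), which is monotone in f.  Dividing by the curve
    maximum instead (the first-order inversion) systematically understates
    f for partially specific sets.
    """
    f_grid = np.linspace(0.0, 1.0, 201)
    d3 = np.clip(decay_fit(x3) ** theta, 1e-9, None)
    d5 = np.clip(decay_fit(x5) ** theta, 1e-9, None)
    b = (
        np.log10(f_grid[:, None] * d3 + (1.0 - f_grid[:, None])).mean(axis=1)
        - np.log10(f_grid[:, None] * d5 + (1.0 - f_grid[:, None])).mean(axis=1)
    )
    return np.interp(np.clip(deg_values, 0.0, b[-1]), b, f_grid)


def _full_bias_sets(sub: pd.DataFrame, curve, rel_grid: np.ndarray, fs_min: float = 0.8):
    """Probe sets expressing the full 3'/5' bias (relative amplitude ≥ 0.8,
    unsaturated side of the hook maximum).

    The specific decay d_S is estimated from these sets; mixing in weakly
    specific sets would make its shape shallower than the bias of the
    fully specific sets it anchors.
    """
    y = sub["log_pm"].to_numpy()
    y_max = curve.sigma[int(np.argmax(curve.delta))]
    fs_set = np.interp(y, curve.sigma, rel_grid)
    mask = (fs_set >= fs_min) & (y <= y_max)
    return sub.index[mask]


def correct_intensities(
    chip: ChipData, model: CorrectionModel
) -> tuple[ChipData, pd.DataFrame]:
    """Rescale raw intensities by 1/C(x, y): ``I_corr = I / C``.

    PM probes use the set's mean log PM as y, MM probes the set's mean log
    MM.  Returns the corrected chip plus an audit table of applied factors.
    """
    df = chip.probes.copy()
    x = (df["k"].to_numpy(dtype=float) - 1.0) if model.scale == "k" else df["L"].to_numpy(dtype=float)
    y_pm = df.groupby("probeset_id")["pm"].transform(lambda s: np.log10(s).mean()).to_numpy()
    y_mm = df.groupby("probeset_id")["mm"].transform(lambda s: np.log10(s).mean()).to_numpy()
    c_pm = model.factor(x, y_pm)
    c_mm = model.factor(x, y_mm)
    df["pm"] = df["pm"] / c_pm
    df["mm"] = df["mm"] / c_mm
    factors = pd.DataFrame(
        {
            "probeset_id": df["probeset_id"],
            "k": df["k"],
            "L": df["L"],
            "x": x,
            "C_pm": c_pm,
            "C_mm": c_mm,
        }
    )
    corrected = chip.with_probes(df)
    corrected.metadata["corrected"] = model.scale
    return corrected, factors
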