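"""Degradation metrics: tongs plot, degradation hook, tongs-opening fit,
positional intensity decays, two-point degradation ratio and the legacy
all-probe slope.

All measures quantify the 3'/5' intensity bias caused by truncated
transcripts (RNA degradation and incomplete in-vitro-transcription
amplification).  Because the bias only expresses itself for specific,
unsaturated hybridization, the estimators condition on the hybridization
regime obtained from the hook analysis.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

from .hook_core import (
    HookCurve,
    HookFit,
    invert_sigma,
    moving_average,
    probeset_hook_points,
    sigma_delta,
    theoretical_hook,
    _saturation_terms,
)
from .probe_model import ChipData, layout_summary

logger = logging.getLogger(__name__)

LN10 = np.log(10.0)

#: index span entering the λ ↔ d^k conversion (k = 2..10 nominal range)
DK_INDEX_SPAN = 8.0


def window_sets(chip: ChipData, base_window_probes: int) -> int:
    """Convert a smoothing window given in probes (~1000) to probe sets."""
    return max(int(base_window_probes // max(chip.n_pset_size, 1)), 20)


@dataclass
class TongsCurve:
    """Smoothed tongs-plot branches (ΔΣ_3', ΔΣ_m, ΔΣ_5') against Σ."""

    sigma: np.ndarray
    d3: np.ndarray
    dm: np.ndarray
    d5: np.ndarray
    window_sizes: np.ndarray | None = None


@dataclass
class DegradationHookCurve:
    """Smoothed degradation hook ΔΣ_3'/5' against Σ."""

    sigma: np.ndarray
    delta35: np.ndarray
    window_sizes: np.ndarray | None = None


@dataclass
class DecayProfile:
    """Positional mean log intensity and normalized decay d(x).

    ``scale`` is "k" (x = k − 1, probe offset from the 3'-most probe) or
    "L" (x = bin-center nucleotide distance from the transcript 3'-end);
    ``subset`` names the hybridization group the probes were taken from.
    """

    scale: str
    subset: str
    x: np.ndarray
    log_intensity: np.ndarray
    d: np.ndarray
    counts: np.ndarray


@dataclass
class DecayFit:
    """Parameters of the shifted-exponential-plus-constant decay law

    d(x) ≈ (1 − d_inf)·exp(−(x − x0)/λ) + d_inf   for x ≥ x0, 1 below.
    """

    lambda_: float
    d_inf: float
    x0: float
    scale: str
    fit_range: tuple[float, float]
    residual_norm: float
    at_bound: bool = False

    def __call__(self, x):
        x = np.asarray(x, dtype=float)
        return (1.0 - self.d_inf) * np.exp(-np.maximum(x - self.x0, 0.0) / self.lambda_) + self.d_inf


@dataclass
class DegradationSummary:
    """Chip-level degradation estimates."""

    tongs_opening: float
    tongs_opening_max: float
    d_tongs: float
    log_dk: float
    lambda_k: float
    lambda_L: float
    mean_log_d: float
    affyslope: float
    decay_fits: dict = field(default_factory=dict)
    flags: list = field(default_factory=list)


# ---------------------------------------------------------------------- #
# tongs plot and degradation hook


def subset_sigma(chip: ChipData, pm_only: bool = False) -> pd.DataFrame:
    """Per-set Σ of the 3', middle and 5' three-probe subsets.

    The 3' subset averages Σ over probes k = 1..3, the 5' subset over the
    last three indices, the middle subset is centered on the middle probe.
    Sets smaller than 3 probes were dropped on ingest; for a 3-probe set
    all subsets coincide.

    Returns a DataFrame indexed by probeset_id with columns
    ``sigma, sigma_3p, sigma_m, sigma_5p, log_pm`` (set means).
    """
    df = chip.regular
    if pm_only:
        sig = np.log10(df["pm"].to_numpy())
    else:
        sig, _ = sigma_delta(df["pm"].to_numpy(), df["mm"].to_numpy())
    per = pd.DataFrame(
        {
            "probeset_id": df["probeset_id"].to_numpy(),
            "k": df["k"].to_numpy(),
            "sig": sig,
            "log_pm": np.log10(df["pm"].to_numpy()),
        }
    )

    def _one(s: pd.DataFrame) -> pd.Series:
        s = s.sort_values("k")
        v = s["sig"].to_numpy()
        n = len(v)
        mid = (n - 1) // 2
        lo, hi = max(mid - 1, 0), min(mid + 2, n)
        return pd.Series(
            {
                "sigma": v.mean(),
                "sigma_3p": v[:3].mean(),
                "sigma_m": v[lo:hi].mean(),
                "sigma_5p": v[-3:].mean(),
                "log_pm": s["log_pm"].mean(),
            }
        )

    out = per.groupby("probeset_id", sort=False).apply(_one, include_groups=False)
    return out.sort_values("sigma", kind="stable")


def tongs_and_deghook(
    chip: ChipData,
    base_window: int = 1000,
    pm_only: bool = False,
) -> tuple[TongsCurve, DegradationHookCurve]:
    """Smoothed tongs plot and degradation hook of one chip.

    The tongs branches are ΔΣ_s = Σ_s − Σ for s ∈ {3', m, 5'}; the
    degradation hook is their end-to-end difference ΔΣ_3'/5' = Σ_3' − Σ_5',
    each smoothed against Σ with a tail-shrinking moving window
    (``base_window`` counts probes, ~90 probe sets at the default).
    """
    sub = subset_sigma(chip, pm_only=pm_only)
    sig = sub["sigma"].to_numpy()
    win = window_sets(chip, base_window)
    curves = {}
    for name, ordinate in (
        ("d3", sub["sigma_3p"] - sub["sigma"]),
        ("dm", sub["sigma_m"] - sub["sigma"]),
        ("d5", sub["sigma_5p"] - sub["sigma"]),
        ("d35", sub["sigma_3p"] - sub["sigma_5p"]),
    ):
        curves[name] = moving_average(sig, ordinate.to_numpy(), base_window=win)
    tongs = TongsCurve(
        sigma=curves["d3"].sigma,
        d3=curves["d3"].delta,
        dm=curves["dm"].delta,
        d5=curves["d5"].delta,
        window_sizes=curves["d3"].window_sizes,
    )
    deghook = DegradationHookCurve(
        sigma=curves["d35"].sigma,
        delta35=curves["d35"].delta,
        window_sizes=curves["d35"].window_sizes,
    )
    return tongs, deghook


# ---------------------------------------------------------------------- #
# theoretical tongs ordinate and tongs-opening fit


def theoretical_tongs_ordinate(R, gamma_s1, gamma_s2, fit: HookFit):
    """Theoretical ΔΣ_{s1/s2}(R): Σ-difference of two probe subsets whose
    specific binding is scaled by r_s = 10^{γ_s} relative to the set mean.

    Tends to 0 for R → 0 (non-specific) and R → ∞ (saturation); without
    saturation it would plateau at γ_s1 − γ_s2.
    """
    R = np.asarray(R, dtype=float)
    a, b, d0 = fit.alpha, fit.beta, fit.delta_start
    r1 = R * 10.0**gamma_s1
    r2 = R * 10.0**gamma_s2

    def half_log_spec(r):
        return 0.5 * np.log10((r + 1.0) * (r * 10.0 ** (-a) + 1.0))

    def half_log_sat(r):
        b_pm, b_mm = _saturation_terms(r, a, b, d0)
        return 0.5 * np.log10(b_pm * b_mm)

    return (half_log_spec(r1) - half_log_spec(r2)) - (half_log_sat(r1) - half_log_sat(r2))


def fit_tongs_opening(
    deghook: DegradationHookCurve,
    fit: HookFit,
    sigma_range: tuple[float, float] | None = None,
) -> tuple[float, float, bool]:
    """Tongs opening Δγ_3'/5' from a least-squares fit of the theoretical
    degradation-hook ordinate to the smoothed curve.

    γ_3' and γ_5' are free; the abscissa is mapped to R through the fitted
    standard hook.  Returns ``(delta_gamma_fit, curve_maximum, converged)``;
    when the fit fails the curve maximum serves as fallback.
    """
    sig, d35 = deghook.sigma, deghook.delta35
    if sigma_range is not None:
        m = (sig >= sigma_range[0]) & (sig <= sigma_range[1])
        sig, d35 = sig[m], d35[m]
    curve_max = float(np.max(d35)) if len(d35) else float("nan")
    logr = invert_sigma(sig, fit.alpha, fit.beta, fit.sigma_start, fit.delta_start)
    R = 10.0**logr

    def resid(p):
        g3, g5 = p
        return theoretical_tongs_ordinate(R, g3, g5, fit) - d35

    g0 = max(curve_max / 2.0, 0.01)
    try:
        sol = least_squares(
            resid, [g0, -g0], bounds=([-1.0, -2.0], [2.0, 1.0]), method="trf"
        )
        if not sol.success:
            raise RuntimeError(sol.message)
        dgamma = float(sol.x[0] - sol.x[1])
        return dgamma, curve_max, True
    except Exception as exc:  # non-convergence: fall back to the raw maximum
        logger.warning("tongs-opening fit failed (%s); using curve maximum", exc)
        return curve_max, curve_max, False


def d_from_tongs(delta_gamma: float) -> float:
    """5'/3' concentration ratio implied by the tongs opening: 10^(−Δγ)."""
    return float(10.0 ** (-delta_gamma))


def mean_log_d(delta_gamma: float) -> float:
    """Mean logged degradation index of the chip: log d ≈ −0.5·Δγ_3'/5'."""
    return -0.5 * delta_gamma


# ---------------------------------------------------------------------- #
# positional decay profiles


def decay_profile(
    chip: ChipData,
    labels: pd.Series,
    subset: str = "S",
    scale: str = "k",
    bin_width: float = 25.0,
    min_bin_count: int = 20,
    s_regimes: tuple = ("S",),
) -> DecayProfile:
    """Mean log PM intensity versus probe position for one hybridization group.

    ``labels`` maps probeset_id → regime.  ``subset`` selects N-labelled sets
    ("N"), specifically hybridized sets ("S": regimes in ``s_regimes``) or
    every set ("all").  On the k-scale probes are grouped by index (x = k−1);
    on the L-scale by nucleotide bins of ``bin_width`` (sparse bins dropped).
    The decay d(x) normalizes the (geometric-mean) intensity to its 3' level:
    the mean over k ∈ {1, 2} or the first populated L-bin below 150 nt.
    """
    if subset == "N":
        keep = labels[labels == "N"].index
    elif subset == "S":
        keep = labels[labels.isin(s_regimes)].index
    elif subset == "all":
        keep = labels.index
    else:
        raise ValueError(f"unknown subset {subset!r}")
    df = chip.regular
    df = df[df["probeset_id"].isin(keep)]
    if df.empty:
        raise ValueError(f"no probe sets in subset {subset!r}")
    logI = np.log10(df["pm"].to_numpy())

    if scale == "k":
        x_all = df["k"].to_numpy(dtype=float) - 1.0
        groups = pd.Series(logI).groupby(x_all)
        x = np.array(sorted(groups.groups))
        mean_log = groups.mean().loc[x].to_numpy()
        counts = groups.size().loc[x].to_numpy()
        ref = mean_log[x <= 1.0].mean()  # k in {1, 2}
    elif scale == "L":
        bins = np.floor(df["L"].to_numpy(dtype=float) / bin_width)
        groups = pd.Series(logI).groupby(bins)
        centers = (np.array(sorted(groups.groups)) + 0.5) * bin_width
        mean_log = groups.mean().to_numpy()
        counts = groups.size().to_numpy()
        ok = counts >= min_bin_count
        if not ok.any():
            raise ValueError("no L-bins with enough probes")
        x, mean_log, counts = centers[ok], mean_log[ok], counts[ok]
        below = x < 150.0
        ref = mean_log[np.argmax(below)] if below.any() else mean_log[0]
    else:
        raise ValueError(f"unknown scale {scale!r}")

    d = 10.0 ** (mean_log - ref)
    return DecayProfile(scale=scale, subset=subset, x=x, log_intensity=mean_log, d=d, counts=counts)


def fit_decay(
    profile: DecayProfile,
    fit_range: tuple[float, float] | None = None,
    fix_d_inf: bool | None = None,
) -> DecayFit:
    """Fit the shifted-exponential-plus-constant law to a normalized decay.

    Defaults: L-scale fits are restricted to 100 < L < 600 (beyond 600 nt
    the sparse distal probes flatten for reasons outside the model) with
    d_inf free; k-scale fits use the full index range with d_inf fixed to 0
    (the last indices absorb the asymptote).  Bounds: λ > 0, d_inf ∈ [0, 1],
    x0 ≥ 0.
    """
    if fit_range is None:
        fit_range = (100.0, 600.0) if profile.scale == "L" else (-np.inf, np.inf)
    if fix_d_inf is None:
        fix_d_inf = profile.scale == "k"
    m = (profile.x > fit_range[0]) & (profile.x < fit_range[1])
    x, d = profile.x[m], profile.d[m]
    if len(x) < 5:
        raise ValueError(f"need >= 5 populated bins in fit range, have {len(x)}")

    span = max(x.max() - x.min(), 1.0)

    def model(p):
        lam, dinf, x0 = (p[0], 0.0, p[1]) if fix_d_inf else p
        return (1.0 - dinf) * np.exp(-np.maximum(x - x0, 0.0) / lam) + dinf

    def resid(p):
        return model(p) - d

    lam0 = span / max(-np.log(max(d[-1], 1e-3)), 0.5)
    if fix_d_inf:
        p0, lo, hi = [lam0, 0.0], [1e-3, 0.0], [50 * span, x.max()]
    else:
        p0, lo, hi = [lam0, max(float(d[-1]), 0.0), 0.0], [1e-3, 0.0, 0.0], [50 * span, 1.0, x.max()]
    p0 = np.clip(p0, lo, hi)
    sol = least_squares(resid, p0, bounds=(lo, hi), method="trf")
    if not sol.success:
        raise RuntimeError(f"decay fit did not converge: {sol.message}")
    lam, dinf, x0 = (sol.x[0], 0.0, sol.x[1]) if fix_d_inf else sol.x
    at_bound = bool(np.any(np.isclose(sol.x, lo, atol=1e-9) | np.isclose(sol.x, hi, atol=1e-9)))
    return DecayFit(
        lambda_=float(lam),
        d_inf=float(dinf),
        x0=float(x0),
        scale=profile.scale,
        fit_range=(float(fit_range[0]), float(fit_range[1])),
        residual_norm=float(np.linalg.norm(sol.fun) / np.sqrt(len(x))),
        at_bound=at_bound,
    )


# ---------------------------------------------------------------------- #
# two-point degradation ratio and λ conversion


def degradation_ratio_dk(
    chip: ChipData,
    labels: pd.Series,
    s_regimes: tuple = ("S",),
    min_sets: int = 50,
) -> tuple[float, bool]:
    """Two-point logged degradation ratio of specifically hybridized sets:

    log d^k = ⟨log I⟩_{k ∈ last two} − ⟨log I⟩_{k ∈ first two}

    computed over PM probes of sets in the specific regimes.  Returns
    ``(log_dk, low_confidence)``; fewer than ``min_sets`` contributing sets
    flags the estimate.
    """
    keep = labels[labels.isin(s_regimes)].index
    df = chip.regular
    df = df[df["probeset_id"].isin(keep)]
    if df.empty:
        raise ValueError("no specifically hybridized probe sets")
    n_pset = int(df["k"].max())
    logI = np.log10(df["pm"].to_numpy())
    k = df["k"].to_numpy()
    first = logI[(k == 1) | (k == 2)]
    last = logI[(k == n_pset - 1) | (k == n_pset)]
    log_dk = float(last.mean() - first.mean())
    n_sets = df["probeset_id"].nunique()
    low_conf = n_sets < min_sets
    if low_conf:
        logger.warning("log d^k from only %d sets: low confidence", n_sets)
    if log_dk > 0.05:
        warnings.warn(f"log d^k = {log_dk:.3f} > 0: 5' intensities exceed 3'", stacklevel=2)
    return log_dk, low_conf


def lambda_from_dk(log_dk: float, delta_L_mean: float) -> tuple[float, float]:
    """Exponential decay lengths implied by the two-point ratio:

    λ_k = −8 / ln(10^{log d^k})  and  λ_L = λ_k · ⟨ΔL⟩.

    The index span 8 corresponds to the nominal k = 2..10 range of the
    estimate.  Undefined (NaN) for log d^k ≥ 0.
    """
    if log_dk >= 0:
        warnings.warn("log d^k >= 0: decay length undefined", stacklevel=2)
        return float("nan"), float("nan")
    ln_dk = log_dk * LN10
    lam_k = -DK_INDEX_SPAN / ln_dk
    return float(lam_k), float(lam_k * delta_L_mean)


# ---------------------------------------------------------------------- #
# legacy all-probe measures


def affyslope(chip: ChipData) -> tuple[DecayProfile, float]:
    """Legacy RNA-degradation plot: mean log PM per probe index over ALL
    probes, plus the OLS slope against k.

    Because absent (non-specifically hybridized) probes show no positional
    bias, this all-probe slope underestimates the degradation of the
    specific signal in proportion to %N.
    """
    df = chip.regular
    logI = np.log10(df["pm"].to_numpy())
    groups = pd.Series(logI).groupby(df["k"].to_numpy(dtype=float))
    k = np.array(sorted(groups.groups))
    mean_log = groups.mean().loc[k].to_numpy()
    counts = groups.size().loc[k].to_numpy()
    slope = float(np.polyfit(k, mean_log, 1)[0])
    ref = mean_log[k <= 2.0].mean()
    profile = DecayProfile(
        scale="k", subset="all", x=k - 1.0, log_intensity=mean_log,
        d=10.0 ** (mean_log - ref), counts=counts,
    )
    return profile, slope


def sn_positional_histograms(
    chip: ChipData,
    labels: pd.Series,
    bins: np.ndarray | None = None,
    s_regimes: tuple = ("S",),
) -> pd.DataFrame:
    """Positional distributions of S- versus N-hybridized probe sets.

    For both the first (L_first) and last (L_max) probe position, returns
    per-bin fractions of S and N sets (each normalized within its group),
    their difference (N − S) and the difference normalized by the mean
    fraction.  Probe sets near the 3'-end (L_first < 100, L_max < 500) are
    expected to be enriched for non-specific hybridization.
    """
    spans = layout_summary(chip)
    spans = spans.join(labels.rename("regime"), how="inner")
    if bins is None:
        bins = np.arange(0.0, spans["L_last"].max() + 100.0, 100.0)
    records = []
    for col, name in (("L_first", "L_first"), ("L_last", "L_max")):
        s_vals = spans.loc[spans["regime"].isin(s_regimes), col]
        n_vals = spans.loc[spans["regime"] == "N", col]
        s_h, _ = np.histogram(s_vals, bins=bins)
        n_h, _ = np.histogram(n_vals, bins=bins)
        s_f = s_h / max(s_h.sum(), 1)
        n_f = n_h / max(n_h.sum(), 1)
        mean_f = 0.5 * (s_f + n_f)
        with np.errstate(divide="ignore", invalid="ignore"):
            norm_diff = np.where(mean_f > 0, (n_f - s_f) / mean_f, 0.0)
        for i in range(len(bins) - 1):
            records.append(
                {
                    "position": name,
                    "bin_left": bins[i],
                    "bin_right": bins[i + 1],
                    "frac_S": s_f[i],
                    "frac_N": n_f[i],
                    "diff_N_minus_S": n_f[i] - s_f[i],
                    "norm_diff": norm_diff[i],
                }
            )
    return pd.DataFrame.from_records(records)
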