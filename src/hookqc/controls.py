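"""3'/5' control-probe quality metrics and the variable "threshold hook".

GeneChip arrays carry control probe sets targeting the 3'-end, middle and
5'-end of long housekeeping transcripts (beta-actin, GAPDH).  The classic
quality rule flags a chip when the 3'/5' PM-intensity ratio of a control
exceeds 3 (log10 3 ≈ 0.48).  Because non-specific hybridization and probe
saturation both compress the observable 3'/5' ratio, a constant threshold
overestimates RNA quality for controls outside the linear specific range.
The threshold hook replaces the constant by a Σ-dependent threshold curve
derived from the PM-only Langmuir hook, calibrated so that its maximum
(reached in the S-range) equals the constant threshold.
"""

from __future__ import annotations

import logging
import re
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .hook_core import HookFit
from .probe_model import ChipData

logger = logging.getLogger(__name__)

#: default constant quality threshold, log10(3)
DEFAULT_THRESHOLD = float(np.log10(3.0))

_REGION_SUFFIX = re.compile(r"[_\-/]*(3prime|5prime|middle|3p|5p|mid|m|3|5)$", re.IGNORECASE)


@dataclass
class ControlPair:
    """3'/5' hook coordinates of one control gene (PM-only, per Eq.-style sums)."""

    gene_label: str
    sigma_sum: float  # ⟨log PM⟩_3'set + ⟨log PM⟩_5'set
    sigma_mean: float  # half-sum, on the standard hook Σ scale
    delta_35: float  # ⟨log PM⟩_3'set − ⟨log PM⟩_5'set
    sigma_3p: float
    sigma_5p: float


@dataclass
class ThresholdHook:
    """Calibrated Σ-dependent 3'/5' quality threshold curve."""

    sigma: np.ndarray  # half-sum abscissa, anchored at [Σ_start, logM]
    delta_threshold: np.ndarray
    delta_gamma: float  # calibrated true tongs opening
    constant_threshold: float
    sigma_n: float  # N-anchor (Σ_start of the standard hook)
    sigma_as: float  # as-anchor (logM)

    def threshold_at(self, sigma) -> np.ndarray:
        """Interpolated hook threshold; 0 beyond the anchors."""
        return np.interp(sigma, self.sigma, self.delta_threshold, left=0.0, right=0.0)


@dataclass
class ControlReport:
    tp: int
    fp: int
    tn: int
    fn: int
    ppv: float
    sp: float


# ---------------------------------------------------------------------- #


def control_metrics(chip: ChipData) -> list[ControlPair]:
    """PM-only 3'/5' metrics of every control gene on the chip.

    Control probe sets are grouped into genes by stripping the region suffix
    from the probeset_id (e.g. ``ctrl_gapdh_3prime`` → ``ctrl_gapdh``); a
    gene lacking either end set is skipped with a warning.
    """
    ctrl = chip.controls
    if ctrl.empty:
        return []
    ctrl = ctrl.copy()
    ctrl["gene"] = [
        _REGION_SUFFIX.sub("", pid) or pid for pid in ctrl["probeset_id"]
    ]
    out: list[ControlPair] = []
    for gene, grp in ctrl.groupby("gene", sort=True):
        means = (
            grp.assign(log_pm=np.log10(grp["pm"]))
            .groupby("control_region")["log_pm"]
            .mean()
        )
        if "3prime" not in means or "5prime" not in means:
            warnings.warn(f"control gene {gene!r} lacks a 3' or 5' probe set; skipped", stacklevel=2)
            continue
        l3, l5 = float(means["3prime"]), float(means["5prime"])
        out.append(
            ControlPair(
                gene_label=gene,
                sigma_sum=l3 + l5,
                sigma_mean=0.5 * (l3 + l5),
                delta_35=l3 - l5,
                sigma_3p=l3,
                sigma_5p=l5,
            )
        )
    return out


# ---------------------------------------------------------------------- #
# threshold hook


def _pm_log_intensity(R, beta, sigma_start):
    """PM-only Langmuir hook ordinate: log I spans [Σ_start, logM].

    This is the α → −∞ limit of the two-species hook (MM terms dropped
    analytically): log I(R) = Σ_start + log(R+1) − log(1 + 10^{−β}(R+1)).
    """
    R = np.asarray(R, dtype=float)
    return sigma_start + np.log10(R + 1.0) - np.log10(1.0 + 10.0 ** (-beta) * (R + 1.0))


def _threshold_curve(delta_gamma, fit: HookFit, n: int = 1200):
    """Trajectory of a 3'/5' control pair with true opening Δγ."""
    logr = np.linspace(-4.0, fit.beta + 4.0, n)
    g3, g5 = 0.5 * delta_gamma, -0.5 * delta_gamma
    l3 = _pm_log_intensity(10.0 ** (logr + g3), fit.beta, fit.sigma_start)
    l5 = _pm_log_intensity(10.0 ** (logr + g5), fit.beta, fit.sigma_start)
    return 0.5 * (l3 + l5), l3 - l5


def build_threshold_hook(
    fit: HookFit,
    constant_threshold: float = DEFAULT_THRESHOLD,
) -> ThresholdHook:
    """Calibrate the variable threshold hook against a constant threshold.

    The curve is the PM-only degradation hook of a hypothetical control pair
    whose 3' and 5' sets differ by a true opening Δγ; Δγ is found by 1-D
    root finding so the curve maximum equals ``constant_threshold``.  The
    start/end anchors come from the standard hook fit (Σ_start and logM),
    where the observable 3'/5' ratio vanishes (non-specific hybridization
    and saturation, respectively).
    """
    if constant_threshold <= 0:
        raise ValueError("constant_threshold must be > 0")

    def excess(dg):
        _, delta = _threshold_curve(dg, fit)
        return float(delta.max()) - constant_threshold

    # the curve maximum is strictly below Δγ (saturation), so the root lies
    # above the constant threshold
    lo, hi = constant_threshold, constant_threshold + 0.5
    for _ in range(20):
        if excess(hi) > 0:
            break
        hi += 0.5
    else:  # pragma: no cover - pathological fit
        raise RuntimeError("threshold-hook calibration failed: maximum never reaches threshold")
    dgamma = brentq(excess, lo, hi, xtol=1e-12)
    sigma, delta = _threshold_curve(dgamma, fit)
    return ThresholdHook(
        sigma=sigma,
        delta_threshold=delta,
        delta_gamma=float(dgamma),
        constant_threshold=float(constant_threshold),
        sigma_n=fit.sigma_start,
        sigma_as=fit.logM,
    )


def classify_controls(
    points: list[ControlPair],
    threshold_hook: ThresholdHook,
    constant_threshold: float | None = None,
) -> ControlReport:
    """Confusion-matrix quality classification of control points.

    A point is a true positive when its apparent 3'/5' ratio stays below the
    variable hook threshold at its Σ, a false positive when it only beats
    the constant threshold (quality overestimated), and a true negative at
    or above the constant threshold.  False negatives cannot occur because
    the hook threshold never exceeds the constant one; boundary ties go to
    the worse-quality class.
    """
    if not points:
        raise ValueError("no control points to classify")
    c = threshold_hook.constant_threshold if constant_threshold is None else constant_threshold
    tp = fp = tn = 0
    for pt in points:
        hook_thr = float(threshold_hook.threshold_at(pt.sigma_mean))
        if pt.delta_35 >= c:
            tn += 1
        elif pt.delta_35 < hook_thr:
            tp += 1
        else:
            fp += 1
    ppv = tp / (tp + fp) if (tp + fp) else float("nan")
    sp = tn / (fp + tn) if (fp + tn) else float("nan")
    return ControlReport(tp=tp, fp=fp, tn=tn, fn=0, ppv=ppv, sp=sp)
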