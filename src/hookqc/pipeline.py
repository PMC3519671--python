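"""End-to-end quality-control driver tying the analysis stages together."""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import controls as ctl
from .correction import CorrectionModel, build_correction_model, correct_intensities
from .degradation import (
    DegradationHookCurve,
    DegradationSummary,
    TongsCurve,
    affyslope,
    d_from_tongs,
    decay_profile,
    degradation_ratio_dk,
    fit_decay,
    fit_tongs_opening,
    lambda_from_dk,
    mean_log_d,
    tongs_and_deghook,
    window_sets,
)
from .hook_core import (
    HookCurve,
    HookFit,
    classify_regimes,
    expression_index,
    fit_hook,
    moving_average,
    pct_absent,
    probeset_hook_points,
)
from .probe_model import ChipData

logger = logging.getLogger(__name__)


@dataclass
class QCResult:
    """Everything the quality-control pipeline computes for one chip."""

    hook_curve: HookCurve
    hook_fit: HookFit
    labels: pd.Series  # probeset_id -> regime
    tongs: TongsCurve
    deghook: DegradationHookCurve
    summary: DegradationSummary
    per_set: pd.DataFrame  # sigma/delta/log_pm/regime per probe set
    control_pairs: list = field(default_factory=list)
    control_report: ctl.ControlReport | None = None
    threshold_hook: ctl.ThresholdHook | None = None


def analyze_chip(
    chip: ChipData,
    base_window: int = 1000,
    control_threshold: float = ctl.DEFAULT_THRESHOLD,
    decay_scales: tuple = ("k", "L"),
    s_regimes: tuple = ("S",),
) -> QCResult:
    """Run the full hook + degradation analysis on one chip.

    Stages: per-set Σ/Δ points → smoothed hook curve → Langmuir hook fit →
    regime labels (%N, φ) → tongs plot and degradation hook → tongs-opening
    fit → positional decay profiles/fits → two-point ratio d^k and decay
    lengths → legacy all-probe slope → control metrics and threshold hook.
    ``base_window`` counts probes (~90 probe sets at the default of 1000).
    """
    points = probeset_hook_points(chip)
    win = window_sets(chip, base_window)
    curve = moving_average(points["sigma"].to_numpy(), points["delta"].to_numpy(), win)
    fit = fit_hook(curve)

    labels = pd.Series(
        classify_regimes(points["sigma"].to_numpy(), fit), index=points.index, name="regime"
    )
    fit.pct_absent = pct_absent(labels.to_numpy())
    fit.phi = expression_index(points["sigma"].to_numpy(), fit, labels.to_numpy())

    tongs, deghook = tongs_and_deghook(chip, base_window=base_window)
    dgamma, dgamma_max, converged = fit_tongs_opening(deghook, fit)
    flags = [] if converged else ["tongs_fit_fallback"]

    decay_fits: dict[str, object] = {}
    for scale in decay_scales:
        try:
            prof = decay_profile(chip, labels, subset="S", scale=scale, s_regimes=s_regimes)
            decay_fits[scale] = fit_decay(prof)
        except (ValueError, RuntimeError) as exc:
            logger.warning("decay fit on %s-scale skipped: %s", scale, exc)
            flags.append(f"decay_fit_{scale}_failed")

    log_dk, low_conf = degradation_ratio_dk(chip, labels, s_regimes=s_regimes)
    if low_conf:
        flags.append("dk_low_confidence")
    from .probe_model import mean_probe_spacing

    # two-point spacing estimator: invariant under the layout's 3' offset
    _, spacing = mean_probe_spacing(chip)
    lam_k, lam_L = lambda_from_dk(log_dk, spacing)
    _, slope = affyslope(chip)

    summary = DegradationSummary(
        tongs_opening=dgamma,
        tongs_opening_max=dgamma_max,
        d_tongs=d_from_tongs(dgamma),
        log_dk=log_dk,
        lambda_k=lam_k,
        lambda_L=lam_L,
        mean_log_d=mean_log_d(dgamma),
        affyslope=slope,
        decay_fits=decay_fits,
        flags=flags,
    )

    per_set = points.join(labels)

    result = QCResult(
        hook_curve=curve,
        hook_fit=fit,
        labels=labels,
        tongs=tongs,
        deghook=deghook,
        summary=summary,
        per_set=per_set,
    )

    pairs = ctl.control_metrics(chip)
    if pairs:
        th = ctl.build_threshold_hook(fit, control_threshold)
        result.control_pairs = pairs
        result.threshold_hook = th
        result.control_report = ctl.classify_controls(pairs, th)
    return result


def correct_chip(
    chip: ChipData,
    scale: str = "k",
    base_window: int = 1000,
    result: QCResult | None = None,
) -> tuple[ChipData, pd.DataFrame, CorrectionModel]:
    """Build the correction model for a chip and apply it.

    Runs the QC pipeline first when no precomputed result is supplied; a
    chip without a specific branch (pure non-specific hybridization) passes
    through unchanged.
    """
    from .hook_core import HookError
    from .correction import CorrectionModel

    if result is None:
        try:
            result = analyze_chip(chip, base_window=base_window, decay_scales=(scale,))
        except HookError as exc:
            logger.warning("hook analysis impossible (%s): identity correction", exc)
            model = CorrectionModel.identity(scale)
            corrected, factors = correct_intensities(chip, model)
            return corrected, factors, model
    model = build_correction_model(
        chip, result.labels, scale=scale, base_window=base_window
    )
    corrected, factors = correct_intensities(chip, model)
    return corrected, factors, model
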