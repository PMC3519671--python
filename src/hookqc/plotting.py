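"""Static figures: hook curve, tongs plot / degradation hook, decay profiles."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

from .degradation import DecayFit, DecayProfile, DegradationHookCurve, TongsCurve
from .hook_core import HookCurve, HookFit, theoretical_hook


def plot_hook(curve: HookCurve, fit: HookFit | None, path: str | Path) -> Path:
    """Smoothed hook curve with the fitted theoretical curve overlaid."""
    fig, ax = plt.subplots(figsize=(5, 4))
    ax.plot(curve.sigma, curve.delta, ".", ms=2, color="steelblue", label="smoothed data")
    if fit is not None:
        r = 10.0 ** np.linspace(-3, fit.beta + 3, 400)
        sig, dlt = theoretical_hook(r, fit.alpha, fit.beta, fit.sigma_start, fit.delta_start)
        ax.plot(sig, dlt, "-", color="crimson", lw=1.5,
                label=rf"fit: $\alpha$={fit.alpha:.2f}, $\beta$={fit.beta:.2f}")
    ax.set_xlabel(r"$\Sigma$")
    ax.set_ylabel(r"$\Delta$")
    ax.legend(fontsize=8)
    ax.set_title("Hook curve")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
    return Path(path)


def plot_tongs(
    tongs: TongsCurve, deghook: DegradationHookCurve, path: str | Path
) -> Path:
    """Tongs plot (three positional branches) and degradation hook."""
    fig, (ax1, ax2) = plt.subplots(2, 1, figsize=(5, 6), sharex=True)
    ax1.plot(deghook.sigma, deghook.delta35, "-", color="crimson")
    ax1.set_ylabel(r"$\Delta\Sigma_{3'/5'}$")
    ax1.set_title("Degradation hook")
    ax2.plot(tongs.sigma, tongs.d3, "-", label="3' subset")
    ax2.plot(tongs.sigma, tongs.dm, "-", label="middle")
    ax2.plot(tongs.sigma, tongs.d5, "-", label="5' subset")
    ax2.axhline(0.0, color="gray", lw=0.5)
    ax2.set_xlabel(r"$\Sigma$")
    ax2.set_ylabel(r"$\Delta\Sigma_s$")
    ax2.set_title("Tongs plot")
    ax2.legend(fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
    return Path(path)


def plot_decay(
    profiles: list[DecayProfile],
    fits: dict[str, DecayFit],
    path: str | Path,
) -> Path:
    """Normalized positional decays d(x) with their fitted curves."""
    fig, ax = plt.subplots(figsize=(5, 4))
    for prof in profiles:
        ax.plot(prof.x, prof.d, "o", ms=3, label=f"{prof.subset} ({prof.scale}-scale)")
        fit = fits.get(prof.scale)
        if fit is not None and prof.subset == "S":
            xx = np.linspace(prof.x.min(), prof.x.max(), 200)
            ax.plot(xx, fit(xx), "-", lw=1,
                    label=rf"fit $\lambda_{prof.scale}$={fit.lambda_:.3g}")
    ax.set_xlabel("probe position x")
    ax.set_ylabel("d(x)")
    ax.set_ylim(0, 1.2)
    ax.legend(fontsize=8)
    ax.set_title("Positional intensity decay")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
    return Path(path)
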