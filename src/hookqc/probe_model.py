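"""Domain types for probe-level GeneChip data and array-layout statistics.

A GeneChip 3'-expression array interrogates each transcript with a probe set
of typically 11-20 perfect-match / mismatch (PM/MM) 25-mer pairs.  Probes are
indexed ``k = 1 .. N_pset`` counted toward the 5'-end (note: opposite to the
vendor's ordering), and each probe sits at an absolute distance ``L`` (in
nucleotides) between the transcript's 3'-end and the probe's nearest base.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Literal

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

ControlRegion = Literal["3prime", "middle", "5prime", "none"]

#: columns required of every probe table
PROBE_COLUMNS = ("probeset_id", "k", "L", "pm", "mm", "is_control", "control_region")

_VALID_BASES = frozenset("ACGTU")


@dataclass(frozen=True)
class ProbePair:
    """One PM/MM probe pair of a probe set."""

    probeset_id: str
    k: int
    L: int
    pm: float
    mm: float
    is_control: bool = False
    control_region: ControlRegion = "none"

    def __post_init__(self) -> None:
        if self.k < 1:
            raise ValueError(f"probe index k must be >= 1, got {self.k}")
        if self.L < 0:
            raise ValueError(f"probe position L must be >= 0, got {self.L}")
        if not (self.pm > 0 and self.mm > 0):
            raise ValueError(
                f"probe {self.probeset_id}:{self.k} has non-positive intensity "
                f"(pm={self.pm}, mm={self.mm})"
            )


@dataclass
class LangmuirParams:
    """Parameters of the two-species hyperbolic hybridization isotherm.

    The probe intensity follows ``I = M (X_S w_S + X_N w_N) / (1 + X_S + X_N) + O``
    where the binding strengths ``X`` are products of target concentration and
    binding constant for the specific (S) and non-specific (N) hybridization
    modes, ``M`` is the intensity at complete probe saturation, ``O`` the
    optical background and ``w`` the post-hybridization washing survival factor.
    """

    M: float = 1.0e4
    O: float = 0.0
    alpha: float = 0.85  # log10 PM/MM specific-affinity gap
    S_target: float = 1.0
    N_chip: float = 1.0
    K_S: float = 1.0
    K_N: float = 1.0
    w: float = 1.0

    def __post_init__(self) -> None:
        if not self.M > self.O >= 0:
            raise ValueError(f"require M > O >= 0, got M={self.M}, O={self.O}")
        for name in ("S_target", "N_chip", "K_S", "K_N", "w"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


class ChipData:
    """All probe pairs of one array, held as a validated DataFrame.

    Parameters
    ----------
    probes
        DataFrame with columns ``probeset_id, k, L, pm, mm`` and optionally
        ``is_control, control_region``, or an iterable of :class:`ProbePair`.
    min_set_size
        Probe sets with fewer pairs are excluded from subset statistics.
    metadata
        Free-form key/value annotations carried through the analysis.
    """

    def __init__(
        self,
        probes: pd.DataFrame | Iterable[ProbePair],
        min_set_size: int = 3,
        metadata: dict | None = None,
    ) -> None:
        if not isinstance(probes, pd.DataFrame):
            probes = pd.DataFrame([p.__dict__ for p in probes])
        df = probes.copy()
        for col, default in (("is_control", False), ("control_region", "none")):
            if col not in df.columns:
                df[col] = default
        missing = [c for c in PROBE_COLUMNS if c not in df.columns]
        if missing:
            raise ValueError(f"probe table missing columns: {missing}")
        if (df["pm"] <= 0).any() or (df["mm"] <= 0).any():
            bad = df.loc[(df["pm"] <= 0) | (df["mm"] <= 0)]
            raise ValueError(
                "non-positive intensities for probes "
                + ", ".join(f"{r.probeset_id}:{r.k}" for r in bad.head(5).itertuples())
            )
        if (df["L"] < 0).any():
            raise ValueError("negative probe positions L")
        dup = df.duplicated(subset=["probeset_id", "k"])
        if dup.any():
            first = df.loc[dup, ["probeset_id", "k"]].iloc[0]
            raise ValueError(
                f"duplicate probe (probeset_id={first['probeset_id']}, k={first['k']})"
            )
        df = df.sort_values(["probeset_id", "k"], kind="stable").reset_index(drop=True)
        sizes = df.groupby("probeset_id", sort=False)["k"].size()
        small = sizes[sizes < min_set_size]
        if len(small):
            logger.info("excluding %d probe sets with < %d probes", len(small), min_set_size)
            df = df[~df["probeset_id"].isin(small.index)].reset_index(drop=True)
        self.probes = df
        self.min_set_size = min_set_size
        self.metadata = dict(metadata or {})

    # ------------------------------------------------------------------ #

    @property
    def regular(self) -> pd.DataFrame:
        """Non-control probes (the expression probe sets)."""
        return self.probes[~self.probes["is_control"]]

    @property
    def controls(self) -> pd.DataFrame:
        return self.probes[self.probes["is_control"]]

    @property
    def n_psets(self) -> int:
        return self.regular["probeset_id"].nunique()

    @property
    def n_pset_size(self) -> int:
        """Typical (modal) number of probe pairs per expression set."""
        sizes = self.regular.groupby("probeset_id")["k"].size()
        return int(sizes.mode().iloc[0])

    @property
    def delta_L_mean(self) -> float:
        """Mean probe spacing ⟨ΔL⟩ (through-origin estimator)."""
        return mean_probe_spacing(self)[0]

    def with_probes(self, probes: pd.DataFrame) -> "ChipData":
        out = ChipData(probes, min_set_size=self.min_set_size, metadata=self.metadata)
        return out

    def __len__(self) -> int:
        return len(self.probes)

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return (
            f"ChipData({len(self.probes)} probes, {self.n_psets} probe sets, "
            f"{self.controls['probeset_id'].nunique()} control sets)"
        )


# ---------------------------------------------------------------------- #
# layout operations


def compute_probe_position(probe_seq: str, target_seq: str) -> int:
    """Distance L between a target's 3'-end and the nearest base of a probe.

    The probe (25-mer) is located in the target by exact substring matching;
    ``L`` counts the nucleotides between the 3' terminus of the target
    (given 5'→3') and the probe base closest to it, so a probe abutting the
    3' terminus has ``L = 0``.  When the probe occurs more than once the most
    3' match (smallest L) is returned with a warning.
    """
    probe = probe_seq.upper().replace("U", "T")
    target = target_seq.upper().replace("U", "T")
    if len(probe) != 25:
        raise ValueError(f"probe sequence must be a 25-mer, got length {len(probe)}")
    if not set(probe) <= _VALID_BASES or not set(target) <= _VALID_BASES:
        raise ValueError("sequences may contain only A, C, G, T/U")
    starts = []
    pos = target.find(probe)
    while pos != -1:
        starts.append(pos)
        pos = target.find(probe, pos + 1)
    if not starts:
        raise ValueError("probe not found in target sequence")
    # distance from the 3' end to the last base of the match
    distances = [len(target) - (s + 25) for s in starts]
    if len(starts) > 1:
        warnings.warn(
            f"probe matches target at {len(starts)} positions; using the most 3' match",
            stacklevel=2,
        )
    return min(distances)


def mean_probe_spacing(chip: ChipData) -> tuple[float, float]:
    """Mean probe spacing ⟨ΔL⟩ in nucleotides per index increment.

    Returns
    -------
    (slope, two_point)
        ``slope`` — regression-through-origin of the median ``L`` per index
        against ``k - 1`` (primary estimator); ``two_point`` — the end-point
        estimator ``(⟨L_last⟩ − ⟨L_1⟩)/(N_pset − 1)``.

    Notes
    -----
    The two-point estimator is invariant under a uniform shift of all L,
    while the through-origin slope is not (it assumes the probe ladder is
    anchored at the per-index median offsets).
    """
    df = chip.regular
    if df["L"].isna().any():
        raise ValueError("L missing for some probes")
    kvals = df.groupby("k")["L"].median()
    if len(kvals) < 2:
        raise ValueError("need at least 2 distinct probe indices to estimate spacing")
    if kvals.nunique() == 1:
        warnings.warn("degenerate layout: all probe positions identical", stacklevel=2)
        return 0.0, 0.0
    k = kvals.index.to_numpy(dtype=float) - 1.0
    L = kvals.to_numpy(dtype=float)
    denom = float(np.dot(k, k))
    slope = float(np.dot(k, L) / denom) if denom > 0 else 0.0

    n_pset = int(df["k"].max())
    L1 = df.loc[df["k"] == 1, "L"].mean()
    Ln = df.loc[df["k"] == n_pset, "L"].mean()
    two_point = float((Ln - L1) / (n_pset - 1))
    return slope, two_point


def classify_probeset_span(
    L_first: float,
    L_last: float,
    low_first: float = 100.0,
    low_last: float = 500.0,
) -> str:
    """Classify a probe set's transcript coverage as LL, LH or HH.

    ``L_first``/``L_last`` are the positions of the 3'-most and 5'-most
    probes.  Sets close to the 3'-end (``L_first < 100`` and ``L_last < 500``)
    are labelled LL; those starting close but reaching far are LH; the rest HH.
    """
    if L_first < 0 or L_last < 0:
        raise ValueError("probe positions must be non-negative")
    if L_first > L_last:
        raise ValueError("L_first must not exceed L_last")
    first_low = L_first < low_first
    last_low = L_last < low_last
    if first_low and last_low:
        return "LL"
    if first_low:
        return "LH"
    return "HH"


@dataclass
class LayoutSummary:
    """Per-set layout spans used by positional histograms."""

    probeset_id: np.ndarray = field(default_factory=lambda: np.array([]))
    L_first: np.ndarray = field(default_factory=lambda: np.array([]))
    L_last: np.ndarray = field(default_factory=lambda: np.array([]))


def layout_summary(chip: ChipData) -> pd.DataFrame:
    """Per-probe-set first/last probe positions (3'-most and 5'-most)."""
    g = chip.regular.groupby("probeset_id", sort=False)
    out = pd.DataFrame(
        {
            "L_first": g.apply(lambda s: s.loc[s["k"].idxmin(), "L"], include_groups=False),
            "L_last": g.apply(lambda s: s.loc[s["k"].idxmax(), "L"], include_groups=False),
        }
    )
    return out
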