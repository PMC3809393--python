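"""Spontaneous DSB rate per cell division from microcolony traces.

The headline estimator follows the microfluidic time-lapse design: each
microcolony contributes its final foci-per-division ratio f_i; the rate
of focus formation per division is the mean of f_i across colonies with
its SEM, and the true break rate per division is obtained by dividing by
the focus-detection efficiency p (r = f/p).  A pooled Wilson binomial
interval on total foci / total divisions is reported alongside.

Also here: conversion of legacy frequency-based estimates (rate of cells
acquiring ≥1 break per generation, times mean breaks per break-carrying
cell), the generation-dependence diagnostic comparing per-division and
per-hour focus rates across division-rate regimes, and the two-sample
fluorescence-exposure control comparison.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.proportion import proportion_confint

from .simulate import MicrocolonyTrace

__all__ = [
    "RateEstimate",
    "LegacyFrequencyInput",
    "MicrocolonyRateModel",
    "foci_per_division",
    "correct_rate",
    "frequency_to_rate",
    "generation_dependence",
    "GenerationDependenceResult",
    "exposure_control_compare",
    "TwoSampleComparison",
]


@dataclass
class RateEstimate:
    """Foci-per-division and efficiency-corrected break rate.

    ``r = f / p`` exactly; by default ``r_sem = f_sem / p`` (uncertainty
    on the efficiency excluded); when an efficiency SE is supplied and
    propagation requested, ``r_sem_full`` adds the delta-method term
    (f·p_sem/p²)² in quadrature.
    """

    f: float
    f_sem: float
    p: float
    r: float
    r_sem: float
    n_colonies: int | None = None
    q_ci: tuple[float, float] | None = None
    pooled_q: float | None = None
    total_foci: int | None = None
    total_divisions: int | None = None
    p_sem: float | None = None
    r_sem_full: float | None = None

    def summary(self) -> str:
        lines = [
            "Spontaneous DSB rate per cell division",
            "=" * 44,
            f"foci per division (f)      {self.f:>10.4g}  ± {self.f_sem:.2g} SEM",
            f"detection efficiency (p)   {self.p:>10.4g}",
            f"DSBs per division (r=f/p)  {self.r:>10.4g}  ± {self.r_sem:.2g}",
        ]
        if self.n_colonies is not None:
            lines.append(f"colonies                   {self.n_colonies:>10d}")
        if self.total_divisions is not None:
            lines.append(
                f"pooled foci/divisions      {self.total_foci}/{self.total_divisions}"
            )
        if self.q_ci is not None:
            lines.append(
                f"pooled 95% Wilson CI on q  [{self.q_ci[0]:.4g}, {self.q_ci[1]:.4g}]"
            )
        if self.r_sem_full is not None:
            lines.append(
                f"r SEM incl. efficiency     {self.r_sem_full:>10.2g}"
            )
        return "\n".join(lines)


@dataclass(frozen=True)
class LegacyFrequencyInput:
    """Inputs for converting a frequency-based estimate to a rate.

    ``F`` is the previously measured rate of cells acquiring ≥1 break per
    generation; ``total_foci``/``focus_cells`` give the mean number of
    foci per focus-carrying cell observed under the same growth
    conditions.
    """

    F: float
    total_foci: int
    focus_cells: int

    def __post_init__(self) -> None:
        if self.F < 0:
            raise ValueError("F must be non-negative")
        if self.focus_cells <= 0:
            raise ValueError("focus_cells must be positive")
        if self.total_foci < 0:
            raise ValueError("total_foci must be non-negative")

    @property
    def m(self) -> float:
        """Mean foci per focus-carrying cell."""
        return self.total_foci / self.focus_cells


def foci_per_division(traces: Sequence[MicrocolonyTrace]) -> tuple[float, float]:
    """Colony-level mean foci per division and its SEM.

    Each colony contributes f_i = final cumulative foci / final
    cumulative divisions.  Colonies whose founder never divided are
    excluded with a warning; if every trace is excluded this is an error.
    """
    f_i = []
    for tr in traces:
        if tr.n_divisions == 0:
            warnings.warn(
                f"colony {tr.colony_id} has 0 divisions; excluded from the rate",
                stacklevel=2,
            )
            continue
        f_i.append(tr.n_foci / tr.n_divisions)
    if not f_i:
        raise ValueError("no trace with at least one division")
    arr = np.asarray(f_i, dtype=float)
    f = float(arr.mean())
    f_sem = float(arr.std(ddof=1) / math.sqrt(len(arr))) if len(arr) > 1 else 0.0
    return f, f_sem


def correct_rate(
    f: float,
    f_sem: float,
    p: float,
    p_sem: float | None = None,
    propagate_efficiency: bool = False,
    **extra,
) -> RateEstimate:
    """Efficiency-correct a foci-per-division rate: r = f/p.

    By default the efficiency is treated as a known constant, so
    ``r_sem = f_sem / p`` (this reproduces the convention of quoting the
    corrected SEM as the focus-rate SEM divided by the efficiency).  With
    ``propagate_efficiency`` and ``p_sem`` given, the delta-method SEM
    including efficiency uncertainty is reported as ``r_sem_full``.
    """
    if not 0.0 < p <= 1.0:
        raise ValueError("efficiency p must lie in (0, 1]")
    if f_sem < 0:
        raise ValueError("f_sem must be non-negative")
    r = f / p
    r_sem = f_sem / p
    r_sem_full = None
    if propagate_efficiency:
        if p_sem is None:
            raise ValueError("propagate_efficiency requires p_sem")
        r_sem_full = math.sqrt((f_sem / p) ** 2 + (f * p_sem / p**2) ** 2)
    return RateEstimate(
        f=f, f_sem=f_sem, p=p, r=r, r_sem=r_sem, p_sem=p_sem,
        r_sem_full=r_sem_full, **extra,
    )


class MicrocolonyRateModel:
    """Rate inference over a set of microcolony traces.

    ``fit(efficiency=...)`` returns a :class:`RateEstimate` carrying the
    colony-level mean ± SEM, the efficiency-corrected rate, and a pooled
    Wilson interval on total foci / total divisions.
    """

    def __init__(self, traces: Sequence[MicrocolonyTrace]):
        if not traces:
            raise ValueError("need at least one trace")
        self.traces = list(traces)

    @classmethod
    def from_frames(cls, frames: pd.DataFrame) -> "MicrocolonyRateModel":
        """Build from a concatenated frames table with a colony_id column."""
        traces = []
        for cid, grp in frames.groupby("colony_id", sort=True):
            traces.append(
                MicrocolonyTrace(
                    colony_id=str(cid),
                    frames=grp.drop(columns="colony_id").reset_index(drop=True),
                    events=pd.DataFrame(columns=["time_h", "kind", "cell_id"]),
                )
            )
        return cls(traces)

    def fit(
        self,
        efficiency: float = 1.0,
        efficiency_se: float | None = None,
        propagate_efficiency: bool = False,
    ) -> RateEstimate:
        f, f_sem = foci_per_division(self.traces)
        used = [t for t in self.traces if t.n_divisions > 0]
        total_foci = sum(t.n_foci for t in used)
        total_div = sum(t.n_divisions for t in used)
        lo, hi = proportion_confint(total_foci, total_div, method="wilson")
        return correct_rate(
            f,
            f_sem,
            efficiency,
            p_sem=efficiency_se,
            propagate_efficiency=propagate_efficiency,
            n_colonies=len(used),
            q_ci=(float(lo), float(hi)),
            pooled_q=total_foci / total_div,
            total_foci=total_foci,
            total_divisions=total_div,
        )


def frequency_to_rate(inp: LegacyFrequencyInput) -> float:
    """Convert a ≥1-break-per-generation frequency to breaks per division.

    rate = F × (total_foci / focus_cells): the frequency of cells gaining
    at least one break per generation, scaled by the observed mean number
    of breaks per break-carrying cell.
    """
    return inp.F * inp.total_foci / inp.focus_cells


@dataclass
class GenerationDependenceResult:
    """Per-regime focus accrual rates and the between-regime ratio test.

    Generation-dependence is supported when the per-division rate ratio
    is compatible with 1 (its CI covers 1) while the per-hour ratio is
    not: focus accrual tracks divisions, not elapsed time.
    """

    regimes: pd.DataFrame
    ratio_per_division: float
    ratio_per_division_ci: tuple[float, float]
    ratio_per_hour: float
    ratio_per_hour_ci: tuple[float, float]
    supported: bool | None
    flags: list = field(default_factory=list)


def _katz_ratio_ci(
    k1: float, n1: float, k2: float, n2: float, z: float = 1.959963984540054
) -> tuple[float, tuple[float, float], bool]:
    """Katz log-ratio interval for (k1/n1)/(k2/n2); 0.5 continuity
    correction applied when any count is zero."""
    corrected = False
    if min(k1, k2) == 0:
        k1, k2 = k1 + 0.5, k2 + 0.5
        n1, n2 = n1 + 0.5, n2 + 0.5
        corrected = True
    ratio = (k1 / n1) / (k2 / n2)
    se = math.sqrt(
        max(1.0 / k1 - 1.0 / n1, 0.0) + max(1.0 / k2 - 1.0 / n2, 0.0)
    )
    lo = ratio * math.exp(-z * se)
    hi = ratio * math.exp(z * se)
    return ratio, (lo, hi), corrected


def _poisson_ratio_ci(
    k1: float, t1: float, k2: float, t2: float, z: float = 1.959963984540054
) -> tuple[float, tuple[float, float], bool]:
    """Log-ratio interval for two Poisson rates (per-hour comparison)."""
    corrected = False
    if min(k1, k2) == 0:
        k1, k2 = k1 + 0.5, k2 + 0.5
        corrected = True
    ratio = (k1 / t1) / (k2 / t2)
    se = math.sqrt(1.0 / k1 + 1.0 / k2)
    return ratio, (ratio * math.exp(-z * se), ratio * math.exp(z * se)), corrected


def _counts_at(trace: MicrocolonyTrace, t: float) -> tuple[int, int]:
    """Cumulative (divisions, foci) at the last frame with time ≤ t."""
    f = trace.frames
    idx = int(np.searchsorted(f["time_h"].to_numpy(), t + 1e-9, side="right")) - 1
    if idx < 0:
        return 0, 0
    return int(f["cum_divisions"].iloc[idx]), int(f["cum_foci"].iloc[idx])


def generation_dependence(
    traces: MicrocolonyTrace | Sequence[MicrocolonyTrace],
    regime_boundaries: Sequence[float],
) -> GenerationDependenceResult:
    """Test whether focus accrual tracks divisions rather than time.

    ``regime_boundaries`` are interior time points partitioning each
    trace's span into division-rate regimes (e.g. [9.0] for a fast-growth
    phase followed by starvation).  Counts are pooled over traces within
    each regime.  The ratio reported compares the first regime against
    the last; per-hour rates use the pooled cell-hours approximated by
    trapezoidal integration of n_cells over time.
    """
    if isinstance(traces, MicrocolonyTrace):
        traces = [traces]
    if not traces:
        raise ValueError("need at least one trace")
    boundaries = sorted(float(b) for b in regime_boundaries)
    t_last = max(float(tr.frames["time_h"].iloc[-1]) for tr in traces)
    if boundaries and (boundaries[0] <= 0 or boundaries[-1] >= t_last):
        raise ValueError("boundaries must lie strictly inside the traced time span")
    edges = [0.0] + boundaries + [t_last]

    flags: list[str] = []
    rows = []
    for lo_t, hi_t in zip(edges[:-1], edges[1:]):
        div = foc = 0
        cell_hours = 0.0
        for tr in traces:
            d0, f0 = _counts_at(tr, lo_t)
            d1, f1 = _counts_at(tr, hi_t)
            div += d1 - d0
            foc += f1 - f0
            fr = tr.frames
            tt = fr["time_h"].to_numpy(dtype=float)
            nn = fr["n_cells"].to_numpy(dtype=float)
            sel = (tt >= lo_t - 1e-9) & (tt <= hi_t + 1e-9)
            if sel.sum() > 1:
                cell_hours += float(np.trapezoid(nn[sel], tt[sel]))
        per_div = foc / div if div > 0 else math.nan
        if div == 0:
            flags.append(f"regime [{lo_t}, {hi_t}] h has 0 divisions; per-division rate undefined")
        per_hour = foc / cell_hours if cell_hours > 0 else math.nan
        rows.append((lo_t, hi_t, div, foc, cell_hours, per_div, per_hour))
    regimes = pd.DataFrame(
        rows,
        columns=["start_h", "end_h", "divisions", "foci", "cell_hours",
                 "foci_per_division", "foci_per_hour"],
    )

    first, last = regimes.iloc[0], regimes.iloc[-1]
    if first["foci"] == 0 and last["foci"] == 0:
        flags.append("no foci in the compared regimes; ratio undefined")
        return GenerationDependenceResult(
            regimes, math.nan, (math.nan, math.nan), math.nan,
            (math.nan, math.nan), None, flags,
        )
    if first["divisions"] == 0 or last["divisions"] == 0:
        return GenerationDependenceResult(
            regimes, math.nan, (math.nan, math.nan), math.nan,
            (math.nan, math.nan), None, flags,
        )
    rr_div, ci_div, corr1 = _katz_ratio_ci(
        first["foci"], first["divisions"], last["foci"], last["divisions"]
    )
    rr_h, ci_h, corr2 = _poisson_ratio_ci(
        first["foci"], first["cell_hours"], last["foci"], last["cell_hours"]
    )
    if corr1 or corr2:
        flags.append("zero focus count in one regime; 0.5 continuity correction applied")
    supported = bool(
        (ci_div[0] <= 1.0 <= ci_div[1]) and not (ci_h[0] <= 1.0 <= ci_h[1])
    )
    return GenerationDependenceResult(
        regimes, rr_div, ci_div, rr_h, ci_h, supported, flags
    )


@dataclass
class TwoSampleComparison:
    """Welch-style two-sample mean difference with 95% CI."""

    difference: float
    ci: tuple[float, float]
    t_stat: float
    p_value: float
    df: float
    mean_a: float
    mean_b: float
    n_a: int
    n_b: int
    degenerate: bool = False


def exposure_control_compare(
    sample_a: Sequence[float], sample_b: Sequence[float], alpha: float = 0.05
) -> TwoSampleComparison:
    """Welch comparison of per-cell (or per-colony) focus means.

    Used for the fluorescence-exposure control: colonies repeatedly
    pulsed with excitation light versus colonies first imaged late.  A
    zero-variance pair with unequal means cannot support a t interval and
    is flagged degenerate (the difference is still reported).
    """
    a = np.asarray(sample_a, dtype=float)
    b = np.asarray(sample_b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each sample needs at least 2 observations")
    diff = float(a.mean() - b.mean())
    va, vb = a.var(ddof=1), b.var(ddof=1)
    if va == 0 and vb == 0:
        return TwoSampleComparison(
            difference=diff, ci=(diff, diff),
            t_stat=math.inf if diff != 0 else 0.0,
            p_value=0.0 if diff != 0 else 1.0,
            df=float(len(a) + len(b) - 2),
            mean_a=float(a.mean()), mean_b=float(b.mean()),
            n_a=len(a), n_b=len(b), degenerate=diff != 0,
        )
    se2 = va / len(a) + vb / len(b)
    se = math.sqrt(se2)
    df = se2**2 / (
        (va / len(a)) ** 2 / (len(a) - 1) + (vb / len(b)) ** 2 / (len(b) - 1)
    )
    t_stat, p_value = stats.ttest_ind(a, b, equal_var=False)
    tcrit = stats.t.ppf(1 - alpha / 2, df)
    return TwoSampleComparison(
        difference=diff, ci=(diff - tcrit * se, diff + tcrit * se),
        t_stat=float(t_stat), p_value=float(p_value), df=float(df),
        mean_a=float(a.mean()), mean_b=float(b.mean()),
        n_a=len(a), n_b=len(b),
    )
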