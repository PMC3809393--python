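"""Detection-efficiency calibration from a gamma-ray dose–response.

Focus formation is linear in absorbed dose over the calibrated range, so
the slope of mean foci per cell against dose (foci/cell/Gy), divided by
the literature break yield (DSBs/cell/Gy, 0.031 for *E. coli*), gives
the probability that a true double-strand break is detected as a focus.

The model object follows the statsmodels convention: build a
:class:`DoseResponseCalibration` from a dose–response table, call
``fit()`` and read the estimates off the returned
:class:`CalibrationResult`.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._rng import child_rng

__all__ = [
    "ECOLI_DSB_YIELD_PER_GY",
    "CalibrationResult",
    "DoseResponseCalibration",
    "fit_dose_response",
    "net_induced_foci",
    "estimate_efficiency",
    "bootstrap_efficiency_ci",
]

#: literature gamma-ray break yield for E. coli (DSBs per cell per Gy),
#: measured by sucrose sedimentation.
ECOLI_DSB_YIELD_PER_GY = 0.031

_COLUMNS = ("dose_gy", "mean_foci", "sd_foci", "n_cells")


def _validate_table(table: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in ("dose_gy", "mean_foci") if c not in table.columns]
    if missing:
        raise ValueError(f"dose–response table missing columns {missing}")
    t = table.copy()
    if "sd_foci" not in t.columns:
        t["sd_foci"] = np.nan
    if "n_cells" not in t.columns:
        t["n_cells"] = np.nan
    if (t["dose_gy"] < 0).any():
        raise ValueError("doses must be non-negative")
    if t["dose_gy"].duplicated().any():
        raise ValueError("doses must be distinct")
    return t.sort_values("dose_gy", kind="stable").reset_index(drop=True)


@dataclass
class CalibrationResult:
    """Fitted dose–response and derived detection efficiency.

    slope/intercept are in foci·cell⁻¹·Gy⁻¹ and foci·cell⁻¹; ``r2`` is
    None when only two doses were fitted (a two-point line has no
    residual degrees of freedom).  ``efficiency = slope / yield_``;
    values above 1 are reported as-is with ``efficiency_gt1`` set.
    """

    slope: float
    intercept: float
    r2: float | None
    yield_: float
    efficiency: float
    slope_se: float | None = None
    efficiency_se: float | None = None
    efficiency_ci: tuple[float, float] | None = None
    efficiency_gt1: bool = False
    n_doses: int = 0
    weighted: bool = False

    def summary(self) -> str:
        lines = [
            "Dose-response calibration",
            "=" * 42,
            f"doses fitted          {self.n_doses:>10d}"
            + ("  (variance-weighted)" if self.weighted else ""),
            f"slope (foci/cell/Gy)  {self.slope:>10.4g}"
            + (f"  SE {self.slope_se:.2g}" if self.slope_se is not None else ""),
            f"intercept (foci/cell) {self.intercept:>10.4g}",
            f"r^2                   {self.r2:>10.4g}" if self.r2 is not None
            else "r^2                      (2-point fit)",
            f"assumed yield         {self.yield_:>10.4g}  DSBs/cell/Gy",
            f"detection efficiency  {self.efficiency:>10.4g}"
            + ("  (> 1: flagged)" if self.efficiency_gt1 else ""),
        ]
        if self.efficiency_ci is not None:
            lo, hi = self.efficiency_ci
            lines.append(f"efficiency 95% CI     [{lo:.4g}, {hi:.4g}]  (bootstrap)")
        return "\n".join(lines)


class DoseResponseCalibration:
    """OLS calibration of mean foci per cell against gamma-ray dose.

    Parameters
    ----------
    table : DataFrame
        Columns ``dose_gy, mean_foci`` and optionally ``sd_foci,
        n_cells`` (required for weighting and the bootstrap).
    yield_ : float
        Assumed true break yield in DSBs/cell/Gy.
    weighted : bool
        If True, weight each dose point by n/sd² (inverse variance of the
        per-dose mean) instead of the default unweighted fit on per-dose
        means.
    """

    def __init__(self, table: pd.DataFrame, yield_: float = ECOLI_DSB_YIELD_PER_GY,
                 weighted: bool = False):
        if yield_ <= 0:
            raise ValueError("yield must be positive")
        self.table = _validate_table(table)
        self.yield_ = float(yield_)
        self.weighted = bool(weighted)
        if len(self.table) < 2:
            raise ValueError("need at least 2 distinct doses to fit")

    def _fit_line(self, means: np.ndarray) -> tuple[float, float, float | None, float | None]:
        """Return (slope, intercept, r2, slope_se) for given per-dose means."""
        x = self.table["dose_gy"].to_numpy(dtype=float)
        y = np.asarray(means, dtype=float)
        if self.weighted:
            sd = self.table["sd_foci"].to_numpy(dtype=float)
            n = self.table["n_cells"].to_numpy(dtype=float)
            if np.isnan(sd).any() or np.isnan(n).any():
                raise ValueError("weighted fit needs sd_foci and n_cells")
            var = np.where(sd > 0, sd**2 / n, np.nan)
            # a zero-variance point would get infinite weight; cap at the
            # smallest positive variance present
            if np.isnan(var).all():
                w = np.ones_like(x)
            else:
                var = np.where(np.isnan(var), np.nanmin(var), var)
                w = 1.0 / var
        else:
            w = np.ones_like(x)
        wsum = w.sum()
        xbar = (w * x).sum() / wsum
        ybar = (w * y).sum() / wsum
        sxx = (w * (x - xbar) ** 2).sum()
        if sxx == 0:
            raise ValueError("all doses identical; slope undefined")
        sxy = (w * (x - xbar) * (y - ybar)).sum()
        slope = sxy / sxx
        intercept = ybar - slope * xbar
        k = len(x)
        if k <= 2:
            return slope, intercept, None, None
        resid = y - intercept - slope * x
        ss_res = (w * resid**2).sum()
        ss_tot = (w * (y - ybar) ** 2).sum()
        r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
        sigma2 = ss_res / (k - 2)
        slope_se = math.sqrt(sigma2 / sxx)
        return slope, intercept, r2, slope_se

    def fit(self, n_boot: int | None = None, seed: int = 0) -> CalibrationResult:
        """Fit the line and derive the detection efficiency.

        With ``n_boot`` set, also attach a percentile 95% bootstrap CI on
        the efficiency (see :meth:`bootstrap_efficiency_ci`).
        """
        slope, intercept, r2, slope_se = self._fit_line(self.table["mean_foci"].to_numpy())
        eff = estimate_efficiency(slope, self.yield_)
        res = CalibrationResult(
            slope=slope,
            intercept=intercept,
            r2=r2,
            yield_=self.yield_,
            efficiency=eff,
            slope_se=slope_se,
            efficiency_se=slope_se / self.yield_ if slope_se is not None else None,
            efficiency_gt1=bool(eff > 1.0),
            n_doses=len(self.table),
            weighted=self.weighted,
        )
        if n_boot is not None:
            res.efficiency_ci = self.bootstrap_efficiency_ci(n_boot=n_boot, seed=seed)
        return res

    def bootstrap_efficiency_ci(
        self, n_boot: int = 2000, seed: int = 0
    ) -> tuple[float, float]:
        """Percentile 95% bootstrap interval on the detection efficiency.

        Cells within each dose are the resampled cases; because the table
        stores per-dose summaries (mean, sd, n) rather than raw counts,
        resampling n cells with replacement is applied in its Gaussian
        limit: each replicate draws mean*_i ~ Normal(mean_i, sd_i/√n_i)
        and refits.  A zero-variance table therefore yields a zero-width
        interval at the point estimate.
        """
        if n_boot < 100:
            raise ValueError("n_boot must be at least 100")
        sd = self.table["sd_foci"].to_numpy(dtype=float)
        n = self.table["n_cells"].to_numpy(dtype=float)
        if np.isnan(sd).any() or np.isnan(n).any() or (n < 1).any():
            raise ValueError("bootstrap needs sd_foci and n_cells for every dose")
        rng = child_rng(seed, "bootstrap_efficiency")
        se = sd / np.sqrt(n)
        means = self.table["mean_foci"].to_numpy(dtype=float)
        draws = means[None, :] + se[None, :] * rng.standard_normal((n_boot, len(means)))
        x = self.table["dose_gy"].to_numpy(dtype=float)
        xbar = x.mean()
        sxx = ((x - xbar) ** 2).sum()
        slopes = ((x - xbar)[None, :] * (draws - draws.mean(axis=1, keepdims=True))).sum(
            axis=1
        ) / sxx
        effs = np.sort(slopes / self.yield_)
        lo, hi = np.percentile(effs, [2.5, 97.5])
        return float(lo), float(hi)

    def plot(self, ax=None, result: CalibrationResult | None = None):
        """Per-dose means with the fitted line."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        t = self.table
        yerr = None
        if t["sd_foci"].notna().all() and t["n_cells"].notna().all():
            yerr = t["sd_foci"] / np.sqrt(t["n_cells"])
        ax.errorbar(t["dose_gy"], t["mean_foci"], yerr=yerr, fmt="o", color="k")
        if result is None:
            result = self.fit()
        xs = np.linspace(0, t["dose_gy"].max(), 50)
        ax.plot(xs, result.intercept + result.slope * xs, color="tab:green")
        ax.set_xlabel("dose (Gy)")
        ax.set_ylabel("mean foci per cell")
        return ax


def fit_dose_response(
    table: pd.DataFrame,
    yield_: float = ECOLI_DSB_YIELD_PER_GY,
    weighted: bool = False,
) -> CalibrationResult:
    """Fit mean foci/cell against dose; see :class:`DoseResponseCalibration`.

    With exactly two doses this reduces to the two-point slope
    Δmean/Δdose and ``r2`` is reported as absent (None).
    """
    return DoseResponseCalibration(table, yield_=yield_, weighted=weighted).fit()


def net_induced_foci(table: pd.DataFrame, dose: float) -> float:
    """Mean foci/cell at ``dose`` minus the zero-dose mean (background)."""
    t = _validate_table(table)
    sel_d = t["dose_gy"].sub(dose).abs() < 1e-9
    sel_0 = t["dose_gy"].abs() < 1e-9
    if not sel_d.any() or not sel_0.any():
        raise ValueError(f"table must contain rows at dose {dose} Gy and 0 Gy")
    return float(t.loc[sel_d, "mean_foci"].iloc[0] - t.loc[sel_0, "mean_foci"].iloc[0])


def estimate_efficiency(slope: float, yield_: float) -> float:
    """Detection efficiency = slope / yield.

    Values above 1 (slope exceeding the assumed true yield) are returned
    unclamped with a warning.
    """
    if yield_ <= 0:
        raise ValueError("yield must be positive")
    eff = slope / yield_
    if eff > 1.0:
        warnings.warn(
            f"estimated efficiency {eff:.3g} exceeds 1; slope is larger than the "
            "assumed break yield",
            stacklevel=2,
        )
    return eff


def bootstrap_efficiency_ci(
    table: pd.DataFrame,
    yield_: float = ECOLI_DSB_YIELD_PER_GY,
    n_boot: int = 2000,
    seed: int = 0,
) -> tuple[float, float]:
    """Module-level wrapper for :meth:`DoseResponseCalibration.bootstrap_efficiency_ci`."""
    return DoseResponseCalibration(table, yield_=yield_).bootstrap_efficiency_ci(
        n_boot=n_boot, seed=seed
    )
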