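"""Relative ori:ter copy number by the ΔCt method, and the forward model
linking copy number to multi-focus fractions.

ΔCt for a sample is the mean threshold-cycle difference between the
terminus- and origin-proximal amplicons (replicates averaged on the Ct
scale); normalising to the ΔCt of a stationary-phase reference culture
(equal ori and ter copies per cell) gives the relative copy number
ratio = E^(ΔCt_sample − ΔCt_reference), with E the per-cycle
amplification factor (2 for perfect doubling).
"""

from __future__ import annotations

from typing import Mapping

import numpy as np
import pandas as pd
from scipy import stats

from .simulate import CopyModel

__all__ = ["relative_copy_number", "expected_multifocus_fraction"]


def relative_copy_number(
    table: pd.DataFrame,
    reference_sample: str,
    amplification_efficiency: float = 2.0,
    target_locus: str = "oriC",
    reference_locus: str = "terC",
) -> pd.Series:
    """Per-sample target:reference (ori:ter) copy-number ratio.

    Parameters
    ----------
    table : DataFrame
        Long format with columns ``sample, locus, ct``; one row per
        replicate reaction.
    reference_sample : str
        Sample assumed to carry equal copies of both loci (stationary
        phase); its ratio is 1 by construction.
    amplification_efficiency : float
        Fold amplification per cycle, E > 1; 2 means perfect doubling.

    Notes
    -----
    The ratio is invariant under adding a constant to all Ct values of a
    sample (a pipetting/loading offset shifts both loci equally and
    cancels in ΔCt).
    """
    required = {"sample", "locus", "ct"}
    if not required.issubset(table.columns):
        raise ValueError(f"Ct table needs columns {sorted(required)}")
    if amplification_efficiency <= 1.0:
        raise ValueError("amplification efficiency must exceed 1 fold/cycle")
    if (table["ct"] <= 0).any():
        raise ValueError("Ct values must be positive")

    mean_ct = table.groupby(["sample", "locus"], sort=True)["ct"].mean().unstack()
    for locus in (target_locus, reference_locus):
        if locus not in mean_ct.columns or mean_ct[locus].isna().any():
            bad = (
                mean_ct.index[mean_ct[locus].isna()].tolist()
                if locus in mean_ct.columns
                else mean_ct.index.tolist()
            )
            raise ValueError(f"locus {locus!r} missing for samples {bad}")
    if reference_sample not in mean_ct.index:
        raise ValueError(f"reference sample {reference_sample!r} not in table")

    delta_ct = mean_ct[reference_locus] - mean_ct[target_locus]
    ddct = delta_ct - delta_ct.loc[reference_sample]
    ratio = amplification_efficiency**ddct
    ratio.name = f"{target_locus}:{reference_locus}"
    return ratio


def expected_multifocus_fraction(model: CopyModel, p: float) -> float:
    """Exact P(cell shows >1 focus) under a copy-number/cutting model.

    Each of the cell's locus copies is cut independently with
    ``model.cut_prob`` and each cut detected with probability ``p``, so
    the detected-focus count given c copies is Binomial(c, cut_prob·p);
    the result is the exact mixture over the copy-number distribution.
    A single-copy cell can never show more than one focus.
    """
    if not 0.0 <= p <= 1.0:
        raise ValueError("detection efficiency p must lie in [0, 1]")
    pe = model.cut_prob * p
    total = 0.0
    for c, pr in model.copies.items():
        p_le1 = stats.binom.pmf(0, c, pe) + stats.binom.pmf(1, c, pe)
        total += pr * (1.0 - p_le1)
    return float(min(max(total, 0.0), 1.0))
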