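"""Two-channel focus matching, overlap, and interfocal geometry.

Green (break-marking) and red (chromosome-label) focus calls are matched
within each cell by minimum-total-distance assignment; cells are
classified by their channel ratio (1:1, 1:2 = one green with two red, or
other).  1:1 pair distances feed the overlap fraction at a configurable
threshold; 1:2 cells contribute a near and a far distance.  A separate
per-focus category count (A only / B only / both) serves experiments
where two break markers are scored in the same channel frame.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import linear_sum_assignment
from scipy.spatial.distance import cdist

__all__ = [
    "ColocConfig",
    "FocusMatches",
    "ColocSummary",
    "CategoryCounts",
    "match_foci",
    "colocalization_fraction",
    "interfocal_summary",
    "category_counts",
    "green_per_red",
]


@dataclass(frozen=True)
class ColocConfig:
    """Overlap threshold (µm) for calling two foci co-localized.

    The default 0.2 µm is approximately the lateral diffraction limit;
    the resolution floor records the smallest distance the optics can
    report and is surfaced in summaries, not applied as a cutoff.
    """

    overlap_threshold_um: float = 0.2
    resolution_floor_um: float = 0.0

    def __post_init__(self) -> None:
        if self.overlap_threshold_um <= 0:
            raise ValueError("overlap threshold must be positive")
        if self.resolution_floor_um < 0:
            raise ValueError("resolution floor must be non-negative")


@dataclass
class FocusMatches:
    """Per-cell matching output.

    ``cells``: one row per cell with both channels present
    (cell_id, n_green, n_red, ratio_class).  ``pairs``: matched pairs
    (cell_id, distance_um, kind) with kind in {"1:1", "1:2-near",
    "1:2-far", "other"}.  ``n_excluded``: cells that had calls in only
    one channel.
    """

    cells: pd.DataFrame
    pairs: pd.DataFrame
    n_excluded: int


def _assign(green_xy: np.ndarray, red_xy: np.ndarray) -> list[tuple[int, int, float]]:
    """Minimum-total-distance assignment of min(n_g, n_r) pairs."""
    dmat = cdist(green_xy, red_xy)
    gi, ri = linear_sum_assignment(dmat)
    return [(int(g), int(r), float(dmat[g, r])) for g, r in zip(gi, ri)]


def match_foci(
    calls: pd.DataFrame,
    green_channel: str = "green",
    red_channel: str = "red",
) -> FocusMatches:
    """Match green and red focus calls within each cell.

    ``calls`` needs columns cell_id, channel, x_um, y_um.  Within a cell,
    calls are sorted by (x, y) before assignment so that equal-distance
    ties resolve deterministically; matching minimises the total
    Euclidean distance over all pairings (for the 1:1 and 1:2 classes
    this coincides with mutual nearest-neighbour pairing).  Cells with an
    empty channel are excluded from pairing and counted.
    """
    required = {"cell_id", "channel", "x_um", "y_um"}
    if not required.issubset(calls.columns):
        raise ValueError(f"calls table needs columns {sorted(required)}")
    cell_rows = []
    pair_rows = []
    n_excluded = 0
    for cid, grp in calls.groupby("cell_id", sort=True):
        g = grp[grp["channel"] == green_channel].sort_values(
            ["x_um", "y_um"], kind="stable"
        )
        r = grp[grp["channel"] == red_channel].sort_values(
            ["x_um", "y_um"], kind="stable"
        )
        if len(g) == 0 or len(r) == 0:
            n_excluded += 1
            continue
        if (len(g), len(r)) == (1, 1):
            ratio = "1:1"
        elif (len(g), len(r)) == (1, 2):
            ratio = "1:2"
        else:
            ratio = "other"
        cell_rows.append((cid, len(g), len(r), ratio))
        gxy = g[["x_um", "y_um"]].to_numpy(dtype=float)
        rxy = r[["x_um", "y_um"]].to_numpy(dtype=float)
        if ratio == "1:2":
            d = np.sort(np.linalg.norm(rxy - gxy[0], axis=1))
            pair_rows.append((cid, float(d[0]), "1:2-near"))
            pair_rows.append((cid, float(d[1]), "1:2-far"))
        else:
            kind = "1:1" if ratio == "1:1" else "other"
            for _, _, dist in _assign(gxy, rxy):
                pair_rows.append((cid, dist, kind))
    cells = pd.DataFrame(cell_rows, columns=["cell_id", "n_green", "n_red", "ratio_class"])
    pairs = pd.DataFrame(pair_rows, columns=["cell_id", "distance_um", "kind"])
    return FocusMatches(cells=cells, pairs=pairs, n_excluded=n_excluded)


def colocalization_fraction(
    matches: FocusMatches,
    config: ColocConfig = ColocConfig(),
    experiments: Mapping[object, object] | None = None,
) -> tuple[float, float]:
    """Percent of 1:1 cells whose pair distance ≤ the overlap threshold.

    Returns (percent, SEM).  With ``experiments`` mapping cell_id to an
    experiment label, the SEM is across per-experiment percentages;
    otherwise it is the binomial SEM over cells.
    """
    p11 = matches.pairs[matches.pairs["kind"] == "1:1"]
    if len(p11) == 0:
        raise ValueError("no 1:1 cells to assess co-localization")
    hit = (p11["distance_um"] <= config.overlap_threshold_um).to_numpy()
    if experiments is not None:
        labels = p11["cell_id"].map(dict(experiments))
        if labels.isna().any():
            raise ValueError("every 1:1 cell needs an experiment label")
        per_exp = pd.Series(hit, index=p11.index).groupby(labels.to_numpy()).mean() * 100.0
        pct = float(per_exp.mean())
        sem = float(per_exp.std(ddof=1) / math.sqrt(len(per_exp))) if len(per_exp) > 1 else 0.0
        return pct, sem
    frac = hit.mean()
    pct = float(frac * 100.0)
    sem = float(100.0 * math.sqrt(frac * (1 - frac) / len(hit)))
    return pct, sem


@dataclass
class ColocSummary:
    """Distance means per ratio class; absent classes are None, not 0."""

    mean_distance_1to1: float | None
    mean_distance_near: float | None
    mean_distance_far: float | None
    counts: dict = field(default_factory=dict)


def interfocal_summary(matches: FocusMatches) -> ColocSummary:
    """Mean interfocal distances, separately for 1:1, 1:2-near, 1:2-far."""

    def _mean(kind: str) -> float | None:
        d = matches.pairs.loc[matches.pairs["kind"] == kind, "distance_um"]
        return float(d.mean()) if len(d) else None

    counts = matches.cells["ratio_class"].value_counts().to_dict()
    counts["excluded"] = matches.n_excluded
    return ColocSummary(
        mean_distance_1to1=_mean("1:1"),
        mean_distance_near=_mean("1:2-near"),
        mean_distance_far=_mean("1:2-far"),
        counts=counts,
    )


@dataclass
class CategoryCounts:
    """Single/double-marker focus percentages.

    With the default pooled denominator a matched pair counts once, so
    both_pct + a_only_pct + b_only_pct = 100.  The per-channel variant
    additionally reports the matched percentage of each channel
    separately.
    """

    both_pct: float
    a_only_pct: float
    b_only_pct: float
    n_matched: int
    n_a: int
    n_b: int
    denominator: str
    both_pct_a: float | None = None
    both_pct_b: float | None = None


def _greedy_threshold_match(
    a_xy: np.ndarray, b_xy: np.ndarray, threshold: float
) -> int:
    """Number of within-threshold pairs, each focus matched at most once.

    Candidate pairs are taken in increasing distance order (ties broken
    by index after coordinate sorting), which is symmetric in the two
    channels.
    """
    if len(a_xy) == 0 or len(b_xy) == 0:
        return 0
    dmat = cdist(a_xy, b_xy)
    order = np.dstack(np.unravel_index(np.argsort(dmat, axis=None, kind="stable"), dmat.shape))[0]
    used_a: set[int] = set()
    used_b: set[int] = set()
    n = 0
    for i, j in order:
        if dmat[i, j] > threshold:
            break
        if i in used_a or j in used_b:
            continue
        used_a.add(int(i))
        used_b.add(int(j))
        n += 1
    return n


def category_counts(
    a_calls: pd.DataFrame,
    b_calls: pd.DataFrame,
    config: ColocConfig = ColocConfig(),
    denominator: str = "pooled",
) -> CategoryCounts:
    """Classify foci as A-only, B-only, or both (within threshold).

    Calls must share a coordinate frame (columns x_um, y_um).  Foci
    within ``config.overlap_threshold_um`` of an unmatched focus in the
    other channel are paired greedily by distance; each focus matches at
    most once.  ``denominator='pooled'`` counts each matched pair once in
    the total (n_a + n_b − n_matched); ``'per_channel'`` also reports the
    matched share of each channel.
    """
    if denominator not in ("pooled", "per_channel"):
        raise ValueError("denominator must be 'pooled' or 'per_channel'")
    n_a, n_b = len(a_calls), len(b_calls)
    if n_a == 0 and n_b == 0:
        raise ValueError("both channels are empty")
    a_xy = (
        a_calls.sort_values(["x_um", "y_um"], kind="stable")[["x_um", "y_um"]]
        .to_numpy(dtype=float)
        if n_a
        else np.empty((0, 2))
    )
    b_xy = (
        b_calls.sort_values(["x_um", "y_um"], kind="stable")[["x_um", "y_um"]]
        .to_numpy(dtype=float)
        if n_b
        else np.empty((0, 2))
    )
    m = _greedy_threshold_match(a_xy, b_xy, config.overlap_threshold_um)
    total = n_a + n_b - m
    out = CategoryCounts(
        both_pct=100.0 * m / total,
        a_only_pct=100.0 * (n_a - m) / total,
        b_only_pct=100.0 * (n_b - m) / total,
        n_matched=m,
        n_a=n_a,
        n_b=n_b,
        denominator=denominator,
    )
    if denominator == "per_channel":
        out.both_pct_a = 100.0 * m / n_a if n_a else None
        out.both_pct_b = 100.0 * m / n_b if n_b else None
    return out


def green_per_red(
    green_counts: Sequence[int], red_counts: Sequence[int]
) -> float:
    """Total green foci per red focus over cells with ≥1 red focus.

    With every chromosome labelled red and every break cut and bound,
    this ratio estimates the per-chromosome focus-detection efficiency.
    """
    g = np.asarray(green_counts, dtype=float)
    r = np.asarray(red_counts, dtype=float)
    if g.shape != r.shape:
        raise ValueError("green and red count vectors must align per cell")
    keep = r > 0
    if not keep.any() or r[keep].sum() == 0:
        raise ValueError("no red foci in any cell")
    return float(g[keep].sum() / r[keep].sum())
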