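"""Synthetic-data generators for the GamGFP focus pipeline.

Every downstream stage (spot calling, dose–response calibration,
per-division rate inference, co-localization geometry, qPCR copy number)
can be exercised on data produced here, with the stochastic structure the
biology implies:

* microcolonies grow as a continuous-time branching process; each cell
  division carries an independent Bernoulli chance of producing a DNA
  double-strand break that is detected as a GamGFP focus, and focus-bearing
  cells stop dividing (GamGFP traps double-strand ends, blocking repair);
* gamma irradiation delivers Poisson-distributed breaks at a fixed yield
  per gray, thinned binomially by the detection efficiency, on top of a
  spontaneous background;
* site-specific endonuclease cutting produces per-cell focus counts that
  scale with the chromosomal copy number at the cut site;
* two-channel focus pairs whose physical separation saturates with genomic
  separation;
* diffraction-limited Gaussian spots rendered onto a Poisson-noise image.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from ._rng import child_rng

__all__ = [
    "SimParams",
    "MicrocolonyTrace",
    "CopyModel",
    "FocusPairGeometry",
    "ImageScene",
    "simulate_microcolony",
    "simulate_microcolonies",
    "simulate_dose_response",
    "simulate_cut_foci",
    "simulate_focus_pairs",
    "render_image",
]


def _check_finite(name: str, value: float) -> None:
    if not math.isfinite(value):
        raise ValueError(f"parameter {name!r} must be finite, got {value!r}")


@dataclass(frozen=True)
class SimParams:
    """Generative parameters for the spontaneous-break branching model.

    Parameters
    ----------
    r : float
        True DSB probability per cell division, in [0, 1].
    p : float
        Probability a DSB is detected as a focus (detection efficiency),
        in [0, 1].
    b : float
        Spontaneous background foci per cell at zero dose (Bernoulli per
        cell; all observed regimes have b < 1).
    y : float
        True DSBs per cell per Gy of ionizing radiation (literature yield
        for *E. coli*: 0.031).
    arrest_on_focus : bool
        If True, cells carrying a focus never divide again (absorbing
        state).
    tau_schedule : sequence of (start_h, tau_h)
        Piecewise-constant mean interdivision time: from ``start_h``
        onwards cells divide with exponential waiting times of mean
        ``tau_h`` hours.  The default emulates fast growth in glucose for
        9 h followed by near-halted division after glucose withdrawal.
    foci_per_hour : float, optional
        If set, replaces the per-division break process with a
        time-driven one: each live cell accrues foci as a Poisson process
        at this hourly rate, irrespective of division.  Used as the
        alternative hypothesis when testing generation-dependence.
    seed : int
        Base seed; fixed seed gives byte-identical outputs.
    """

    r: float = 0.021
    p: float = 0.71
    b: float = 0.043
    y: float = 0.031
    arrest_on_focus: bool = True
    tau_schedule: tuple[tuple[float, float], ...] = ((0.0, 1.0), (9.0, 12.0))
    foci_per_hour: float | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("r", "p"):
            v = getattr(self, name)
            _check_finite(name, v)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"parameter {name!r} must lie in [0, 1], got {v}")
        for name in ("b", "y"):
            v = getattr(self, name)
            _check_finite(name, v)
            if v < 0:
                raise ValueError(f"parameter {name!r} must be non-negative, got {v}")
        sched = tuple((float(t0), float(tau)) for t0, tau in self.tau_schedule)
        if not sched:
            raise ValueError("tau_schedule must contain at least one regime")
        if sched[0][0] != 0.0:
            raise ValueError("tau_schedule must start at time 0")
        starts = [t0 for t0, _ in sched]
        if any(b <= a for a, b in zip(starts, starts[1:])):
            raise ValueError("tau_schedule start times must be strictly increasing")
        for t0, tau in sched:
            _check_finite("tau_schedule", t0)
            _check_finite("tau_schedule", tau)
            if tau <= 0:
                raise ValueError("interdivision times must be strictly positive")
        object.__setattr__(self, "tau_schedule", sched)
        if self.foci_per_hour is not None:
            _check_finite("foci_per_hour", self.foci_per_hour)
            if self.foci_per_hour < 0:
                raise ValueError("foci_per_hour must be non-negative")
        if self.seed < 0:
            raise ValueError("seed must be non-negative")

    def tau_at(self, t: float) -> float:
        """Mean interdivision time in force at time ``t`` (hours)."""
        tau = self.tau_schedule[0][1]
        for t0, tt in self.tau_schedule:
            if t0 <= t:
                tau = tt
            else:
                break
        return tau

    def next_boundary(self, t: float) -> float:
        """First schedule change strictly after ``t``, or +inf."""
        for t0, _ in self.tau_schedule:
            if t0 > t:
                return t0
        return math.inf


@dataclass
class MicrocolonyTrace:
    """Lineage/time record of one microcolony.

    ``frames`` is a time-sampled summary (time_h, n_cells, cum_divisions,
    cum_foci); ``events`` is the full event log (time_h, kind, cell_id)
    with kind in {"division", "focus"}.  Division events record the mother
    cell; a focus event records the daughter carrying the scored focus.
    """

    colony_id: str
    frames: pd.DataFrame
    events: pd.DataFrame

    @property
    def n_divisions(self) -> int:
        return int(self.frames["cum_divisions"].iloc[-1])

    @property
    def n_foci(self) -> int:
        return int(self.frames["cum_foci"].iloc[-1])

    def validate(self, arrest_on_focus: bool = True) -> None:
        """Raise ValueError if any structural invariant is violated."""
        f = self.frames
        if (np.diff(f["cum_divisions"]) < 0).any() or (np.diff(f["cum_foci"]) < 0).any():
            raise ValueError("cumulative counts must be non-decreasing")
        if not (f["n_cells"] == 1 + f["cum_divisions"]).all():
            raise ValueError("n_cells must equal 1 + cum_divisions at every frame")
        if arrest_on_focus and len(self.events):
            ev = self.events.sort_values("time_h", kind="stable")
            focus_time: dict[str, float] = {}
            for _, row in ev.iterrows():
                if row["kind"] == "focus":
                    focus_time[row["cell_id"]] = row["time_h"]
                elif row["kind"] == "division" and row["cell_id"] in focus_time:
                    raise ValueError(
                        f"cell {row['cell_id']} divided after its focus event"
                    )

    def plot(self, ax=None):
        """Cumulative divisions and foci against time (one colony)."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        ax.step(self.frames["time_h"], self.frames["cum_divisions"], where="post",
                color="tab:blue", label="cumulative divisions")
        ax.step(self.frames["time_h"], self.frames["cum_foci"], where="post",
                color="tab:green", label="cumulative foci")
        ax.set_xlabel("time (h)")
        ax.set_ylabel("count")
        ax.set_title(self.colony_id)
        ax.legend()
        return ax


def simulate_microcolony(
    params: SimParams,
    t_end: float,
    colony_id: str = "c0",
    max_cells: int | None = None,
    frame_interval_h: float = 1.0,
) -> MicrocolonyTrace:
    """Grow one microcolony from a single founder cell.

    Cells divide with exponential waiting times whose mean follows
    ``params.tau_schedule`` (the process is Markovian, so regime changes
    simply re-draw the waiting clock).  Each division carries an
    independent Bernoulli(q) chance, q = r·p, of producing a detected
    focus.  A focus formed at division affects both products of that
    division (the broken, GamGFP-bound chromosome cannot complete
    segregation), so one focus event is scored and — when
    ``arrest_on_focus`` — both daughters leave the dividing pool.

    Parameters
    ----------
    params : SimParams
    t_end : float
        Simulated duration in hours; must be positive and covered by the
        tau schedule (which starts at 0).
    max_cells : int, optional
        Stop once the colony reaches this size (the trace then ends at
        the stopping time rather than ``t_end``).
    frame_interval_h : float
        Cadence of the ``frames`` summary; a final frame at the stop
        time is always included.
    """
    if not (t_end > 0 and math.isfinite(t_end)):
        raise ValueError("t_end must be positive and finite")
    if frame_interval_h <= 0:
        raise ValueError("frame_interval_h must be positive")
    if max_cells is not None and max_cells < 2:
        raise ValueError("max_cells must be at least 2")

    rng = child_rng(params.seed, "microcolony", colony_id)
    q = params.r * params.p
    lam_t = params.foci_per_hour  # time-driven alternative; None = per-division

    active: list[int] = [0]
    next_id = 1
    divisions = 0
    events: list[tuple[float, str, str]] = []
    t = 0.0
    t_stop = t_end

    while active:
        tau = params.tau_at(t)
        boundary = min(params.next_boundary(t), t_end)
        div_rate = len(active) / tau
        foc_rate = len(active) * lam_t if lam_t is not None else 0.0
        total_rate = div_rate + foc_rate
        dt = rng.exponential(1.0 / total_rate)
        if t + dt >= boundary:
            t = boundary
            if t >= t_end:
                break
            continue  # memoryless: re-draw under the new regime
        t += dt
        if lam_t is not None and rng.random() < foc_rate / total_rate:
            i = int(rng.integers(len(active)))
            cell = active[i]
            events.append((t, "focus", f"c{cell}"))
            if params.arrest_on_focus:
                active.pop(i)
            continue
        # division
        i = int(rng.integers(len(active)))
        mother = active.pop(i)
        d1, d2 = next_id, next_id + 1
        next_id += 2
        divisions += 1
        events.append((t, "division", f"c{mother}"))
        got_focus = lam_t is None and rng.random() < q
        if got_focus:
            events.append((t, "focus", f"c{d1}"))
            if not params.arrest_on_focus:
                active.extend((d1, d2))
        else:
            active.extend((d1, d2))
        if max_cells is not None and 1 + divisions >= max_cells:
            t_stop = t
            break

    ev = pd.DataFrame(events, columns=["time_h", "kind", "cell_id"])
    frame_times = np.arange(0.0, t_stop, frame_interval_h)
    frame_times = np.append(frame_times, t_stop)
    div_times = np.sort(ev.loc[ev["kind"] == "division", "time_h"].to_numpy())
    foc_times = np.sort(ev.loc[ev["kind"] == "focus", "time_h"].to_numpy())
    cum_div = np.searchsorted(div_times, frame_times, side="right")
    cum_foc = np.searchsorted(foc_times, frame_times, side="right")
    frames = pd.DataFrame(
        {
            "time_h": frame_times,
            "n_cells": 1 + cum_div,
            "cum_divisions": cum_div,
            "cum_foci": cum_foc,
        }
    )
    return MicrocolonyTrace(colony_id=colony_id, frames=frames, events=ev)


def simulate_microcolonies(
    params: SimParams,
    n_colonies: int,
    t_end: float,
    max_cells: int = 100,
    frame_interval_h: float = 1.0,
    require_growth: bool = True,
    max_attempts_factor: int = 50,
) -> list[MicrocolonyTrace]:
    """Simulate founders until ``n_colonies`` grow into microcolonies.

    Time-lapse experiments score founder cells that grow into
    microcolonies of the target size; a founder whose lineage fully
    arrests beforehand (e.g. a focus at the very first division stops
    both daughters) never becomes a scoreable microcolony.  With
    ``require_growth`` such clones are discarded and further founders
    drawn (each founder has its own seed stream, so the kept set is
    reproducible).
    """
    if n_colonies < 1:
        raise ValueError("n_colonies must be at least 1")
    traces: list[MicrocolonyTrace] = []
    attempt = 0
    while len(traces) < n_colonies:
        if attempt >= max_attempts_factor * n_colonies:
            raise RuntimeError(
                "too few founders grew into microcolonies; check parameters"
            )
        tr = simulate_microcolony(
            params, t_end, colony_id=f"colony{attempt:04d}",
            max_cells=max_cells, frame_interval_h=frame_interval_h,
        )
        attempt += 1
        if require_growth and int(tr.frames["n_cells"].iloc[-1]) < max_cells:
            continue
        traces.append(tr)
    return traces


def simulate_dose_response(
    params: SimParams,
    doses: Sequence[float],
    n_cells: int,
) -> pd.DataFrame:
    """Simulate a gamma-ray dose–response experiment.

    Per cell at dose D: true breaks ~ Poisson(y·D); each detected with
    probability p (binomial thinning); plus a Bernoulli(b) spontaneous
    background focus.  Returns one row per dose with columns
    ``dose_gy, mean_foci, sd_foci, n_cells``.
    """
    doses = [float(d) for d in doses]
    if not doses:
        raise ValueError("doses must be non-empty")
    if any(d < 0 for d in doses):
        raise ValueError("doses must be non-negative")
    if n_cells < 1:
        raise ValueError("n_cells must be at least 1")
    rng = child_rng(params.seed, "dose_response")
    rows = []
    for d in doses:
        true = rng.poisson(params.y * d, size=n_cells)
        detected = rng.binomial(true, params.p)
        background = rng.random(n_cells) < params.b
        obs = detected + background
        sd = float(obs.std(ddof=1)) if n_cells > 1 else 0.0
        rows.append((d, float(obs.mean()), sd, n_cells))
    return pd.DataFrame(rows, columns=["dose_gy", "mean_foci", "sd_foci", "n_cells"])


@dataclass(frozen=True)
class CopyModel:
    """Distribution of locus copies per cell and a per-copy cut probability.

    ``copies`` maps copy number (positive int) to probability; probabilities
    must sum to 1.  In log-phase *E. coli* an origin-proximal locus is
    present in more copies than a terminus-proximal one (some cells carry
    two, some four ori:ter regions).
    """

    copies: Mapping[int, float]
    cut_prob: float

    def __post_init__(self) -> None:
        if not self.copies:
            raise ValueError("copies distribution must be non-empty")
        total = 0.0
        for k, pr in self.copies.items():
            if int(k) != k or k < 1:
                raise ValueError("copy numbers must be positive integers")
            if pr < 0:
                raise ValueError("copy probabilities must be non-negative")
            total += pr
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"copy distribution must sum to 1, got {total}")
        if not 0.0 <= self.cut_prob <= 1.0:
            raise ValueError("cut_prob must lie in [0, 1]")

    @property
    def support(self) -> np.ndarray:
        return np.array(sorted(self.copies), dtype=int)

    @property
    def probs(self) -> np.ndarray:
        return np.array([self.copies[k] for k in sorted(self.copies)], dtype=float)


def simulate_cut_foci(
    model: CopyModel, p: float, n_cells: int, seed: int
) -> np.ndarray:
    """Per-cell detected-focus counts from site-specific cutting.

    Each cell draws a copy number, each copy is cut independently with
    ``model.cut_prob``, and each cut is detected as a focus with
    probability ``p``.
    """
    if not 0.0 <= p <= 1.0:
        raise ValueError("detection efficiency p must lie in [0, 1]")
    if n_cells < 1:
        raise ValueError("n_cells must be at least 1")
    rng = child_rng(seed, "cut_foci")
    copies = rng.choice(model.support, size=n_cells, p=model.probs)
    cut = rng.binomial(copies, model.cut_prob)
    return rng.binomial(cut, p)


@dataclass(frozen=True)
class FocusPairGeometry:
    """Saturating map from genomic separation to mean interfocal distance.

    mean(g) = floor + (plateau − floor)·(1 − exp(−g/halfsat)) for g > 0,
    and exactly 0 at g = 0 when floor = 0.  The plateau reflects the
    observation that loci beyond ~80 kb apart are not proportionally
    farther apart in space within the nucleoid.  Distances are drawn from
    a Gamma distribution with this mean and shape ``shape`` (fixed
    coefficient of variation 1/sqrt(shape)).
    """

    plateau_um: float = 0.57
    halfsat_kb: float = 35.0
    floor_um: float = 0.0
    shape: float = 4.0

    def __post_init__(self) -> None:
        if self.plateau_um < 0 or self.floor_um < 0 or self.halfsat_kb <= 0:
            raise ValueError("geometry parameters must be non-negative (halfsat positive)")
        if self.floor_um > self.plateau_um:
            raise ValueError("floor must not exceed plateau")
        if self.shape <= 0:
            raise ValueError("shape must be positive")

    def mean_distance_um(self, genomic_distance_kb: float) -> float:
        if genomic_distance_kb < 0:
            raise ValueError("genomic distance must be non-negative")
        if genomic_distance_kb == 0:
            return self.floor_um
        sat = 1.0 - math.exp(-genomic_distance_kb / self.halfsat_kb)
        return self.floor_um + (self.plateau_um - self.floor_um) * sat


def simulate_focus_pairs(
    genomic_distance_kb: float,
    geom: FocusPairGeometry,
    n_cells: int,
    seed: int,
) -> pd.DataFrame:
    """Two-channel focus table: one red and one green focus per cell.

    The red (chromosome-label) focus sits at a uniform position within a
    cell-sized box; the green (break) focus is displaced by a Gamma-
    distributed distance with mean ``geom.mean_distance_um(genomic
    distance)`` in a uniform direction.  Columns: cell_id, channel,
    x_um, y_um, intensity.
    """
    if genomic_distance_kb < 0:
        raise ValueError("genomic distance must be non-negative")
    if n_cells < 1:
        raise ValueError("n_cells must be at least 1")
    rng = child_rng(seed, "focus_pairs", genomic_distance_kb)
    mu = geom.mean_distance_um(genomic_distance_kb)
    rx = rng.uniform(0.5, 2.0, n_cells)
    ry = rng.uniform(0.2, 0.8, n_cells)
    if mu == 0.0:
        d = np.zeros(n_cells)
    else:
        d = rng.gamma(geom.shape, mu / geom.shape, n_cells)
    theta = rng.uniform(0.0, 2.0 * math.pi, n_cells)
    gx = rx + d * np.cos(theta)
    gy = ry + d * np.sin(theta)
    cells = [f"cell{i}" for i in range(n_cells)]
    red = pd.DataFrame(
        {"cell_id": cells, "channel": "red", "x_um": rx, "y_um": ry, "intensity": 1000.0}
    )
    green = pd.DataFrame(
        {"cell_id": cells, "channel": "green", "x_um": gx, "y_um": gy, "intensity": 1000.0}
    )
    return (
        pd.concat([red, green], ignore_index=True)
        .sort_values(["cell_id", "channel"], kind="stable")
        .reset_index(drop=True)
    )


@dataclass(frozen=True)
class ImageScene:
    """Ground truth for a rendered fluorescence field.

    ``spots`` are (x_um, y_um, amplitude, sigma_um) with amplitude the
    peak expected photon count above background; ``background`` is the
    expected photons per pixel.  Pixel (row, col) has its center at
    physical position (x, y) = (col, row) · pixel_size_um.
    """

    shape: tuple[int, int]
    pixel_size_um: float
    spots: tuple[tuple[float, float, float, float], ...] = ()
    background: float = 0.0

    def __post_init__(self) -> None:
        nr, nc = self.shape
        if nr < 1 or nc < 1:
            raise ValueError("image shape must be positive")
        if self.pixel_size_um <= 0:
            raise ValueError("pixel size must be positive")
        if self.background < 0:
            raise ValueError("background must be non-negative")
        spots = tuple(tuple(map(float, s)) for s in self.spots)
        xmax = (nc - 1) * self.pixel_size_um
        ymax = (nr - 1) * self.pixel_size_um
        for x, y, amp, sig in spots:
            if amp < 0 or sig <= 0:
                raise ValueError("spot amplitude must be >= 0 and sigma > 0")
            if not (0.0 <= x <= xmax and 0.0 <= y <= ymax):
                raise ValueError(f"spot at ({x}, {y}) µm lies outside the field")
        object.__setattr__(self, "spots", spots)

    def expected_image(self) -> np.ndarray:
        """Noise-free expected photon count per pixel."""
        nr, nc = self.shape
        img = np.full((nr, nc), float(self.background))
        px = self.pixel_size_um
        for x, y, amp, sig in self.spots:
            s_px = sig / px
            c0, r0 = x / px, y / px
            half = int(math.ceil(6.0 * s_px)) + 1
            rlo = max(0, int(math.floor(r0)) - half)
            rhi = min(nr, int(math.ceil(r0)) + half + 1)
            clo = max(0, int(math.floor(c0)) - half)
            chi = min(nc, int(math.ceil(c0)) + half + 1)
            rr = np.arange(rlo, rhi)[:, None]
            cc = np.arange(clo, chi)[None, :]
            img[rlo:rhi, clo:chi] += amp * np.exp(
                -((rr - r0) ** 2 + (cc - c0) ** 2) / (2.0 * s_px**2)
            )
        return img


def render_image(scene: ImageScene, seed: int) -> np.ndarray:
    """Render a scene with per-pixel Poisson shot noise (photon counts)."""
    rng = child_rng(seed, "render_image")
    return rng.poisson(scene.expected_image()).astype(np.float64)
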