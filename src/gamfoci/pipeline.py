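"""End-to-end orchestration: simulate → calibrate → rate → coloc → report.

A :class:`RunConfig` plus its seed fully determines every output byte;
per-stage random streams are derived from the single seed by stable
labels, so adding a stage does not shift existing streams.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import calibration, coloc, io, qpcr, rates
from .simulate import (
    CopyModel,
    FocusPairGeometry,
    SimParams,
    simulate_dose_response,
    simulate_focus_pairs,
    simulate_microcolonies,
)

__all__ = ["RunConfig", "PipelineError", "run_pipeline"]

log = logging.getLogger("gamfoci")


class PipelineError(RuntimeError):
    """One or more pipeline stages failed; message lists them."""


@dataclass
class RunConfig:
    """Complete configuration for a pipeline run."""

    seed: int = 0
    outdir: str = "gamfoci_run"
    # microcolony simulation
    r: float = 0.021
    p: float = 0.71
    b: float = 0.043
    y: float = 0.031
    arrest_on_focus: bool = True
    tau_schedule: tuple[tuple[float, float], ...] = ((0.0, 1.0), (9.0, 12.0))
    n_colonies: int = 20
    max_cells: int = 100
    t_end_h: float = 30.0
    # dose-response
    doses_gy: tuple[float, ...] = (0.0, 20.0, 40.0, 70.0, 100.0, 140.0)
    n_cells_per_dose: int = 5000
    n_boot: int = 2000
    # coloc
    overlap_threshold_um: float = 0.2
    genomic_distances_kb: tuple[float, ...] = (10.0, 55.0, 80.0, 2400.0)
    n_pair_cells: int = 300
    # legacy frequency correction
    legacy_F: float = 0.01
    legacy_total_foci: int = 108
    legacy_focus_cells: int = 98
    log_level: str = "INFO"

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with Path(path).open() as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "tau_schedule" in raw:
            raw["tau_schedule"] = tuple(tuple(x) for x in raw["tau_schedule"])
        for key in ("doses_gy", "genomic_distances_kb"):
            if key in raw:
                raw[key] = tuple(raw[key])
        return cls(**raw)

    def sim_params(self, seed: int) -> SimParams:
        return SimParams(
            r=self.r, p=self.p, b=self.b, y=self.y,
            arrest_on_focus=self.arrest_on_focus,
            tau_schedule=self.tau_schedule, seed=seed,
        )


def _arithmetic_report(config: RunConfig) -> list[str]:
    """The deterministic arithmetic chain from the configured constants."""
    mean0 = config.b
    mean140 = config.b + config.p * config.y * 140.0
    table = pd.DataFrame(
        {
            "dose_gy": [0.0, 140.0],
            "mean_foci": [mean0, mean140],
            "sd_foci": [0.0, 0.0],
            "n_cells": [1, 1],
        }
    )
    fit = calibration.fit_dose_response(table, yield_=config.y)
    net = calibration.net_induced_foci(table, 140.0)
    legacy = rates.frequency_to_rate(
        rates.LegacyFrequencyInput(
            config.legacy_F, config.legacy_total_foci, config.legacy_focus_cells
        )
    )
    return [
        "Deterministic arithmetic chain",
        "------------------------------",
        f"two-point slope (0 -> 140 Gy):        {fit.slope:.3g} foci/cell/Gy",
        f"net induced foci at 140 Gy:           {net:.3g} foci/cell",
        f"detection efficiency (slope/yield):   {fit.efficiency:.2f}",
        f"legacy frequency correction:          "
        f"{config.legacy_F:g} x {config.legacy_total_foci}/{config.legacy_focus_cells}"
        f" = {legacy:.3g} DSBs/division",
        "",
    ]


def run_pipeline(config: RunConfig) -> dict:
    """Run every stage, write the report bundle, return results.

    Stage failures are logged and the remaining stages still run; a
    :class:`PipelineError` naming the failed stages is raised at the end
    (the CLI converts it to a non-zero exit status).
    """
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), logging.INFO))
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    results: dict = {}
    failed: list[str] = []
    report: list[str] = ["gamfoci pipeline report", "=" * 23, ""]
    report += _arithmetic_report(config)

    # --- simulate + rate ---------------------------------------------------
    try:
        params = config.sim_params(config.seed)
        traces = simulate_microcolonies(
            params, config.n_colonies, t_end=config.t_end_h,
            max_cells=config.max_cells,
        )
        io.write_traces(traces, outdir / "traces.tsv", outdir / "events.tsv")
        results["traces"] = traces
    except Exception:
        log.exception("microcolony simulation failed")
        failed.append("simulate_traces")
        traces = []

    # --- dose-response + calibration --------------------------------------
    try:
        dose_table = simulate_dose_response(
            config.sim_params(config.seed), config.doses_gy, config.n_cells_per_dose
        )
        io.write_table(dose_table, outdir / "dose_response.tsv", io.DOSE_SCHEMA)
        model = calibration.DoseResponseCalibration(dose_table, yield_=config.y)
        cal = model.fit(n_boot=config.n_boot, seed=config.seed)
        io.write_result_json(cal, outdir / "calibration.json")
        results["calibration"] = cal
        report += [
            "Calibration (synthetic dose-response)",
            "-------------------------------------",
            cal.summary(),
            "",
        ]
    except Exception:
        log.exception("calibration failed")
        failed.append("calibrate")
        cal = None

    try:
        if not traces:
            raise ValueError("no traces available")
        eff = cal.efficiency if cal is not None else config.p
        eff_se = cal.efficiency_se if cal is not None else None
        rate = rates.MicrocolonyRateModel(traces).fit(
            efficiency=eff,
            efficiency_se=eff_se,
            propagate_efficiency=eff_se is not None,
        )
        io.write_result_json(rate, outdir / "rate.json")
        results["rate"] = rate
        report += ["Rate inference (microcolony traces)", "-" * 35, rate.summary(), ""]
    except Exception:
        log.exception("rate inference failed")
        failed.append("rate")

    # --- co-localization ---------------------------------------------------
    try:
        geom = FocusPairGeometry()
        cfg = coloc.ColocConfig(overlap_threshold_um=config.overlap_threshold_um)
        pair_frames = []
        coloc_rows = []
        for g_kb in config.genomic_distances_kb:
            calls = simulate_focus_pairs(g_kb, geom, config.n_pair_cells, config.seed)
            calls = calls.assign(cell_id=calls["cell_id"] + f"_g{g_kb:g}")
            pair_frames.append(calls)
            matches = coloc.match_foci(calls)
            pct, sem = coloc.colocalization_fraction(matches, cfg)
            summ = coloc.interfocal_summary(matches)
            coloc_rows.append(
                {
                    "genomic_distance_kb": g_kb,
                    "pct_overlap": pct,
                    "pct_overlap_sem": sem,
                    "mean_distance_1to1_um": summ.mean_distance_1to1,
                }
            )
        io.write_table(
            pd.concat(pair_frames, ignore_index=True),
            outdir / "focus_pairs.tsv",
            io.FOCUS_SCHEMA,
        )
        io.write_result_json({"per_distance": coloc_rows}, outdir / "coloc.json")
        results["coloc"] = coloc_rows
        report += ["Co-localization vs genomic distance", "-" * 35]
        for row in coloc_rows:
            report.append(
                f"  {row['genomic_distance_kb']:>7g} kb: overlap "
                f"{row['pct_overlap']:5.1f}% , mean 1:1 distance "
                f"{row['mean_distance_1to1_um']:.3g} um"
            )
        report.append("")
    except Exception:
        log.exception("co-localization failed")
        failed.append("coloc")

    # --- qPCR copy number --------------------------------------------------
    try:
        # log-phase sample with 3x ori:ter (DDCt = log2(3)) vs stationary ref
        import math

        ct = pd.DataFrame(
            [
                ("stationary", "oriC", 20.0),
                ("stationary", "terC", 20.0),
                ("log_phase", "oriC", 18.0),
                ("log_phase", "terC", 18.0 + math.log2(3.0)),
            ],
            columns=["sample", "locus", "ct"],
        )
        io.write_table(ct, outdir / "ct.tsv", io.CT_SCHEMA)
        ratios = qpcr.relative_copy_number(ct, reference_sample="stationary")
        mf = qpcr.expected_multifocus_fraction(
            CopyModel(copies={2: 0.5, 4: 0.5}, cut_prob=1.0), p=config.p
        )
        io.write_result_json(
            {"ori_ter_ratio": ratios, "multifocus_fraction_2or4_copies": mf},
            outdir / "qcopy.json",
        )
        results["qcopy"] = ratios
        report += [
            "qPCR copy-number control",
            "------------------------",
            f"  ori:ter ratio (log phase):  {ratios['log_phase']:.3g}",
            "",
        ]
    except Exception:
        log.exception("qPCR stage failed")
        failed.append("qcopy")

    (outdir / "report.txt").write_text("\n".join(report) + "\n")
    results["report_path"] = outdir / "report.txt"
    if failed:
        raise PipelineError(f"stages failed: {', '.join(failed)}")
    return results
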