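"""End-to-end driver: simulate -> call -> chip -> fsv -> evaluate.

One seed drives every stage; re-running with the same configuration
reproduces identical output tables byte-for-byte.  A JSON manifest
records the configuration snapshot, the seed, output digests, package
version and timestamps so any output can be traced to its run.
"""

from __future__ import annotations

import datetime
import logging
from dataclasses import dataclass
from pathlib import Path

import pandas as pd

from . import __version__
from .config import SimulationConfig
from .simulate import simulate_truth, simulate_chip, simulate_pools
from .poolcall import call_sites, snp_density
from .chip import summarize_chip
from .fsv import fsv_scan, DEFAULT_WINDOWS_KB
from .evaluate import sensitivity, fsv_by_delta_bins, correlation_scan, best_windows
from . import io

logger = logging.getLogger(__name__)

STAGE_FILES = {
    "truth_snps": "truth_snps.tsv",
    "truth_blocks": "truth_blocks.tsv",
    "pileup": "pileup.tsv",
    "genotypes_high": "chip_genotypes_high.tsv",
    "genotypes_low": "chip_genotypes_low.tsv",
    "calls": "calls.tsv",
    "chip_summary": "chip_summary.tsv",
    "fsv": "fsv.tsv",
    "sensitivity": "sensitivity.tsv",
    "fsv_delta_bins": "fsv_delta_bins.tsv",
    "correlation_scan": "correlation_scan.tsv",
    "snp_density": "snp_density.tsv",
}


@dataclass
class PipelineResult:
    """In-memory handles to every stage output of one pipeline run."""

    config: SimulationConfig
    truth: object
    pileup: pd.DataFrame
    genotypes: dict
    calls: pd.DataFrame
    chip_summary: pd.DataFrame
    fsv_table: pd.DataFrame
    sensitivity: pd.DataFrame
    fsv_delta_bins: pd.DataFrame
    correlation: pd.DataFrame
    density: pd.DataFrame
    manifest: dict

    @property
    def best_windows(self) -> dict[str, int]:
        return best_windows(self.correlation)


def run_pipeline(
    config: SimulationConfig,
    out_dir=None,
    threshold: int = 3,
    windows_kb=DEFAULT_WINDOWS_KB,
    min_call_freq: float = 0.95,
    delta_min: float = 0.4,
) -> PipelineResult:
    """Run every stage on one seed; optionally persist all tables.

    The focal set for the flanking-window scan is the usable, polymorphic
    chip SNPs — the positions whose between-line informativity the scan
    is meant to predict.
    """
    logger.info("stage simulate: seed=%d, %d chromosomes, %.1f Mb",
                config.rng_seed, config.n_chromosomes,
                sum(config.chromosome_lengths.values()) / 1e6)
    truth = simulate_truth(config)
    genotypes = simulate_chip(truth, config)
    pileup = simulate_pools(truth, config)
    logger.info("simulated %d true SNPs (%d on chip)", len(truth.snps),
                int(truth.snps["on_chip"].sum()))

    calls = call_sites(pileup, threshold=threshold)
    logger.info("stage call: %d SNPs detected (threshold %d), %d excluded",
                len(calls), threshold, int(calls["excluded"].sum()))
    density = snp_density(
        calls, config.chromosome_lengths, config.chromosome_class_map
    ).reset_index()

    chip_summary = summarize_chip(genotypes, min_call_freq=min_call_freq)
    usable = chip_summary["usable"] & chip_summary["polymorphic"]
    logger.info("stage chip: %d chip SNPs, %d usable and polymorphic",
                len(chip_summary), int(usable.sum()))

    focal = chip_summary.loc[usable, ["chrom", "pos"]]
    fsv_table = fsv_scan(focal, calls, windows_kb=windows_kb,
                         chrom_lengths=config.chromosome_lengths)
    logger.info("stage fsv: %d focal SNPs x %d windows; %d rows pass filters",
                len(focal), len(windows_kb),
                int((fsv_table["defined"] & fsv_table["density_pass"]).sum()))

    sens = sensitivity(chip_summary, calls)
    scan = correlation_scan(chip_summary, fsv_table,
                            dict(config.chromosome_class_map),
                            delta_min=delta_min)
    ref_window = next(iter(best_windows(scan).values()), windows_kb[-1] * 1000)
    bins = fsv_by_delta_bins(chip_summary, fsv_table, window_total=ref_window)
    logger.info("stage evaluate: best windows %s", best_windows(scan))

    manifest = {
        "package": "fsvkit",
        "version": __version__,
        "seed": config.rng_seed,
        "config": config.to_dict(),
        "threshold": threshold,
        "windows_kb": list(windows_kb),
        "min_call_freq": min_call_freq,
        "delta_min": delta_min,
        "created": datetime.datetime.now(datetime.timezone.utc).isoformat(),
        "outputs": {},
    }

    result = PipelineResult(
        config=config, truth=truth, pileup=pileup, genotypes=genotypes,
        calls=calls, chip_summary=chip_summary, fsv_table=fsv_table,
        sensitivity=sens, fsv_delta_bins=bins, correlation=scan,
        density=density, manifest=manifest,
    )
    if out_dir is not None:
        _persist(result, Path(out_dir))
    return result


def _persist(result: PipelineResult, out_dir: Path) -> None:
    out_dir.mkdir(parents=True, exist_ok=True)
    comments = {"seed": result.config.rng_seed, "fsvkit": __version__}
    tables = {
        "truth_snps": result.truth.snps,
        "truth_blocks": result.truth.blocks,
        "pileup": result.pileup,
        "genotypes_high": result.genotypes["high"],
        "genotypes_low": result.genotypes["low"],
        "calls": result.calls,
        "chip_summary": result.chip_summary,
        "fsv": result.fsv_table,
        "sensitivity": result.sensitivity,
        "fsv_delta_bins": result.fsv_delta_bins,
        "correlation_scan": result.correlation,
        "snp_density": result.density,
    }
    for name, frame in tables.items():
        path = out_dir / STAGE_FILES[name]
        io.write_table(frame, path, comments)
        result.manifest["outputs"][STAGE_FILES[name]] = io.file_digest(path)
    result.config.to_yaml(out_dir / "config.yaml")
    io.write_manifest(out_dir / "manifest.json", result.manifest)
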