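"""End-to-end pipeline harness and the cells-by-depth downsampling sweep.

The sweep mirrors the classic experimental design for integrative phasing:
simulate one full data set per trial, then for every (number of Strand-seq
cells, read depth) grid point downsample cells and read rows, run
strand-state calling -> matrix sorting -> consensus -> super-read wMEC
integration -> evaluation, and average the quality metrics over trials.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .integrate import IntegrationConfig, integrative_phase
from .metrics import EvalReport, aggregate_reports, evaluate
from .simulate import (
    SimConfig,
    SimTruth,
    StrandSeqData,
    downsample_cells,
    downsample_rows,
    simulate_prephased_blocks,
    simulate_reads,
    simulate_strandseq,
    simulate_truth,
)
from .strandphase import phase_strandseq

logger = logging.getLogger(__name__)

METRIC_COLUMNS = (
    "completeness",
    "switch_error_rate",
    "largest_block_fraction",
    "largest_block_hamming_rate",
)


def run_pipeline(
    config: SimConfig,
    cell_ids: list[str] | None = None,
    target_read_depth: float | None = None,
    downsample_seed: int | None = None,
    use_blocks: bool = False,
    integration: IntegrationConfig | None = None,
) -> list[EvalReport]:
    """Simulate, phase integratively, and evaluate; one report per chromosome.

    ``cell_ids`` restricts the Strand-seq libraries used;
    ``target_read_depth`` thins the read rows (both seeded by
    ``downsample_seed``).
    """
    truth = simulate_truth(config)
    strandseq = simulate_strandseq(truth, config)
    reads = simulate_reads(truth, config)
    blocks = simulate_prephased_blocks(truth, config) if use_blocks else None
    reports: list[EvalReport] = []
    for chrom in truth.chroms:
        sites = truth.sites[chrom]
        obs = strandseq.observations[chrom]
        bins = strandseq.bins[chrom]
        if cell_ids is not None:
            wanted = set(cell_ids)
            obs = [o for o in obs if o.cell_id in wanted]
            bins = {c: b for c, b in bins.items() if c in wanted}
        consensus, _, _ = phase_strandseq(obs, bins, sites)
        read_matrix = reads[chrom]
        if target_read_depth is not None:
            read_matrix = downsample_rows(
                read_matrix, target_read_depth, seed=downsample_seed or 0
            )
        pred = integrative_phase(
            consensus,
            reads=read_matrix,
            blocks=blocks[chrom] if blocks else None,
            config=integration,
            sites=sites,
        )
        reports.append(evaluate(pred, truth.hap1[chrom], len(sites)))
    return reports


def sweep_base_config(seed: int) -> SimConfig:
    """Default study conditions for the downsampling sweep.

    Strand-seq is kept sparse (0.125 observations per site per cell) so that
    the largest library subset, 40 cells, reaches the ~5x cumulative
    Strand-seq coverage of a full real data set; one 200-site chromosome
    keeps a full grid affordable.
    """
    return SimConfig(
        seed=seed,
        n_chromosomes=1,
        n_sites_per_chrom=200,
        n_cells=40,
        cell_read_depth=0.125,
        read_depth=15.0,
        allele_error_rate=0.01,
    )


@dataclass(slots=True)
class SweepGrid:
    """Grid of (cells, depth) conditions, replicated over trials."""

    base: SimConfig
    cell_counts: tuple[int, ...] = (5, 10, 20, 40)
    depths: tuple[float, ...] = (2, 3, 5, 10, 15)
    n_trials: int = 5

    def __post_init__(self) -> None:
        if max(self.cell_counts) > self.base.n_cells:
            raise ValueError("cell_counts exceed simulated cells")
        if self.n_trials < 1:
            raise ValueError("n_trials must be >= 1")


@dataclass(slots=True)
class SweepResult:
    """Long-format per-(cells, depth, trial) metrics plus per-point means."""

    table: pd.DataFrame
    means: pd.DataFrame

    def pivot(self, metric: str) -> pd.DataFrame:
        return self.means.reset_index().pivot(
            index="cells", columns="depth", values=metric
        )


def run_sweep(grid: SweepGrid) -> SweepResult:
    """Run the full grid; failures at a grid point become NA rows."""
    records = []
    for trial in range(grid.n_trials):
        config = dataclasses.replace(grid.base, seed=grid.base.seed + trial)
        truth = simulate_truth(config)
        strandseq = simulate_strandseq(truth, config)
        reads = simulate_reads(truth, config)
        all_cells = sorted({cell for cell, _ in strandseq.states})
        for ci, n_cells in enumerate(grid.cell_counts):
            for di, depth in enumerate(grid.depths):
                ds_seed = (
                    config.seed + 7919 * trial + 104729 * ci + 1299709 * di
                ) % (2**31)
                record = {"cells": n_cells, "depth": depth, "trial": trial}
                try:
                    cells = downsample_cells(all_cells, n_cells, seed=ds_seed)
                    reports = []
                    for chrom in truth.chroms:
                        sites = truth.sites[chrom]
                        wanted = set(cells)
                        obs = [
                            o
                            for o in strandseq.observations[chrom]
                            if o.cell_id in wanted
                        ]
                        bins = {
                            c: b
                            for c, b in strandseq.bins[chrom].items()
                            if c in wanted
                        }
                        consensus, _, _ = phase_strandseq(obs, bins, sites)
                        read_matrix = downsample_rows(
                            reads[chrom], depth, seed=ds_seed + 1
                        )
                        pred = integrative_phase(
                            consensus, reads=read_matrix, sites=sites
                        )
                        reports.append(
                            evaluate(pred, truth.hap1[chrom], len(sites))
                        )
                    agg = aggregate_reports(reports)
                    record.update({m: agg[m] for m in METRIC_COLUMNS})
                except Exception:  # failed grid point: NA, sweep continues
                    logger.exception(
                        "sweep point failed: cells=%d depth=%s trial=%d",
                        n_cells,
                        depth,
                        trial,
                    )
                    record.update({m: np.nan for m in METRIC_COLUMNS})
                records.append(record)
    table = pd.DataFrame.from_records(
        records, columns=["cells", "depth", "trial", *METRIC_COLUMNS]
    )
    means = table.groupby(["cells", "depth"])[list(METRIC_COLUMNS)].mean()
    return SweepResult(table=table, means=means)
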