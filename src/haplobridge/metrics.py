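"""Haplotype quality metrics.

Four measures compare an assembled phasing against truth haplotypes:

* **completeness** — phase connections achieved over phase connections
  possible, where a *phase connection* is an adjacent pair of het variants
  phased within one haplotype segment: sum over blocks of (|block| - 1),
  divided by (number of het sites - 1);
* **switch error rate** — fraction of phase connections whose predicted
  relative phase disagrees with truth (a local accuracy measure);
* **largest block fraction** — fraction of het sites in the largest segment
  (a contiguity measure);
* **largest block Hamming rate** — fraction of the largest segment's sites
  assigned to the wrong haplotype under the best of the two label pairings
  (a global accuracy measure; a single mid-block switch error already gives
  rate 0.5).

All metrics are invariant under swapping any block's haplotype labels.
Rates that are undefined (no phase connections, empty phasing) are reported
as missing (None), never as zero.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .model import PhasedBlock, Phasing

logger = logging.getLogger(__name__)


@dataclass(slots=True)
class EvalReport:
    chrom: str
    n_het_sites: int
    completeness: float
    switch_error_rate: float | None
    largest_block_fraction: float
    largest_block_hamming_rate: float | None
    per_block: list[dict] = field(default_factory=list)
    n_switch_errors: int = 0
    n_connections_evaluated: int = 0

    TSV_COLUMNS = (
        "chrom",
        "n_het_sites",
        "completeness",
        "switch_error_rate",
        "largest_block_fraction",
        "largest_block_hamming_rate",
    )

    def row(self) -> dict:
        return {c: getattr(self, c) for c in self.TSV_COLUMNS}


def _as_truth_array(truth, n_sites: int) -> np.ndarray:
    """Truth hap1 alleles as an int array with -1 for uncovered sites."""
    if isinstance(truth, Phasing):
        arr = np.full(n_sites, -1, dtype=np.int64)
        for b in truth.blocks:
            for i, s in enumerate(b.site_indices):
                arr[s] = int(b.hap1[i])
        return arr
    if isinstance(truth, PhasedBlock):
        arr = np.full(n_sites, -1, dtype=np.int64)
        for i, s in enumerate(truth.site_indices):
            arr[s] = int(truth.hap1[i])
        return arr
    arr = np.asarray(truth, dtype=np.int64)
    if arr.shape != (n_sites,):
        raise ValueError(f"truth must cover all {n_sites} sites")
    return arr


def completeness(pred: Phasing, n_het_sites: int) -> float:
    """Achieved over maximum possible phase connections."""
    if n_het_sites < 2:
        raise ValueError("completeness needs at least 2 het sites")
    for b in pred.blocks:
        if b.site_indices[-1] >= n_het_sites:
            raise ValueError("block site outside [0, n_het_sites)")
    connections = sum(b.n_phase_connections for b in pred.blocks)
    return connections / (n_het_sites - 1)


def _block_switches(block: PhasedBlock, truth: np.ndarray) -> tuple[int, int]:
    """(#switch errors, #evaluable phase connections) of one block.

    Connections involving a site absent from truth are excluded from the
    denominator.
    """
    errors = 0
    total = 0
    skipped = 0
    for i in range(block.n_sites - 1):
        s1, s2 = block.site_indices[i], block.site_indices[i + 1]
        t1, t2 = truth[s1], truth[s2]
        if t1 < 0 or t2 < 0:
            skipped += 1
            continue
        pred_equal = block.hap1[i] == block.hap1[i + 1]
        true_equal = t1 == t2
        total += 1
        if pred_equal != true_equal:
            errors += 1
    if skipped:
        logger.info(
            "block %s: %d phase connections skipped (site missing from truth)",
            block.block_id,
            skipped,
        )
    return errors, total


def switch_error_rate(pred: Phasing, truth) -> float | None:
    """Fraction of phase connections whose relative phase disagrees with truth.

    Returns None when the phasing has no evaluable phase connection.
    """
    arr = _as_truth_array(truth, pred.n_sites)
    errors = 0
    total = 0
    for b in pred.blocks:
        e, t = _block_switches(b, arr)
        errors += e
        total += t
    if total == 0:
        return None
    return errors / total


def largest_block_fraction(pred: Phasing, n_het_sites: int) -> float:
    """Fraction of het sites inside the largest haplotype segment."""
    if n_het_sites < 1:
        raise ValueError("needs at least 1 het site")
    block = pred.largest_block
    if block is None:
        return 0.0
    return block.n_sites / n_het_sites


def hamming_rate_largest(pred: Phasing, truth) -> float | None:
    """Wrongly phased fraction of the largest segment, best label pairing.

    min over the two haplotype pairings of the per-site disagreement count,
    divided by the segment size; hence always in [0, 0.5].  None for an
    empty phasing.
    """
    block = pred.largest_block
    if block is None:
        return None
    arr = _as_truth_array(truth, pred.n_sites)
    mism1 = 0
    total = 0
    for i, s in enumerate(block.site_indices):
        if arr[s] < 0:
            continue
        total += 1
        if int(block.hap1[i]) != arr[s]:
            mism1 += 1
    if total == 0:
        return None
    return min(mism1, total - mism1) / total


def evaluate(pred: Phasing, truth, n_het_sites: int | None = None) -> EvalReport:
    """All four metrics plus a per-block table."""
    n = n_het_sites if n_het_sites is not None else pred.n_sites
    arr = _as_truth_array(truth, pred.n_sites)
    per_block = []
    n_err = 0
    n_eval = 0
    for b in sorted(pred.blocks, key=lambda b: b.block_id):
        e, t = _block_switches(b, arr)
        n_err += e
        n_eval += t
        per_block.append(
            {
                "block_id": b.block_id,
                "n_sites": b.n_sites,
                "n_phase_connections": b.n_phase_connections,
                "n_switch_errors": e,
            }
        )
    return EvalReport(
        chrom=pred.chrom,
        n_het_sites=n,
        completeness=completeness(pred, n),
        switch_error_rate=(n_err / n_eval) if n_eval else None,
        largest_block_fraction=largest_block_fraction(pred, n),
        largest_block_hamming_rate=hamming_rate_largest(pred, arr),
        per_block=per_block,
        n_switch_errors=n_err,
        n_connections_evaluated=n_eval,
    )


def aggregate_reports(reports: Sequence[EvalReport]) -> dict:
    """Pool per-chromosome reports.

    Completeness and switch error pool their numerators/denominators over
    chromosomes; largest-block fraction and Hamming rate are averaged over
    chromosomes with a defined value (each chromosome contributes its own
    largest segment).
    """
    conn = sum(
        sum(b["n_phase_connections"] for b in r.per_block) for r in reports
    )
    conn_max = sum(r.n_het_sites - 1 for r in reports)
    sw_err = sum(r.n_switch_errors for r in reports)
    sw_tot = sum(r.n_connections_evaluated for r in reports)
    lb = [r.largest_block_fraction for r in reports]
    hams = [
        r.largest_block_hamming_rate
        for r in reports
        if r.largest_block_hamming_rate is not None
    ]
    return {
        "completeness": conn / conn_max if conn_max else None,
        "switch_error_rate": (sw_err / sw_tot) if sw_tot else None,
        "largest_block_fraction": float(np.mean(lb)) if lb else None,
        "largest_block_hamming_rate": float(np.mean(hams)) if hams else None,
    }


def write_report_tsv(reports: Sequence[EvalReport], path: str | Path) -> None:
    """Stable-column TSV: one row per chromosome plus per-block rows."""
    with open(path, "w") as fh:
        fh.write("\t".join(EvalReport.TSV_COLUMNS) + "\n")
        for r in reports:
            vals = []
            for c in EvalReport.TSV_COLUMNS:
                v = getattr(r, c)
                if v is None:
                    vals.append("NA")
                elif isinstance(v, float):
                    vals.append(f"{v:.6g}")
                else:
                    vals.append(str(v))
            fh.write("\t".join(vals) + "\n")
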