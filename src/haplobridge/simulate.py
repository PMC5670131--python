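"""Synthetic diploid-genome generator for Strand-seq + read phasing.

The simulator produces, at desk scale, data with the statistical structure
the phasing method assumes:

* a diploid chromosome set with biallelic het SNVs whose haplotype-1 alleles
  are i.i.d. Bernoulli(0.5) (hap2 is the complement);
* Strand-seq cells whose chromosomes inherit template-strand states WW / CC
  / WC with probabilities 1/4, 1/4, 1/2, independently across cells and
  chromosomes; only in the WC state does the mapping strand reveal the
  homolog, elsewhere both homologs emit on the same strand (an
  uninformative mixture);
* long reads spanning a geometric number of consecutive het sites with a
  per-allele error rate;
* pre-phased haplotype blocks with geometric lengths and injected internal
  switch errors;
* binned Watson/Crick read counts consistent with each cell's strand state,
  for the strand-state caller.

All outputs are bit-reproducible given (seed, config); independent
sub-streams are derived from the config seed per data type.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .model import (
    AlleleCall,
    FragmentMatrix,
    FragmentRow,
    PhasedBlock,
    Phasing,
    VariantSite,
)
from .strandphase import BinCounts, CellObservations

_BASES = ("A", "C", "G", "T")

# sub-stream tags so the four generators draw independent randomness
_TRUTH, _STRANDSEQ, _READS, _BLOCKS = 11, 22, 33, 44


@dataclass(slots=True)
class SimConfig:
    """Study conditions of the synthetic experiment.

    ``cell_read_depth`` is the mean number of Strand-seq allele observations
    per site per cell (both strands combined); ``read_depth`` the mean number
    of long-read rows covering a site; ``read_span_sites`` the mean het
    sites per long read (geometric).
    """

    seed: int
    n_chromosomes: int = 3
    n_sites_per_chrom: int = 500
    chrom_length_bp: int = 5_000_000
    n_cells: int = 10
    cell_read_depth: float = 5.0
    wc_prob: float = 0.5
    ww_prob: float = 0.25
    cc_prob: float = 0.25
    allele_error_rate: float = 0.01
    background_read_fraction: float = 0.0
    read_span_sites: float = 5.0
    read_depth: float = 10.0
    block_length_sites: float = 50.0
    block_switch_rate: float = 0.01
    bin_size: int = 1_000_000
    bin_reads_mean: float = 60.0

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ValueError("seed is mandatory")
        if abs(self.wc_prob + self.ww_prob + self.cc_prob - 1.0) > 1e-9:
            raise ValueError("strand-state probabilities must sum to 1")
        for name in ("allele_error_rate", "background_read_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        if self.n_sites_per_chrom > self.chrom_length_bp:
            raise ValueError("more sites than base pairs")
        if self.read_span_sites < 1:
            raise ValueError("read_span_sites must be >= 1")


@dataclass(slots=True)
class SimTruth:
    """Ground-truth diploid genome."""

    chroms: list[str]
    sites: dict[str, list[VariantSite]]
    hap1: dict[str, np.ndarray]  # 0/1 alleles per site

    def hap2(self, chrom: str) -> np.ndarray:
        return 1 - self.hap1[chrom]


@dataclass(slots=True)
class StrandSeqData:
    """Simulated Strand-seq observations with their generating states."""

    observations: dict[str, list[CellObservations]]  # chrom -> per-cell obs
    bins: dict[str, dict[str, list[BinCounts]]]  # chrom -> cell -> bins
    states: dict[tuple[str, str], str]  # (cell, chrom) -> WW|CC|WC
    watson_homolog: dict[tuple[str, str], int]  # WC only: 0 -> W carries hap1


def _rng(config: SimConfig, tag: int) -> np.random.Generator:
    return np.random.default_rng([config.seed, tag])


def simulate_truth(config: SimConfig) -> SimTruth:
    rng = _rng(config, _TRUTH)
    chroms = [f"chr{i + 1}" for i in range(config.n_chromosomes)]
    sites: dict[str, list[VariantSite]] = {}
    hap1: dict[str, np.ndarray] = {}
    for chrom in chroms:
        n = config.n_sites_per_chrom
        pos = np.sort(
            rng.choice(config.chrom_length_bp, size=n, replace=False)
        ) + 1
        alleles = rng.integers(0, 2, size=n, dtype=np.int8)
        ref_idx = rng.integers(0, 4, size=n)
        alt_shift = rng.integers(1, 4, size=n)
        sites[chrom] = [
            VariantSite(
                chrom,
                int(pos[i]),
                _BASES[ref_idx[i]],
                _BASES[(ref_idx[i] + alt_shift[i]) % 4],
                site_index=i,
            )
            for i in range(n)
        ]
        hap1[chrom] = alleles
    return SimTruth(chroms, sites, hap1)


def _expand_counts(
    counts: np.ndarray,
    source_alleles: np.ndarray,
    strand: str,
    error_rate: float,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Expand per-site observation counts into (site, allele, strand) arrays."""
    idx = np.repeat(np.arange(len(counts)), counts)
    alleles = source_alleles[idx].astype(np.int8)
    if error_rate > 0 and idx.size:
        flip = rng.random(idx.size) < error_rate
        alleles = np.where(flip, 1 - alleles, alleles).astype(np.int8)
    strands = np.full(idx.size, strand, dtype="U1")
    return idx, alleles, strands


def simulate_strandseq(truth: SimTruth, config: SimConfig) -> StrandSeqData:
    rng = _rng(config, _STRANDSEQ)
    obs_out: dict[str, list[CellObservations]] = {c: [] for c in truth.chroms}
    bins_out: dict[str, dict[str, list[BinCounts]]] = {c: {} for c in truth.chroms}
    states: dict[tuple[str, str], str] = {}
    watson_h: dict[tuple[str, str], int] = {}
    cells = [f"cell{i:03d}" for i in range(config.n_cells)]
    half = config.cell_read_depth / 2.0
    e = config.allele_error_rate
    b = config.background_read_fraction
    n_bins = max(1, math.ceil(config.chrom_length_bp / config.bin_size))
    for chrom in truth.chroms:
        n = len(truth.sites[chrom])
        h1 = truth.hap1[chrom]
        h2 = 1 - h1
        for cell in cells:
            state = rng.choice(("WW", "CC", "WC"), p=(config.ww_prob, config.cc_prob, config.wc_prob))
            states[(cell, chrom)] = str(state)
            parts = []
            if state == "WC":
                h = int(rng.integers(0, 2))
                watson_h[(cell, chrom)] = h
                w_src, c_src = (h1, h2) if h == 0 else (h2, h1)
                parts.append(
                    _expand_counts(rng.poisson(half, n), w_src, "W", e, rng)
                )
                parts.append(
                    _expand_counts(rng.poisson(half, n), c_src, "C", e, rng)
                )
            else:
                strand = "W" if state == "WW" else "C"
                # both homologs emit on the same strand: uninformative mixture
                parts.append(
                    _expand_counts(rng.poisson(half, n), h1, strand, e, rng)
                )
                parts.append(
                    _expand_counts(rng.poisson(half, n), h2, strand, e, rng)
                )
            site_idx = np.concatenate([p[0] for p in parts])
            alleles = np.concatenate([p[1] for p in parts])
            strands = np.concatenate([p[2] for p in parts])
            if b > 0 and site_idx.size:
                swap = rng.random(site_idx.size) < b
                strands = np.where(
                    swap, np.where(strands == "W", "C", "W"), strands
                )
            obs_out[chrom].append(
                CellObservations(cell, chrom, site_idx, alleles, strands)
            )
            # binned W/C read counts consistent with the state
            totals = rng.poisson(config.bin_reads_mean, n_bins)
            if state == "WC":
                p_w = 0.5
            elif state == "WW":
                p_w = 1.0 - b
            else:
                p_w = b
            watson = rng.binomial(totals, p_w)
            bins = []
            for i in range(n_bins):
                start = i * config.bin_size
                end = min((i + 1) * config.bin_size, config.chrom_length_bp)
                bins.append(
                    BinCounts(chrom, start, end, int(watson[i]), int(totals[i] - watson[i]))
                )
            bins_out[chrom][cell] = bins
    return StrandSeqData(obs_out, bins_out, states, watson_h)


def phred_from_error(error_rate: float, cap: float = 30.0) -> float:
    """Phred weight of a per-allele error rate (capped for error-free data)."""
    if error_rate <= 0:
        return cap
    return min(-10.0 * math.log10(error_rate), cap)


def simulate_reads(truth: SimTruth, config: SimConfig) -> dict[str, FragmentMatrix]:
    """Long reads as fragment-matrix rows, one matrix per chromosome.

    Each read copies a geometric-length run of consecutive sites from a
    uniformly chosen homolog, flipping each allele with the configured error
    rate.  Read starts extend past the chromosome ends (truncated) so mean
    per-site coverage is uniform and equals ``read_depth``.
    """
    rng = _rng(config, _READS)
    out: dict[str, FragmentMatrix] = {}
    weight = phred_from_error(config.allele_error_rate)
    for chrom in truth.chroms:
        n = len(truth.sites[chrom])
        rows: list[FragmentRow] = []
        if n > 0:
            haps = (truth.hap1[chrom], 1 - truth.hap1[chrom])
            n_reads = int(round(config.read_depth * n / config.read_span_sites))
            spans = rng.geometric(1.0 / config.read_span_sites, size=n_reads)
            homologs = rng.integers(0, 2, size=n_reads)
            for i in range(n_reads):
                span = int(spans[i])
                start = int(rng.integers(1 - span, n))
                s0, s1 = max(0, start), min(n, start + span)
                alleles = haps[homologs[i]][s0:s1].copy()
                if config.allele_error_rate > 0:
                    flip = rng.random(s1 - s0) < config.allele_error_rate
                    alleles = np.where(flip, 1 - alleles, alleles)
                calls = tuple(
                    AlleleCall(s0 + j, int(alleles[j]), weight)
                    for j in range(s1 - s0)
                )
                rows.append(FragmentRow(f"read{i:05d}", calls, source="read"))
        out[chrom] = FragmentMatrix(chrom, n, rows)
    return out


def simulate_prephased_blocks(
    truth: SimTruth, config: SimConfig
) -> dict[str, Phasing]:
    """Pre-phased haplotype segments with injected internal switch errors.

    The chromosome is partitioned into consecutive blocks of geometric
    length; each block copies truth and, independently after each site, a
    switch flips all subsequent alleles of the block with probability
    ``block_switch_rate``.
    """
    if config.block_length_sites < 2:
        raise ValueError("block_length_sites must be >= 2")
    rng = _rng(config, _BLOCKS)
    out: dict[str, Phasing] = {}
    for chrom in truth.chroms:
        n = len(truth.sites[chrom])
        h1 = truth.hap1[chrom]
        blocks: list[PhasedBlock] = []
        start = 0
        while start < n:
            length = int(rng.geometric(1.0 / config.block_length_sites))
            end = min(n, start + length)
            seg = h1[start:end].copy()
            if end - start > 1 and config.block_switch_rate > 0:
                switches = rng.random(end - start - 1) < config.block_switch_rate
                parity = np.concatenate(([0], np.cumsum(switches) % 2))
                seg = seg ^ parity.astype(seg.dtype)
            hap1 = "".join(str(int(a)) for a in seg)
            hap2 = "".join("1" if ch == "0" else "0" for ch in hap1)
            blocks.append(
                PhasedBlock(
                    chrom,
                    tuple(range(start, end)),
                    hap1,
                    hap2,
                    block_id=truth.sites[chrom][start].pos,
                )
            )
            start = end
        out[chrom] = Phasing(chrom, n, blocks)
    return out


def downsample_cells(cells: Sequence[str], k: int, seed: int) -> list[str]:
    """Uniform subset of cell ids without replacement, in original order."""
    if k > len(cells):
        raise ValueError(f"cannot select {k} of {len(cells)} cells")
    rng = np.random.default_rng(seed)
    idx = sorted(rng.choice(len(cells), size=k, replace=False))
    return [cells[i] for i in idx]


def downsample_rows(
    matrix: FragmentMatrix, target_depth: float, seed: int
) -> FragmentMatrix:
    """Thin read rows so mean per-site coverage approaches ``target_depth``.

    Each read row is kept independently with probability target/current;
    non-read rows (blocks, super reads) are always kept.
    """
    read_rows = [r for r in matrix.rows if r.source == "read"]
    total_calls = sum(r.n_calls for r in read_rows)
    current = total_calls / matrix.n_sites if matrix.n_sites else 0.0
    if current <= target_depth:
        return FragmentMatrix(matrix.chrom, matrix.n_sites, list(matrix.rows))
    p = target_depth / current
    rng = np.random.default_rng(seed)
    keep_mask = rng.random(len(read_rows)) < p
    kept = [r for r in matrix.rows if r.source != "read"]
    kept.extend(r for r, keep in zip(read_rows, keep_mask) if keep)
    return FragmentMatrix(matrix.chrom, matrix.n_sites, kept)


def wc_coverage_probability(
    n_cells: int, n_chromosomes: int = 23, wc_prob: float = 0.5
) -> float:
    """Probability that every chromosome has >= 1 WC (haplotype-informative)
    cell, under independence of strand states across cells and chromosomes:
    (1 - (1 - wc_prob)^n_cells)^n_chromosomes.
    """
    if n_cells < 0:
        raise ValueError("n_cells must be non-negative")
    return (1.0 - (1.0 - wc_prob) ** n_cells) ** n_chromosomes


def strandseq_cumulative_coverage(
    n_libraries: int = 134, depth_per_library: float = 0.037
) -> float:
    """Cumulative sequencing depth of a set of equally deep libraries."""
    return n_libraries * depth_per_library
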