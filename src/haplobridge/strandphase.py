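"""Strand-seq single-cell haplotype phasing.

Strand-seq preserves DNA template-strand identity: in a cell that inherited
one Watson (reverse, '-') and one Crick (forward, '+') template for a
chromosome (a *WC* cell), the mapping strand of every read reveals which
parental homolog it came from.  This module re-implements the sorting-based
phasing pipeline for such data:

1. classify each cell's chromosomes (or sub-regions) as WW / CC / WC from
   binned Watson/Crick read counts, using an exact binomial test of the
   50:50 expectation for WC regions;
2. collect the alleles seen by Watson and Crick reads inside WC regions into
   two parallel cell-by-site matrices;
3. greedily swap whole rows (cells) between the matrices so that each column
   becomes as monoallelic as possible — the two matrices then hold the two
   chromosome-length haplotypes;
4. report per-site consensus alleles with Phred and entropy confidence, and
   rescue unphased sites from strand-uninformative (WW/CC) reads that also
   overlap phased sites.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from scipy.stats import binomtest

from .model import FragmentMatrix, PhasedBlock, Phasing, VariantSite

logger = logging.getLogger(__name__)

STATES = ("WC", "WW", "CC", "unknown")

DEFAULT_ALPHA = 0.05
DEFAULT_PURITY = 0.8
DEFAULT_BIN_SIZE = 1_000_000
DEFAULT_ROUNDS = 2


@dataclass(frozen=True, slots=True)
class BinCounts:
    """Watson/Crick read counts in one genomic bin of one cell."""

    chrom: str
    bin_start: int  # 0-based half-open
    bin_end: int
    watson: int  # reverse-strand ('-') reads
    crick: int  # forward-strand ('+') reads

    def __post_init__(self) -> None:
        if self.bin_end <= self.bin_start:
            raise ValueError("bin_end must exceed bin_start")
        if self.watson < 0 or self.crick < 0:
            raise ValueError("counts must be non-negative")


@dataclass(frozen=True, slots=True)
class StrandStateCall:
    """Strand-state of a maximal run of equally classified bins."""

    cell_id: str
    chrom: str
    start: int
    end: int
    state: str  # WC | WW | CC | unknown
    p_value: float  # two-sided exact test of W:C against 50:50


@dataclass(slots=True)
class CellObservations:
    """Allele observations of one cell on one chromosome, with strand labels."""

    cell_id: str
    chrom: str
    site_index: np.ndarray  # int
    allele: np.ndarray  # 0/1
    strand: np.ndarray  # 'W'/'C' (unicode)

    def __post_init__(self) -> None:
        n = len(self.site_index)
        if len(self.allele) != n or len(self.strand) != n:
            raise ValueError("observation arrays must have equal length")


@dataclass(slots=True)
class CellHaplotypeMatrices:
    """The two parallel cell-by-site allele matrices (missing = -1).

    Rows are cells ordered by decreasing number of covered sites; columns are
    the chromosome's dense site indices.  The Watson matrix holds alleles
    seen on Watson templates in WC regions, the Crick matrix those seen on
    Crick templates.
    """

    chrom: str
    n_sites: int
    cells: list[str]
    watson: np.ndarray  # (n_cells, n_sites) int8, -1 missing
    crick: np.ndarray

    @property
    def coverage_per_cell(self) -> np.ndarray:
        return ((self.watson >= 0).sum(axis=1) + (self.crick >= 0).sum(axis=1))

    def copy(self) -> "CellHaplotypeMatrices":
        return CellHaplotypeMatrices(
            self.chrom,
            self.n_sites,
            list(self.cells),
            self.watson.copy(),
            self.crick.copy(),
        )


@dataclass(slots=True)
class ConsensusHaplotypes:
    """Per-site consensus haplotypes with confidence annotations.

    Arrays have length ``n_sites``; ``hap1 == -1`` marks unphased sites.
    ``hap2`` is the complement of ``hap1`` wherever phased.  ``phred`` is
    the pseudocounted error estimate -10*log10((minority+1)/(total+2)) and
    ``entropy`` the base-2 Shannon entropy of the deciding column's allele
    distribution (0 iff monoallelic).
    """

    chrom: str
    n_sites: int
    hap1: np.ndarray  # int8, -1 unphased
    phred: np.ndarray  # float
    entropy: np.ndarray  # float
    support: np.ndarray  # (n_sites, 2) int: (majority count, total count)

    @property
    def hap2(self) -> np.ndarray:
        out = np.where(self.hap1 >= 0, 1 - self.hap1, -1)
        return out.astype(np.int8)

    @property
    def phased_sites(self) -> np.ndarray:
        return np.flatnonzero(self.hap1 >= 0)

    @property
    def n_phased(self) -> int:
        return int((self.hap1 >= 0).sum())


# ---------------------------------------------------------------------------
# Strand-state calling
# ---------------------------------------------------------------------------

def _classify_bin(w: int, c: int, alpha: float, purity: float) -> tuple[str, float]:
    total = w + c
    if total == 0:
        return "unknown", 1.0
    p = binomtest(w, total, 0.5).pvalue
    frac = w / total
    if frac >= purity:
        return "WW", p
    if frac <= 1.0 - purity:
        return "CC", p
    if p >= alpha:
        return "WC", p
    return "unknown", p


def call_strand_states(
    bins: Sequence[BinCounts],
    cell_id: str = "cell",
    alpha: float = DEFAULT_ALPHA,
    purity: float = DEFAULT_PURITY,
) -> list[StrandStateCall]:
    """Classify binned W/C counts of one cell and chromosome into state runs.

    Per bin: WW if the Watson fraction >= ``purity``, CC if <= 1 - ``purity``,
    WC if the two-sided exact binomial test against 50:50 accepts at level
    ``alpha``, otherwise unknown.  Maximal runs of equal state merge into one
    call whose p-value is recomputed on the pooled counts.
    """
    if not 0.0 < alpha < 1.0:
        raise ValueError("alpha must be in (0, 1)")
    if not 0.5 < purity <= 1.0:
        raise ValueError("purity must be in (0.5, 1]")
    if not bins:
        return []
    chroms = {b.chrom for b in bins}
    if len(chroms) != 1:
        raise ValueError(f"bins span multiple chromosomes: {sorted(chroms)}")
    ordered = sorted(bins, key=lambda b: b.bin_start)
    for a, b in zip(ordered, ordered[1:]):
        if b.bin_start < a.bin_end:
            raise ValueError(
                f"overlapping bins [{a.bin_start},{a.bin_end}) and "
                f"[{b.bin_start},{b.bin_end})"
            )
    states = [_classify_bin(b.watson, b.crick, alpha, purity)[0] for b in ordered]
    calls: list[StrandStateCall] = []
    i = 0
    while i < len(ordered):
        j = i
        while j + 1 < len(ordered) and states[j + 1] == states[i]:
            j += 1
        w = sum(b.watson for b in ordered[i : j + 1])
        c = sum(b.crick for b in ordered[i : j + 1])
        p = binomtest(w, w + c, 0.5).pvalue if w + c > 0 else 1.0
        calls.append(
            StrandStateCall(
                cell_id=cell_id,
                chrom=ordered[i].chrom,
                start=ordered[i].bin_start,
                end=ordered[j].bin_end,
                state=states[i],
                p_value=float(p),
            )
        )
        i = j + 1
    return calls


def wc_regions(states: Iterable[StrandStateCall], cell_id: str) -> list[tuple[int, int]]:
    return sorted(
        (s.start, s.end) for s in states if s.cell_id == cell_id and s.state == "WC"
    )


# ---------------------------------------------------------------------------
# Cell haplotype matrices
# ---------------------------------------------------------------------------

def build_cell_haplotypes(
    observations: Sequence[CellObservations],
    states: Sequence[StrandStateCall],
    sites: Sequence[VariantSite],
) -> CellHaplotypeMatrices:
    """Fill the Watson/Crick matrices from per-cell strand-labelled alleles.

    Only observations falling inside a cell's haplotype-informative WC
    regions contribute.  Duplicate observations at one (cell, strand, site)
    are resolved by majority; ties drop the site for that cell and strand.
    Cells are ordered by decreasing number of covered sites.
    """
    if not observations:
        raise ValueError("no observations supplied")
    chrom = observations[0].chrom
    n_sites = len(sites)
    positions = np.asarray([s.pos for s in sites])
    rows: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    for obs in observations:
        if obs.chrom != chrom:
            raise ValueError("observations span multiple chromosomes")
        idx = np.asarray(obs.site_index, dtype=np.int64)
        if idx.size and (idx.min() < 0 or idx.max() >= n_sites):
            raise ValueError(
                f"cell {obs.cell_id}: observation at unknown site index"
            )
        watson = np.full(n_sites, -1, dtype=np.int8)
        crick = np.full(n_sites, -1, dtype=np.int8)
        regions = wc_regions(states, obs.cell_id)
        if idx.size and regions:
            pos = positions[idx]  # 1-based; regions are 0-based half-open
            keep = np.zeros(len(idx), dtype=bool)
            for start, end in regions:
                keep |= (pos - 1 >= start) & (pos - 1 < end)
            for strand, mat in (("W", watson), ("C", crick)):
                sel = keep & (np.asarray(obs.strand) == strand)
                if not sel.any():
                    continue
                ones = np.bincount(
                    idx[sel], weights=np.asarray(obs.allele)[sel], minlength=n_sites
                )
                tot = np.bincount(idx[sel], minlength=n_sites)
                covered = tot > 0
                maj = np.where(ones * 2 > tot, 1, np.where(ones * 2 < tot, 0, -1))
                mat[covered] = maj[covered]
        rows[obs.cell_id] = (watson, crick)
    order = sorted(
        rows,
        key=lambda cid: (
            -int((rows[cid][0] >= 0).sum() + (rows[cid][1] >= 0).sum()),
            cid,
        ),
    )
    watson = np.vstack([rows[cid][0] for cid in order])
    crick = np.vstack([rows[cid][1] for cid in order])
    return CellHaplotypeMatrices(chrom, n_sites, order, watson, crick)


# ---------------------------------------------------------------------------
# Two-matrix binary sorting
# ---------------------------------------------------------------------------

def column_score(column_alleles: Iterable[int]) -> int:
    """Disagreement of one column: total calls minus the most abundant allele."""
    vals = list(column_alleles)
    if not vals:
        return 0
    n1 = sum(1 for a in vals if a == 1)
    n0 = len(vals) - n1
    return len(vals) - max(n0, n1)


def _matrix_score_arrays(watson: np.ndarray, crick: np.ndarray) -> int:
    score = 0
    for mat in (watson, crick):
        n1 = (mat == 1).sum(axis=0)
        n0 = (mat == 0).sum(axis=0)
        score += int(np.minimum(n0, n1).sum())
    return score


def matrix_score(matrices: CellHaplotypeMatrices) -> int:
    """Sum of column scores over both matrices; 0 means full concordance."""
    return _matrix_score_arrays(matrices.watson, matrices.crick)


def sort_matrices(
    matrices: CellHaplotypeMatrices, n_rounds: int = DEFAULT_ROUNDS
) -> CellHaplotypeMatrices:
    """Greedy row-swap sorting of the Watson/Crick matrices.

    For each cell in row order, its Watson and Crick contents are swapped
    between the matrices (equivalent to exchanging the cell's template
    strands); the swap is kept iff the matrix score strictly decreases.  The
    full pass is repeated ``n_rounds`` times (two passes suffice in
    practice).  The score never increases.
    """
    out = matrices.copy()
    score = _matrix_score_arrays(out.watson, out.crick)
    for _ in range(n_rounds):
        for i in range(len(out.cells)):
            out.watson[[i]], out.crick[[i]] = (
                out.crick[[i]].copy(),
                out.watson[[i]].copy(),
            )
            new_score = _matrix_score_arrays(out.watson, out.crick)
            if new_score < score:
                score = new_score
            else:  # revert
                out.watson[[i]], out.crick[[i]] = (
                    out.crick[[i]].copy(),
                    out.watson[[i]].copy(),
                )
    return out


# ---------------------------------------------------------------------------
# Consensus and rescue
# ---------------------------------------------------------------------------

def _entropy(n0: int, n1: int) -> float:
    total = n0 + n1
    if total == 0:
        return 0.0
    h = 0.0
    for n in (n0, n1):
        if n > 0:
            p = n / total
            h -= p * math.log2(p)
    return h


def _phred(minority: int, total: int) -> float:
    return -10.0 * math.log10((minority + 1) / (total + 2))


def consensus_haplotypes(matrices: CellHaplotypeMatrices) -> ConsensusHaplotypes:
    """Column-wise consensus of the sorted matrices.

    hap1 takes the Watson matrix's majority allele and hap2 the Crick
    matrix's; a site is left unphased when the two consensuses are not
    complementary, a deciding column ties, or no data exists.  When only one
    matrix covers a column, its majority decides and the other haplotype is
    the complement.  Confidence values come from the *deciding* matrix —
    the one with more observations at the column (ties favour Watson).
    """
    n = matrices.n_sites
    n1w = (matrices.watson == 1).sum(axis=0)
    n0w = (matrices.watson == 0).sum(axis=0)
    n1c = (matrices.crick == 1).sum(axis=0)
    n0c = (matrices.crick == 0).sum(axis=0)
    hap1 = np.full(n, -1, dtype=np.int8)
    phred = np.zeros(n, dtype=float)
    entropy = np.zeros(n, dtype=float)
    support = np.zeros((n, 2), dtype=np.int64)
    for j in range(n):
        tw, tc = n0w[j] + n1w[j], n0c[j] + n1c[j]
        majw = 1 if n1w[j] > n0w[j] else (0 if n0w[j] > n1w[j] else -1)
        majc = 1 if n1c[j] > n0c[j] else (0 if n0c[j] > n1c[j] else -1)
        if tw > 0 and tc > 0:
            if majw == -1 or majc == -1 or majw == majc:
                continue  # tie or non-complementary consensus: unphased
            allele = majw
        elif tw > 0:
            if majw == -1:
                continue
            allele = majw
        elif tc > 0:
            if majc == -1:
                continue
            allele = 1 - majc
        else:
            continue
        # deciding matrix: more observations, ties favour Watson
        if tw >= tc:
            d0, d1 = n0w[j], n1w[j]
        else:
            d0, d1 = n0c[j], n1c[j]
        total = d0 + d1
        minority = min(d0, d1)
        hap1[j] = allele
        phred[j] = _phred(minority, total)
        entropy[j] = _entropy(d0, d1)
        support[j] = (max(d0, d1), total)
    return ConsensusHaplotypes(matrices.chrom, n, hap1, phred, entropy, support)


def rescue_missing_alleles(
    consensus: ConsensusHaplotypes, all_reads: FragmentMatrix
) -> ConsensusHaplotypes:
    """Phase leftover sites from strand-uninformative (WW/CC) reads.

    A read covering at least one phased and one unphased site is oriented to
    the haplotype that best agrees with its phased alleles (orientation ties
    discard the read); it then votes the haplotype-1 allele of each unphased
    site it covers.  Sites receiving conflicting votes stay unphased; newly
    phased sites get a Phred from the pseudocounted vote total.
    """
    if consensus.n_phased < 1:
        raise ValueError("consensus has no phased site to anchor the rescue")
    if all_reads.n_sites != consensus.n_sites:
        raise ValueError("fragment matrix and consensus disagree on n_sites")
    hap1 = consensus.hap1
    votes: dict[int, set[int]] = {}
    counts: dict[int, int] = {}
    for row in all_reads.rows:
        phased = [(c.site_index, c.allele) for c in row.calls if hap1[c.site_index] >= 0]
        unphased = [(c.site_index, c.allele) for c in row.calls if hap1[c.site_index] < 0]
        if not phased or not unphased:
            continue
        agree1 = sum(1 for s, a in phased if a == hap1[s])
        agree2 = len(phased) - agree1
        if agree1 == agree2:
            continue  # orientation tie: read is uninformative
        on_hap1 = agree1 > agree2
        for s, a in unphased:
            voted_allele = a if on_hap1 else 1 - a
            votes.setdefault(s, set()).add(voted_allele)
            counts[s] = counts.get(s, 0) + 1
    out = ConsensusHaplotypes(
        consensus.chrom,
        consensus.n_sites,
        consensus.hap1.copy(),
        consensus.phred.copy(),
        consensus.entropy.copy(),
        consensus.support.copy(),
    )
    for s, alleles in votes.items():
        if len(alleles) != 1:
            continue  # conflicting assignments across reads
        (allele,) = alleles
        out.hap1[s] = allele
        out.phred[s] = _phred(0, counts[s])
        out.entropy[s] = 0.0
        out.support[s] = (counts[s], counts[s])
    return out


def consensus_to_phasing(
    consensus: ConsensusHaplotypes, sites: Sequence[VariantSite] | None = None
) -> Phasing:
    """One chromosome-spanning block holding all consensus-phased sites."""
    phased = consensus.phased_sites
    if phased.size == 0:
        return Phasing(consensus.chrom, consensus.n_sites, [])
    hap1 = "".join(str(int(consensus.hap1[s])) for s in phased)
    hap2 = "".join("1" if ch == "0" else "0" for ch in hap1)
    block_id = sites[phased[0]].pos if sites is not None else int(phased[0]) + 1
    block = PhasedBlock(
        consensus.chrom, tuple(int(s) for s in phased), hap1, hap2, block_id
    )
    return Phasing(consensus.chrom, consensus.n_sites, [block])


# ---------------------------------------------------------------------------
# BED export
# ---------------------------------------------------------------------------

def export_strand_states_bed(
    states: Sequence[StrandStateCall], path: str | Path
) -> None:
    """Write strand-state calls as a BED file (0-based half-open).

    Name is ``cell:state``; score is the Phred-scaled p-value (capped).
    """
    ordered = sorted(states, key=lambda s: (s.chrom, s.start, s.end, s.cell_id))
    with open(path, "w") as fh:
        fh.write("#chrom\tstart\tend\tname\tscore\tstrand\n")
        for s in ordered:
            score = int(round(-10.0 * math.log10(max(s.p_value, 1e-30))))
            fh.write(
                f"{s.chrom}\t{s.start}\t{s.end}\t{s.cell_id}:{s.state}\t{score}\t.\n"
            )


# ---------------------------------------------------------------------------
# Pipeline
# ---------------------------------------------------------------------------

def phase_strandseq(
    observations: Sequence[CellObservations],
    bins_by_cell: dict[str, Sequence[BinCounts]],
    sites: Sequence[VariantSite],
    alpha: float = DEFAULT_ALPHA,
    purity: float = DEFAULT_PURITY,
    n_rounds: int = DEFAULT_ROUNDS,
    rescue_reads: FragmentMatrix | None = None,
) -> tuple[ConsensusHaplotypes, list[StrandStateCall], CellHaplotypeMatrices]:
    """Run the full single-chromosome Strand-seq phasing pipeline."""
    states: list[StrandStateCall] = []
    for cell_id, bins in bins_by_cell.items():
        states.extend(call_strand_states(bins, cell_id, alpha=alpha, purity=purity))
    matrices = build_cell_haplotypes(observations, states, sites)
    matrices = sort_matrices(matrices, n_rounds=n_rounds)
    consensus = consensus_haplotypes(matrices)
    if rescue_reads is not None and consensus.n_phased > 0:
        consensus = rescue_missing_alleles(consensus, rescue_reads)
    return consensus, states, matrices
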