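"""Core domain types for fragment-matrix haplotype phasing.

The central object is the *fragment matrix*: rows are sequencing reads,
pre-phased haplotype segments, or chromosome-spanning "super reads"; columns
are heterozygous biallelic SNV sites.  Entries are 0 (reference allele),
1 (alternative allele), or missing, each with a Phred-scaled confidence
weight.  Haplotypes are represented as collections of disjoint phased blocks;
within a block the two haplotype strings are complementary because every
column is a heterozygous site.

Coordinate conventions: VCF positions are 1-based; internally every
chromosome's sites carry a dense 0-based ``site_index`` ordered by position.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

ROW_SOURCES = ("read", "block", "super_read")


@dataclass(frozen=True, slots=True)
class VariantSite:
    """One heterozygous biallelic SNV."""

    chrom: str
    pos: int  # 1-based
    ref_allele: str
    alt_allele: str
    site_index: int  # dense 0-based rank within the chromosome

    def __post_init__(self) -> None:
        if self.ref_allele == self.alt_allele:
            raise ValueError(
                f"site {self.chrom}:{self.pos}: ref and alt alleles are equal"
            )
        if self.pos < 1:
            raise ValueError(f"position must be 1-based positive, got {self.pos}")


def index_sites(sites: Iterable[VariantSite]) -> list[VariantSite]:
    """Re-index sites of one chromosome densely by increasing position.

    Raises on duplicate positions (the site list must be a set of distinct
    het SNVs).
    """
    ordered = sorted(sites, key=lambda s: s.pos)
    out: list[VariantSite] = []
    prev = None
    for i, s in enumerate(ordered):
        if prev is not None and s.pos == prev:
            raise ValueError(f"duplicate position {s.chrom}:{s.pos}")
        prev = s.pos
        out.append(
            VariantSite(s.chrom, s.pos, s.ref_allele, s.alt_allele, site_index=i)
        )
    return out


@dataclass(frozen=True, slots=True)
class AlleleCall:
    """One allele observation at a site: 0=reference, 1=alternative."""

    site_index: int
    allele: int
    weight: float  # Phred-scaled confidence, >= 0

    def __post_init__(self) -> None:
        if self.allele not in (0, 1):
            raise ValueError(f"allele must be 0 or 1, got {self.allele}")
        if self.weight < 0:
            raise ValueError(f"weight must be non-negative, got {self.weight}")


@dataclass(slots=True)
class FragmentRow:
    """One row of the fragment matrix.

    ``source`` distinguishes sequencing reads, pre-phased block rows and
    Strand-seq super reads.  ``strand`` optionally carries the Strand-seq
    template strand ('W' or 'C') of the underlying read.
    """

    row_id: str
    calls: tuple[AlleleCall, ...]
    source: str = "read"
    strand: str | None = None

    def __post_init__(self) -> None:
        self.calls = tuple(self.calls)
        if len(self.calls) < 1:
            raise ValueError(f"row {self.row_id}: needs at least one call")
        if self.source not in ROW_SOURCES:
            raise ValueError(f"row {self.row_id}: unknown source {self.source!r}")
        if self.strand is not None and self.strand not in ("W", "C"):
            raise ValueError(f"row {self.row_id}: strand must be 'W' or 'C'")
        idx = [c.site_index for c in self.calls]
        if any(b <= a for a, b in zip(idx, idx[1:])):
            raise ValueError(
                f"row {self.row_id}: calls must be strictly sorted by site with "
                "no duplicates"
            )

    @property
    def site_indices(self) -> tuple[int, ...]:
        return tuple(c.site_index for c in self.calls)

    @property
    def first_site(self) -> int:
        return self.calls[0].site_index

    @property
    def last_site(self) -> int:
        return self.calls[-1].site_index

    @property
    def n_calls(self) -> int:
        return len(self.calls)

    @property
    def total_weight(self) -> float:
        return float(sum(c.weight for c in self.calls))

    def allele_at(self, site_index: int) -> int | None:
        for c in self.calls:
            if c.site_index == site_index:
                return c.allele
        return None


@dataclass(slots=True)
class FragmentMatrix:
    """Fragment matrix over one chromosome's dense site list."""

    chrom: str
    n_sites: int
    rows: list[FragmentRow] = field(default_factory=list)

    def __post_init__(self) -> None:
        for row in self.rows:
            if row.last_site >= self.n_sites or row.first_site < 0:
                raise ValueError(
                    f"row {row.row_id}: site index out of range "
                    f"[0, {self.n_sites})"
                )

    def coverage(self) -> np.ndarray:
        """Number of rows calling each site."""
        cov = np.zeros(self.n_sites, dtype=np.int64)
        for row in self.rows:
            for c in row.calls:
                cov[c.site_index] += 1
        return cov

    def subset(self, row_ids: Iterable[str]) -> "FragmentMatrix":
        wanted = set(row_ids)
        return FragmentMatrix(
            self.chrom, self.n_sites, [r for r in self.rows if r.row_id in wanted]
        )


def _complement(hap: str) -> str:
    table = str.maketrans("01", "10")
    return hap.translate(table)


@dataclass(slots=True)
class PhasedBlock:
    """A haplotype segment: contiguously phased subset of a chromosome's sites.

    ``block_id`` mirrors a VCF phase-set tag: by convention the 1-based
    position of the smallest member site.
    """

    chrom: str
    site_indices: tuple[int, ...]
    hap1: str
    hap2: str
    block_id: int

    def __post_init__(self) -> None:
        self.site_indices = tuple(self.site_indices)
        if len(self.site_indices) != len(self.hap1) or len(self.hap1) != len(self.hap2):
            raise ValueError("site_indices, hap1, hap2 must have equal length")
        if any(
            b <= a for a, b in zip(self.site_indices, self.site_indices[1:])
        ):
            raise ValueError("site_indices must be strictly increasing")
        if self.hap2 != _complement(self.hap1):
            raise ValueError("hap2 must be the complement of hap1 at het sites")

    @property
    def n_sites(self) -> int:
        return len(self.site_indices)

    @property
    def n_phase_connections(self) -> int:
        return max(self.n_sites - 1, 0)

    def allele(self, site_index: int, hap: int) -> int:
        i = self.site_indices.index(site_index)
        return int((self.hap1 if hap == 1 else self.hap2)[i])

    def flipped(self) -> "PhasedBlock":
        """Same block with the haplotype labels swapped."""
        return PhasedBlock(
            self.chrom, self.site_indices, self.hap2, self.hap1, self.block_id
        )


@dataclass(slots=True)
class Phasing:
    """A set of disjoint phased blocks over one chromosome's sites."""

    chrom: str
    n_sites: int
    blocks: list[PhasedBlock] = field(default_factory=list)

    def __post_init__(self) -> None:
        seen: set[int] = set()
        for b in self.blocks:
            for s in b.site_indices:
                if s in seen:
                    raise ValueError(f"site {s} phased in more than one block")
                if s < 0 or s >= self.n_sites:
                    raise ValueError(f"site {s} out of range [0, {self.n_sites})")
                seen.add(s)

    @property
    def phased_sites(self) -> set[int]:
        return {s for b in self.blocks for s in b.site_indices}

    @property
    def unphased(self) -> set[int]:
        return set(range(self.n_sites)) - self.phased_sites

    @property
    def largest_block(self) -> PhasedBlock | None:
        if not self.blocks:
            return None
        # ties broken by smallest block_id
        return min(self.blocks, key=lambda b: (-b.n_sites, b.block_id))

    def block_of(self, site_index: int) -> PhasedBlock | None:
        for b in self.blocks:
            if site_index in b.site_indices:
                return b
        return None


class _UnionFind:
    def __init__(self, n: int) -> None:
        self.parent = list(range(n))

    def find(self, x: int) -> int:
        while self.parent[x] != x:
            self.parent[x] = self.parent[self.parent[x]]
            x = self.parent[x]
        return x

    def union(self, a: int, b: int) -> None:
        ra, rb = self.find(a), self.find(b)
        if ra != rb:
            self.parent[rb] = ra


def blocks_from_rows(matrix: FragmentMatrix) -> list[set[int]]:
    """Connected components of sites linked by co-coverage in any row.

    Two sites are connected when some row calls both; components are the
    maximal haplotype segments any bipartition of these rows can phase.
    Sites covered by no row are excluded.  Components are returned sorted by
    their smallest site.
    """
    uf = _UnionFind(matrix.n_sites)
    covered: set[int] = set()
    for row in matrix.rows:
        idx = row.site_indices
        covered.update(idx)
        for a, b in zip(idx, idx[1:]):
            uf.union(a, b)
    comps: dict[int, set[int]] = {}
    for s in covered:
        comps.setdefault(uf.find(s), set()).add(s)
    return sorted(comps.values(), key=min)
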