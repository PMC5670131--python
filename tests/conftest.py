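"""Shared fixtures and builders for the test suite."""

from __future__ import annotations

import numpy as np
import pytest

from haplobridge.model import (
    AlleleCall,
    FragmentMatrix,
    FragmentRow,
    PhasedBlock,
    Phasing,
    VariantSite,
)


def make_row(
    row_id: str,
    first: int,
    alleles: str,
    weight: float | list[float] = 30.0,
    source: str = "read",
    strand: str | None = None,
) -> FragmentRow:
    """Row from an allele string with '-' gaps, e.g. ('r1', 2, '0-11')."""
    calls = []
    wi = 0
    weights = weight if isinstance(weight, (list, tuple)) else None
    for offset, ch in enumerate(alleles):
        if ch == "-":
            continue
        w = weights[wi] if weights is not None else weight
        calls.append(AlleleCall(first + offset, int(ch), float(w)))
        wi += 1
    return FragmentRow(row_id, tuple(calls), source=source, strand=strand)


def make_matrix(n_sites: int, rows, chrom: str = "chr1") -> FragmentMatrix:
    return FragmentMatrix(chrom, n_sites, list(rows))


def make_sites(n: int, chrom: str = "chr1", spacing: int = 100) -> list[VariantSite]:
    return [
        VariantSite(chrom, (i + 1) * spacing, "A", "C", site_index=i)
        for i in range(n)
    ]


def make_block(
    site_indices, hap1: str, chrom: str = "chr1", block_id: int | None = None
) -> PhasedBlock:
    hap2 = "".join("1" if c == "0" else "0" for c in hap1)
    bid = block_id if block_id is not None else min(site_indices) + 1
    return PhasedBlock(chrom, tuple(site_indices), hap1, hap2, block_id=bid)


def random_matrix(
    rng: np.random.Generator, max_rows: int = 8, max_sites: int = 10
) -> FragmentMatrix:
    n_rows = int(rng.integers(1, max_rows + 1))
    n_sites = int(rng.integers(1, max_sites + 1))
    rows = []
    for i in range(n_rows):
        k = int(rng.integers(1, n_sites + 1))
        idx = np.sort(rng.choice(n_sites, size=k, replace=False))
        calls = tuple(
            AlleleCall(int(s), int(rng.integers(0, 2)), float(rng.integers(1, 40)))
            for s in idx
        )
        rows.append(FragmentRow(f"r{i}", calls))
    return FragmentMatrix("chr1", n_sites, rows)


def random_phasing(rng: np.random.Generator, n_sites: int, chrom: str = "chr1") -> Phasing:
    """Random disjoint blocks over a site range (block_id = min pos rule)."""
    sites = make_sites(n_sites, chrom)
    perm = rng.permutation(n_sites)
    n_phased = int(rng.integers(0, n_sites + 1))
    chosen = np.sort(perm[:n_phased])
    blocks = []
    i = 0
    while i < len(chosen):
        size = int(rng.integers(1, len(chosen) - i + 1))
        members = tuple(int(s) for s in chosen[i : i + size])
        hap1 = "".join(str(int(rng.integers(0, 2))) for _ in members)
        blocks.append(
            make_block(members, hap1, chrom, block_id=sites[members[0]].pos)
        )
        i += size
    return Phasing(chrom, n_sites, blocks)


@pytest.fixture
def rng():
    return np.random.default_rng(20260926)


def write_vcf(path, records, sample: str = "S1", chrom: str = "chr1"):
    """Write a tiny VCF by hand; records = (pos, ref, alt, gt_string[, ps, gq])."""
    lines = [
        "##fileformat=VCFv4.2",
        f"##contig=<ID={chrom},length=100000000>",
        '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">',
        '##FORMAT=<ID=PS,Number=1,Type=Integer,Description="Phase set">',
        '##FORMAT=<ID=GQ,Number=1,Type=Integer,Description="Phase quality">',
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + sample,
    ]
    for rec in records:
        pos, ref, alt, gt = rec[:4]
        ps = rec[4] if len(rec) > 4 else None
        gq = rec[5] if len(rec) > 5 else None
        fmt = ["GT"]
        vals = [gt]
        if ps is not None:
            fmt.append("PS")
            vals.append(str(ps))
        if gq is not None:
            fmt.append("GQ")
            vals.append(str(gq))
        lines.append(
            f"{chrom}\t{pos}\t.\t{ref}\t{alt}\t.\tPASS\t.\t"
            + ":".join(fmt)
            + "\t"
            + ":".join(vals)
        )
    path.write_text("\n".join(lines) + "\n")
    return path
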