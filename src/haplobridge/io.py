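"""Readers and writers for the standard formats the phasing tool touches.

* VCF 4.2 (via pysam): heterozygous SNV site lists, pre-phased haplotype
  blocks (``GT`` with ``|`` grouped by the ``PS`` phase-set tag), and phased
  output haplotypes.
* Fragment files (HapCUT-style text dialect): one fragment-matrix row per
  line, ``<row_id> <first_site_index> <allele string with '-' gaps>
  <comma-separated Phred weights> [source] [strand]`` after a header line
  ``#n_sites=<N> chrom=<name>``.
"""

from __future__ import annotations

import logging
import math
from pathlib import Path
from typing import Iterable, Sequence

import pysam

from .model import (
    AlleleCall,
    FragmentMatrix,
    FragmentRow,
    PhasedBlock,
    Phasing,
    VariantSite,
    index_sites,
)

logger = logging.getLogger(__name__)

#: Phred weight assumed when a fragment file omits weights.
DEFAULT_WEIGHT = 30.0


# ---------------------------------------------------------------------------
# VCF input
# ---------------------------------------------------------------------------

def _het_snv_records(vcf: pysam.VariantFile, chrom: str | None):
    """Yield (record, gt, phased, ps) for biallelic het SNVs of one chromosome.

    Non-SNV, multi-allelic, non-diploid and homozygous records are skipped
    with a debug log, mirroring the phasing model that operates on known
    heterozygous biallelic SNVs only.
    """
    for rec in vcf.fetch(region=None):
        if chrom is not None and rec.chrom != chrom:
            continue
        if rec.alts is None or len(rec.alts) != 1:
            logger.debug("skipping non-biallelic record %s:%s", rec.chrom, rec.pos)
            continue
        if len(rec.ref) != 1 or len(rec.alts[0]) != 1:
            logger.debug("skipping non-SNV record %s:%s", rec.chrom, rec.pos)
            continue
        if not rec.samples:
            continue
        sample = rec.samples[0]
        gt = sample.get("GT")
        if gt is None or len(gt) != 2 or None in gt:
            continue
        if set(gt) != {0, 1}:  # homozygous or non-(0,1) genotype
            continue
        ps = sample.get("PS") if "PS" in sample else None
        yield rec, tuple(int(a) for a in gt), bool(sample.phased), ps


def read_het_sites(vcf_path: str | Path, chrom: str) -> list[VariantSite]:
    """Read biallelic heterozygous SNVs of ``chrom``, densely re-indexed.

    Returns an empty list when the chromosome carries no het SNVs; raises on
    duplicate positions.
    """
    with pysam.VariantFile(str(vcf_path)) as vcf:
        raw = [
            VariantSite(rec.chrom, rec.pos, rec.ref, rec.alts[0], 0)
            for rec, _, _, _ in _het_snv_records(vcf, chrom)
        ]
    return index_sites(raw)


def vcf_chromosomes(vcf_path: str | Path) -> list[str]:
    """Chromosome names that carry at least one biallelic het SNV."""
    seen: list[str] = []
    with pysam.VariantFile(str(vcf_path)) as vcf:
        for rec, _, _, _ in _het_snv_records(vcf, None):
            if rec.chrom not in seen:
                seen.append(rec.chrom)
    return seen


def read_phased_blocks(
    vcf_path: str | Path,
    chrom: str | None = None,
    with_quals: bool = False,
):
    """Read a pre-phased VCF into a :class:`Phasing` for one chromosome.

    Records sharing a ``PS`` phase-set value form one block; phased records
    without ``PS`` become singleton blocks (with a warning); unphased het
    records stay unphased.  Site indices refer to the dense ordering of all
    het SNVs of the chromosome in this file.

    With ``with_quals=True`` additionally returns ``{site_index: GQ}`` for
    records that carry a genotype quality.
    """
    with pysam.VariantFile(str(vcf_path)) as vcf:
        if chrom is None:
            chroms = vcf_chromosomes(vcf_path)
            if len(chroms) != 1:
                raise ValueError(
                    f"{vcf_path}: expected a single chromosome, found {chroms}; "
                    "pass chrom= explicitly"
                )
            chrom = chroms[0]
        entries = list(_het_snv_records(vcf, chrom))
        quals: dict[int, float] = {}
        groups: dict[int, list[tuple[int, int]]] = {}  # ps -> [(site_idx, hap1)]
        positions = []
        for idx, (rec, gt, phased, ps) in enumerate(entries):
            positions.append(rec.pos)
            sample = rec.samples[0]
            gq = sample.get("GQ") if "GQ" in sample else None
            if gq is not None:
                quals[idx] = float(gq)
            if not phased:
                continue
            if ps is None:
                logger.warning(
                    "%s:%s phased genotype without PS tag; treated as singleton "
                    "block",
                    rec.chrom,
                    rec.pos,
                )
                ps = -rec.pos  # unique key; block_id fixed to pos below
            groups.setdefault(ps, []).append((idx, gt[0]))
    blocks = []
    for ps, members in groups.items():
        members.sort()
        sites = tuple(i for i, _ in members)
        hap1 = "".join(str(a) for _, a in members)
        hap2 = "".join("1" if a == 0 else "0" for _, a in members)
        # block_id convention: 1-based position of the smallest member site
        blocks.append(
            PhasedBlock(chrom, sites, hap1, hap2, block_id=positions[sites[0]])
        )
    blocks.sort(key=lambda b: b.site_indices[0])
    phasing = Phasing(chrom, n_sites=len(entries), blocks=blocks)
    return (phasing, quals) if with_quals else phasing


def read_phased_blocks_all(
    vcf_path: str | Path, with_quals: bool = False
) -> dict[str, Phasing]:
    return {
        c: read_phased_blocks(vcf_path, c, with_quals=with_quals)
        for c in vcf_chromosomes(vcf_path)
    }


# ---------------------------------------------------------------------------
# VCF output
# ---------------------------------------------------------------------------

def _make_header(
    per_chrom: Sequence[tuple[Phasing, Sequence[VariantSite]]], sample: str
) -> pysam.VariantHeader:
    header = pysam.VariantHeader()
    for _, sites in per_chrom:
        if not sites:
            continue
        length = max(s.pos for s in sites) + 1
        header.contigs.add(sites[0].chrom, length=length)
    header.formats.add("GT", 1, "String", "Genotype")
    header.formats.add("PS", 1, "Integer", "Phase set identifier")
    header.formats.add("GQ", 1, "Integer", "Phred-scaled genotype/phase quality")
    header.add_sample(sample)
    return header


def write_phased_vcf_multi(
    entries: Sequence[tuple[Phasing, Sequence[VariantSite], dict[int, float] | None]],
    path: str | Path,
    sample: str = "SAMPLE",
) -> None:
    """Write phasings of one or more chromosomes to an uncompressed VCF."""
    header = _make_header([(p, s) for p, s, _ in entries], sample)
    with pysam.VariantFile(str(path), "w", header=header) as out:
        for phasing, sites, quals in entries:
            if len(sites) != phasing.n_sites:
                raise ValueError(
                    f"{phasing.chrom}: phasing covers {phasing.n_sites} sites but "
                    f"{len(sites)} sites supplied"
                )
            hap_at: dict[int, tuple[int, int, int]] = {}
            for b in phasing.blocks:
                for i, s in enumerate(b.site_indices):
                    hap_at[s] = (int(b.hap1[i]), int(b.hap2[i]), b.block_id)
            for site in sites:
                rec = out.new_record(
                    contig=site.chrom,
                    start=site.pos - 1,
                    stop=site.pos,
                    alleles=(site.ref_allele, site.alt_allele),
                )
                fmt = rec.samples[sample]
                if site.site_index in hap_at:
                    a1, a2, ps = hap_at[site.site_index]
                    fmt["GT"] = (a1, a2)
                    fmt.phased = True
                    fmt["PS"] = ps
                else:
                    fmt["GT"] = (0, 1)
                    fmt.phased = False
                if quals and site.site_index in quals:
                    fmt["GQ"] = int(round(quals[site.site_index]))
                out.write(rec)


def write_phased_vcf(
    phasing: Phasing,
    sites: Sequence[VariantSite],
    path: str | Path,
    quals: dict[int, float] | None = None,
    sample: str = "SAMPLE",
) -> None:
    """Write one chromosome's phasing as a VCF (phase sets via ``PS``)."""
    write_phased_vcf_multi([(phasing, sites, quals)], path, sample=sample)


# ---------------------------------------------------------------------------
# Fragment files
# ---------------------------------------------------------------------------

def read_fragment_file(path: str | Path) -> FragmentMatrix:
    """Parse a fragment file into a :class:`FragmentMatrix`.

    Malformed lines raise :class:`ValueError` naming the line number.
    """
    path = Path(path)
    with open(path) as fh:
        lines = fh.read().splitlines()
    if not lines or not lines[0].startswith("#"):
        raise ValueError(f"{path}:1: missing '#n_sites=<N> chrom=<name>' header")
    header: dict[str, str] = {}
    for tok in lines[0].lstrip("#").split():
        if "=" not in tok:
            raise ValueError(f"{path}:1: malformed header token {tok!r}")
        key, val = tok.split("=", 1)
        header[key] = val
    try:
        n_sites = int(header["n_sites"])
        chrom = header["chrom"]
    except KeyError as exc:
        raise ValueError(f"{path}:1: header missing {exc} field") from exc

    rows: list[FragmentRow] = []
    for lineno, line in enumerate(lines[1:], start=2):
        if not line.strip() or line.startswith("#"):
            continue
        fields = line.split()
        if len(fields) < 3 or len(fields) > 6:
            raise ValueError(f"{path}:{lineno}: expected 3-6 fields, got {len(fields)}")
        row_id, first_str, alleles = fields[0], fields[1], fields[2]
        weights_str = fields[3] if len(fields) >= 4 else ""
        source = fields[4] if len(fields) >= 5 else "read"
        strand = fields[5] if len(fields) == 6 else None
        try:
            first = int(first_str)
        except ValueError:
            raise ValueError(
                f"{path}:{lineno}: first site index {first_str!r} is not an integer"
            ) from None
        bad = set(alleles) - set("01-")
        if bad:
            raise ValueError(
                f"{path}:{lineno}: invalid allele character(s) {sorted(bad)}"
            )
        n_nongap = sum(1 for ch in alleles if ch != "-")
        if n_nongap < 1:
            raise ValueError(f"{path}:{lineno}: row has no allele calls")
        if weights_str in ("", "."):
            weights = [DEFAULT_WEIGHT] * n_nongap
        else:
            try:
                weights = [float(w) for w in weights_str.split(",")]
            except ValueError:
                raise ValueError(
                    f"{path}:{lineno}: malformed weight list {weights_str!r}"
                ) from None
            if len(weights) != n_nongap:
                raise ValueError(
                    f"{path}:{lineno}: {len(weights)} weights for {n_nongap} calls"
                )
        calls = []
        wi = 0
        for offset, ch in enumerate(alleles):
            if ch == "-":
                continue
            calls.append(AlleleCall(first + offset, int(ch), weights[wi]))
            wi += 1
        if calls[-1].site_index >= n_sites or calls[0].site_index < 0:
            raise ValueError(
                f"{path}:{lineno}: site indices outside [0, {n_sites})"
            )
        try:
            rows.append(FragmentRow(row_id, tuple(calls), source=source, strand=strand))
        except ValueError as exc:
            raise ValueError(f"{path}:{lineno}: {exc}") from None
    return FragmentMatrix(chrom, n_sites, rows)


def write_fragment_file(matrix: FragmentMatrix, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write(f"#n_sites={matrix.n_sites} chrom={matrix.chrom}\n")
        for row in matrix.rows:
            first = row.first_site
            span = row.last_site - first + 1
            chars = ["-"] * span
            weights = []
            for c in row.calls:
                chars[c.site_index - first] = str(c.allele)
                weights.append(f"{c.weight:g}")
            fields = [row.row_id, str(first), "".join(chars), ",".join(weights)]
            if row.source != "read" or row.strand is not None:
                fields.append(row.source)
            if row.strand is not None:
                fields.append(row.strand)
            fh.write(" ".join(fields) + "\n")
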