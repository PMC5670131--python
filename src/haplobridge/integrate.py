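"""Integrative phasing: Strand-seq consensus haplotypes as super reads.

The sparse but chromosome-spanning consensus haplotypes from Strand-seq are
injected into the fragment matrix as a pair of complementary *super read*
rows.  Sequencing reads (long or short) and/or pre-phased haplotype blocks
(e.g. linked-read segments) enter as further rows, and the joint matrix is
solved as one wMEC instance: the maximum-likelihood bipartition arbitrates
conflicts between sources by weight, and the super reads stitch read-only
haplotype segments into a single chromosome-length block.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

from .model import AlleleCall, FragmentMatrix, FragmentRow, Phasing, VariantSite
from .strandphase import ConsensusHaplotypes
from .wmec import DEFAULT_MAX_COVERAGE, WmecSolution, select_rows, solve_wmec

logger = logging.getLogger(__name__)


@dataclass(slots=True)
class IntegrationConfig:
    max_coverage: int = DEFAULT_MAX_COVERAGE
    superread_weight_mode: str = "consensus_phred"  # or "constant"
    constant_weight: float = 30.0
    include_sources: frozenset = frozenset({"read", "block"})

    def __post_init__(self) -> None:
        if self.superread_weight_mode not in ("consensus_phred", "constant"):
            raise ValueError(
                f"unknown superread_weight_mode {self.superread_weight_mode!r}"
            )
        if self.superread_weight_mode == "constant" and self.constant_weight <= 0:
            raise ValueError("constant_weight must be positive")
        self.include_sources = frozenset(self.include_sources)


def build_super_reads(
    consensus: ConsensusHaplotypes, config: IntegrationConfig | None = None
) -> tuple[FragmentRow, FragmentRow]:
    """Two complementary chromosome-spanning rows from the consensus.

    Row 1 carries the haplotype-1 allele at every phased site, row 2 the
    complement; unphased sites are gaps.  Per-allele weights are the
    consensus Phred scores (or a constant, per config).
    """
    config = config or IntegrationConfig()
    phased = consensus.phased_sites
    if phased.size == 0:
        raise ValueError("consensus has no phased sites; cannot build super reads")
    calls1 = []
    calls2 = []
    for s in phased:
        if config.superread_weight_mode == "constant":
            w = config.constant_weight
        else:
            w = max(float(consensus.phred[s]), 0.0)
        a = int(consensus.hap1[s])
        calls1.append(AlleleCall(int(s), a, w))
        calls2.append(AlleleCall(int(s), 1 - a, w))
    return (
        FragmentRow("superread_hap1", tuple(calls1), source="super_read"),
        FragmentRow("superread_hap2", tuple(calls2), source="super_read"),
    )


def blocks_to_rows(phasing: Phasing, weight: float = 30.0) -> list[FragmentRow]:
    """One fragment row per pre-phased block, carrying its hap1 alleles.

    A single row per block suffices: the bipartition supplies the
    complement.  Singleton blocks carry no phase connection and are dropped
    with a warning.
    """
    rows: list[FragmentRow] = []
    for block in phasing.blocks:
        if block.n_sites < 2:
            logger.warning(
                "dropping singleton pre-phased block %s:%d (no phase connection)",
                block.chrom,
                block.block_id,
            )
            continue
        calls = tuple(
            AlleleCall(s, int(block.hap1[i]), weight)
            for i, s in enumerate(block.site_indices)
        )
        rows.append(FragmentRow(f"block_{block.block_id}", calls, source="block"))
    return rows


def build_joint_matrix(
    consensus: ConsensusHaplotypes | None,
    reads: FragmentMatrix | None = None,
    blocks: Phasing | None = None,
    config: IntegrationConfig | None = None,
    block_row_weight: float = 30.0,
) -> FragmentMatrix:
    """Assemble super reads + reads + block rows into one fragment matrix."""
    config = config or IntegrationConfig()
    if reads is None and blocks is None:
        raise ValueError("at least one of reads or blocks must be provided")
    n_sites = None
    chrom = None
    for obj in (consensus, reads, blocks):
        if obj is None:
            continue
        if n_sites is None:
            n_sites, chrom = obj.n_sites, obj.chrom
        elif obj.n_sites != n_sites or obj.chrom != chrom:
            raise ValueError(
                f"site-index mismatch between inputs: ({chrom}, {n_sites}) vs "
                f"({obj.chrom}, {obj.n_sites})"
            )
    rows: list[FragmentRow] = []
    if consensus is not None and consensus.n_phased > 0:
        rows.extend(build_super_reads(consensus, config))
    if reads is not None and "read" in config.include_sources:
        rows.extend(r for r in reads.rows if r.source == "read")
    if blocks is not None and "block" in config.include_sources:
        rows.extend(blocks_to_rows(blocks, weight=block_row_weight))
    return FragmentMatrix(chrom, n_sites, rows)


def integrative_solve(
    consensus: ConsensusHaplotypes | None,
    reads: FragmentMatrix | None = None,
    blocks: Phasing | None = None,
    config: IntegrationConfig | None = None,
    sites: Sequence[VariantSite] | None = None,
) -> WmecSolution:
    """Joint wMEC solve of super reads, reads and pre-phased block rows."""
    config = config or IntegrationConfig()
    joint = build_joint_matrix(consensus, reads, blocks, config)
    selection = select_rows(joint, max_coverage=config.max_coverage)
    if selection.dropped_rows:
        logger.info(
            "read selection dropped %d of %d rows (coverage cap %d)",
            len(selection.dropped_rows),
            len(joint.rows),
            config.max_coverage,
        )
        joint = joint.subset(selection.kept_rows)
    return solve_wmec(joint, sites=sites)


def integrative_phase(
    consensus: ConsensusHaplotypes | None,
    reads: FragmentMatrix | None = None,
    blocks: Phasing | None = None,
    config: IntegrationConfig | None = None,
    sites: Sequence[VariantSite] | None = None,
) -> Phasing:
    """The integrative phasing strategy; returns the assembled haplotypes.

    With an empty consensus this degrades to read-only (or block-only)
    phasing; with consensus only, the consensus sites form one block.
    """
    return integrative_solve(consensus, reads, blocks, config, sites).haplotypes
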