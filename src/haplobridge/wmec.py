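"""Exact weighted minimum-error-correction (wMEC) phasing.

Given a fragment matrix, the wMEC problem asks for a bipartition of the rows
into two haplotype groups such that the total Phred weight of allele calls
that must be flipped to make each group consistent with a single haplotype
is minimal.  Because every column is a known heterozygous site, the two
haplotypes are constrained to be complementary: the per-column cost of a
bipartition is

    min over a in {0,1} of  w(calls in group 1 with allele != a)
                          + w(calls in group 2 with allele != 1-a).

The solver processes columns in site order with a dynamic program whose
state is the bipartition (up to complement) of the rows *active* at the
column — a row is active from its first to its last covered site.  Runtime
is linear in the number of sites and exponential only in the per-column
coverage, which is why a coverage-capped read selection precedes solving.
States are canonicalized by fixing the lowest-index active row to group 1;
equal-cost ties resolve to the lexicographically smallest canonical state.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .model import (
    FragmentMatrix,
    FragmentRow,
    PhasedBlock,
    Phasing,
    VariantSite,
    blocks_from_rows,
)

logger = logging.getLogger(__name__)

DEFAULT_MAX_COVERAGE = 15

#: Hard cap on simultaneously active rows; beyond this the DP state space is
#: impractical and the caller must thin the matrix with :func:`select_rows`.
MAX_ACTIVE_ROWS = 20


@dataclass(slots=True)
class SelectionResult:
    """Outcome of coverage-capped greedy read selection."""

    kept_rows: list[str]
    dropped_rows: list[str]
    coverage: np.ndarray  # per-site calling coverage after selection


@dataclass(slots=True)
class WmecSolution:
    """Optimal bipartition of fragment rows into two haplotype groups."""

    chrom: str
    cost: float  # total Phred weight of corrected alleles
    partition: dict[str, int]  # row_id -> haplotype 1 or 2
    haplotypes: Phasing  # one block per connected component
    corrected_cells: list[tuple[str, int]]  # (row_id, site_index) flipped
    n_columns: int = 0  # DP columns processed (== number of covered sites)


def select_rows(
    matrix: FragmentMatrix, max_coverage: int = DEFAULT_MAX_COVERAGE
) -> SelectionResult:
    """Greedy selection of rows under a per-site coverage cap.

    Super-read rows are always kept (they carry the global scaffold); the
    remaining rows are considered by decreasing (number of covered sites,
    total weight) with row_id as the deterministic tie-break, and a row is
    kept iff it pushes no site above ``max_coverage``.
    """
    if max_coverage < 2:
        raise ValueError("max_coverage must be >= 2")
    coverage = np.zeros(matrix.n_sites, dtype=np.int64)
    kept: list[str] = []
    dropped: list[str] = []
    supers = [r for r in matrix.rows if r.source == "super_read"]
    others = [r for r in matrix.rows if r.source != "super_read"]
    for row in supers:
        for c in row.calls:
            coverage[c.site_index] += 1
        kept.append(row.row_id)
    if supers and coverage.max(initial=0) > max_coverage:
        raise ValueError(
            f"super-read rows alone exceed max_coverage={max_coverage}"
        )
    others.sort(key=lambda r: (-r.n_calls, -r.total_weight, r.row_id))
    for row in others:
        idx = list(row.site_indices)
        if all(coverage[i] < max_coverage for i in idx):
            for i in idx:
                coverage[i] += 1
            kept.append(row.row_id)
        else:
            dropped.append(row.row_id)
    return SelectionResult(kept, dropped, coverage)


# ---------------------------------------------------------------------------
# Column DP over one connected component
# ---------------------------------------------------------------------------

def _solve_component(
    rows: list[FragmentRow], columns: list[int]
) -> tuple[dict[str, int], dict[int, int], list[tuple[str, int]], float]:
    """Solve wMEC for the rows of one connected component.

    Returns (row sides 0/1, {site: hap1 allele}, corrected cells, cost).
    """
    col_pos = {s: t for t, s in enumerate(columns)}
    n_cols = len(columns)
    first = np.empty(len(rows), dtype=np.int64)
    last = np.empty(len(rows), dtype=np.int64)
    calls_by_col: list[list[tuple[int, int, float]]] = [[] for _ in range(n_cols)]
    for i, row in enumerate(rows):
        first[i] = col_pos[row.first_site]
        last[i] = col_pos[row.last_site]
        for c in row.calls:
            calls_by_col[col_pos[c.site_index]].append((i, c.allele, c.weight))

    # per-column DP records for the backtrace
    actives: list[list[int]] = []
    ptrs: list[np.ndarray | None] = []
    flips: list[np.ndarray | None] = []
    F_prev: np.ndarray | None = None
    active_prev: list[int] = []

    for t in range(n_cols):
        active = [i for i in range(len(rows)) if first[i] <= t <= last[i]]
        k = len(active)
        if k > MAX_ACTIVE_ROWS:
            raise ValueError(
                f"{k} rows active at one column exceeds the solver limit "
                f"({MAX_ACTIVE_ROWS}); thin the matrix with select_rows()"
            )
        pos = {r: p for p, r in enumerate(active)}
        nstates = 1 << max(k - 1, 0)
        states = np.arange(nstates, dtype=np.int64)
        # column cost under the heterozygosity constraint
        m0a1 = np.zeros(nstates)
        m0a0 = np.zeros(nstates)
        m1a1 = np.zeros(nstates)
        m1a0 = np.zeros(nstates)
        for ri, allele, weight in calls_by_col[t]:
            p = pos[ri]
            if p == 0:
                b = np.zeros(nstates)
            else:
                b = ((states >> (p - 1)) & 1).astype(np.float64)
            if allele == 1:
                m0a1 += weight * (1.0 - b)
                m1a1 += weight * b
            else:
                m0a0 += weight * (1.0 - b)
                m1a0 += weight * b
        delta = np.minimum(m0a1 + m1a0, m0a0 + m1a1)

        if t == 0:
            F = delta
            ptrs.append(None)
            flips.append(None)
        else:
            shared = [r for r in active_prev if last[r] >= t]  # also active now
            m = len(shared)
            mask = (1 << m) - 1
            pos_prev = {r: p for p, r in enumerate(active_prev)}
            # keys of previous states restricted to the shared rows
            nprev = len(F_prev)
            sprev = np.arange(nprev, dtype=np.int64)
            key_prev = np.zeros(nprev, dtype=np.int64)
            for q, r in enumerate(shared):
                p = pos_prev[r]
                bit = ((sprev >> (p - 1)) & 1) if p > 0 else np.zeros(nprev, dtype=np.int64)
                key_prev |= bit << q
            f_prev = (key_prev & 1).astype(np.int64) if m > 0 else np.zeros(nprev, dtype=np.int64)
            keyc_prev = np.where(f_prev == 1, ~key_prev & mask, key_prev)
            table_val = np.full(1 << m, np.inf)
            table_arg = np.zeros(1 << m, dtype=np.int64)
            table_flip = np.zeros(1 << m, dtype=np.int64)
            order = np.argsort(F_prev, kind="stable")[::-1]
            table_val[keyc_prev[order]] = F_prev[order]
            table_arg[keyc_prev[order]] = order
            table_flip[keyc_prev[order]] = f_prev[order]
            # keys of current states restricted to the shared rows
            key_cur = np.zeros(nstates, dtype=np.int64)
            for q, r in enumerate(shared):
                p = pos[r]
                bit = ((states >> (p - 1)) & 1) if p > 0 else np.zeros(nstates, dtype=np.int64)
                key_cur |= bit << q
            f_cur = (key_cur & 1).astype(np.int64) if m > 0 else np.zeros(nstates, dtype=np.int64)
            keyc_cur = np.where(f_cur == 1, ~key_cur & mask, key_cur)
            F = delta + table_val[keyc_cur]
            ptrs.append(table_arg[keyc_cur])
            flips.append(f_cur ^ table_flip[keyc_cur])
        actives.append(active)
        F_prev = F
        active_prev = active

    # backtrace
    s = int(np.argmin(F_prev))
    cost = float(F_prev[s])
    g = 0
    sides: dict[int, int] = {}
    for t in range(n_cols - 1, -1, -1):
        active = actives[t]
        for p, r in enumerate(active):
            bit = (s >> (p - 1)) & 1 if p > 0 else 0
            side = bit ^ g
            if r in sides:
                assert sides[r] == side, "inconsistent backtrace"
            else:
                sides[r] = side
        if t > 0:
            g ^= int(flips[t][s])
            s = int(ptrs[t][s])

    # haplotype extraction and corrected cells
    hap1: dict[int, int] = {}
    corrected: list[tuple[str, int]] = []
    check_cost = 0.0
    for t, site in enumerate(columns):
        cost_a = [0.0, 0.0]
        for ri, allele, weight in calls_by_col[t]:
            target0 = [0, 1][sides[ri]]  # group's target when hap1 allele = 0
            if allele != target0:
                cost_a[0] += weight
            if allele != 1 - target0:
                cost_a[1] += weight
        a = 0 if cost_a[0] <= cost_a[1] else 1
        if cost_a[0] == cost_a[1] and calls_by_col[t]:
            logger.debug("column %d: tied haplotype allele, choosing 0", site)
        hap1[site] = a
        check_cost += cost_a[a]
        for ri, allele, weight in calls_by_col[t]:
            target = (a if sides[ri] == 0 else 1 - a)
            if allele != target:
                corrected.append((rows[ri].row_id, site))
    assert abs(check_cost - cost) < 1e-6 * max(1.0, abs(cost)), (
        "extracted corrections disagree with DP optimum"
    )
    row_sides = {rows[i].row_id: side for i, side in sides.items()}
    return row_sides, hap1, corrected, check_cost


def solve_wmec(
    matrix: FragmentMatrix, sites: Sequence[VariantSite] | None = None
) -> WmecSolution:
    """Solve wMEC optimally, reporting haplotypes per connected component.

    The cost is the global minimum over all row bipartitions; per column the
    haplotype allele is the weight-majority allele of the haplotype-1 group
    (ties choose the reference allele).  ``sites`` supplies 1-based
    positions for phase-set block identifiers; without it the smallest site
    index + 1 is used.
    """
    components = blocks_from_rows(matrix)
    partition: dict[str, int] = {}
    corrected: list[tuple[str, int]] = []
    blocks: list[PhasedBlock] = []
    total_cost = 0.0
    n_columns = 0
    comp_of_site: dict[int, int] = {}
    for ci, comp in enumerate(components):
        for s in comp:
            comp_of_site[s] = ci
    rows_by_comp: list[list[FragmentRow]] = [[] for _ in components]
    for row in matrix.rows:
        rows_by_comp[comp_of_site[row.first_site]].append(row)
    for comp, rows in zip(components, rows_by_comp):
        columns = sorted(comp)
        n_columns += len(columns)
        row_sides, hap1, corr, cost = _solve_component(rows, columns)
        total_cost += cost
        corrected.extend(corr)
        for row_id, side in row_sides.items():
            partition[row_id] = side + 1
        h1 = "".join(str(hap1[s]) for s in columns)
        h2 = "".join("1" if ch == "0" else "0" for ch in h1)
        block_id = sites[columns[0]].pos if sites is not None else columns[0] + 1
        blocks.append(
            PhasedBlock(matrix.chrom, tuple(columns), h1, h2, block_id=block_id)
        )
    phasing = Phasing(matrix.chrom, matrix.n_sites, blocks)
    return WmecSolution(
        chrom=matrix.chrom,
        cost=total_cost,
        partition=partition,
        haplotypes=phasing,
        corrected_cells=corrected,
        n_columns=n_columns,
    )


def wmec_cost_bruteforce(matrix: FragmentMatrix) -> float:
    """Minimum correction weight by enumerating all row bipartitions.

    Test oracle only; refuses matrices with more than 12 rows.
    """
    rows = matrix.rows
    if len(rows) > 12:
        raise ValueError("brute-force oracle limited to 12 rows")
    if not rows:
        return 0.0
    nmasks = 1 << (len(rows) - 1)  # row 0 fixed to group 0 (complement symmetry)
    masks = np.arange(nmasks, dtype=np.int64)
    side = np.zeros((len(rows), nmasks), dtype=np.float64)
    for i in range(1, len(rows)):
        side[i] = (masks >> (i - 1)) & 1
    covered = sorted({c.site_index for r in rows for c in r.calls})
    total = np.zeros(nmasks)
    for s in covered:
        m0a1 = np.zeros(nmasks)
        m0a0 = np.zeros(nmasks)
        m1a1 = np.zeros(nmasks)
        m1a0 = np.zeros(nmasks)
        for i, row in enumerate(rows):
            a = row.allele_at(s)
            if a is None:
                continue
            w = next(c.weight for c in row.calls if c.site_index == s)
            b = side[i]
            if a == 1:
                m0a1 += w * (1 - b)
                m1a1 += w * b
            else:
                m0a0 += w * (1 - b)
                m1a0 += w * b
        total += np.minimum(m0a1 + m1a0, m0a0 + m1a1)
    return float(total.min())
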