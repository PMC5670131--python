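# Methods

## The phasing model

`haplobridge` phases known biallelic heterozygous SNVs; it never re-calls
genotypes. All evidence about phase lives in a *fragment matrix*: rows are
sequencing reads, pre-phased haplotype segments, or chromosome-spanning
super reads; columns are the chromosome's het sites in dense 0-based order
(VCF positions remain 1-based at the interfaces); entries are 0 (reference
allele), 1 (alternative allele) or missing, each with a Phred-scaled weight
`-10·log10(error probability)` that prices the cost of overriding the call.

Because every column is heterozygous, the two haplotypes are complementary,
and phasing reduces to bipartitioning the rows into two haplotype groups.
The weighted minimum-error-correction (wMEC) objective charges, per column,

    min over a in {0,1}:  w(group-1 calls != a) + w(group-2 calls != 1-a),

and the optimum over all bipartitions is found exactly by a dynamic program
over columns whose state is the bipartition — up to complement — of the
rows *active* at that column (a row is active from its first to its last
covered site, so rows with internal gaps still transmit phase across them).
States are canonicalized by pinning the lowest-index active row to group 1;
transitions match states on the rows shared by consecutive columns, with a
flip bit tracking complement changes for the backtrace. Equal-cost ties
resolve to the lexicographically smallest canonical state, and tied column
alleles resolve to the reference allele, making the solver deterministic.
Connected components of the co-coverage graph (sites linked by some row)
are solved independently and become the output haplotype blocks; each block
carries a phase-set identifier equal to the 1-based position of its
smallest site.

The genotype-constrained column cost above (complementary targets) is used
in both the solver and the brute-force enumeration oracle. It coincides
with per-side-independent minimisation whenever one group is absent from a
column or the data are error-free, and it guarantees the reported
haplotypes are complementary with cost equal to the summed weight of the
reported corrected cells.

Per-column coverage is capped before solving (default 15, the solver being
exponential in coverage): rows are greedily admitted in decreasing
(covered sites, total weight) order, with row identifier as the final
deterministic tie-break, and super reads are always admitted first — they
carry the global scaffold.

## Strand-seq phasing

Strand-seq preserves template-strand identity, so in a WC chromosome of a
cell the Watson (reverse) reads come from one parental homolog and the
Crick (forward) reads from the other. The pipeline:

1. **Strand-state calling.** Watson/Crick read counts in fixed bins
   (default 1 Mb) are classified per bin: WW when the Watson fraction is at
   least the purity bound (default 0.8), CC when at most 1 - purity, WC
   when a two-sided exact binomial test of W among W+C at p=0.5 accepts at
   level alpha (default 0.05), otherwise unknown. Maximal runs of equal
   state merge into regions; the region p-value is recomputed on pooled
   counts. The binomial-versus-50:50 test is the package's formalization of
   the exact-test check on the expected 1:1 strand ratio; alpha and purity
   are exposed because no canonical values exist. Empty regions are
   unknown; the discreteness of the exact test makes the WC classification
   conservative (type-I error at most alpha).
2. **Cell haplotype matrices.** Alleles observed inside each cell's WC
   regions fill two parallel cell-by-site matrices, Watson and Crick.
   Duplicate observations at one (cell, strand, site) resolve by majority,
   ties dropping the entry. Cells are ordered by decreasing covered sites
   so the best-covered cells anchor the sorting.
3. **Two-matrix sorting.** The per-column score is (calls − most abundant
   allele); the matrix score is the sum over both matrices' columns. For
   each cell in row order, its Watson and Crick rows are swapped between
   the matrices and the swap is kept only if the score *strictly*
   decreases (strictness guarantees termination and determinism). The pass
   is repeated twice by default; further passes change nothing in practice.
   Greedy single-row swaps can in principle stall above the global optimum
   of the 2^cells swap space on pathological sparse noise — the test suite
   checks both the exhaustive-minimum match on well-covered instances and
   the never-below-optimum / never-increasing bounds in general.
4. **Consensus.** Per column, haplotype 1 takes the Watson majority and
   haplotype 2 the Crick majority; non-complementary consensus or a tied
   deciding column leaves the site unphased, and a column covered by only
   one matrix is decided by that matrix with the complement implied. Each
   phased site gets a Phred quality from the pseudocounted error estimate
   `-10·log10((minority+1)/(total+2))` and the base-2 Shannon entropy of
   the deciding column (0 iff monoallelic) — both bounded and
   deterministic; the specific formulas are package choices.
5. **Rescue.** Reads from strand-uninformative WW/CC regions still link
   sites. A read covering at least one phased and one unphased site is
   oriented to the haplotype agreeing with the majority of its phased
   alleles (orientation ties discard it) and votes alleles for its
   unphased sites; any conflict across reads leaves the site unphased, and
   rescued sites get the same pseudocount Phred from their vote count.

## Integration

The consensus becomes two complementary super-read rows weighted by the
per-site consensus Phred (a constant-weight mode exists for sensitivity
analysis); the weight the original pipeline gives these rows is not
documented anywhere, and the consensus Phred is the natural
confidence-propagating choice. Pre-phased blocks enter as *one* row per
block (the bipartition supplies the complement; a pair would double their
coverage and their effective weight); singleton blocks carry no phase
connection and are dropped. Reads enter as-is. One exact wMEC solve then
arbitrates all sources by weight — a wrong super-read allele at a
well-covered site is simply corrected, while at read-coverage gaps the
super read alone carries the phase. Chromosomes are processed
independently.

## Evaluation metrics

With `n` het sites and blocks `B`:

* completeness = Σ_B (|B|−1) / (n−1) — achieved over possible *phase
  connections* (adjacent phased pairs within a block);
* switch error rate = wrongly oriented phase connections / all evaluable
  phase connections; undefined (reported missing, never 0) without
  connections;
* largest-block fraction = |largest block| / n, ties by smallest phase-set
  id;
* largest-block Hamming rate = min over the two label pairings of the
  mismatch count with truth inside the largest block, / |block| — hence in
  [0, 0.5]; one mid-block switch already costs 0.5, which is what makes it
  the stringent global measure.

All four are invariant under swapping any block's haplotype labels. Sites
phased by the prediction but absent from truth are excluded from the
switch/Hamming denominators with a logged count. When aggregating over
chromosomes, completeness and switch error pool numerators and
denominators; largest-block fraction and Hamming average per-chromosome
values (each chromosome has its own largest segment).

## The simulator and its defaults

`SimConfig` defaults define the package's reference study conditions:
3 chromosomes × 500 sites over 5 Mb, 10 cells, WC:WW:CC = 1/2:1/4:1/4
independent across cells and chromosomes (the independence behind the
`(1−0.5^n)^23` coverage probability), 1% allele error, reads of geometric
mean span 5 sites at 10-fold mean coverage with uniform edge coverage
(read windows may overhang and truncate), pre-phased blocks of geometric
mean length 50 with 1% per-connection switch injection, and 60-read 1 Mb
bins for strand-state calling.

Two depth parameters deserve explanation:

* `cell_read_depth` (default 5 observations per site per cell) is
  deliberately *saturated*: the simulator compresses a chromosome to a few
  hundred sites, and the end-to-end recovery contract (completeness 1.0 on
  error-free data) requires the union of Strand-seq and read coverage to
  touch every site. Real Strand-seq is far sparser per cell.
* the downsampling sweep (`experiments.sweep_base_config`) instead uses a
  *sparse* per-cell depth of 0.125, chosen so its largest library subset
  (40 cells) accumulates the ~5× cumulative Strand-seq coverage of a full
  real data set — the sparse regime is the one the cells-by-depth sweep is
  designed to probe, and it is what makes the largest-block fraction grow
  with both axes of the grid.

What the simulator does **not** model: base-level sequences and alignment,
mappability or GC bias, sister-chromatid exchanges (strand states are
constant per cell and chromosome; mixed regions would be classified
unknown and excluded upstream in real data), realistic read-length
distributions, and variant-calling errors. Passing tests therefore
demonstrate the algorithmic correctness and statistical behaviour of the
method under its own assumptions, not performance on real libraries.

Strand-state independence, Bernoulli(0.5) truth alleles, and geometric
span/block lengths (one-parameter, memoryless, easily swapped) are
modelling choices; all randomness derives from a single mandatory seed via
independent sub-streams per data type, so every output is bit-reproducible
given (seed, config).

## Problem sizes and numerics

The bundled experiments use 500–1000 sites per chromosome, 5–40 cells and
2–15-fold read depth; the sweep grid runs 4 cell counts × 5 depths × 5
trials on one 200-site chromosome. The DP allows at most 20 simultaneously
active rows (2^19 canonical states) and refuses beyond that, pointing to
read selection. Weights are floats; cost comparisons in tests use absolute
tolerances around 1e-6. Degenerate inputs: empty matrices phase nothing at
cost 0; zero-read bins are unknown; sites covered by no row stay unphased;
an empty consensus degrades integration to read-only phasing.

## Known limitations

* Greedy matrix sorting is a heuristic; its fixed points can exceed the
  exhaustive swap optimum on sparse, noisy matrices (bounded and tested,
  never worse than the input).
* The rescue step's strict conflict rule favours precision over yield.
* Whole-genome Hamming aggregation is intentionally not defined — only the
  largest segment's Hamming rate is meaningful under this design.
* Polyploid phasing, genotype likelihoods, re-alignment-based allele
  detection and raw linked-read molecules are out of scope.
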