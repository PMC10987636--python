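# Methods

## The recording model

CRISPR scar recording marks lineage in a set of diploid endogenous target
genes. Each allele of each target can be edited at most once — a scar
destroys the sgRNA recognition site — and only during an early developmental
window (between fertilization and gastrulation). The observable state of an
allele is its *sequence-ID*: the 40 reference bases centered on the cut site
(20 on each side, half-open `[cut-20, cut+20)`), with read bases substituted,
inserted bases included when they fall strictly inside the window, and
deleted bases absent. This identifier distinguishes scars that share an
indel structure (same CIGAR) but differ in sequence, while ignoring
sequencing differences far from the cut site. The window is centered on the
cut site; the anchoring of the original 40-base window is not documented, so
this convention is stated rather than inherited. An unedited allele's
sequence-ID is the reference window itself (the *wildtype-ID*), defined from
the reference, never inferred from abundance.

## Filtering to a diploid allele table

Reads are kept when their cell barcode passed transcriptome QC and their
sequence starts with the gene-specific primer; kept reads are truncated to
75 nt (a cap, not padding). Reads are aligned to the amplicon reference
(edlib, infix mode) unless an alignment is already supplied (SAM with
CIGAR), and collapsed to UMI counts; a UMI observed with several
sequence-IDs is credited to its majority ID, ties broken to the
lexicographically smallest.

Per (cell, target), sequence-IDs are sorted by UMI count (descending, ties
lexicographic) and the *minimal prefix* whose cumulative count reaches 80%
of the total is taken; reaching exactly 80% counts as reached (comparisons
carry a 1e-9 tolerance so the decimal threshold behaves exactly in binary
floating point). If more than two sequences are needed, the target is
flagged for that cell and contributes no alleles; a cell with more than one
flagged target is removed entirely as a putative doublet. "Transcripts" are
UMIs throughout. One flagged target removes only that target's data — the
cell survives.

## Clone identification

Counting is cell-based everywhere: a sequence-ID in a cell counts once,
regardless of UMI count.

**Per target.** Sequence-IDs detected in exactly one cell are removed; the
analysis then restricts to cells with exactly two distinct retained IDs
(wildtype + scar allowed). Unordered pairs observed in fewer than 4 cells
are dropped. For each remaining pair, each member's *exclusivity fraction*
is the pair count divided by the member's total occurrences **within the
two-ID cell set**; the pair is a *true pair* when at least one member
reaches 0.8. Taking the denominator over the same cell population in which
pairs are counted keeps the fraction insensitive to allele dropout (a cell
that lost its second allele simply leaves the population); a parent scar is
still correctly diluted because it occurs in many different pairs. The
alternative denominator — all cells retaining the ID — was evaluated and
rejected: combined with dropout and the top-80% filter it pushes every
child-scar fraction below 0.8 and the pipeline returns no clones at any
realistic noise level.

A pair member is *clone-defining* when it reaches the exclusivity threshold
and is neither the wildtype-ID nor a *parent scar*, operationalized as an ID
occurring in ≥2 distinct true pairs (the number of pairs is not prescribed
anywhere; 2 is the most conservative choice and is configurable). Cells
showing a full true pair join that pair's clone; cells showing exactly one
retained ID that is clone-defining for exactly one pair join that clone;
cells with only wildtype, only parent scars, or ambiguous IDs stay
unassigned.

**Across targets.** For every unordered pair of targets, combinations of
per-target clone-IDs are counted over cells assigned on both targets;
combinations in fewer than 3 cells are dropped (the per-target cutoff keeps
pairs in ≥4 cells while merging keeps combinations in ≥3 — both inherited
verbatim and configurable separately). A combination is kept when one
member's fraction within the both-assigned population reaches 0.8.
*Clone-defining* status of a clone-ID — which licenses placing cells
assigned on only one of the two targets — is judged against **all** of that
clone-ID's per-target assignments, not just the both-assigned population:
otherwise an ID shared with a clone that is invisible on the partner target
(homozygous or wildtype there) appears falsely exclusive and pulls sibling
clones into one combination.

**Deduplication.** A cell placed by several target pairs accumulates
per-target clone-ID components; components must agree per target, else the
cell is dropped as conflicting (dropping, not arbitration). Component sets
supported by ≥3 cells act as clone *cores*. A cell whose components are a
strict subset of a core is ambiguous — dropout of the distinguishing allele
cannot be told apart from membership in a genuinely silent ancestral
lineage — and is left unassigned; a cell whose components extend a unique
core (spurious extras from chimeric observations) joins that core. This
conservatism is why the pipeline reports high agreement on placed cells
while leaving 30–45% of cells unplaced at the default noise levels.

**Display.** Cells with merged assignments form a binary incidence matrix
over target-qualified clone-defining sequence-IDs, ordered by average-linkage
hierarchical clustering on Jaccard distance (neither metric nor linkage is
prescribed; these are the standard choices for sparse binary profiles), with
a newick export of the dendrogram.

## The simulator

A full binary tree of depth 10 (default) is edited during the first 5
generations: each wildtype allele of each of 6 targets is edited with
probability p = 0.2 per generation, drawing its scar from a global
heavy-tailed outcome distribution (Zipf over 300 outcomes, exponent 0.7 —
the commonest repair outcome takes ~6% of events, so a handful of outcomes
recur in independent lineages as parent-like scars while most are unique).
Edits are fixed in a cell *before* it divides, so both daughters inherit
them; a G-generation window therefore resolves at most 2^(G-1) founder
lineages, and the defaults give ~15–16 clones among 500 sampled cells. The
closed-form edited-allele fraction is 1 − (1 − p)^G. A *true clone* is the
set of sampled cells sharing the identical set of edit events on their
ancestry (with no edits at all, the whole embryo is one clone); this is the
finest resolution a scar recorder can reach. Subtrees rooted at
generation 4 commit to one of four brain regions; clones whose genotype was
finalized at or after that commitment are single-region, earlier-established
clones can span regions — as real gastrulation-stage clones do.

The readout draws, per true allele: observation with probability 0.9
(10% allele dropout), a UMI count, and with probability 1% a reassignment
of the observation to a different random barcode (chimeras). 5% of barcodes
are replaced by the merged observations of two cells (doublets), flagged in
the ground truth. UMI counts default to 1 + Poisson(mean 29) per allele:
the targets are deeply sequenced amplicons of highly and uniformly expressed
housekeeping genes, so allelic fractions concentrate near equality and the
top-80% rule behaves as designed — real alleles survive, 3- and 4-allele
doublet targets are flagged. Overdispersed (geometric) and degenerate
(constant) count models are selectable; the geometric model is exercised in
unit tests, where its mode-1 skew demonstrably collapses minor alleles.
Dropout, chimera and doublet rates are plausible assumptions for 10x
targeted libraries, not measured values.

The noise-free benchmark configuration turns all three noise modes off, uses
constant UMI counts (count skew is itself a noise source), makes every edit
event's scar unique, and forbids homozygous edits — the one state the
pair-based caller cannot represent, since a homozygous cell shows a single
sequence-ID.

What the simulator does **not** model: per-base sequencing errors and
read-level FASTQ structure, PCR amplification beyond UMI counts,
transcriptome content, target-specific editing efficiencies, and scar
microhomology structure. Passing tests therefore demonstrate the logic of
filtering and clone calling under controlled noise, not performance on any
particular sequencing run.

## Analytics

*Regionality*: per cluster of a clusters × regions count table (dissected
samples only), the maximum region fraction ≥ 0.70 ⇒ *regional*, else
*global*; the boundary is inclusive ("70% or more"), and argmax ties break
by the fixed order telencephalon, diencephalon, mesencephalon,
rhombencephalon. *Stage contributions*: for an adult subtype, each joint
cluster of the integrated embedding is weighted by the fraction of the
subtype's adult cells it contains; weighted developmental-stage counts are
normalized to 100% (the normalization is applied literally to the weighted
counts; stages are not rebalanced for unequal sampling depth). *Transition
summaries*: per cell, the argmax destination of a row-stochastic transition
matrix (self-transitions included, ties to the lowest cell index), mapped to
clusters and tabulated as per-source-cluster fractions. *Substitution
rates*: records below Phred Q20 are eliminated; the rate of ref→alt is the
surviving record count divided by the aligned coverage of the reference
base (so sub-threshold records and record order cannot change the result);
zero-coverage bases report a missing rate.

## Numerical and testing choices

Fractional thresholds (0.8 exclusivity, 0.8 top fraction, 0.7 regionality)
are compared with a small epsilon so exact decimal boundaries pass. All ties
break deterministically (lexicographic IDs, fixed region order, lowest
index). Every stochastic component takes an explicit seed and identical
configurations produce byte-identical outputs. Benchmarks use 500 cells,
6 targets and 5 replicate seeds — large enough that the adjusted Rand index
and removal rates are stable to a few percent, small enough that the whole
suite runs in seconds. Agreement checks against brute-force
reimplementations (plain loops and dictionaries, in `tests/oracles.py`)
cover the pair rules, the merge, the top-80% prefix, transition aggregation
and stage weighting.

## Known limitations

- Homozygous edited cells are invisible to the pair logic and can cause a
  single-ID parent scar to absorb cells of a homozygous sibling clone; the
  pipeline inherits this blind spot deliberately.
- Clones distinguished only by scars that failed exclusivity (recurrent
  outcomes) merge with their siblings; the adjusted Rand index on placed
  cells stays high because such cells are usually left unplaced instead.
- The strict-subset rule discards genuinely silent ancestral clones along
  with dropout artifacts; coverage, not correctness, pays the price.
- The per-target pair search is quadratic in the number of IDs per target
  and the merge enumerates target pairs; both are trivial at realistic
  scales (dozens of IDs, ≤ tens of targets).
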