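# scartrace

Clone identification from CRISPR genetic scars in single cells.

In scar-based lineage tracing, Cas9 and sgRNAs delivered to the one-cell
zebrafish embryo create small indels ("genetic scars") in the 3' UTRs of
highly expressed endogenous genes (*actb1*, *actb2*, *cfl1*, *cirbpb*,
*rpl39*, *ube2e1*). Scars accumulate during early development, are inherited
unchanged, and are read out together with the transcriptome from targeted
10x amplicon libraries of the adult brain. Because every target gene is
diploid, a cell carries **at most two sequence variants per target** — and
that constraint drives both the quality filtering and the clone calling this
package implements:

- **scar_filtering** — from raw scar reads to a diploid *allele table*:
  barcode/primer retention, 75-nt truncation, extraction of a 40-base
  sequence-ID around the cut site, UMI collapse, the top-80%-of-transcripts
  rule keeping at most two sequences per (cell, target), and removal of
  barcodes flagged at more than one target as putative doublets.
- **clone_identification** — per target, *true pairs* of sequence-IDs whose
  co-occurrence is ≥80% exclusive for at least one member; clone-defining
  IDs (excluding wildtype and recurrent "parent" scars); placement of
  single-allele cells; pairwise merging across targets with the same
  cutoffs; deduplication into one clone per cell; and the binary
  cell × clone-defining-ID matrix with average-linkage/Jaccard hierarchical
  clustering (newick export) for heatmap display.
- **scar_simulator** — synthetic scar-recording experiments with full ground
  truth: a binary lineage tree edited during an early window, heavy-tailed
  scar-outcome recurrence (parent vs. child scars), region-committed
  subtrees, allele dropout, chimeric misassignment, and doublets.
- **state_analytics** — the small companion quantifications used alongside
  such an atlas: regional vs. global cluster calls (≥70% of cells from one
  dissected region), developmental stage-contribution weighting,
  per-cluster RNA-velocity transition summaries, and bulk SLAM-seq
  substitution-rate tables with Phred ≥ Q20 filtering (T→C conversions
  report 4sU metabolic labeling).

## Worked example

```python
import scartrace as st

config = st.SimConfig(seed=0)                      # 6 targets, 500 cells, noisy readout
sim = st.simulate_dataset(config)
alleles = st.filter_alleles(sim.scartable)         # diploid top-80% filter
wildtype = {t: ref.wildtype_id() for t, ref in sim.tree.references.items()}
clones = st.identify_clones(alleles, wildtype)

print(f"true clones simulated:   {sim.truth.cells['clone'].nunique()}")
print(f"doublet barcodes removed: {len(alleles.doublets)}")
print(f"cells placed into clones: {len(clones.merged.assignments)} / {len(sim.truth.cells)}")
print(f"merged clones found:      {clones.merged.assignments['clone'].nunique()}")
print(f"ARI vs simulated truth:   {st.clone_recovery_ari(clones.merged, sim.truth.clone_of()):.3f}")
```

prints

```
true clones simulated:   15
doublet barcodes removed: 26
cells placed into clones: 259 / 470
merged clones found:      12
ARI vs simulated truth:   1.000
```

Under 10% allele dropout, 1% chimeric observations and 5% doublets, the
filter removes 26 doublet barcodes, and the clone caller places 259 of 470
cells. Placement is deliberately conservative: cells whose surviving scars
cannot be told apart from an ancestral lineage (e.g. after dropout of the
distinguishing allele) are left unassigned rather than guessed, so the cells
that *are* placed agree perfectly with the simulated truth here (adjusted
Rand index 1.000). Twelve of fifteen true clones are recovered; the
remainder cannot be separated from related lineages with the scars that
survived filtering.

The same pipeline is available from the shell:

```bash
scartrace simulate --out-prefix sim/
scartrace filter --scartable sim/scartable.tsv --targets sim/targets.fa \
    --cutsites sim/cutsites.bed --out alleles.tsv
scartrace clones --alleles alleles.tsv --targets sim/targets.fa \
    --cutsites sim/cutsites.bed --out-prefix clones/
scartrace analytics regionality --counts region_counts.tsv --out calls.tsv
```

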