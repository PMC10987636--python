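"""Synthetic CRISPR-scar lineage datasets with ground truth.

The generator emulates scar-based lineage recording in the early embryo:
Cas9 and sgRNAs against several diploid endogenous target genes are delivered
at the one-cell stage, and during a short window of early divisions (between
fertilization and gastrulation) each unedited allele can independently
acquire a scar.  A scar destroys the sgRNA site, so an allele is edited at
most once and the resulting genotype is inherited unchanged afterwards.
Scar outcomes are drawn from a heavy-tailed distribution over repair
outcomes, so frequent outcomes recur in independent lineages ("parent"-like
scars) while rare outcomes are effectively unique ("child" scars).

Sampled cells are read out as a long (cell, target, seq_id, umi_count)
ScarTable with per-allele dropout, rare chimeric misassignment of
observations to other barcodes, and optional doublet barcodes merging two
cells — the noise modes the diploid filter and clone caller must survive.

A *true clone* is a set of sampled cells whose full edited genotype arose
from the same edit lineage: cells share a clone label iff the set of edit
events on their ancestry is identical.  This is the finest resolution a scar
recorder can reach; with no edits at all the whole embryo is one clone.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .filtering import DEFAULT_FLANK, TargetReference

#: endogenous target genes used for scar recording (3' UTR sgRNA targets)
ZEBRAFISH_TARGETS = ("actb1", "actb2", "cfl1", "cirbpb", "rpl39", "ube2e1")

#: dissected brain regions used as spatial compartments
BRAIN_REGIONS = ("telencephalon", "diencephalon", "mesencephalon", "rhombencephalon")

_BASES = np.array(list("ACGT"))

# sub-stream tags mixed into the seed so each stage draws independent numbers
_S_REFS, _S_TREE, _S_SAMPLE, _S_SCARS, _S_OBS, _S_DOUBLET = 1, 2, 3, 4, 5, 6


def zipf_weights(n_outcomes: int = 300, alpha: float = 0.7) -> tuple[float, ...]:
    """Heavy-tailed distribution over scar repair outcomes (normalized Zipf).

    The default spectrum gives the commonest repair outcome ~6% of edit
    events, so with a handful of edits per target a few outcomes recur in
    independent lineages (parent-like scars) while most are unique.
    """
    w = 1.0 / np.arange(1, n_outcomes + 1) ** alpha
    return tuple(w / w.sum())


@dataclass(frozen=True)
class SimConfig:
    """Parameters of one simulated scar-recording experiment.

    Defaults describe the reference scenario used throughout the test suite:
    six diploid targets, a five-division edit window (edits are fixed before
    each division, so the finest founder resolution is the 16 cells entering
    the last window division), 500 cells sampled from a depth-10 tree, four
    brain regions committed in generation 4, 10% allele dropout, 1% chimeric
    misassignment, 5% doublets, and near-Poisson UMI counts with mean 30 per
    allele (UMI sampling of deeply sequenced amplicons of highly expressed
    housekeeping genes; overdispersed count models are available as options).
    Dropout/chimeric/doublet levels are modeling assumptions chosen to be
    plausible for 10x targeted amplicon data, not measured values.
    """

    n_targets: int = 6
    targets: tuple[str, ...] | None = None
    n_generations_edit_window: int = 5
    p_edit_per_allele_per_generation: float = 0.2
    scar_outcome_weights: tuple[float, ...] = field(default_factory=zipf_weights)
    unique_scar_ids: bool = False
    allow_homozygous: bool = True
    tree_depth: int = 10
    n_cells_sampled: int = 500
    n_regions: int = 4
    region_assignment_depth: int = 4
    p_allele_dropout: float = 0.1
    p_chimeric: float = 0.01
    doublet_rate: float = 0.05
    umi_count_distribution: tuple[str, float] = ("poisson", 30.0)
    ref_length: int = 240
    cut_site: int = 120
    seed: int = 0

    def __post_init__(self):
        probs = {
            "p_edit_per_allele_per_generation": self.p_edit_per_allele_per_generation,
            "p_allele_dropout": self.p_allele_dropout,
            "p_chimeric": self.p_chimeric,
            "doublet_rate": self.doublet_rate,
        }
        for name, p in probs.items():
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {p}")
        if self.targets is not None and len(self.targets) != self.n_targets:
            raise ValueError("len(targets) must equal n_targets")
        if self.n_targets < 1:
            raise ValueError("n_targets must be >= 1")
        if not 0 <= self.n_generations_edit_window <= self.tree_depth:
            raise ValueError("edit window must fit within tree_depth")
        if not 0 <= self.region_assignment_depth <= self.tree_depth:
            raise ValueError("region_assignment_depth must be <= tree_depth")
        if not 1 <= self.tree_depth <= 22:
            raise ValueError("tree_depth must be in [1, 22]")
        if not 1 <= self.n_cells_sampled <= 2**self.tree_depth:
            raise ValueError("n_cells_sampled must be <= 2**tree_depth")
        if self.n_regions < 1:
            raise ValueError("n_regions must be >= 1")
        w = np.asarray(self.scar_outcome_weights, dtype=float)
        if w.ndim != 1 or len(w) < 2 or (w < 0).any() or abs(w.sum() - 1.0) > 1e-9:
            raise ValueError("scar_outcome_weights must be >=2 non-negative weights summing to 1")
        kind, param = self.umi_count_distribution
        if kind not in ("poisson", "geometric", "constant") or param < 1:
            raise ValueError(
                "umi_count_distribution must be ('poisson'|'geometric'|'constant', value >= 1)"
            )
        if not 0 <= self.cut_site < self.ref_length:
            raise ValueError("cut_site must lie within the reference")

    @property
    def target_names(self) -> tuple[str, ...]:
        if self.targets is not None:
            return tuple(self.targets)
        base = list(ZEBRAFISH_TARGETS[: self.n_targets])
        base += [f"target_{i}" for i in range(len(base), self.n_targets)]
        return tuple(base)

    @property
    def region_names(self) -> tuple[str, ...]:
        base = list(BRAIN_REGIONS[: self.n_regions])
        base += [f"region_{i}" for i in range(len(base), self.n_regions)]
        return tuple(base)


@dataclass
class LineageTree:
    """A simulated binary lineage tree, stored at clone-founder resolution.

    After the edit window closes genotypes are inherited unchanged, so only
    the nodes at the end of the window (the potential clone founders) are
    materialized; deeper structure is implicit in the leaf indices.
    """

    config: SimConfig
    references: dict[str, TargetReference]
    #: (2**window, n_targets, 2) integer allele codes, 0 = wildtype
    window_genotypes: np.ndarray
    #: per window node: integer clone index (shared edit lineage)
    clone_index: np.ndarray
    #: per window node: tree depth at which its genotype was finalized
    establish_depth: np.ndarray
    #: per node at region_assignment_depth: region index
    region_index: np.ndarray
    #: sampled leaf indices within [0, 2**tree_depth)
    leaf_indices: np.ndarray
    #: (target, allele code) -> sequence-ID string (code 0 = wildtype window)
    scar_ids: dict[tuple[str, int], str]

    def seq_id(self, target: str, code: int) -> str:
        if code == 0:
            return self.references[target].wildtype_id()
        return self.scar_ids[(target, code)]

    def leaf_window_nodes(self) -> np.ndarray:
        shift = self.config.tree_depth - self.config.n_generations_edit_window
        return self.leaf_indices >> shift

    def leaf_region_nodes(self) -> np.ndarray:
        shift = self.config.tree_depth - self.config.region_assignment_depth
        return self.leaf_indices >> shift


@dataclass
class SimTruth:
    """Ground truth for sampled cells.

    ``cells`` has columns ``cell, clone, region, is_doublet, partner``
    (partner is the second cell merged into a doublet barcode, else NA);
    ``alleles`` has one row per true allele:
    ``cell, target, allele, seq_id`` with ``allele`` in {0, 1}.
    """

    cells: pd.DataFrame
    alleles: pd.DataFrame

    def clone_of(self) -> pd.Series:
        return self.cells.set_index("cell")["clone"]


def _random_sequence(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(_BASES, size=length))


def _scar_sequence(window: str, rng: np.random.Generator, flank: int = DEFAULT_FLANK) -> str:
    """One repair outcome: a deletion centered at the cut, optionally with insertion."""
    del_len = int(rng.integers(1, 13))
    ins_len = int(rng.integers(0, 7))
    insertion = "".join(rng.choice(_BASES, size=ins_len)) if ins_len else ""
    start = max(0, flank - del_len // 2)
    return window[:start] + insertion + window[start + del_len :]


def simulate_lineage(config: SimConfig) -> tuple[LineageTree, SimTruth]:
    """Grow the edited lineage tree and sample cells with ground-truth labels."""
    targets = config.target_names
    n_t = config.n_targets
    window_depth = config.n_generations_edit_window

    rng_refs = np.random.default_rng([config.seed, _S_REFS])
    references = {}
    for t in targets:
        seq = _random_sequence(rng_refs, config.ref_length)
        references[t] = TargetReference(
            target=t, sequence=seq, cut_site=config.cut_site, primer=seq[:20]
        )

    # --- editing during the window -------------------------------------
    rng_tree = np.random.default_rng([config.seed, _S_TREE])
    weights = np.asarray(config.scar_outcome_weights, dtype=float)
    n_outcomes = len(weights)
    genotypes = np.zeros((1, n_t, 2), dtype=np.int64)
    last_edit_node = np.zeros(1, dtype=np.int64)  # heap id of last edited ancestor, 0 = none
    event_counter = 0
    for depth in range(window_depth):
        editable = genotypes == 0
        do_edit = editable & (rng_tree.random(genotypes.shape) < config.p_edit_per_allele_per_generation)
        for i, t_idx, allele in np.argwhere(do_edit):
            event_counter += 1
            if config.unique_scar_ids:
                code = event_counter
            else:
                code = int(rng_tree.choice(n_outcomes, p=weights)) + 1
                other = genotypes[i, t_idx, 1 - allele]
                while not config.allow_homozygous and code == other:
                    code = int(rng_tree.choice(n_outcomes, p=weights)) + 1
            genotypes[i, t_idx, allele] = code
            last_edit_node[i] = (1 << depth) + i
        genotypes = np.repeat(genotypes, 2, axis=0)
        last_edit_node = np.repeat(last_edit_node, 2)

    clone_index = pd.factorize(last_edit_node)[0]
    establish_depth = np.where(
        last_edit_node > 0, np.floor(np.log2(np.maximum(last_edit_node, 1))).astype(int), 0
    )
    region_index = rng_tree.integers(0, config.n_regions, size=2**config.region_assignment_depth)

    # --- sample leaves --------------------------------------------------
    rng_sample = np.random.default_rng([config.seed, _S_SAMPLE])
    leaf_indices = np.sort(
        rng_sample.choice(2**config.tree_depth, size=config.n_cells_sampled, replace=False)
    )

    # --- scar sequence-IDs ---------------------------------------------
    scar_ids: dict[tuple[str, int], str] = {}
    for t_idx, t in enumerate(targets):
        window = references[t].wildtype_id()
        used = {window}
        for code in np.unique(genotypes[:, t_idx, :]):
            if code == 0:
                continue
            attempt = 0
            while True:
                rng_scar = np.random.default_rng([config.seed, _S_SCARS, t_idx, int(code), attempt])
                seq = _scar_sequence(window, rng_scar)
                if seq not in used:
                    break
                attempt += 1
            used.add(seq)
            scar_ids[(t, int(code))] = seq

    tree = LineageTree(
        config=config,
        references=references,
        window_genotypes=genotypes,
        clone_index=clone_index,
        establish_depth=establish_depth,
        region_index=region_index,
        leaf_indices=leaf_indices,
        scar_ids=scar_ids,
    )

    # --- ground truth tables -------------------------------------------
    n_cells = config.n_cells_sampled
    cell_names = np.array([f"cell_{i:05d}" for i in range(n_cells)])
    founders = tree.leaf_window_nodes()
    region_nodes = tree.leaf_region_nodes()
    pad = max(3, len(str(clone_index.max())))
    cells = pd.DataFrame(
        {
            "cell": cell_names,
            "clone": [f"clone_{clone_index[f]:0{pad}d}" for f in founders],
            "region": [config.region_names[region_index[r]] for r in region_nodes],
            "is_doublet": False,
            "partner": pd.array([pd.NA] * n_cells, dtype="string"),
        }
    )

    rows = []
    for cell, founder in zip(cell_names, founders):
        for t_idx, t in enumerate(targets):
            for allele in (0, 1):
                code = int(genotypes[founder, t_idx, allele])
                rows.append((cell, t, allele, tree.seq_id(t, code)))
    alleles = pd.DataFrame(rows, columns=["cell", "target", "allele", "seq_id"])
    return tree, SimTruth(cells=cells, alleles=alleles)


def sample_observations(tree: LineageTree, truth: SimTruth, config: SimConfig) -> pd.DataFrame:
    """Read out sampled cells as a ScarTable with dropout, UMI counts, and chimeras.

    Each true allele is observed with probability ``1 - p_allele_dropout``;
    observed alleles receive a UMI count from the configured distribution;
    with probability ``p_chimeric`` an observation is credited to a different
    random cell.  Wildtype alleles emit the wildtype sequence-ID.
    """
    rng = np.random.default_rng([config.seed, _S_OBS])
    obs = truth.alleles.copy()
    keep = rng.random(len(obs)) < (1.0 - config.p_allele_dropout)
    obs = obs[keep].reset_index(drop=True)
    if obs.empty:
        return pd.DataFrame(columns=["cell", "target", "seq_id", "umi_count"])

    kind, param = config.umi_count_distribution
    if kind == "poisson":
        # UMI sampling of a uniformly, highly expressed target: shifted so
        # an observed allele always has at least one UMI
        counts = 1 + rng.poisson(param - 1.0, size=len(obs))
    elif kind == "geometric":
        counts = rng.geometric(1.0 / param, size=len(obs))
    else:
        counts = np.full(len(obs), int(param))
    obs["umi_count"] = counts

    cell_names = truth.cells["cell"].to_numpy()
    name_to_idx = {c: i for i, c in enumerate(cell_names)}
    chimeric = rng.random(len(obs)) < config.p_chimeric
    if chimeric.any():
        own = obs.loc[chimeric, "cell"].map(name_to_idx).to_numpy()
        offset = rng.integers(1, len(cell_names), size=chimeric.sum())
        obs.loc[chimeric, "cell"] = cell_names[(own + offset) % len(cell_names)]

    table = (
        obs.groupby(["cell", "target", "seq_id"], sort=True)["umi_count"]
        .sum()
        .reset_index()
    )
    return table


def inject_doublets(
    table: pd.DataFrame, truth: SimTruth, rate: float, seed: int
) -> tuple[pd.DataFrame, SimTruth]:
    """Merge pairs of barcodes to emulate droplets that captured two cells.

    Each barcode independently becomes a doublet host with probability
    ``rate``; a distinct victim barcode is folded into it (observations and
    truth alleles re-credited, the victim removed).  Hosts keep their own
    clone/region labels and are flagged ``is_doublet`` with the victim
    recorded as ``partner``.
    """
    if not 0.0 <= rate <= 1.0:
        raise ValueError(f"doublet rate must be in [0, 1], got {rate}")
    rng = np.random.default_rng([seed, _S_DOUBLET])
    cells = truth.cells["cell"].to_numpy()
    host_mask = rng.random(len(cells)) < rate
    hosts = cells[host_mask]
    pool = cells[~host_mask]
    if len(hosts) == 0:
        return table.copy(), SimTruth(cells=truth.cells.copy(), alleles=truth.alleles.copy())
    if len(hosts) > len(pool):
        raise ValueError("doublet rate too high: not enough victim barcodes to pair")
    victims = rng.choice(pool, size=len(hosts), replace=False)
    victim_to_host = dict(zip(victims, hosts))

    new_table = table.copy()
    new_table["cell"] = new_table["cell"].map(lambda c: victim_to_host.get(c, c))
    new_table = (
        new_table.groupby(["cell", "target", "seq_id"], sort=True)["umi_count"].sum().reset_index()
    )

    cells_df = truth.cells.copy()
    host_set = set(hosts)
    cells_df.loc[cells_df["cell"].isin(host_set), "is_doublet"] = True
    host_partner = {h: v for v, h in victim_to_host.items()}
    mask = cells_df["cell"].isin(host_set)
    cells_df.loc[mask, "partner"] = cells_df.loc[mask, "cell"].map(host_partner)
    cells_df = cells_df[~cells_df["cell"].isin(set(victims))].reset_index(drop=True)

    alleles = truth.alleles.copy()
    alleles["cell"] = alleles["cell"].map(lambda c: victim_to_host.get(c, c))
    return new_table, SimTruth(cells=cells_df, alleles=alleles)


@dataclass
class SimResult:
    """A complete simulated dataset: tree, truth, and the observed ScarTable."""

    tree: LineageTree
    truth: SimTruth
    scartable: pd.DataFrame

    @property
    def config(self) -> SimConfig:
        return self.tree.config


def simulate_dataset(config: SimConfig) -> SimResult:
    """Run the full generator: lineage, observation noise, doublets."""
    tree, truth = simulate_lineage(config)
    table = sample_observations(tree, truth, config)
    table, truth = inject_doublets(table, truth, config.doublet_rate, config.seed)
    return SimResult(tree=tree, truth=truth, scartable=table)


def edited_allele_fraction(tree: LineageTree) -> float:
    """Fraction of edited alleles across sampled cells (all targets pooled).

    With edit probability p per allele per generation over a window of G
    divisions, the expectation is 1 - (1 - p)**G.
    """
    g = tree.window_genotypes[tree.leaf_window_nodes()]
    return float((g != 0).mean())


def write_dataset(result: SimResult, outdir) -> None:
    """Write the simulated dataset as plain-text files.

    Emits ``scartable.tsv`` (cell, target, seq_id, umi_count), ``truth.tsv``
    (cell, clone, region, is_doublet, partner), ``truth_alleles.tsv``,
    ``targets.fa``, ``cutsites.bed`` (0-based half-open) and ``barcodes.txt``.
    """
    import os

    from . import io

    os.makedirs(outdir, exist_ok=True)
    cfg = result.config
    header = {"seed": cfg.seed, "n_targets": cfg.n_targets, "n_cells": cfg.n_cells_sampled}
    io.write_tsv(result.scartable, os.path.join(outdir, "scartable.tsv"), header=header)
    io.write_tsv(result.truth.cells, os.path.join(outdir, "truth.tsv"), header=header)
    io.write_tsv(result.truth.alleles, os.path.join(outdir, "truth_alleles.tsv"), header=header)
    io.write_fasta(
        {t: ref.sequence for t, ref in result.tree.references.items()},
        os.path.join(outdir, "targets.fa"),
    )
    io.write_cutsites_bed(
        {t: ref.cut_site for t, ref in result.tree.references.items()},
        os.path.join(outdir, "cutsites.bed"),
    )
    io.write_barcodes(result.truth.cells["cell"], os.path.join(outdir, "barcodes.txt"))
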