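"""Clone identification from diploid scar allele tables.

Clone calling works per target first.  Because every target gene is diploid,
a clone is marked at one target by an unordered *pair* of sequence-IDs
(wildtype + scar, or scar + scar).  Pairs that co-occur across enough cells
and account for at least 80% of one member's observations are *true pairs*;
their non-wildtype, non-recurrent members become clone-defining IDs that can
also place cells in which only a single allele was detected.  Per-target
clones are then merged across all pairs of targets with the same
co-occurrence/exclusivity logic applied at the clone-ID level, and cells are
deduplicated into a single merged assignment.

Observations are counted as cell presence: a sequence-ID detected in a cell
counts once regardless of its UMI count.
"""

from __future__ import annotations

import itertools
import logging
from collections import Counter, defaultdict
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .filtering import AlleleTable

logger = logging.getLogger(__name__)

# tolerance when comparing count ratios against fractional thresholds, so an
# exclusivity of exactly 80% counts as reached despite binary floating point
_FRACTION_EPS = 1e-12

#: separator used in per-target clone labels
_PAIR_SEP = "|"


@dataclass
class TruePair:
    """A validated co-occurring sequence-ID pair on one target."""

    target: str
    id_a: str
    id_b: str
    n_cells: int
    frac_a: float
    frac_b: float
    clone_defining: frozenset[str] = field(default_factory=frozenset)

    def __post_init__(self):
        if self.id_b < self.id_a:  # canonical unordered pair
            self.id_a, self.id_b = self.id_b, self.id_a
            self.frac_a, self.frac_b = self.frac_b, self.frac_a

    @property
    def ids(self) -> frozenset[str]:
        return frozenset((self.id_a, self.id_b))

    @property
    def label(self) -> str:
        return f"{self.target}:{self.id_a}{_PAIR_SEP}{self.id_b}"


@dataclass
class CloneAssignment:
    """cell -> clone labels at one level (per-target or merged)."""

    level: str
    assignments: pd.DataFrame  # columns: cell, clone (+ provenance for merged)
    dropped_conflicts: list[str] = field(default_factory=list)

    def as_series(self) -> pd.Series:
        return self.assignments.set_index("cell")["clone"]


def _presence(alleles: AlleleTable | pd.DataFrame, target: str) -> pd.DataFrame:
    """Distinct (cell, seq_id) presence rows for one target."""
    df = alleles.retained if isinstance(alleles, AlleleTable) else alleles
    if target not in set(df["target"]):
        raise KeyError(f"unknown target {target!r}")
    sub = df[df["target"] == target]
    return sub[["cell", "seq_id"]].drop_duplicates()


def find_true_pairs(
    alleles: AlleleTable | pd.DataFrame,
    target: str,
    min_pair_cells: int = 4,
    exclusivity: float = 0.8,
) -> list[TruePair]:
    """Validated sequence-ID pairs for one target.

    Steps: drop sequence-IDs detected in exactly one cell; restrict to cells
    with exactly two distinct retained IDs (wildtype + scar allowed); count
    each unordered pair; drop pairs below ``min_pair_cells`` cells; keep a
    pair if at least ``exclusivity`` of one member's observations *within
    the two-ID cell set* fall in this pair.  Counting totals over the same
    cell set the pairs are counted in keeps the fractions insensitive to
    allele dropout; a parent scar is still diluted because it appears in
    many different combinations.
    """
    pres = _presence(alleles, target)
    cells_per_id = pres.groupby("seq_id")["cell"].nunique()
    keep_ids = set(cells_per_id[cells_per_id > 1].index)
    pres = pres[pres["seq_id"].isin(keep_ids)]
    if pres.empty:
        return []

    ids_by_cell = pres.groupby("cell")["seq_id"].agg(frozenset)
    two_id = ids_by_cell[ids_by_cell.map(len) == 2]
    pair_counts = Counter(two_id)
    totals = Counter(itertools.chain.from_iterable(two_id))

    pairs = []
    for pair, n in sorted(pair_counts.items(), key=lambda kv: tuple(sorted(kv[0]))):
        if n < min_pair_cells:
            continue
        a, b = sorted(pair)
        frac_a = n / totals[a]
        frac_b = n / totals[b]
        if max(frac_a, frac_b) >= exclusivity - _FRACTION_EPS:
            pairs.append(
                TruePair(target=target, id_a=a, id_b=b, n_cells=int(n), frac_a=frac_a, frac_b=frac_b)
            )
    return pairs


def derive_clone_defining_ids(
    pairs: Sequence[TruePair],
    wildtype_id: str,
    exclusivity: float = 0.8,
    parent_min_pairs: int = 2,
) -> list[TruePair]:
    """Fill in each pair's clone-defining sequence-IDs.

    A member is clone-defining if its exclusivity fraction reaches the
    threshold, it is not the wildtype-ID, and it is not a parent scar (an ID
    appearing in at least ``parent_min_pairs`` distinct true pairs).  A pair
    whose clone-defining set is empty still defines a clone, but only via the
    exact pair, never via a single ID.
    """
    membership = Counter(itertools.chain.from_iterable(p.ids for p in pairs))
    parents = {i for i, n in membership.items() if n >= parent_min_pairs}
    out = []
    for p in pairs:
        defining = {
            i
            for i, frac in ((p.id_a, p.frac_a), (p.id_b, p.frac_b))
            if frac >= exclusivity - _FRACTION_EPS and i != wildtype_id and i not in parents
        }
        out.append(
            TruePair(
                target=p.target, id_a=p.id_a, id_b=p.id_b, n_cells=p.n_cells,
                frac_a=p.frac_a, frac_b=p.frac_b, clone_defining=frozenset(defining),
            )
        )
    return out


def assign_cells_per_target(
    alleles: AlleleTable | pd.DataFrame,
    target: str,
    pairs: Sequence[TruePair],
) -> CloneAssignment:
    """Place cells into per-target clones.

    Cells showing a full true pair get that pair's clone; cells showing
    exactly one retained ID that is clone-defining for exactly one pair get
    that clone; cells with only wildtype, only parent scars, or ambiguous
    IDs stay unassigned.
    """
    pair_by_ids = {p.ids: p for p in pairs}
    defining_pairs: dict[str, list[TruePair]] = defaultdict(list)
    for p in pairs:
        for i in p.clone_defining:
            defining_pairs[i].append(p)

    pres = _presence(alleles, target)
    rows = []
    for cell, ids in pres.groupby("cell")["seq_id"].agg(frozenset).items():
        pair = pair_by_ids.get(ids)
        if pair is not None:
            rows.append((cell, pair.label))
        elif len(ids) == 1:
            (only,) = ids
            cands = defining_pairs.get(only, [])
            if len(cands) == 1:
                rows.append((cell, cands[0].label))
    return CloneAssignment(
        level=f"target:{target}",
        assignments=pd.DataFrame(rows, columns=["cell", "clone"]),
    )


@dataclass
class _Combo:
    """A validated clone-ID combination for one target pair."""

    clone_a: str  # per-target clone label on the first target
    clone_b: str
    n_cells: int
    frac_a: float
    frac_b: float
    defining: frozenset[str] = field(default_factory=frozenset)


def merge_targets(
    per_target: Mapping[str, CloneAssignment],
    min_combo_cells: int = 3,
    exclusivity: float = 0.8,
) -> CloneAssignment:
    """Merge per-target clones across all pairs of targets into one assignment.

    For every unordered target pair, clone-ID combinations supported by at
    least ``min_combo_cells`` cells and passing the exclusivity rule are
    kept; cells assigned on both targets fall into their combination, and
    cells carrying a clone-defining clone-ID on only one of the two targets
    are placed into its combination.  Placements are unioned over all target
    pairs: a cell's merged clone is the canonical set of per-target clone-IDs
    it was placed into; cells given conflicting clone-IDs for the same target
    by different target pairs are dropped and logged.
    """
    targets = sorted(per_target)
    if len(targets) < 2:
        raise ValueError("merging requires assignments on at least two targets")
    assign = {t: per_target[t].as_series() for t in targets}

    # cell -> target -> per-target clone placements accumulated over pairs
    placed: dict[str, dict[str, set[str]]] = defaultdict(lambda: defaultdict(set))
    provenance: dict[str, set[str]] = defaultdict(set)

    for t1, t2 in itertools.combinations(targets, 2):
        a1, a2 = assign[t1], assign[t2]
        both = a1.index.intersection(a2.index)
        combos = Counter(zip(a1.loc[both], a2.loc[both]))
        # combo validity uses totals over the both-assigned cell set (robust
        # to allele dropout on the partner target), but clone-defining status
        # — which licenses placing cells seen on only one target — must hold
        # against *all* of a clone-ID's assignments, otherwise an ID shared
        # with a clone that is invisible on the partner target would wrongly
        # look exclusive and pull that clone into the combination
        tot1 = Counter(a1.loc[both])
        tot2 = Counter(a2.loc[both])
        all1 = a1.value_counts()
        all2 = a2.value_counts()
        kept: list[_Combo] = []
        for (c1, c2), n in combos.items():
            if n < min_combo_cells:
                continue
            frac1 = n / tot1[c1]
            frac2 = n / tot2[c2]
            if max(frac1, frac2) < exclusivity - _FRACTION_EPS:
                continue
            defining = {
                c
                for c, frac in ((c1, n / all1[c1]), (c2, n / all2[c2]))
                if frac >= exclusivity - _FRACTION_EPS
            }
            kept.append(_Combo(c1, c2, int(n), frac1, frac2, frozenset(defining)))

        combo_by_pair = {(c.clone_a, c.clone_b): c for c in kept}
        defining_combos: dict[str, list[_Combo]] = defaultdict(list)
        for c in kept:
            for d in c.defining:
                defining_combos[d].append(c)

        pair_tag = f"{t1}+{t2}"
        for cell in both:
            combo = combo_by_pair.get((a1.loc[cell], a2.loc[cell]))
            if combo is not None:
                placed[cell][t1].add(combo.clone_a)
                placed[cell][t2].add(combo.clone_b)
                provenance[cell].add(pair_tag)
        for cell in a1.index.difference(a2.index):
            cands = defining_combos.get(a1.loc[cell], [])
            if len(cands) == 1 and a1.loc[cell] in cands[0].defining:
                placed[cell][t1].add(cands[0].clone_a)
                placed[cell][t2].add(cands[0].clone_b)
                provenance[cell].add(pair_tag)
        for cell in a2.index.difference(a1.index):
            cands = defining_combos.get(a2.loc[cell], [])
            if len(cands) == 1 and a2.loc[cell] in cands[0].defining:
                placed[cell][t1].add(cands[0].clone_a)
                placed[cell][t2].add(cands[0].clone_b)
                provenance[cell].add(pair_tag)

    # deduplicate multiply-supported cells into one clone per cell: a cell's
    # components (per-target clone-IDs accumulated over target pairs) must be
    # internally consistent, and are matched against the maximal consistent
    # component sets observed, so that cells missing a target (allele
    # dropout) still land in the same clone as their fully-observed clonemates
    dropped = []
    cell_items: dict[str, frozenset[tuple[str, str]]] = {}
    for cell in sorted(placed):
        components = placed[cell]
        if any(len(clones) > 1 for clones in components.values()):
            dropped.append(cell)
            logger.info("cell %s placed into conflicting merged clones; dropped", cell)
            continue
        cell_items[cell] = frozenset((t, next(iter(cs))) for t, cs in components.items())

    # component sets supported by at least min_combo_cells cells are clone
    # "cores".  A cell whose components are a strict subset of a core is
    # ambiguous — allele dropout on its distinguishing targets cannot be told
    # apart from membership in a genuinely silent ancestral lineage — and is
    # dropped, not arbitrated.  A cell whose components are a superset of a
    # core (spurious extras from chimeric observations) shows everything the
    # core requires and joins it when that core is unique.
    label_counts = Counter(cell_items.values())
    cores = {L for L, n in label_counts.items() if n >= min_combo_cells}
    rows = []
    for cell, items in cell_items.items():
        supersets = [C for C in cores if items < C]
        if supersets:
            dropped.append(cell)
            logger.info("cell %s is compatible with several merged clones; dropped", cell)
            continue
        if items in cores:
            resolved = items
        else:
            subsets = [C for C in cores if C < items]
            if subsets:
                maximal_subs = [C for C in subsets if not any(C < D for D in subsets)]
                if len(maximal_subs) != 1:
                    dropped.append(cell)
                    continue
                resolved = maximal_subs[0]
            else:
                resolved = items  # stands alone; keep its own label
        label = ";".join(f"{t}={c}" for t, c in sorted(resolved))
        rows.append((cell, label, ",".join(sorted(provenance[cell]))))
    rows.sort()
    return CloneAssignment(
        level="merged",
        assignments=pd.DataFrame(rows, columns=["cell", "clone", "supporting_target_pairs"]),
        dropped_conflicts=dropped,
    )


@dataclass
class CloneMatrix:
    """Binary cell x clone-defining-ID incidence matrix, clustering-ordered."""

    matrix: pd.DataFrame  # index: cells (clustering order), columns: target-qualified IDs
    linkage: np.ndarray | None
    newick: str | None
    annotations: pd.DataFrame | None = None


def build_clone_matrix(
    merged: CloneAssignment,
    alleles: AlleleTable | pd.DataFrame,
    pairs_by_target: Mapping[str, Sequence[TruePair]],
    annotations: pd.DataFrame | None = None,
) -> CloneMatrix:
    """Binary incidence of clone-defining IDs for merged-assignment cells.

    Rows are cells with a merged clone (hence valid combinations on at least
    two targets), ordered by average-linkage hierarchical clustering on
    Jaccard distance; columns are target-qualified clone-defining
    sequence-IDs grouped by merged clone.  The dendrogram is also exported
    as a newick string.
    """
    df = alleles.retained if isinstance(alleles, AlleleTable) else alleles
    cells = list(merged.assignments["cell"])
    if not cells:
        logger.warning("no cells with merged clone assignments; clone matrix is empty")
        return CloneMatrix(matrix=pd.DataFrame(), linkage=None, newick=None)

    columns = []
    for target in sorted(pairs_by_target):
        for p in pairs_by_target[target]:
            for i in sorted(p.clone_defining):
                col = f"{target}:{i}"
                if col not in columns:
                    columns.append(col)

    pres = df[df["cell"].isin(set(cells))][["cell", "target", "seq_id"]].drop_duplicates()
    key = pres["target"] + ":" + pres["seq_id"]
    incidence = (
        pd.crosstab(pres["cell"], key).reindex(index=cells, columns=columns, fill_value=0)
    )
    incidence = (incidence > 0).astype(np.int8)

    newick = None
    linkage = None
    if len(cells) > 2 and incidence.shape[1] > 0:
        from scipy.cluster.hierarchy import leaves_list, linkage as scipy_linkage
        from scipy.spatial.distance import pdist

        dist = pdist(incidence.to_numpy(dtype=bool), metric="jaccard")
        dist = np.nan_to_num(dist, nan=1.0)  # all-zero rows: maximally distant
        linkage = scipy_linkage(dist, method="average")
        order = leaves_list(linkage)
        incidence = incidence.iloc[order]
        from skbio import TreeNode

        tree = TreeNode.from_linkage_matrix(linkage, cells)
        newick = str(tree).strip()

    # group columns by the merged clone they best mark, for block structure
    clone_of = merged.assignments.set_index("cell")["clone"]
    col_order = sorted(
        incidence.columns,
        key=lambda c: (
            clone_of.loc[incidence.index[incidence[c] > 0]].mode().iloc[0]
            if (incidence[c] > 0).any()
            else "~",
            c,
        ),
    )
    incidence = incidence[col_order]

    ann = None
    if annotations is not None:
        ann = annotations.set_index("cell").reindex(incidence.index)
    return CloneMatrix(matrix=incidence, linkage=linkage, newick=newick, annotations=ann)


@dataclass
class CloneResults:
    """Bundle of every stage of the clone-identification pipeline."""

    pairs_by_target: dict[str, list[TruePair]]
    per_target: dict[str, CloneAssignment]
    merged: CloneAssignment
    matrix: CloneMatrix | None = None


def identify_clones(
    alleles: AlleleTable | pd.DataFrame,
    wildtype_ids: Mapping[str, str],
    targets: Iterable[str] | None = None,
    min_pair_cells: int = 4,
    min_combo_cells: int = 3,
    exclusivity: float = 0.8,
    parent_min_pairs: int = 2,
    annotations: pd.DataFrame | None = None,
    build_matrix: bool = True,
) -> CloneResults:
    """Run the full clone-identification pipeline over all targets."""
    df = alleles.retained if isinstance(alleles, AlleleTable) else alleles
    if targets is None:
        targets = sorted(df["target"].unique())
    targets = list(targets)

    pairs_by_target = {}
    per_target = {}
    for t in targets:
        pairs = find_true_pairs(alleles, t, min_pair_cells=min_pair_cells, exclusivity=exclusivity)
        pairs = derive_clone_defining_ids(
            pairs, wildtype_ids[t], exclusivity=exclusivity, parent_min_pairs=parent_min_pairs
        )
        pairs_by_target[t] = pairs
        per_target[t] = assign_cells_per_target(alleles, t, pairs)

    merged = merge_targets(per_target, min_combo_cells=min_combo_cells, exclusivity=exclusivity)
    matrix = None
    if build_matrix:
        matrix = build_clone_matrix(merged, alleles, pairs_by_target, annotations=annotations)
    return CloneResults(
        pairs_by_target=pairs_by_target, per_target=per_target, merged=merged, matrix=matrix
    )


def clone_recovery_ari(assignment: CloneAssignment, truth_clones: pd.Series) -> float:
    """Adjusted Rand index between an assignment and true clone labels.

    Computed over the assigned cells only (unassigned cells carry no call to
    score).
    """
    from sklearn.metrics import adjusted_rand_score

    assigned = assignment.as_series()
    common = assigned.index.intersection(truth_clones.index)
    if len(common) == 0:
        return float("nan")
    return float(adjusted_rand_score(truth_clones.loc[common], assigned.loc[common]))
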