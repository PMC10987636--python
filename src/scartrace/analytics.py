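"""Small bespoke quantifications around the atlas:

* regional vs. global classification of clusters from dissected-region
  cell counts (a cluster is *regional* when one region contributes at
  least 70% of its cells),
* developmental stage-contribution weighting for adult subtypes
  co-clustered with embryonic/larval cells,
* per-cluster aggregation of RNA-velocity transition probabilities
  (each cell's most likely destination cell, mapped to its cluster),
* bulk SLAM-seq substitution-rate tables with Phred-quality filtering
  (T-to-C conversions report metabolic labeling).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

#: fixed region priority used to break argmax ties
REGION_ORDER = ("telencephalon", "diencephalon", "mesencephalon", "rhombencephalon")

_NUCLEOTIDES = ("A", "C", "G", "T")


def classify_regional_global(
    counts: pd.DataFrame,
    cutoff: float = 0.7,
    region_order: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Classify clusters as regional or global from region cell counts.

    ``counts`` is clusters x regions (non-negative integers from dissected
    samples only).  A cluster is *regional* when its maximum region fraction
    is at least ``cutoff`` (70% or more), otherwise *global*.  Ties for the
    maximum are broken by ``region_order`` (default: telencephalon,
    diencephalon, mesencephalon, rhombencephalon, then input order).

    Returns a DataFrame indexed by cluster with columns
    ``max_fraction, argmax_region, label``.
    """
    if region_order is None:
        region_order = [r for r in REGION_ORDER if r in counts.columns]
        region_order += [c for c in counts.columns if c not in region_order]
    counts = counts[list(region_order)]
    totals = counts.sum(axis=1)
    zero = totals[totals == 0]
    if len(zero):
        raise ValueError(f"cluster {zero.index[0]!r} has zero total cell count")
    fractions = counts.div(totals, axis=0)
    values = fractions.to_numpy()
    argmax = values.argmax(axis=1)  # first max in region-priority order
    max_frac = values[np.arange(len(values)), argmax]
    return pd.DataFrame(
        {
            "max_fraction": max_frac,
            "argmax_region": [region_order[i] for i in argmax],
            "label": np.where(max_frac >= cutoff, "regional", "global"),
        },
        index=counts.index,
    )


def stage_contribution(adult: pd.DataFrame, developmental: pd.DataFrame) -> pd.DataFrame:
    """Developmental-stage contributions per adult subtype, weighted by adult share.

    ``adult`` is a long table ``(cluster, subtype, n_cells)`` giving, per
    joint cluster of the integrated embedding, how many adult cells of each
    subtype co-cluster there; ``developmental`` is ``(cluster, stage,
    n_cells)`` for the embryonic/larval cells.  For subtype s, each joint
    cluster k is weighted by the fraction of s's adult cells found in k
    (e.g. 0.25 if 25% of the adult cells are in that cluster); the weighted
    developmental counts are then normalized to percentages per subtype.

    Returns subtypes x stages percentages (rows sum to 100).
    """
    W = adult.pivot_table(index="subtype", columns="cluster", values="n_cells",
                          aggfunc="sum", fill_value=0).astype(float)
    D = developmental.pivot_table(index="cluster", columns="stage", values="n_cells",
                                  aggfunc="sum", fill_value=0).astype(float)
    adult_totals = W.sum(axis=1)
    zero = adult_totals[adult_totals == 0]
    if len(zero):
        raise ValueError(f"adult subtype {zero.index[0]!r} has zero adult cells")
    W = W.div(adult_totals, axis=0)
    D = D.reindex(W.columns, fill_value=0.0)
    scores = W @ D
    score_totals = scores.sum(axis=1)
    zero = score_totals[score_totals == 0]
    if len(zero):
        raise ValueError(
            f"adult subtype {zero.index[0]!r} co-clusters with no developmental cells"
        )
    return scores.div(score_totals, axis=0) * 100.0


def summarize_transitions(
    P: pd.DataFrame | np.ndarray,
    labels: pd.Series | Sequence[str],
    atol: float = 1e-6,
) -> pd.DataFrame:
    """Per-cluster fractions of most-likely transition destinations.

    ``P`` is a row-stochastic cell x cell transition matrix; ``labels`` maps
    each cell to its cluster.  For each cell the destination cell with the
    maximal transition probability is taken (self-transitions included, ties
    broken by lowest cell index) and mapped to its cluster; per source
    cluster the fractions of member cells per destination cluster are
    returned (rows sum to 1).
    """
    values = P.to_numpy() if isinstance(P, pd.DataFrame) else np.asarray(P, dtype=float)
    if values.ndim != 2 or values.shape[0] != values.shape[1]:
        raise ValueError("transition matrix must be square")
    labels = pd.Series(np.asarray(labels), name="cluster")
    if len(labels) != values.shape[0]:
        raise ValueError("labels must cover all cells")
    row_sums = values.sum(axis=1)
    bad = np.flatnonzero(np.abs(row_sums - 1.0) > atol)
    if len(bad):
        row_id = P.index[bad[0]] if isinstance(P, pd.DataFrame) else bad[0]
        raise ValueError(f"row {row_id!r} of the transition matrix sums to {row_sums[bad[0]]:.6g}, not 1")

    dest = values.argmax(axis=1)  # argmax returns the lowest index on ties
    df = pd.DataFrame({"source": labels.to_numpy(), "dest": labels.to_numpy()[dest]})
    clusters = sorted(labels.unique())
    table = pd.crosstab(df["source"], df["dest"]).reindex(
        index=clusters, columns=clusters, fill_value=0
    )
    return table.div(table.sum(axis=1), axis=0)


def substitution_rates(
    records: pd.DataFrame,
    coverage: Mapping[str, int] | pd.Series,
    min_quality: int = 20,
) -> pd.DataFrame:
    """Per-substitution-type rates from quality-filtered substitution records.

    ``records`` has columns ``ref_base, read_base, quality`` (one row per
    observed substitution); ``coverage`` gives the total number of aligned
    bases per reference nucleotide.  Records below ``min_quality`` (Phred)
    are eliminated; the rate for ref->alt is the count of surviving records
    divided by the aligned coverage of the reference base.  Reference bases
    with zero coverage yield a missing (NaN) rate.

    Returns a 12-row table ``ref_base, read_base, n_substitutions, rate``.
    """
    coverage = pd.Series(coverage, dtype=float)
    records = records.copy()
    bad = (set(records["ref_base"]) | set(records["read_base"])) - set(_NUCLEOTIDES)
    if bad:
        raise ValueError(f"invalid bases in substitution records: {sorted(bad)}")
    if (records["quality"] < 0).any():
        raise ValueError("Phred qualities must be >= 0")
    kept = records[records["quality"] >= min_quality]
    counts = kept.groupby(["ref_base", "read_base"]).size()

    rows = []
    for ref in _NUCLEOTIDES:
        cov = float(coverage.get(ref, 0.0))
        for alt in _NUCLEOTIDES:
            if alt == ref:
                continue
            n = int(counts.get((ref, alt), 0))
            rate = n / cov if cov > 0 else float("nan")
            rows.append((ref, alt, n, rate))
    return pd.DataFrame(rows, columns=["ref_base", "read_base", "n_substitutions", "rate"])


@dataclass
class SlamSimulation:
    """Synthetic bulk SLAM-seq readout with known T-to-C conversion probability."""

    records: pd.DataFrame
    coverage: dict[str, int]
    p_true: float


def simulate_slam_readout(
    n_t_positions: int = 100_000,
    p_conversion: float = 0.02,
    quality: int = 37,
    background_rate: float = 0.0005,
    low_quality_rate: float = 0.002,
    seed: int = 0,
) -> SlamSimulation:
    """Simulate aligned-base substitution records for one 4sU-labeled sample.

    ``n_t_positions`` aligned T bases convert to C with probability
    ``p_conversion`` at high quality; all 12 substitution types additionally
    occur at a small background rate, and some low-quality (< Q20) error
    records are added that a correct pipeline must discard.  Coverage of the
    other reference bases matches the T coverage.
    """
    rng = np.random.default_rng([seed, 7])
    coverage = {b: n_t_positions for b in _NUCLEOTIDES}
    rows = []
    n_tc = rng.binomial(n_t_positions, p_conversion)
    rows += [("T", "C", quality)] * int(n_tc)
    for ref in _NUCLEOTIDES:
        for alt in _NUCLEOTIDES:
            if alt == ref:
                continue
            n_bg = rng.binomial(n_t_positions, background_rate)
            rows += [(ref, alt, quality)] * int(n_bg)
            n_low = rng.binomial(n_t_positions, low_quality_rate)
            rows += [(ref, alt, int(rng.integers(3, 20)))] * int(n_low)
    records = pd.DataFrame(rows, columns=["ref_base", "read_base", "quality"])
    records = records.sample(frac=1.0, random_state=int(rng.integers(2**31))).reset_index(drop=True)
    return SlamSimulation(records=records, coverage=coverage, p_true=p_conversion)
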