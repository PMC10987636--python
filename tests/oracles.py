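"""Independent brute-force reference implementations used as test oracles.

Every function here re-implements a pipeline rule with plain dictionaries
and loops, deliberately sharing no code with the package, so agreement is a
meaningful check.
"""

from collections import Counter
from itertools import combinations

EPS = 1e-12


def oracle_true_pairs(presence, min_pair_cells=4, exclusivity=0.8):
    """Literal per-target true-pair rules.

    ``presence``: dict cell -> set of sequence-IDs on one target.
    Returns dict frozenset({id_a, id_b}) -> (n_cells, {id: frac}).
    """
    # 1. drop IDs detected in exactly one cell
    id_cells = Counter()
    for ids in presence.values():
        for i in ids:
            id_cells[i] += 1
    keep = {i for i, n in id_cells.items() if n > 1}
    pruned = {c: {i for i in ids if i in keep} for c, ids in presence.items()}
    # 2. cells with exactly two distinct IDs
    two_id = {c: ids for c, ids in pruned.items() if len(ids) == 2}
    # 3. count pairs; totals over the same cell set
    pair_n = Counter(frozenset(ids) for ids in two_id.values())
    totals = Counter()
    for ids in two_id.values():
        for i in ids:
            totals[i] += 1
    # 4-5. cutoffs and exclusivity
    out = {}
    for pair, n in pair_n.items():
        if n < min_pair_cells:
            continue
        fracs = {i: n / totals[i] for i in pair}
        if max(fracs.values()) >= exclusivity - EPS:
            out[pair] = (n, fracs)
    return out


def oracle_clone_defining(pairs, wildtype_id, exclusivity=0.8, parent_min_pairs=2):
    """Literal clone-defining rules: exclusive members minus wildtype and parents.

    ``pairs``: output of :func:`oracle_true_pairs`.
    Returns dict pair -> set of clone-defining IDs.
    """
    membership = Counter()
    for pair in pairs:
        for i in pair:
            membership[i] += 1
    parents = {i for i, n in membership.items() if n >= parent_min_pairs}
    out = {}
    for pair, (_n, fracs) in pairs.items():
        out[pair] = {
            i for i, f in fracs.items()
            if f >= exclusivity - EPS and i != wildtype_id and i not in parents
        }
    return out


def oracle_merge(per_target, min_combo_cells=3, exclusivity=0.8):
    """Literal pairwise multi-target merge.

    ``per_target``: dict target -> dict cell -> per-target clone label.
    Returns (dict cell -> merged clone label, list of dropped cells).
    """
    targets = sorted(per_target)
    placed = {}   # cell -> target -> set of clone labels
    for t1, t2 in combinations(targets, 2):
        a1, a2 = per_target[t1], per_target[t2]
        both = sorted(set(a1) & set(a2))
        combo_n = Counter((a1[c], a2[c]) for c in both)
        tot1 = Counter(a1[c] for c in both)
        tot2 = Counter(a2[c] for c in both)
        all1 = Counter(a1.values())
        all2 = Counter(a2.values())
        kept = {}
        for (c1, c2), n in combo_n.items():
            if n < min_combo_cells:
                continue
            if max(n / tot1[c1], n / tot2[c2]) < exclusivity - EPS:
                continue
            defining = set()
            if n / all1[c1] >= exclusivity - EPS:
                defining.add(c1)
            if n / all2[c2] >= exclusivity - EPS:
                defining.add(c2)
            kept[(c1, c2)] = defining
        def_combos = {}
        for combo, defining in kept.items():
            for d in defining:
                def_combos.setdefault(d, []).append(combo)
        for cell in both:
            combo = (a1[cell], a2[cell])
            if combo in kept:
                placed.setdefault(cell, {}).setdefault(t1, set()).add(combo[0])
                placed[cell].setdefault(t2, set()).add(combo[1])
        for cell in sorted(set(a1) - set(a2)):
            cands = def_combos.get(a1[cell], [])
            if len(cands) == 1:
                placed.setdefault(cell, {}).setdefault(t1, set()).add(cands[0][0])
                placed[cell].setdefault(t2, set()).add(cands[0][1])
        for cell in sorted(set(a2) - set(a1)):
            cands = def_combos.get(a2[cell], [])
            if len(cands) == 1:
                placed.setdefault(cell, {}).setdefault(t1, set()).add(cands[0][0])
                placed[cell].setdefault(t2, set()).add(cands[0][1])

    dropped = []
    items_of = {}
    for cell, comp in placed.items():
        if any(len(v) > 1 for v in comp.values()):
            dropped.append(cell)
            continue
        items_of[cell] = frozenset((t, next(iter(v))) for t, v in comp.items())
    counts = Counter(items_of.values())
    cores = {L for L, n in counts.items() if n >= min_combo_cells}
    assigned = {}
    for cell, items in items_of.items():
        supersets = [C for C in cores if items < C]
        if supersets:
            dropped.append(cell)
            continue
        if items in cores:
            resolved = items
        else:
            subsets = [C for C in cores if C < items]
            if subsets:
                maximal = [C for C in subsets if not any(C < D for D in subsets)]
                if len(maximal) != 1:
                    dropped.append(cell)
                    continue
                resolved = maximal[0]
            else:
                resolved = items
        assigned[cell] = ";".join(f"{t}={c}" for t, c in sorted(resolved))
    return assigned, dropped


def oracle_filter_prefix(counts, top_fraction=0.8):
    """Minimal count-descending prefix reaching the top fraction of UMIs.

    ``counts``: dict seq_id -> umi_count for one (cell, target).
    Returns the list of retained IDs.
    """
    order = sorted(counts, key=lambda i: (-counts[i], i))
    total = sum(counts.values())
    kept, cum = [], 0
    for i in order:
        if cum >= top_fraction * total - 1e-9:
            break
        kept.append(i)
        cum += counts[i]
    return kept


def oracle_transition_summary(P, labels):
    """Naive per-cell loop for transition aggregation."""
    n = len(labels)
    clusters = sorted(set(labels))
    counts = {s: Counter() for s in clusters}
    for i in range(n):
        best, best_p = 0, P[i][0]
        for j in range(1, n):
            if P[i][j] > best_p:
                best, best_p = j, P[i][j]
        counts[labels[i]][labels[best]] += 1
    out = {}
    for s in clusters:
        tot = sum(counts[s].values())
        out[s] = {d: counts[s][d] / tot for d in clusters}
    return out


def oracle_stage_contribution(adult_rows, dev_rows):
    """Matrix-free stage weighting: explicit loops over clusters.

    ``adult_rows``: list of (cluster, subtype, n); ``dev_rows``: (cluster, stage, n).
    Returns dict subtype -> dict stage -> percentage.
    """
    adult = {}
    for cluster, subtype, n in adult_rows:
        adult.setdefault(subtype, Counter())[cluster] += n
    dev = {}
    for cluster, stage, n in dev_rows:
        dev.setdefault(cluster, Counter())[stage] += n
    stages = sorted({s for c in dev.values() for s in c})
    out = {}
    for subtype, clusters in adult.items():
        total_adult = sum(clusters.values())
        scores = Counter()
        for cluster, n in clusters.items():
            w = n / total_adult
            for stage, d in dev.get(cluster, {}).items():
                scores[stage] += w * d
        tot = sum(scores.values())
        out[subtype] = {s: 100.0 * scores[s] / tot for s in stages}
    return out
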