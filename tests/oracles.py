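"""Independent brute-force reference implementations used as test oracles.

Everything here is written as plain loops over definitions, deliberately
sharing no code with the package.
"""

import math
from itertools import combinations

import numpy as np


def pearson_loop(x, y):
    n = len(x)
    mx = sum(x) / n
    my = sum(y) / n
    sxy = sum((a - mx) * (b - my) for a, b in zip(x, y))
    sxx = sum((a - mx) ** 2 for a in x)
    syy = sum((b - my) ** 2 for b in y)
    return sxy / math.sqrt(sxx * syy)


def fisher_z_loop(r, clamp=1.0 - 1e-7):
    r = max(min(r, clamp), -clamp)
    return 0.5 * math.log((1 + r) / (1 - r))


def average_ranks_loop(x):
    order = sorted(range(len(x)), key=lambda i: x[i])
    ranks = [0.0] * len(x)
    i = 0
    while i < len(order):
        j = i
        while j + 1 < len(order) and x[order[j + 1]] == x[order[i]]:
            j += 1
        avg = (i + j) / 2 + 1
        for k in range(i, j + 1):
            ranks[order[k]] = avg
        i = j + 1
    return ranks


def spearman_loop(x, y):
    return pearson_loop(average_ranks_loop(list(x)), average_ranks_loop(list(y)))


def cross_corr_z_loop(A, B):
    """z-matrix between rows of A and rows of B, per definition."""
    out = np.empty((len(A), len(B)))
    for i, a in enumerate(A):
        for j, b in enumerate(B):
            out[i, j] = fisher_z_loop(pearson_loop(list(a), list(b)))
    return out


def pairmate_score_loop(Z, scenes_a, scenes_b, s1, s2):
    """Exhaustive enumeration of the 2 pairmate + 2*2*(n-2) baseline entries."""
    ia = {s: i for i, s in enumerate(scenes_a)}
    ib = {s: i for i, s in enumerate(scenes_b)}
    pair_entries = [Z[ia[s1], ib[s2]], Z[ia[s2], ib[s1]]]
    baseline = []
    for s in (s1, s2):
        for t in scenes_b:
            if t not in (s1, s2):
                baseline.append(Z[ia[s], ib[t]])
    for t in scenes_a:
        if t not in (s1, s2):
            for s in (s1, s2):
                baseline.append(Z[ia[t], ib[s]])
    pair = sum(pair_entries) / len(pair_entries)
    non = sum(baseline) / len(baseline)
    return pair, non, pair - non


def learned_round_loop(flags):
    """Smallest k with flags[k-1:] all True, testing every k; None if none."""
    n = len(flags)
    for k in range(1, n + 1):
        if all(flags[k - 1:]):
            return k
    return None


def scene_object_loop(scene_mats, object_mat, catalog, lr_of_pair):
    """Brute-force target/competitor/baseline scene-object scores.

    ``scene_mats``: {round: {scene_id: vector}}; ``object_mat``:
    {object_id: vector} (already averaged over object rounds).
    Returns {(pair, state, relevance): value}.
    """
    out = {}
    for k, lr in lr_of_pair.items():
        if lr is None or lr < 2:
            continue
        s1, s2 = catalog.scenes_of_pair(k)
        for state, rnd in (("pre-learned", lr - 1), ("learned", lr)):
            vals = {"target": 0.0, "competitor": 0.0}
            for s in (s1, s2):
                srow = scene_mats[rnd][s]
                zs = {o: fisher_z_loop(pearson_loop(list(srow), list(v)))
                      for o, v in object_mat.items()}
                t_obj = catalog.assoc_object[s]
                c_obj = catalog.competitor_object(s)
                base = [z for o, z in zs.items() if o not in (t_obj, c_obj)]
                base_mean = sum(base) / len(base)
                vals["target"] += 0.5 * (zs[t_obj] - base_mean)
                vals["competitor"] += 0.5 * (zs[c_obj] - base_mean)
            for relevance, v in vals.items():
                out[(k, state, relevance)] = v
    return out


def rm_anova_loop(Y, factor_names):
    """Classical within-subject ANOVA by explicit marginal-mean loops.

    ``Y``: ndarray (n_subj, l1[, l2[, l3]]).  Returns
    {effect: (F, df1, df2, eta2)} with classical eta^2 = SS/SS_total.
    """
    shape = Y.shape
    axes = list(range(Y.ndim))
    grand = Y.mean()
    ss_total = float(((Y - grand) ** 2).sum())

    def marginal_effect(subset, cache={}):
        # inclusion-exclusion over marginal means, computed per index tuple
        pass

    # effect arrays by explicit inclusion-exclusion
    effects = {(): np.array(grand)}
    ss = {}
    dfs = {}
    for size in range(1, Y.ndim + 1):
        for subset in combinations(axes, size):
            other = tuple(ax for ax in axes if ax not in subset)
            m = Y.mean(axis=other, keepdims=True)
            e = m - grand
            for sub in effects:
                if sub and set(sub) < set(subset):
                    e = e - effects[sub]
            effects[subset] = e
            mult = 1
            for ax in other:
                mult *= shape[ax]
            ss[subset] = float((e ** 2).sum()) * mult
            d = 1.0
            for ax in subset:
                d *= shape[ax] - 1
            dfs[subset] = d
    out = {}
    from scipy.stats import f as fdist
    for size in range(1, Y.ndim):
        for subset in combinations(range(1, Y.ndim), size):
            err = tuple(sorted((0,) + subset))
            if ss[err] == 0:
                F = 0.0
            else:
                F = (ss[subset] / dfs[subset]) / (ss[err] / dfs[err])
            name = "*".join(factor_names[ax - 1] for ax in subset)
            out[name] = (F, dfs[subset], dfs[err],
                         ss[subset] / ss_total if ss_total else 0.0,
                         float(fdist.sf(F, dfs[subset], dfs[err])))
    return out
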