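"""Independent brute-force reference implementations.

Everything here is written with plain Python loops and the direct textbook
formulas, deliberately sharing no code with the package, so the package's
vectorized/caching implementations can be checked against them.
"""

import itertools
import math
import statistics

from scipy import special
from scipy import stats as sps


# ---------------------------------------------------------------- cleavage
def _student_t_p(a, b):
    n1, n2 = len(a), len(b)
    ma = sum(a) / n1
    mb = sum(b) / n2
    df = n1 + n2 - 2
    if df <= 0:
        return 1.0
    ssa = sum((x - ma) ** 2 for x in a)
    ssb = sum((x - mb) ** 2 for x in b)
    sp2 = (ssa + ssb) / df
    if sp2 <= 0:
        return 1.0 if ma == mb else 0.0
    t = (ma - mb) / math.sqrt(sp2 * (1 / n1 + 1 / n2))
    return 2 * sps.t.sf(abs(t), df)


def _sign(x):
    return (x > 0) - (x < 0)


def brute_force_calls(peptides, b_start=0.05, b_end=0.95, b_step=0.01,
                      alpha=0.05, fc_min=1.5, min_sig=2, min_count=2):
    """Direct-loop substrate calling for one protein.

    peptides: list of (midpoint_frac, log2fc, p). Returns None or a dict
    with boundary, side, direction, n_sig, factor, p_sep, n_block, n_rest.
    """
    lfc_min = math.log2(fc_min)
    n_bounds = int(round((b_end - b_start) / b_step)) + 1
    best = None
    for i in range(n_bounds):
        b = round(b_start + i * b_step, 10)
        block = [pep for pep in peptides if pep[0] <= b]
        rest = [pep for pep in peptides if pep[0] > b]
        if len(block) < min_count or len(rest) < min_count:
            continue
        lfc_block = [pep[1] for pep in block]
        lfc_rest = [pep[1] for pep in rest]
        med_b = statistics.median(lfc_block)
        med_r = statistics.median(lfc_rest)
        abs_b = statistics.median([abs(x) for x in lfc_block])
        abs_r = statistics.median([abs(x) for x in lfc_rest])
        factor = med_b - med_r
        p_sep = _student_t_p(lfc_block, lfc_rest)
        if abs_b >= abs_r:
            changed, changed_med, unchanged_abs, side = (
                block, med_b, abs_r, "N_side")
        else:
            changed, changed_med, unchanged_abs, side = (
                rest, med_r, abs_b, "C_side")
        n_sig = sum(
            1 for pep in changed
            if pep[2] < alpha and abs(pep[1]) >= lfc_min
            and _sign(pep[1]) == _sign(changed_med)
        )
        ok = (
            n_sig >= min_sig
            and abs(factor) >= lfc_min
            and p_sep < alpha
            and unchanged_abs < lfc_min
        )
        if ok and (best is None or p_sep < best["p_sep"]):
            best = {
                "boundary": b,
                "side": side,
                "direction": ("reduced_in_case" if changed_med < 0
                              else "increased_in_case"),
                "n_sig": n_sig,
                "factor": factor,
                "p_sep": p_sep,
                "n_block": len(block),
                "n_rest": len(rest),
            }
    return best


# ------------------------------------------------------- multiple testing
def brute_force_bh(pvalues):
    """Step-up BH: p_(i) * m / i, monotonized from the largest rank down."""
    m = len(pvalues)
    order = sorted(range(m), key=lambda i: pvalues[i])
    adjusted = [0.0] * m
    running_min = 1.0
    for rank_from_top in range(m, 0, -1):
        i = order[rank_from_top - 1]
        value = pvalues[i] * m / rank_from_top
        running_min = min(running_min, value)
        adjusted[i] = min(running_min, 1.0)
    return adjusted


# ------------------------------------------------------------ moderated t
def brute_force_moderated_t(case_rows, ctrl_rows, prior_df=None):
    """Loop implementation of the shrunken-variance two-group t.

    case_rows/ctrl_rows: lists of per-protein value lists (no missing).
    Returns list of (logfc, t, p) plus (d0, s0_sq).
    """
    s2_list, df_list, logfc_list, n_pairs = [], [], [], []
    for a, b in zip(case_rows, ctrl_rows):
        n1, n2 = len(a), len(b)
        ma, mb = sum(a) / n1, sum(b) / n2
        ssa = sum((x - ma) ** 2 for x in a)
        ssb = sum((x - mb) ** 2 for x in b)
        df = n1 + n2 - 2
        s2_list.append((ssa + ssb) / df)
        df_list.append(df)
        logfc_list.append(ma - mb)
        n_pairs.append((n1, n2))

    if prior_df is None:
        es = [
            math.log(s2) - special.digamma(df / 2) + math.log(df / 2)
            for s2, df in zip(s2_list, df_list) if s2 > 0
        ]
        e_mean = sum(es) / len(es)
        e_var = sum((e - e_mean) ** 2 for e in es) / (len(es) - 1)
        mean_tri = sum(
            special.polygamma(1, df / 2)
            for s2, df in zip(s2_list, df_list) if s2 > 0
        ) / len(es)
        excess = e_var - mean_tri
        if excess <= 0:
            d0 = math.inf
            s0_sq = math.exp(e_mean)
        else:
            # bisection solve trigamma(d0/2) = excess
            lo, hi = 1e-8, 1e8
            for _ in range(200):
                mid = math.sqrt(lo * hi)
                if special.polygamma(1, mid) > excess:
                    lo = mid
                else:
                    hi = mid
            d0 = 2 * math.sqrt(lo * hi)
            s0_sq = math.exp(
                e_mean + special.digamma(d0 / 2) - math.log(d0 / 2)
            )
    else:
        d0 = prior_df
        s0_sq = None

    results = []
    for s2, df, logfc, (n1, n2) in zip(s2_list, df_list, logfc_list, n_pairs):
        if d0 == 0:
            s2_post, df_tot = s2, df
        elif math.isinf(d0):
            s2_post, df_tot = s0_sq, math.inf
        else:
            s2_post = (d0 * s0_sq + df * s2) / (d0 + df)
            df_tot = d0 + df
        se = math.sqrt(s2_post * (1 / n1 + 1 / n2))
        t = logfc / se
        if math.isinf(df_tot):
            p = 2 * sps.norm.sf(abs(t))
        else:
            p = 2 * sps.t.sf(abs(t), df_tot)
        results.append((logfc, t, p))
    return results, (d0, s0_sq)


# ------------------------------------------------- average-linkage merges
def brute_force_average_linkage(dist):
    """Naive agglomeration; returns the cophenetic distance matrix.

    dist: full symmetric matrix (list of lists or ndarray). Average
    linkage: the distance between clusters is the mean of all pairwise
    original distances between their members.
    """
    n = len(dist)
    clusters = [[i] for i in range(n)]
    coph = [[0.0] * n for _ in range(n)]
    while len(clusters) > 1:
        best = None
        for i, j in itertools.combinations(range(len(clusters)), 2):
            d = sum(
                dist[a][b] for a in clusters[i] for b in clusters[j]
            ) / (len(clusters[i]) * len(clusters[j]))
            if best is None or d < best[0]:
                best = (d, i, j)
        d, i, j = best
        for a in clusters[i]:
            for b in clusters[j]:
                coph[a][b] = coph[b][a] = d
        clusters[i] = clusters[i] + clusters[j]
        del clusters[j]
    return coph


def brute_force_cut(dist, k):
    """Partition from naive average-linkage agglomeration stopped at k
    clusters; returns a set of frozensets."""
    n = len(dist)
    clusters = [[i] for i in range(n)]
    while len(clusters) > k:
        best = None
        for i, j in itertools.combinations(range(len(clusters)), 2):
            d = sum(
                dist[a][b] for a in clusters[i] for b in clusters[j]
            ) / (len(clusters[i]) * len(clusters[j]))
            if best is None or d < best[0]:
                best = (d, i, j)
        _, i, j = best
        clusters[i] = clusters[i] + clusters[j]
        del clusters[j]
    return {frozenset(c) for c in clusters}
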