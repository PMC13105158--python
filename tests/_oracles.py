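"""Independent brute-force oracles used to validate the fast paths.

Each function here is deliberately written as a naive loop from the
definition of the quantity, sharing no code with the package.
"""

from __future__ import annotations

import numpy as np


def edge_perturbation_loop(values, ref_means, edges):
    """Naive per-sample, per-edge perturbation from raw expression.

    ``values``: dict gene -> list of per-sample expression values;
    ``ref_means``: dict gene -> reference mean; ``edges``: list of
    (gene_a, gene_b).  Returns {edge: [p per sample]}.
    """
    genes = sorted(values)
    n_samples = len(next(iter(values.values())))

    def avg_rank(vector: dict[str, float]) -> dict[str, float]:
        ranks = {}
        for g in genes:
            less = sum(1 for h in genes if vector[h] < vector[g])
            equal = sum(1 for h in genes if vector[h] == vector[g])
            ranks[g] = less + (equal + 1) / 2.0
        return ranks

    # reference ranks: strict ordering by (mean, gene id)
    order = sorted(genes, key=lambda g: (ref_means[g], g))
    ref_rank = {g: i + 1.0 for i, g in enumerate(order)}

    out = {}
    for a, b in edges:
        ps = []
        for s in range(n_samples):
            vec = {g: values[g][s] for g in genes}
            r = avg_rank(vec)
            d_s = r[a] - r[b]
            d_ref = ref_rank[a] - ref_rank[b]
            ps.append(d_s - d_ref)
        out[(a, b)] = ps
    return out


def harrell_c_pairs(scores, time, event):
    """O(n^2) concordance by explicit pair enumeration."""
    n = len(scores)
    concordant = discordant = tied = 0
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            if time[i] < time[j] and event[i] == 1:
                if scores[i] > scores[j]:
                    concordant += 1
                elif scores[i] < scores[j]:
                    discordant += 1
                else:
                    tied += 1
    usable = concordant + discordant + tied
    return (concordant + 0.5 * tied) / usable


def logrank_risk_table(time, event, group):
    """k-group log-rank chi-square via an explicit risk-table loop.

    Observed-minus-expected per group with the hypergeometric
    covariance, inverting the covariance of the first k-1 groups.
    """
    time = np.asarray(time, dtype=float)
    event = np.asarray(event)
    group = np.asarray(group)
    labels = sorted(set(group.tolist()))
    k = len(labels)
    OE = np.zeros(k)
    V = np.zeros((k, k))
    for t in sorted(set(time[event == 1].tolist())):
        at_risk = time >= t
        n = at_risk.sum()
        d = ((time == t) & (event == 1)).sum()
        if n <= 1:
            continue
        for gi, g in enumerate(labels):
            n_g = (at_risk & (group == g)).sum()
            d_g = ((time == t) & (event == 1) & (group == g)).sum()
            OE[gi] += d_g - d * n_g / n
            for hi, h in enumerate(labels):
                n_h = (at_risk & (group == h)).sum()
                delta = 1.0 if g == h else 0.0
                V[gi, hi] += (
                    d * (n_g / n) * (delta - n_h / n) * (n - d) / (n - 1)
                )
    sub = slice(0, k - 1)
    return float(OE[sub] @ np.linalg.solve(V[sub, sub], OE[sub]))


def bh_sort_cummin(p):
    """Benjamini-Hochberg by sort then cumulative minimum of p*m/rank."""
    p = np.asarray(p, dtype=float)
    m = len(p)
    order = np.argsort(p, kind="stable")
    adj_sorted = p[order] * m / np.arange(1, m + 1)
    for i in range(m - 2, -1, -1):
        adj_sorted[i] = min(adj_sorted[i], adj_sorted[i + 1])
    adj = np.empty(m)
    adj[order] = np.minimum(adj_sorted, 1.0)
    return adj


def ssgsea_walk(values, genes, member_genes, alpha):
    """ssGSEA score of one sample by an explicit walk over the list.

    ``values``: per-gene expression (same order as ``genes``).
    """
    values = list(values)
    n = len(genes)
    # average ties, ascending with expression
    ranks = []
    for i in range(n):
        less = sum(1 for v in values if v < values[i])
        equal = sum(1 for v in values if v == values[i])
        ranks.append(less + (equal + 1) / 2.0)
    order = sorted(range(n), key=lambda i: (-values[i], genes[i]))
    member = set(member_genes)
    total_in = 0.0
    for i in order:
        if genes[i] in member:
            total_in += abs(ranks[i]) ** alpha
    n_out = sum(1 for g in genes if g not in member)
    score = 0.0
    run_in = 0.0
    run_out = 0.0
    for i in order:
        if genes[i] in member:
            run_in += abs(ranks[i]) ** alpha
        else:
            run_out += 1.0
        p_in = run_in / total_in
        p_out = run_out / n_out if n_out else 0.0
        score += p_in - p_out
    return score


def td_auc_weighted_pairs(scores, time, event, tau):
    """Cumulative-dynamic AUC by explicit weighted pair counting.

    Case weights are 1/G(t-) with G the Kaplan-Meier estimator of the
    censoring distribution evaluated just before the case's time.
    """
    time = np.asarray(time, dtype=float)
    event = np.asarray(event)
    scores = np.asarray(scores, dtype=float)

    def g_minus(t):
        prod = 1.0
        for u in sorted(set(time.tolist())):
            if u >= t:
                break
            n_at = (time >= u).sum()
            c_at = ((time == u) & (event == 0)).sum()
            prod *= 1.0 - c_at / n_at
        return prod

    cases = [i for i in range(len(time)) if time[i] <= tau and event[i] == 1]
    controls = [j for j in range(len(time)) if time[j] > tau]
    if not cases or not controls:
        return float("nan")
    num = 0.0
    wsum = 0.0
    for i in cases:
        w = 1.0 / g_minus(time[i])
        wsum += w
        for j in controls:
            if scores[i] > scores[j]:
                num += w
            elif scores[i] == scores[j]:
                num += 0.5 * w
    return num / (wsum * len(controls))
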