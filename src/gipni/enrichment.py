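"""Single-sample gene-set enrichment and score association.

The ssGSEA score of a set in a sample is the integral of the
difference between a rank-weighted empirical distribution of the
in-set genes and the unweighted distribution of the out-of-set genes,
walked down the sample's expression-ranked gene list.  Because the
statistic depends on expression only through within-sample ranks, it
is invariant to any monotone per-sample transform.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .io import ExpressionMatrix, GeneSetCollection

logger = logging.getLogger(__name__)


@dataclass
class SsgseaScores:
    """Sets x samples enrichment score matrix."""

    scores: pd.DataFrame
    normalized: bool
    alpha: float


def _sample_walk_order(values: np.ndarray, genes: np.ndarray) -> np.ndarray:
    """Indices ordering genes by decreasing expression, gene id as tie-break.

    The deterministic tie-break makes scores invariant to gene storage
    order.
    """
    return np.lexsort((genes, -values))


def ssgsea(
    expr: ExpressionMatrix,
    sets: GeneSetCollection,
    alpha: float = 0.25,
    normalize: bool = True,
) -> SsgseaScores:
    """Single-sample gene-set enrichment scores.

    Per sample, genes get average-tie ranks ascending with expression;
    walking the genes in decreasing-expression order, the score is the
    running sum of (in-set weighted ECDF - out-set ECDF) where in-set
    steps are weighted by ``rank ** alpha``.  With ``normalize=True``
    the score matrix is min-max scaled globally to [0, 1].

    Sets with fewer than 2 genes present in the matrix are skipped
    (logged); absent genes are dropped per set.
    """
    genes = np.asarray(expr.gene_ids)
    gene_pos = {g: i for i, g in enumerate(genes)}
    memberships: dict[str, np.ndarray] = {}
    for name, members in sets.sets.items():
        present = [g for g in dict.fromkeys(members) if g in gene_pos]
        if len(present) < len(set(members)):
            logger.warning(
                "set %s: %d genes absent from the matrix",
                name,
                len(set(members)) - len(present),
            )
        if len(present) < 2:
            logger.warning("set %s has < 2 genes present; skipped", name)
            continue
        mask = np.zeros(len(genes), dtype=bool)
        mask[[gene_pos[g] for g in present]] = True
        memberships[name] = mask
    if not memberships:
        raise ValueError("no gene set has at least 2 genes in the matrix")

    vals = expr.values.to_numpy(dtype=float)
    n_genes, n_samples = vals.shape
    out = np.zeros((len(memberships), n_samples))
    set_names = list(memberships)
    for s in range(n_samples):
        col = vals[:, s]
        ranks = stats.rankdata(col)  # ascending with expression, average ties
        order = _sample_walk_order(col, genes)
        r_sorted = ranks[order]
        weights = np.abs(r_sorted) ** alpha
        for k, name in enumerate(set_names):
            in_set = memberships[name][order]
            w_in = np.where(in_set, weights, 0.0)
            total_in = np.cumsum(w_in)[-1]
            n_out = n_genes - int(in_set.sum())
            if n_out == 0:
                # degenerate set covering every gene: both ECDFs walk
                # together, score contribution is the in-set integral only
                p_out = np.zeros(n_genes)
            else:
                p_out = np.cumsum(np.where(in_set, 0.0, 1.0)) / n_out
            p_in = np.cumsum(w_in) / total_in
            out[k, s] = np.cumsum(p_in - p_out)[-1]
    scores = pd.DataFrame(out, index=set_names, columns=expr.sample_ids)
    if normalize:
        lo, hi = out.min(), out.max()
        if hi > lo:
            scores = (scores - lo) / (hi - lo)
        else:
            scores = scores * 0.0
    return SsgseaScores(scores=scores, normalized=normalize, alpha=alpha)


def associate_scores(scores: SsgseaScores, index_scores: pd.Series) -> pd.DataFrame:
    """Spearman association of each set's scores with a per-sample index.

    Returns a per-set table with tie-corrected Spearman ``rho``, ``p``
    and BH ``q``; sets with a constant score vector have an undefined
    correlation and are reported as missing (excluded from the BH
    family).
    """
    shared = scores.scores.columns.intersection(index_scores.index)
    if len(shared) < 5:
        raise ValueError("association needs at least 5 shared samples")
    idx = index_scores.loc[shared].to_numpy(dtype=float)
    rows = []
    for name, row in scores.scores[shared].iterrows():
        vec = row.to_numpy(dtype=float)
        if np.unique(vec).size == 1 or np.unique(idx).size == 1:
            rows.append({"set": name, "rho": np.nan, "p": np.nan})
            continue
        rho, p = stats.spearmanr(vec, idx)
        rows.append({"set": name, "rho": float(rho), "p": float(p)})
    table = pd.DataFrame(rows).set_index("set")
    defined = table["p"].notna()
    q = pd.Series(np.nan, index=table.index)
    if defined.any():
        q.loc[defined] = multipletests(table.loc[defined, "p"], method="fdr_bh")[1]
    table["q"] = q
    return table


def group_compare(
    score_row: pd.Series, groups: pd.Series
) -> tuple[float, str]:
    """Two-sided rank-sum comparison of one set's scores between groups.

    ``groups`` maps samples to ``"high"``/``"low"``; returns the
    p-value and the direction (``"up"`` when the high group's median is
    larger).
    """
    shared = score_row.index.intersection(groups.index)
    g = groups.loc[shared]
    hi = score_row.loc[shared[g == "high"]].to_numpy(dtype=float)
    lo = score_row.loc[shared[g == "low"]].to_numpy(dtype=float)
    if len(hi) < 3 or len(lo) < 3:
        raise ValueError("both groups need at least 3 samples")
    p = float(stats.mannwhitneyu(hi, lo, alternative="two-sided").pvalue)
    direction = "up" if np.median(hi) > np.median(lo) else "down"
    return p, direction
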