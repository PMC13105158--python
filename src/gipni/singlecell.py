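"""Single-cell QC filtering and malignant-vs-benign differential expression.

Clustering, embedding and malignancy calling are consumed as labels
(from cell metadata); this module covers the downstream, reproducible
steps: QC filtering with the standard feature/count/mitochondrial
bounds, library-size log-normalization, rank-sum differential
expression at single-cell and bulk level, and the direction-concordant
intersection that yields the dysregulated-gene list feeding the
interaction network.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .io import NORMAL, TUMOR, ExpressionMatrix

LOG2FC_PSEUDOCOUNT = 1e-9


@dataclass(frozen=True)
class QCThresholds:
    """Per-cell quality bounds; all bounds are inclusive.

    Defaults are the conventional droplet-QC values: 200-6000 detected
    genes, 500-40000 total counts, and at most 20% mitochondrial
    counts (genes identified by ``mito_prefix``).
    """

    min_features: int = 200
    max_features: int = 6000
    min_counts: int = 500
    max_counts: int = 40000
    max_percent_mt: float = 20.0
    mito_prefix: str = "MT-"

    def __post_init__(self) -> None:
        if self.min_features >= self.max_features:
            raise ValueError("min_features must be < max_features")
        if self.min_counts >= self.max_counts:
            raise ValueError("min_counts must be < max_counts")
        if not 0.0 <= self.max_percent_mt <= 100.0:
            raise ValueError("max_percent_mt must lie in [0, 100]")


def qc_filter(
    counts: pd.DataFrame, thresholds: QCThresholds = QCThresholds()
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Filter low-quality cells from a cells x genes count table.

    A cell is kept when its detected-gene count, total count and
    mitochondrial percentage all lie within the (inclusive) bounds.
    Returns the filtered table and a per-cell report with the QC
    metrics, a ``kept`` flag and semicolon-joined failure ``reasons``.
    """
    if (counts.to_numpy() < 0).any():
        raise ValueError("counts must be nonnegative")
    n_features = (counts > 0).sum(axis=1)
    total = counts.sum(axis=1)
    mito_cols = [c for c in counts.columns if c.startswith(thresholds.mito_prefix)]
    mito_total = counts[mito_cols].sum(axis=1) if mito_cols else pd.Series(0, index=counts.index)
    with np.errstate(invalid="ignore"):
        pct_mt = np.where(total > 0, 100.0 * mito_total / total, 0.0)
    pct_mt = pd.Series(pct_mt, index=counts.index)

    checks = {
        "min_features": n_features >= thresholds.min_features,
        "max_features": n_features <= thresholds.max_features,
        "min_counts": total >= thresholds.min_counts,
        "max_counts": total <= thresholds.max_counts,
        "max_percent_mt": pct_mt <= thresholds.max_percent_mt,
    }
    kept = pd.Series(True, index=counts.index)
    for ok in checks.values():
        kept &= ok
    reasons = pd.Series(
        [
            ";".join(name for name, ok in checks.items() if not ok.loc[cell])
            for cell in counts.index
        ],
        index=counts.index,
    )
    report = pd.DataFrame(
        {
            "n_features": n_features,
            "total_counts": total,
            "percent_mt": pct_mt,
            "kept": kept,
            "reasons": reasons,
        }
    )
    filtered = counts.loc[kept]
    if filtered.empty:
        raise ValueError("no cells pass QC filtering")
    return filtered, report


def normalize_log(counts: pd.DataFrame, target_sum: float = 1e4) -> pd.DataFrame:
    """Library-size normalize each cell to ``target_sum``, then log1p."""
    total = counts.sum(axis=1)
    if (total == 0).any():
        bad = total.index[total == 0][0]
        raise ValueError(f"cell {bad!r} has zero total counts")
    scaled = counts.div(total, axis=0) * target_sum
    return np.log1p(scaled)


def _bh(p: np.ndarray) -> np.ndarray:
    return multipletests(p, method="fdr_bh")[1]


def _rank_sum_table(
    a: np.ndarray, b: np.ndarray, gene_ids: pd.Index, log2fc: np.ndarray
) -> pd.DataFrame:
    """Per-gene two-sided rank-sum p-values with BH adjustment."""
    res = stats.mannwhitneyu(a, b, axis=0, alternative="two-sided")
    p = np.asarray(res.pvalue, dtype=float)
    q = _bh(p)
    return pd.DataFrame(
        {
            "log2fc": log2fc,
            "p": p,
            "q": q,
            "direction": np.where(log2fc > 0, "up", "down"),
        },
        index=gene_ids,
    )


def wilcoxon_de(
    expr: pd.DataFrame,
    group_a_cells: list[str],
    group_b_cells: list[str],
    lfc_threshold: float = 0.25,
    q_threshold: float = 0.05,
) -> pd.DataFrame:
    """Rank-sum differential expression between two cell groups.

    ``expr`` is a cells x genes log-normalized table.  The fold change
    compares de-logged group means:
    ``log2((mean expm1 a + pc) / (mean expm1 b + pc))`` with pseudocount
    ``pc = 1e-9``.  BH adjustment runs across all tested genes; only
    genes with ``|log2fc| > lfc_threshold`` and ``q < q_threshold`` are
    returned (direction ``up`` means higher in group a).
    """
    set_a, set_b = set(group_a_cells), set(group_b_cells)
    if set_a & set_b:
        raise ValueError("cell groups must be disjoint")
    if len(set_a) < 3 or len(set_b) < 3:
        raise ValueError("each cell group needs at least 3 cells")
    a = expr.loc[group_a_cells].to_numpy(dtype=float)
    b = expr.loc[group_b_cells].to_numpy(dtype=float)
    mean_a = np.expm1(a).mean(axis=0)
    mean_b = np.expm1(b).mean(axis=0)
    log2fc = np.log2((mean_a + LOG2FC_PSEUDOCOUNT) / (mean_b + LOG2FC_PSEUDOCOUNT))
    table = _rank_sum_table(a, b, expr.columns, log2fc)
    sig = table[(table["log2fc"].abs() > lfc_threshold) & (table["q"] < q_threshold)]
    return sig.sort_values("q", kind="stable")


def bulk_de(
    matrix: ExpressionMatrix,
    lfc_threshold: float = 0.5,
    q_threshold: float = 0.05,
) -> pd.DataFrame:
    """Rank-sum tumor-vs-normal differential expression on log2 values.

    The fold change is the difference of mean log2 values (tumor minus
    normal).  Returns genes passing ``|log2fc| > lfc_threshold`` and
    BH ``q < q_threshold``.
    """
    if matrix.tissue_class is None:
        raise ValueError("bulk_de requires tissue_class labels")
    tumor = matrix.samples_of_class(TUMOR)
    normal = matrix.samples_of_class(NORMAL)
    if len(tumor) < 3 or len(normal) < 3:
        raise ValueError("need at least 3 samples per tissue class")
    t = matrix.values[tumor].to_numpy(dtype=float).T
    n = matrix.values[normal].to_numpy(dtype=float).T
    log2fc = t.mean(axis=0) - n.mean(axis=0)
    table = _rank_sum_table(t, n, matrix.values.index, log2fc)
    sig = table[(table["log2fc"].abs() > lfc_threshold) & (table["q"] < q_threshold)]
    return sig.sort_values("q", kind="stable")


def intersect_sc_bulk(sc: pd.DataFrame, bulk: pd.DataFrame) -> list[str]:
    """Genes significant at both levels with concordant direction.

    Both inputs are DE tables (as returned by :func:`wilcoxon_de` and
    :func:`bulk_de`) carrying a ``direction`` column; a gene is kept
    only when it appears in both and is dysregulated the same way.
    """
    shared = sc.index.intersection(bulk.index)
    concordant = [
        g for g in shared if sc.loc[g, "direction"] == bulk.loc[g, "direction"]
    ]
    return sorted(concordant)
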