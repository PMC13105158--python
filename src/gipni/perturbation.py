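"""Per-sample gene-interaction perturbation against a normal reference.

The central statistic: expression values are converted to within-sample
ranks; for every network edge (i, j) the rank difference
``d_s(i, j) = rank_s(i) - rank_s(j)`` is compared with the reference
rank difference derived from genes ordered by mean expression in normal
samples, and the deviation ``p_s(i, j) = d_s(i, j) - d_ref(i, j)`` is
the edge's perturbation in sample ``s``.  Rank differences are robust
to platform scaling and monotone batch distortions, and a sample whose
ordering equals the reference ordering has zero perturbation on every
edge.

Perturbation values are stored signed (swapping an edge's endpoints
flips the sign); the per-sample summary score and the differential-edge
test operate on magnitudes, which are the interpretable quantity.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .io import NORMAL, TUMOR, ExpressionMatrix, InteractionNetwork

logger = logging.getLogger(__name__)


@dataclass
class ReferenceBenchmark:
    """Reference gene ranking from mean expression in normal samples.

    ``ref_rank`` maps each gene to its position 1..G when genes are
    ordered by ascending mean expression over the reference cohort;
    ties in the mean are broken lexicographically by gene identifier so
    the ranking is deterministic.
    """

    ref_rank: pd.Series
    source_cohort: str = ""

    @property
    def genes(self) -> list[str]:
        return list(self.ref_rank.index)


@dataclass
class EdgePerturbationMatrix:
    """Edges x samples matrix of rank-difference deviations.

    ``values`` is indexed by canonical edge id ``"a|b"`` (a < b); an
    entry is the signed deviation of the sample's rank difference from
    the reference rank difference, bounded by ``2(G-1)`` in magnitude.
    """

    values: pd.DataFrame
    tissue_class: pd.Series | None = None
    n_genes: int = 0

    @property
    def edge_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    def samples_of_class(self, tissue: str) -> list[str]:
        if self.tissue_class is None:
            raise ValueError("matrix carries no tissue_class labels")
        return list(self.tissue_class.index[self.tissue_class == tissue])

    def subset_samples(self, samples: list[str]) -> "EdgePerturbationMatrix":
        tc = None if self.tissue_class is None else self.tissue_class.loc[samples]
        return EdgePerturbationMatrix(
            values=self.values[samples], tissue_class=tc, n_genes=self.n_genes
        )


def common_universe(
    network: InteractionNetwork,
    reference: ExpressionMatrix,
    *cohorts: ExpressionMatrix,
) -> list[str]:
    """Network genes present in the reference and every cohort.

    Ranks are only comparable when computed over a shared gene
    universe, so the pipeline restricts all matrices to this set and
    recomputes ranks within it.
    """
    universe = set(network.genes) & set(reference.gene_ids)
    for cohort in cohorts:
        universe &= set(cohort.gene_ids)
    return sorted(universe)


def rank_transform(matrix: ExpressionMatrix) -> pd.DataFrame:
    """Within-sample average-tie ranks, ascending with expression.

    Returns a genes x samples DataFrame of ranks in 1..G; each column
    sums to G(G+1)/2.
    """
    if matrix.n_genes < 2:
        raise ValueError("rank transform needs at least 2 genes")
    ranks = stats.rankdata(matrix.values.to_numpy(dtype=float), axis=0)
    return pd.DataFrame(ranks, index=matrix.values.index, columns=matrix.values.columns)


def build_reference(
    normals: ExpressionMatrix, network: InteractionNetwork | None = None
) -> ReferenceBenchmark:
    """Rank genes by mean expression across normal reference samples.

    If a network is given, the reference is restricted to network genes
    first (mismatches are logged) so downstream cohorts see a matched
    universe.
    """
    if normals.n_samples < 2:
        raise ValueError("reference requires at least 2 normal samples")
    values = normals.values
    if network is not None:
        shared = sorted(set(network.genes) & set(values.index))
        if len(shared) < len(set(network.genes)):
            logger.warning(
                "%d network genes absent from the reference cohort",
                len(set(network.genes)) - len(shared),
            )
        values = values.loc[shared]
    means = values.mean(axis=1)
    ordered = sorted(means.index, key=lambda g: (means[g], g))
    ref_rank = pd.Series(
        np.arange(1, len(ordered) + 1, dtype=float), index=ordered, name="ref_rank"
    ).loc[values.index]
    return ReferenceBenchmark(ref_rank=ref_rank, source_cohort=normals.cohort_id)


def edge_perturbation(
    ranks: pd.DataFrame,
    reference: ReferenceBenchmark,
    network: InteractionNetwork,
    tissue_class: pd.Series | None = None,
) -> EdgePerturbationMatrix:
    """Assemble the edges x samples perturbation matrix.

    For each canonical edge (a, b):
    ``p_s = (rank_s(a) - rank_s(b)) - (ref(a) - ref(b))``.
    Edges referencing genes absent from the rank matrix or the
    reference are dropped with a logged count.
    """
    gene_set = set(ranks.index) & set(reference.ref_rank.index)
    edges = network.edges
    ok = edges["gene_a"].isin(gene_set) & edges["gene_b"].isin(gene_set)
    if (~ok).any():
        logger.warning("dropped %d edges with genes missing from the universe", int((~ok).sum()))
        edges = edges.loc[ok]
    if edges.empty:
        raise ValueError("no network edges left in the gene universe")
    ra = ranks.loc[edges["gene_a"]].to_numpy(dtype=float)
    rb = ranks.loc[edges["gene_b"]].to_numpy(dtype=float)
    ref = reference.ref_rank
    dref = (
        ref.loc[edges["gene_a"]].to_numpy(dtype=float)
        - ref.loc[edges["gene_b"]].to_numpy(dtype=float)
    )
    p = (ra - rb) - dref[:, None]
    values = pd.DataFrame(p, index=edges.index, columns=ranks.columns)
    if tissue_class is not None:
        tissue_class = tissue_class.reindex(values.columns)
    return EdgePerturbationMatrix(
        values=values, tissue_class=tissue_class, n_genes=len(ranks.index)
    )


def perturbation_matrix(
    cohort: ExpressionMatrix,
    reference_cohort: ExpressionMatrix,
    network: InteractionNetwork,
) -> EdgePerturbationMatrix:
    """Convenience pipeline: restrict universe, rank, benchmark, perturb."""
    universe = common_universe(network, reference_cohort, cohort)
    net = network.restrict_to(universe)
    ref = build_reference(reference_cohort.subset_genes(universe))
    ranks = rank_transform(cohort.subset_genes(universe))
    return edge_perturbation(ranks, ref, net, tissue_class=cohort.tissue_class)


def sample_perturbation_score(epm: EdgePerturbationMatrix) -> pd.Series:
    """Per-sample mean absolute edge perturbation on a log2 scale.

    ``score_s = log2(mean_e |p_s(e)| + 1)``; the +1 keeps the
    unperturbed (all-zero) sample at score 0.
    """
    if len(epm.edge_ids) == 0:
        raise ValueError("perturbation matrix has no edges")
    mean_abs = epm.values.abs().mean(axis=0)
    return np.log2(mean_abs + 1.0).rename("perturbation_score")


def differential_edges(
    epm: EdgePerturbationMatrix, q_threshold: float = 0.05
) -> pd.DataFrame:
    """Edges whose perturbation magnitude differs between tumor and normal.

    Per edge, a two-sided rank-sum test compares ``|p|`` across tumor
    versus normal samples; BH adjustment runs across edges.  Returns a
    per-edge table (all edges) with ``p``, ``q``, the mean-|p|
    difference ``effect`` and a ``significant`` flag, sorted by q then
    descending |effect|; the significant set is ``table[table.significant]``.
    """
    tumor = epm.samples_of_class(TUMOR)
    normal = epm.samples_of_class(NORMAL)
    if len(tumor) < 3 or len(normal) < 3:
        raise ValueError("need at least 3 samples per tissue class")
    at = epm.values[tumor].abs().to_numpy()
    an = epm.values[normal].abs().to_numpy()
    res = stats.mannwhitneyu(at, an, axis=1, alternative="two-sided")
    p = np.asarray(res.pvalue, dtype=float)
    q = multipletests(p, method="fdr_bh")[1]
    effect = at.mean(axis=1) - an.mean(axis=1)
    table = pd.DataFrame(
        {
            "p": p,
            "q": q,
            "effect": effect,
            "significant": q < q_threshold,
        },
        index=epm.values.index,
    )
    table["abs_effect"] = table["effect"].abs()
    table = table.sort_values(["q", "abs_effect"], ascending=[True, False], kind="stable")
    return table.drop(columns="abs_effect")


def extract_node_genes(edges) -> list[str]:
    """Deduplicated, sorted union of edge endpoint genes.

    Accepts an iterable of canonical edge ids (``"A|B"``), a DataFrame
    with ``gene_a``/``gene_b`` columns, or a DataFrame indexed by edge
    id (e.g. the output of :func:`differential_edges`).
    """
    genes: set[str] = set()
    if isinstance(edges, pd.DataFrame):
        if {"gene_a", "gene_b"}.issubset(edges.columns):
            genes.update(edges["gene_a"])
            genes.update(edges["gene_b"])
        else:
            edges = list(edges.index)
    if not isinstance(edges, pd.DataFrame):
        for eid in edges:
            a, _, b = str(eid).partition("|")
            genes.add(a)
            genes.add(b)
    genes.discard("")
    return sorted(genes)
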