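"""Synthetic cohorts with planted gene-interaction perturbation.

The generator emulates the study design the pipeline assumes: a normal
reference cohort whose genes follow a stable latent ordering, tumor
cohorts in which a planted subset of network genes loses rank
coordination with its interaction partners, survival times whose hazard
grows with the per-sample perturbation burden, and a toy single-cell
experiment with labeled malignant/benign epithelial clusters.

Latent model
------------
Gene ``g`` has a fixed latent mean ``mu_g`` taken from a strictly
decreasing sequence spanning a log2(TPM+1)-like range (10 down to 0).
A normal sample is ``mu + N(0, sigma^2)`` i.i.d. per gene, so the
normal rank ordering is preserved in expectation.  Tumor perturbation
is planted on latent means, not on ranks, so it propagates through the
real pipeline: each molecular subtype owns a disjoint set of perturbed
genes, and every tumor sample of that subtype shifts those genes'
latent values by ``direction * perturb_shift * intensity`` where the
per-sample intensity is log-normal around 1.  An edge is truly
perturbed when at least one endpoint is a shifted gene; the recorded
ground truth is exactly that edge set.

Survival
--------
Event times are exponential with hazard proportional to
``exp(hazard_beta * z(burden))`` where ``burden`` is the per-sample
shift magnitude (zero for normals) standardized across the cohort's
tumors; censoring is independent exponential, calibrated so the
expected censored fraction is close to ``censor_rate``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .io import (
    NORMAL,
    TUMOR,
    ExpressionMatrix,
    InteractionNetwork,
    SurvivalTable,
)

DEFAULT_SEED = 17


class ParameterError(ValueError):
    """Raised for infeasible or inconsistent simulation parameters."""


@dataclass(frozen=True)
class SimulationConfig:
    """Study-scale parameters for the synthetic bulk cohorts."""

    n_genes: int = 200
    n_edges: int = 600
    n_normal: int = 50
    n_tumor: int = 50
    n_cohorts: int = 2
    frac_perturbed_edges: float = 0.1
    perturb_shift: float = 3.0
    hazard_beta: float = 1.5
    censor_rate: float = 0.3
    n_subtypes: int = 3
    sigma: float = 1.0
    seed: int = DEFAULT_SEED

    def __post_init__(self) -> None:
        for name in ("n_genes", "n_edges", "n_normal", "n_tumor", "n_cohorts", "n_subtypes"):
            if getattr(self, name) < 1:
                raise ParameterError(f"{name} must be >= 1")
        if not 0.0 <= self.frac_perturbed_edges <= 1.0:
            raise ParameterError("frac_perturbed_edges must lie in [0, 1]")
        if not 0.0 <= self.censor_rate < 1.0:
            raise ParameterError("censor_rate must lie in [0, 1)")
        if self.perturb_shift < 0:
            raise ParameterError("perturb_shift must be nonnegative")
        if self.sigma <= 0:
            raise ParameterError("sigma must be positive")


@dataclass
class SyntheticTruth:
    """Ground truth recorded alongside a simulation."""

    perturbed_edge_ids: frozenset[str] = frozenset()
    subtype_labels: pd.Series | None = None  # tumor sample -> 1..n_subtypes
    burden: pd.Series | None = None  # sample -> shift magnitude (0 for normals)
    perturbed_genes: dict[int, list[str]] = field(default_factory=dict)
    malignant_cell_labels: pd.Series | None = None
    planted_deg_ids: frozenset[str] = frozenset()
    planted_log2fc: pd.Series | None = None


def _gene_names(n_genes: int) -> list[str]:
    return [f"G{i:04d}" for i in range(1, n_genes + 1)]


def make_toy_network(
    n_genes: int, n_edges: int, seed: int = DEFAULT_SEED
) -> InteractionNetwork:
    """Random simple undirected graph with confidence scores in [0.8, 1].

    A stand-in for a high-confidence protein-interaction prior: no
    self-loops, no duplicate edges regardless of gene order.
    """
    max_edges = n_genes * (n_genes - 1) // 2
    if n_edges > max_edges:
        raise ParameterError(
            f"{n_edges} edges infeasible for {n_genes} genes (max {max_edges})"
        )
    rng = np.random.default_rng(seed)
    genes = _gene_names(n_genes)
    pairs: set[tuple[int, int]] = set()
    if n_edges >= n_genes - 1 and n_genes > 1:
        # random spanning tree so every gene participates, as in a
        # network built from the node genes of observed interactions
        order = rng.permutation(n_genes)
        for pos in range(1, n_genes):
            a = int(order[pos])
            b = int(order[rng.integers(0, pos)])
            pairs.add((min(a, b), max(a, b)))
    while len(pairs) < n_edges:
        need = n_edges - len(pairs)
        a = rng.integers(0, n_genes, size=2 * need + 8)
        b = rng.integers(0, n_genes, size=2 * need + 8)
        for x, y in zip(a, b):
            if x == y:
                continue
            pairs.add((min(int(x), int(y)), max(int(x), int(y))))
            if len(pairs) == n_edges:
                break
    conf = rng.uniform(0.8, 1.0, size=n_edges)
    return InteractionNetwork.from_pairs(
        (genes[a], genes[b], c) for (a, b), c in zip(sorted(pairs), conf)
    )


def _plant_perturbed_genes(
    network: InteractionNetwork,
    frac_perturbed_edges: float,
    n_subtypes: int,
    rng: np.random.Generator,
) -> tuple[list[str], dict[int, np.ndarray], frozenset[str]]:
    """Choose the perturbed genes and subtype-specific shift directions.

    Genes are drawn until the edges incident to them reach
    ``frac_perturbed_edges * n_edges``; an edge is truly perturbed when
    at least one endpoint is a chosen gene.  Every tumor sample shifts
    every chosen gene; each subtype carries its own random sign vector
    over the chosen genes, so subtypes differ by the direction pattern
    of the same perturbed subnetwork.
    """
    target = frac_perturbed_edges * network.n_edges
    incident: dict[str, list[str]] = {}
    for eid, row in network.edges.iterrows():
        incident.setdefault(row["gene_a"], []).append(eid)
        incident.setdefault(row["gene_b"], []).append(eid)
    pool = list(network.genes)
    rng.shuffle(pool)
    chosen: list[str] = []
    perturbed_edges: set[str] = set()
    cursor = 0
    while len(perturbed_edges) < target and cursor < len(pool):
        g = pool[cursor]
        cursor += 1
        chosen.append(g)
        perturbed_edges.update(incident.get(g, ()))
    dirs_by_subtype = {
        subtype: rng.choice([-1.0, 1.0], size=len(chosen))
        for subtype in range(1, n_subtypes + 1)
    }
    return chosen, dirs_by_subtype, frozenset(perturbed_edges)


def _censoring_hazard(hazards: np.ndarray, censor_rate: float) -> float:
    """Exponential censoring rate achieving the target censored fraction.

    With event hazard ``h_s`` and censoring hazard ``c``, sample ``s``
    is censored with probability ``c / (c + h_s)``; the average over
    samples is monotone in ``c``, so bisection solves for the target.
    """
    if censor_rate <= 0:
        return 0.0

    def censored_fraction(c: float) -> float:
        return float(np.mean(c / (c + hazards)))

    lo, hi = 1e-12, float(hazards.max()) * 1e6
    for _ in range(200):
        mid = np.sqrt(lo * hi)  # hazards are positive; bisect in log space
        if censored_fraction(mid) < censor_rate:
            lo = mid
        else:
            hi = mid
    return float(np.sqrt(lo * hi))


def latent_means(n_genes: int) -> np.ndarray:
    """The fixed strictly decreasing latent mean sequence."""
    return np.linspace(10.0, 0.0, n_genes)


def simulate_bulk(
    config: SimulationConfig, network: InteractionNetwork
) -> tuple[list[ExpressionMatrix], SurvivalTable, SyntheticTruth]:
    """Simulate a normal reference cohort plus tumor cohorts.

    Returns ``(cohorts, survival, truth)`` where ``cohorts[0]`` is the
    pure normal reference (cohort id ``"REF"``) and each subsequent
    element is a cohort with ``n_tumor`` tumor and ``n_normal`` normal
    samples.  The survival table covers every tumor sample and carries
    ``cohort``, ``age`` and ``stage`` covariate columns.
    """
    genes = _gene_names(config.n_genes)
    missing = set(network.genes) - set(genes)
    if missing:
        raise ParameterError(
            f"network references genes outside the simulated universe: "
            f"{sorted(missing)[:3]}..."
        )
    rng = np.random.default_rng(config.seed)
    mu = latent_means(config.n_genes)
    gene_pos = {g: i for i, g in enumerate(genes)}

    perturbed_genes, dirs_by_subtype, perturbed_edges = _plant_perturbed_genes(
        network, config.frac_perturbed_edges, config.n_subtypes, rng
    )
    perturbed_pos = np.array([gene_pos[g] for g in perturbed_genes], dtype=int)

    def draw_normals(cohort: str, n: int, offset: int) -> pd.DataFrame:
        cols = [f"{cohort}_N{j:03d}" for j in range(offset, offset + n)]
        vals = mu[:, None] + rng.normal(0.0, config.sigma, size=(config.n_genes, n))
        return pd.DataFrame(vals, index=genes, columns=cols)

    cohorts: list[ExpressionMatrix] = []
    ref_vals = draw_normals("REF", config.n_normal, 0)
    cohorts.append(
        ExpressionMatrix(
            values=ref_vals,
            cohort_id="REF",
            tissue_class=pd.Series(NORMAL, index=ref_vals.columns),
        )
    )

    surv_rows = []
    subtype_labels: dict[str, int] = {}
    burden: dict[str, float] = {}
    for c in range(1, config.n_cohorts + 1):
        cid = f"COHORT{c}"
        tumor_cols = [f"{cid}_T{j:03d}" for j in range(config.n_tumor)]
        tvals = mu[:, None] + rng.normal(
            0.0, config.sigma, size=(config.n_genes, config.n_tumor)
        )
        intensity = rng.lognormal(mean=0.0, sigma=0.35, size=config.n_tumor)
        for s, col in enumerate(tumor_cols):
            subtype = (s % config.n_subtypes) + 1
            subtype_labels[col] = subtype
            shift = config.perturb_shift * intensity[s]
            burden[col] = shift
            if perturbed_pos.size:
                tvals[perturbed_pos, s] += dirs_by_subtype[subtype] * shift
        tumor_df = pd.DataFrame(tvals, index=genes, columns=tumor_cols)
        normal_df = draw_normals(cid, config.n_normal, 0)
        values = pd.concat([tumor_df, normal_df], axis=1)
        tissue = pd.Series(
            [TUMOR] * config.n_tumor + [NORMAL] * config.n_normal,
            index=values.columns,
        )
        cohorts.append(
            ExpressionMatrix(values=values, cohort_id=cid, tissue_class=tissue)
        )
        for col in normal_df.columns:
            burden[col] = 0.0

        # survival for the cohort's tumor samples
        b = np.array([burden[col] for col in tumor_cols])
        sd = b.std()
        z = (b - b.mean()) / sd if sd > 0 else np.zeros_like(b)
        base_hazard = 1.0 / 36.0  # median survival on a months-like scale
        hazard = base_hazard * np.exp(config.hazard_beta * z)
        event_t = rng.exponential(1.0 / hazard)
        if config.censor_rate > 0:
            cens_hazard = _censoring_hazard(hazard, config.censor_rate)
            censor_t = rng.exponential(1.0 / cens_hazard, size=config.n_tumor)
        else:
            censor_t = np.full(config.n_tumor, np.inf)
        time = np.minimum(event_t, censor_t)
        event = (event_t <= censor_t).astype(int)
        age = rng.normal(60.0, 8.0, size=config.n_tumor).round(1)
        stage = rng.integers(1, 4, size=config.n_tumor)
        for i, col in enumerate(tumor_cols):
            surv_rows.append(
                {
                    "sample": col,
                    "time": max(time[i], 1e-3),
                    "event": event[i],
                    "cohort": cid,
                    "age": age[i],
                    "stage": stage[i],
                }
            )

    survival = SurvivalTable(pd.DataFrame(surv_rows).set_index("sample"))
    truth = SyntheticTruth(
        perturbed_edge_ids=perturbed_edges,
        subtype_labels=pd.Series(subtype_labels, name="subtype"),
        burden=pd.Series(burden, name="burden"),
        perturbed_genes={
            subtype: list(perturbed_genes) for subtype in dirs_by_subtype
        },
    )
    return cohorts, survival, truth


def simulate_prognostic(
    n_genes: int = 50,
    n_signature_genes: int = 5,
    beta_scale: float = 1.5,
    n_samples: int = 300,
    n_cohorts: int = 2,
    censor_rate: float = 0.3,
    seed: int = DEFAULT_SEED,
) -> tuple[list[ExpressionMatrix], SurvivalTable, pd.Series]:
    """Cohorts in which survival depends linearly on a few genes.

    Expression is standard normal per gene; the first
    ``n_signature_genes`` genes carry planted log-hazard coefficients
    of magnitude up to ``beta_scale`` with random signs.  Used to test
    coefficient recovery and cross-cohort generalization of fitted
    signatures.  Returns ``(cohorts, survival, planted_betas)``.
    """
    rng = np.random.default_rng(seed)
    genes = _gene_names(n_genes)
    sig_genes = genes[:n_signature_genes]
    betas = beta_scale * rng.choice([-1.0, 1.0], n_signature_genes) * rng.uniform(
        0.4, 1.0, n_signature_genes
    )
    cohorts: list[ExpressionMatrix] = []
    rows = []
    for c in range(1, n_cohorts + 1):
        cid = f"PROG{c}"
        cols = [f"{cid}_S{j:03d}" for j in range(n_samples)]
        X = rng.normal(size=(n_genes, n_samples))
        values = pd.DataFrame(X, index=genes, columns=cols)
        cohorts.append(
            ExpressionMatrix(
                values=values,
                cohort_id=cid,
                tissue_class=pd.Series(TUMOR, index=cols),
            )
        )
        lp = betas @ X[:n_signature_genes, :]
        base_hazard = 1.0 / 36.0
        hazard = base_hazard * np.exp(lp)
        event_t = rng.exponential(1.0 / hazard)
        if censor_rate > 0:
            cens_hazard = _censoring_hazard(hazard, censor_rate)
            censor_t = rng.exponential(1.0 / cens_hazard, size=n_samples)
        else:
            censor_t = np.full(n_samples, np.inf)
        time = np.maximum(np.minimum(event_t, censor_t), 1e-3)
        event = (event_t <= censor_t).astype(int)
        for i, col in enumerate(cols):
            rows.append(
                {"sample": col, "time": time[i], "event": event[i], "cohort": cid}
            )
    survival = SurvivalTable(pd.DataFrame(rows).set_index("sample"))
    return cohorts, survival, pd.Series(betas, index=sig_genes, name="beta")


# ---------------------------------------------------------------------------
# toy single-cell experiment
# ---------------------------------------------------------------------------


def simulate_single_cell(
    n_genes: int = 1000,
    n_cells_per_cluster: int = 300,
    planted_deg_ids: Iterable[str] | None = None,
    planted_log2fc: float = 2.0,
    n_planted_degs: int = 50,
    mito_prefix: str = "MT-",
    n_mito_genes: int = 10,
    violator_frac: float = 0.1,
    dispersion: float = 0.5,
    seed: int = DEFAULT_SEED,
) -> tuple[pd.DataFrame, pd.DataFrame, SyntheticTruth]:
    """Negative-binomial toy single-cell counts with planted structure.

    Three clusters are generated: ``malignant`` and ``benign``
    epithelial clusters of ``n_cells_per_cluster`` cells each, plus a
    smaller ``other`` cluster.  The planted DEGs receive a
    ``planted_log2fc`` fold change (alternating sign) in the malignant
    cluster.  Genes named with ``mito_prefix`` contribute a per-cell
    mitochondrial fraction, and ``violator_frac`` of the epithelial
    cells are engineered to violate one QC bound each (too few detected
    genes, too many counts, or excessive mitochondrial content) so that
    filters are exercised.

    Returns ``(counts, metadata, truth)``: counts are cells x genes
    integers; metadata carries ``cluster`` and ``qc_violation``
    columns.
    """
    rng = np.random.default_rng(seed)
    regular = [f"SCG{i:04d}" for i in range(1, n_genes - n_mito_genes + 1)]
    mito = [f"{mito_prefix}SCG{i:02d}" for i in range(1, n_mito_genes + 1)]
    genes = regular + mito

    if planted_deg_ids is None:
        planted = list(rng.choice(regular, size=n_planted_degs, replace=False))
    else:
        planted = sorted(planted_deg_ids)
        unknown = set(planted) - set(genes)
        if unknown:
            raise ParameterError(f"planted DEGs outside gene universe: {unknown}")
    signs = np.where(np.arange(len(planted)) % 2 == 0, 1.0, -1.0)
    lfc = pd.Series(signs * planted_log2fc, index=planted, name="log2fc")

    base_rate = rng.lognormal(mean=0.7, sigma=1.0, size=len(genes))
    base_rate = pd.Series(base_rate, index=genes)
    base_rate[mito] = base_rate[regular].mean() * 5.0  # mito-rich but below QC bound

    cluster_sizes = {
        "malignant": n_cells_per_cluster,
        "benign": n_cells_per_cluster,
        "other": max(n_cells_per_cluster // 3, 10),
    }
    counts_blocks = []
    meta_rows = []
    cell_idx = 0
    for cluster, size in cluster_sizes.items():
        rate = base_rate.copy()
        if cluster == "malignant":
            rate[planted] = rate[planted] * np.power(2.0, lfc.values)
        if cluster == "other":
            # a distinct lineage: shuffle a third of the gene rates
            shuffled = rng.permutation(len(regular) // 3)
            idx = np.array(regular)[: len(regular) // 3]
            rate[idx] = rate[idx].to_numpy()[shuffled]
        libsize = rng.lognormal(mean=0.0, sigma=0.3, size=size)
        mean_mat = rate.to_numpy()[:, None] * libsize[None, :]
        # NB via gamma-Poisson; dispersion = 1/size parameter
        shape = 1.0 / dispersion
        lam = rng.gamma(shape, mean_mat / shape)
        block = rng.poisson(lam).astype(np.int64)
        counts_blocks.append(block)
        for j in range(size):
            meta_rows.append(
                {"cell": f"CELL{cell_idx:05d}", "cluster": cluster, "qc_violation": ""}
            )
            cell_idx += 1
    counts = np.concatenate(counts_blocks, axis=1)
    cells = [row["cell"] for row in meta_rows]
    counts = pd.DataFrame(counts.T, index=cells, columns=genes)
    meta = pd.DataFrame(meta_rows).set_index("cell")

    # engineer QC violators among epithelial cells
    epithelial = meta.index[meta["cluster"].isin(["malignant", "benign"])]
    n_violators = int(round(violator_frac * len(epithelial)))
    violators = rng.choice(epithelial, size=n_violators, replace=False)
    kinds = ["min_features", "max_counts", "max_percent_mt", "min_counts"]
    for i, cell in enumerate(violators):
        kind = kinds[i % len(kinds)]
        row = counts.loc[cell].to_numpy().copy()
        if kind == "min_features":
            keep = rng.choice(len(genes), size=100, replace=False)
            mask = np.zeros(len(genes), dtype=bool)
            mask[keep] = True
            row[~mask] = 0
            row[row > 0] = np.maximum(row[row > 0], 1)
        elif kind == "min_counts":
            detected = np.flatnonzero(row)
            row[:] = 0
            chosen = rng.choice(detected, size=min(300, len(detected)), replace=False)
            row[chosen] = 1
        elif kind == "max_counts":
            row = row * (45000 // max(row.sum(), 1) + 1)
        elif kind == "max_percent_mt":
            mito_idx = [counts.columns.get_loc(g) for g in mito]
            total = row.sum()
            row[mito_idx] = int(total) // len(mito_idx) + 1
        counts.loc[cell] = row
        meta.loc[cell, "qc_violation"] = kind

    truth = SyntheticTruth(
        malignant_cell_labels=meta["cluster"].rename("label"),
        planted_deg_ids=frozenset(planted),
        planted_log2fc=lfc,
    )
    return counts, meta, truth
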