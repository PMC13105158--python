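"""Readers, writers, and shared domain containers.

All on-disk formats are plain text: TSV for expression matrices, edge
lists, survival tables and cell metadata; GMT for gene sets; JSON for
signatures.  Expression values are log2(TPM+1) unless a matrix is read
with ``raw_tpm=True``, in which case the transform is applied on load.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

NORMAL = "normal"
TUMOR = "tumor"


class FormatError(ValueError):
    """Raised when an input file violates the expected text format."""


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------


@dataclass
class ExpressionMatrix:
    """Genes x samples expression table on the log2(TPM+1) scale.

    Parameters
    ----------
    values
        DataFrame indexed by gene identifier with one column per sample.
    cohort_id
        Label of the cohort the samples belong to; cohorts are always
        processed independently downstream.
    tissue_class
        Per-sample label, ``"normal"`` or ``"tumor"``; optional for
        matrices where the distinction is irrelevant.
    constant_genes
        Genes whose row was constant when the matrix was z-scaled; empty
        for unscaled matrices.
    """

    values: pd.DataFrame
    cohort_id: str = "cohort"
    tissue_class: pd.Series | None = None
    constant_genes: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.values.index.has_duplicates:
            dup = self.values.index[self.values.index.duplicated()][0]
            raise FormatError(f"duplicate gene identifier {dup!r}")
        if self.values.columns.has_duplicates:
            dup = self.values.columns[self.values.columns.duplicated()][0]
            raise FormatError(f"duplicate sample identifier {dup!r}")
        if not np.isfinite(self.values.to_numpy(dtype=float)).all():
            raise FormatError("expression values must be finite")
        if self.tissue_class is not None:
            self.tissue_class = self.tissue_class.reindex(self.values.columns)

    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def samples_of_class(self, tissue: str) -> list[str]:
        if self.tissue_class is None:
            raise ValueError("matrix carries no tissue_class labels")
        return list(self.tissue_class.index[self.tissue_class == tissue])

    def subset_genes(self, genes: Sequence[str]) -> "ExpressionMatrix":
        return replace(self, values=self.values.loc[list(genes)])


@dataclass
class InteractionNetwork:
    """Undirected gene-pair edge list with confidence scores.

    Edges are stored canonically: ``gene_a < gene_b`` lexicographically
    and the edge identifier is ``"gene_a|gene_b"``, so storage is
    order-free and duplicate orientations collapse to one edge.
    """

    edges: pd.DataFrame  # columns gene_a, gene_b, confidence; index edge_id

    def __post_init__(self) -> None:
        if self.edges.index.has_duplicates:
            raise FormatError("duplicate edge identifiers")
        if (self.edges["gene_a"] == self.edges["gene_b"]).any():
            raise FormatError("self-loop edge")

    @classmethod
    def from_pairs(
        cls,
        pairs: Iterable[tuple[str, str, float]],
        keep: str = "max",
    ) -> "InteractionNetwork":
        """Build a network from (gene, gene, confidence) triples.

        Self-loops are dropped; duplicate edges (either orientation)
        are resolved by keeping the maximum confidence, the STRING
        convention.
        """
        best: dict[str, tuple[str, str, float]] = {}
        for a, b, conf in pairs:
            if a == b:
                continue
            lo, hi = (a, b) if a < b else (b, a)
            eid = f"{lo}|{hi}"
            if eid not in best or conf > best[eid][2]:
                best[eid] = (lo, hi, float(conf))
        df = pd.DataFrame.from_dict(
            best, orient="index", columns=["gene_a", "gene_b", "confidence"]
        )
        df.index.name = "edge_id"
        return cls(df.sort_index())

    @property
    def edge_ids(self) -> list[str]:
        return list(self.edges.index)

    @property
    def genes(self) -> list[str]:
        return sorted(set(self.edges["gene_a"]) | set(self.edges["gene_b"]))

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    @property
    def n_genes(self) -> int:
        return len(set(self.edges["gene_a"]) | set(self.edges["gene_b"]))

    def mean_degree(self) -> float:
        """Average node degree 2E/N of the stored graph."""
        return 2.0 * self.n_edges / self.n_genes

    def restrict_to(self, genes: Iterable[str]) -> "InteractionNetwork":
        """Drop edges with an endpoint outside ``genes`` (logged)."""
        keep = set(genes)
        mask = self.edges["gene_a"].isin(keep) & self.edges["gene_b"].isin(keep)
        dropped = int((~mask).sum())
        if dropped:
            logger.warning("dropped %d edges outside the gene universe", dropped)
        return InteractionNetwork(self.edges.loc[mask])


@dataclass
class SurvivalTable:
    """Per-sample time-to-event outcomes with optional covariates.

    ``data`` is indexed by sample and must carry a positive ``time``
    column and a binary ``event`` column; any further columns are
    treated as covariates.
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        for col in ("time", "event"):
            if col not in self.data.columns:
                raise FormatError(f"survival table missing column {col!r}")
        if self.data.index.has_duplicates:
            raise FormatError("duplicate sample identifiers in survival table")
        if (self.data["time"] <= 0).any():
            raise FormatError("survival times must be positive")
        if not self.data["event"].isin([0, 1]).all():
            raise FormatError("event indicator must be 0/1")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def time(self) -> pd.Series:
        return self.data["time"]

    @property
    def event(self) -> pd.Series:
        return self.data["event"]

    @property
    def covariate_names(self) -> list[str]:
        return [c for c in self.data.columns if c not in ("time", "event")]

    def subset(self, samples: Sequence[str]) -> "SurvivalTable":
        return SurvivalTable(self.data.loc[list(samples)])


@dataclass
class GeneSetCollection:
    """Named gene sets with one-line descriptions (GMT semantics)."""

    sets: dict[str, list[str]]
    descriptions: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, genes in self.sets.items():
            if not genes:
                raise FormatError(f"gene set {name!r} is empty")

    def __len__(self) -> int:
        return len(self.sets)

    def __iter__(self):
        return iter(self.sets)

    def __getitem__(self, name: str) -> list[str]:
        return self.sets[name]


@dataclass
class SignatureModel:
    """A linear risk signature: ordered genes, coefficients, cutoff.

    The risk score of a sample is the inner product of the coefficient
    vector with the sample's (z-scaled) expression of the signature
    genes; ``cutoff`` is the optional high/low stratification threshold.
    """

    gene_ids: list[str]
    coefficients: np.ndarray
    cutoff: float | None = None
    training_cohort: str = ""

    def __post_init__(self) -> None:
        self.coefficients = np.asarray(self.coefficients, dtype=float)
        if len(self.gene_ids) != len(self.coefficients):
            raise ValueError("one coefficient per gene required")
        if len(set(self.gene_ids)) != len(self.gene_ids):
            raise ValueError("signature genes must be unique")

    def to_dict(self) -> dict:
        return {
            "gene_ids": list(self.gene_ids),
            "coefficients": [float(c) for c in self.coefficients],
            "cutoff": None if self.cutoff is None else float(self.cutoff),
            "training_cohort": self.training_cohort,
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "SignatureModel":
        return cls(
            gene_ids=list(d["gene_ids"]),
            coefficients=np.asarray(d["coefficients"], dtype=float),
            cutoff=d.get("cutoff"),
            training_cohort=d.get("training_cohort", ""),
        )


# ---------------------------------------------------------------------------
# expression I/O and preprocessing
# ---------------------------------------------------------------------------


def read_expression(
    path: str | Path,
    raw_tpm: bool = False,
    metadata: str | Path | pd.Series | None = None,
    cohort_id: str | None = None,
) -> ExpressionMatrix:
    """Read a genes-as-rows TSV expression matrix.

    The first column holds gene identifiers and the header row holds
    sample identifiers.  With ``raw_tpm=True`` values are interpreted
    as TPM and transformed to log2(TPM+1).  Duplicate gene rows are
    collapsed by the per-sample maximum.  ``metadata`` may be a TSV
    path (columns ``sample`` and ``tissue_class``) or a Series mapping
    samples to ``normal``/``tumor``.
    """
    path = Path(path)
    try:
        df = pd.read_csv(path, sep="\t", index_col=0)
    except pd.errors.EmptyDataError:
        raise FormatError(f"{path}: empty expression file") from None
    if df.empty:
        raise FormatError(f"{path}: empty expression file")
    df.index.name = None
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")[1:]
    seen: set[str] = set()
    for col in header:
        if col in seen:
            raise FormatError(f"{path}: duplicate sample column {col!r}")
        seen.add(col)
    for col in df.columns:
        if not pd.api.types.is_numeric_dtype(df[col]):
            bad = df[col][pd.to_numeric(df[col], errors="coerce").isna()].index[0]
            raise FormatError(
                f"{path}: non-numeric value in column {col!r}, row {bad!r}"
            )
    if df.index.has_duplicates:
        df = df.groupby(level=0, sort=False).max()
    values = df.astype(float)
    if raw_tpm:
        if (values.to_numpy() < 0).any():
            raise FormatError(f"{path}: negative TPM value")
        values = np.log2(values + 1.0)
    tissue = None
    if metadata is not None:
        if isinstance(metadata, pd.Series):
            tissue = metadata
        else:
            meta = pd.read_csv(metadata, sep="\t")
            if "sample" not in meta.columns or "tissue_class" not in meta.columns:
                raise FormatError(
                    f"{metadata}: metadata needs 'sample' and 'tissue_class' columns"
                )
            tissue = meta.set_index("sample")["tissue_class"]
    return ExpressionMatrix(
        values=values,
        cohort_id=cohort_id or path.stem,
        tissue_class=tissue,
    )


def write_expression(
    matrix: ExpressionMatrix,
    path: str | Path,
    metadata_path: str | Path | None = None,
) -> None:
    out = matrix.values.copy()
    out.index.name = "gene_id"
    out.to_csv(path, sep="\t")
    if metadata_path is not None and matrix.tissue_class is not None:
        meta = matrix.tissue_class.rename("tissue_class").rename_axis("sample")
        meta.to_frame().to_csv(metadata_path, sep="\t")


def zscore(matrix: ExpressionMatrix) -> ExpressionMatrix:
    """Standardize each gene row to mean 0, sample SD 1 within the cohort.

    Constant rows cannot be scaled; they map to all-zero rows and are
    recorded in ``constant_genes``.  Cohorts are always scaled
    independently: this function sees one cohort at a time.
    """
    if matrix.n_samples < 2:
        raise ValueError(
            f"cohort {matrix.cohort_id!r} has a single sample; cannot z-score"
        )
    vals = matrix.values.to_numpy(dtype=float)
    mean = vals.mean(axis=1, keepdims=True)
    sd = vals.std(axis=1, ddof=1, keepdims=True)
    constant = (sd[:, 0] == 0.0)
    sd[constant, :] = 1.0
    scaled = (vals - mean) / sd
    scaled[constant, :] = 0.0
    return replace(
        matrix,
        values=pd.DataFrame(scaled, index=matrix.values.index, columns=matrix.values.columns),
        constant_genes=tuple(matrix.values.index[constant]),
    )


# ---------------------------------------------------------------------------
# network I/O
# ---------------------------------------------------------------------------


def read_network(
    path: str | Path,
    min_confidence: float = 0.8,
    gene_a_col: str | int = 0,
    gene_b_col: str | int = 1,
    confidence_col: str | int = 2,
) -> InteractionNetwork:
    """Read a two-gene-column edge list TSV with a confidence column.

    STRING-style integer scores in 0-999 are divided by 1000.  Edges
    with confidence strictly below ``min_confidence`` are dropped;
    duplicates keep the maximum confidence and self-loops are removed.
    """
    path = Path(path)
    try:
        df = pd.read_csv(path, sep="\t")
    except pd.errors.EmptyDataError:
        raise FormatError(f"{path}: empty network file") from None
    named = {"gene_a", "gene_b", "confidence"}
    if (
        (gene_a_col, gene_b_col, confidence_col) == (0, 1, 2)
        and named.issubset(df.columns)
    ):
        gene_a_col, gene_b_col, confidence_col = "gene_a", "gene_b", "confidence"
    cols = []
    for c in (gene_a_col, gene_b_col, confidence_col):
        if isinstance(c, int):
            if c >= df.shape[1]:
                raise FormatError(f"{path}: missing column index {c}")
            cols.append(df.columns[c])
        else:
            if c not in df.columns:
                raise FormatError(f"{path}: missing column {c!r}")
            cols.append(c)
    a, b, conf = (df[c] for c in cols)
    conf = pd.to_numeric(conf, errors="coerce")
    if conf.isna().any():
        raise FormatError(f"{path}: non-numeric confidence value")
    if conf.max() > 1.0:  # STRING combined scores are 0-999
        conf = conf / 1000.0
    net = InteractionNetwork.from_pairs(
        zip(a.astype(str), b.astype(str), conf.astype(float))
    )
    keep = net.edges["confidence"] >= min_confidence
    return InteractionNetwork(net.edges.loc[keep])


def write_network(network: InteractionNetwork, path: str | Path) -> None:
    out = network.edges.copy()
    out.index.name = "edge_id"
    out.to_csv(path, sep="\t")


# ---------------------------------------------------------------------------
# survival I/O
# ---------------------------------------------------------------------------


def read_survival(path: str | Path) -> SurvivalTable:
    try:
        df = pd.read_csv(path, sep="\t", index_col=0)
    except pd.errors.EmptyDataError:
        raise FormatError(f"{path}: empty survival file") from None
    df.index.name = None
    return SurvivalTable(df)


def write_survival(table: SurvivalTable, path: str | Path) -> None:
    out = table.data.copy()
    out.index.name = "sample"
    out.to_csv(path, sep="\t")


# ---------------------------------------------------------------------------
# gene sets (GMT)
# ---------------------------------------------------------------------------


def read_gmt(path: str | Path) -> GeneSetCollection:
    """Read a GMT file: name, description, then tab-separated genes."""
    sets: dict[str, list[str]] = {}
    descriptions: dict[str, str] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(
                    f"{path}: line {lineno}: GMT line needs name, description "
                    f"and at least one gene"
                )
            name, desc, *genes = fields
            genes = [g for g in genes if g]
            if not genes:
                raise FormatError(f"{path}: line {lineno}: empty gene set {name!r}")
            if name in sets:
                raise FormatError(f"{path}: line {lineno}: duplicate set {name!r}")
            sets[name] = genes
            descriptions[name] = desc
    return GeneSetCollection(sets=sets, descriptions=descriptions)


def write_gmt(collection: GeneSetCollection, path: str | Path) -> None:
    with open(path, "w") as fh:
        for name, genes in collection.sets.items():
            desc = collection.descriptions.get(name, "")
            fh.write("\t".join([name, desc, *genes]) + "\n")


# ---------------------------------------------------------------------------
# signatures (JSON)
# ---------------------------------------------------------------------------


def read_signature(path: str | Path) -> SignatureModel:
    with open(path) as fh:
        return SignatureModel.from_dict(json.load(fh))


def write_signature(sig: SignatureModel, path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump(sig.to_dict(), fh, indent=1)
        fh.write("\n")
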