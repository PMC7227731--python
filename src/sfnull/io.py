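"""Domain types and delimited-text I/O.

The spatial substrate of every analysis is a :class:`SampleTable`: one row per
cortical tissue sample with MNI millimetre coordinates, an anatomical tissue
label (used for the within-tissue correction) and a resting-state network
label in 0..13 (0 = the sample belongs to no rsfMRI network).  Expression is a
genes x samples matrix aligned to a table.  Both are read from and written to
plain TSV/CSV.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform

from .errors import (
    AlignmentError,
    ConfigurationError,
    FormatError,
    ParseError,
    ValidationError,
)

logger = logging.getLogger(__name__)

SAMPLE_COLUMNS = ("sample_id", "x", "y", "z", "tissue_label", "network_label")

#: cluster counts per network: nine networks of three clusters, three of two,
#: one singleton network — 13 networks, 34 clusters.
DEFAULT_COMPOSITION: tuple[int, ...] = (3,) * 9 + (2,) * 3 + (1,)

VARIANTS = ("All", "Z-cn", "omit-RS")


def _delimiter_for(path: Path, delimiter: str | None) -> str:
    if delimiter is not None:
        return delimiter
    return "," if Path(path).suffix.lower() == ".csv" else "\t"


@dataclass
class SampleTable:
    """Per-sample id, 3D mm coordinates, tissue label and network label."""

    sample_ids: np.ndarray
    coords: np.ndarray
    tissue_labels: np.ndarray
    network_labels: np.ndarray

    def __post_init__(self) -> None:
        self.sample_ids = np.asarray(self.sample_ids, dtype=object)
        self.coords = np.asarray(self.coords, dtype=float)
        self.tissue_labels = np.asarray(self.tissue_labels, dtype=object)
        self.network_labels = np.asarray(self.network_labels, dtype=int)
        n = len(self.sample_ids)
        if self.coords.shape != (n, 3):
            raise ValidationError(
                f"coords must be (n, 3); got {self.coords.shape} for n={n}"
            )
        if len(self.tissue_labels) != n or len(self.network_labels) != n:
            raise ValidationError("all column arrays must have equal length")
        ids, counts = np.unique(self.sample_ids.astype(str), return_counts=True)
        if (counts > 1).any():
            dupes = ids[counts > 1].tolist()
            raise ValidationError(f"duplicate sample_id values: {dupes}")
        if not np.isfinite(self.coords).all():
            raise ValidationError("coordinates must be finite")
        if (self.network_labels < 0).any():
            raise ValidationError("network labels must be >= 0")
        nonzero = np.unique(self.network_labels[self.network_labels > 0])
        if len(nonzero) > 13:
            raise ValidationError(
                f"{len(nonzero)} distinct non-zero network labels; at most 13 allowed"
            )
        self._index = {sid: i for i, sid in enumerate(self.sample_ids)}

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def rsfmri_mask(self) -> np.ndarray:
        """Boolean mask of samples belonging to some rsfMRI network."""
        return self.network_labels > 0

    @property
    def network_ids(self) -> np.ndarray:
        """Sorted distinct non-zero network labels present."""
        return np.unique(self.network_labels[self.network_labels > 0])

    def indices_of(self, sample_ids: Sequence[str]) -> np.ndarray:
        try:
            return np.array([self._index[s] for s in sample_ids], dtype=int)
        except KeyError as exc:  # pragma: no cover - message matters, not path
            raise ValidationError(f"unknown sample id {exc.args[0]!r}") from exc

    def distance_matrix(self) -> np.ndarray:
        """Dense Euclidean distance matrix in mm (cached)."""
        cached = getattr(self, "_dmat", None)
        if cached is None:
            cached = squareform(pdist(self.coords))
            self._dmat = cached
        return cached

    def subset(self, mask: np.ndarray) -> "SampleTable":
        return SampleTable(
            self.sample_ids[mask],
            self.coords[mask],
            self.tissue_labels[mask],
            self.network_labels[mask],
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "sample_id": self.sample_ids.astype(str),
                "x": self.coords[:, 0],
                "y": self.coords[:, 1],
                "z": self.coords[:, 2],
                "tissue_label": self.tissue_labels.astype(str),
                "network_label": self.network_labels,
            }
        )


def read_sample_table(path: str | Path, delimiter: str | None = None) -> SampleTable:
    """Read a sample table from TSV/CSV (delimiter auto-detected by suffix)."""
    path = Path(path)
    sep = _delimiter_for(path, delimiter)
    df = pd.read_csv(path, sep=sep, dtype=object)
    missing = [c for c in SAMPLE_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing required column(s) {missing}")
    coords = np.empty((len(df), 3), dtype=float)
    for j, col in enumerate(("x", "y", "z")):
        vals = pd.to_numeric(df[col], errors="coerce")
        bad = np.flatnonzero(vals.isna().to_numpy())
        if bad.size:
            # +2: header line plus 1-based numbering
            raise ParseError(
                f"{path}: non-numeric {col!r} at file line(s) {(bad + 2).tolist()}"
            )
        coords[:, j] = vals.to_numpy()
    nets = pd.to_numeric(df["network_label"], errors="coerce")
    bad = np.flatnonzero(nets.isna().to_numpy())
    if bad.size:
        raise ParseError(
            f"{path}: non-numeric 'network_label' at file line(s) {(bad + 2).tolist()}"
        )
    return SampleTable(
        df["sample_id"].to_numpy(),
        coords,
        df["tissue_label"].to_numpy(),
        nets.to_numpy().astype(int),
    )


def write_sample_table(
    table: SampleTable, path: str | Path, delimiter: str | None = None
) -> None:
    path = Path(path)
    table.to_frame().to_csv(path, sep=_delimiter_for(path, delimiter), index=False)


@dataclass
class ExpressionMatrix:
    """Genes x samples real-valued expression, sample order tied to a table.

    ``zero_variance_genes`` lists genes whose profile is constant across
    samples; they are loaded but reported, because correlation and Moran
    statistics are undefined for them.
    """

    gene_ids: np.ndarray
    sample_ids: np.ndarray
    values: np.ndarray
    zero_variance_genes: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        self.gene_ids = np.asarray(self.gene_ids, dtype=object)
        self.sample_ids = np.asarray(self.sample_ids, dtype=object)
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.gene_ids), len(self.sample_ids)):
            raise ValidationError(
                f"values shape {self.values.shape} does not match "
                f"{len(self.gene_ids)} genes x {len(self.sample_ids)} samples"
            )
        if len(self.gene_ids) == 0 or len(self.sample_ids) == 0:
            raise FormatError("empty expression matrix")
        ids, counts = np.unique(self.gene_ids.astype(str), return_counts=True)
        if (counts > 1).any():
            raise ValidationError(f"duplicate gene ids: {ids[counts > 1].tolist()}")
        if not np.isfinite(self.values).all():
            raise ValidationError("expression values must be finite after loading")
        if not self.zero_variance_genes:
            zv = self.values.std(axis=1) == 0.0
            self.zero_variance_genes = tuple(self.gene_ids[zv].astype(str))

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            self.values, columns=self.sample_ids.astype(str)
        )
        df.insert(0, "gene_id", self.gene_ids.astype(str))
        return df


def read_expression(
    path: str | Path,
    table: SampleTable,
    delimiter: str | None = None,
    impute_mean: bool = False,
) -> ExpressionMatrix:
    """Read a genes x samples matrix and align its columns to ``table`` order.

    The header must hold sample ids forming a subset/permutation of the
    table's ids.  Missing values are an error unless ``impute_mean`` is set,
    in which case each missing entry is replaced by its gene's mean and the
    imputation is logged.
    """
    path = Path(path)
    sep = _delimiter_for(path, delimiter)
    df = pd.read_csv(path, sep=sep)
    if df.shape[1] < 2 or df.shape[0] == 0:
        raise FormatError(f"{path}: empty expression matrix")
    gene_col = df.columns[0]
    matrix_samples = list(df.columns[1:])
    unknown = [s for s in matrix_samples if s not in table._index]
    if unknown:
        raise AlignmentError(
            f"{path}: sample id(s) not present in the sample table: {unknown}"
        )
    # reorder columns to table order, keeping only samples present in the file
    present = [str(s) for s in table.sample_ids if str(s) in set(matrix_samples)]
    values = df[present].to_numpy(dtype=float)
    if np.isnan(values).any():
        genes_with_na = df[gene_col].to_numpy()[np.isnan(values).any(axis=1)]
        if not impute_mean:
            raise ValidationError(
                f"{path}: missing expression values in gene(s) "
                f"{genes_with_na[:10].tolist()}; pass impute_mean=True to impute"
            )
        logger.warning(
            "imputing %d missing values in %d gene(s) with per-gene means",
            int(np.isnan(values).sum()),
            len(genes_with_na),
        )
        means = np.nanmean(values, axis=1, keepdims=True)
        values = np.where(np.isnan(values), means, values)
    return ExpressionMatrix(df[gene_col].to_numpy(), np.array(present, dtype=object), values)


def write_expression(
    expr: ExpressionMatrix, path: str | Path, delimiter: str | None = None
) -> None:
    path = Path(path)
    expr.to_frame().to_csv(path, sep=_delimiter_for(path, delimiter), index=False)


@dataclass
class GeneSet:
    """An ordered list of gene identifiers (treated as opaque strings)."""

    gene_ids: tuple[str, ...]

    def __len__(self) -> int:
        return len(self.gene_ids)


def read_gene_set(path: str | Path) -> GeneSet:
    """One id per line; blank lines and ``#`` comments ignored."""
    ids = []
    for line in Path(path).read_text().splitlines():
        line = line.split("#", 1)[0].strip()
        if line:
            ids.append(line)
    return GeneSet(tuple(ids))


@dataclass
class GeneSetResolution:
    in_set: np.ndarray
    out_of_set: np.ndarray
    unresolved: tuple[str, ...]


def resolve_gene_set(gene_set: GeneSet, expr: ExpressionMatrix) -> GeneSetResolution:
    """Partition gene indices of ``expr`` into in-set / out-of-set.

    Unresolved ids are reported on the result, never fatal.
    """
    index = {str(g): i for i, g in enumerate(expr.gene_ids)}
    in_idx = sorted({index[g] for g in gene_set.gene_ids if g in index})
    unresolved = tuple(g for g in gene_set.gene_ids if g not in index)
    if unresolved:
        logger.warning("%d gene-set id(s) not found in the matrix", len(unresolved))
    mask = np.zeros(expr.n_genes, dtype=bool)
    mask[list(in_idx)] = True
    return GeneSetResolution(
        np.flatnonzero(mask), np.flatnonzero(~mask), unresolved
    )


@dataclass
class RunConfig:
    """Configuration of a false-positive-rate sweep.

    ``n_networks`` simulated network sets are drawn per radius and variant;
    each receives ``n_shuffles`` label shuffles for the permutation test.
    """

    radii_mm: tuple[float, ...] = tuple(range(6, 16))
    n_clusters: int = 34
    network_composition: tuple[int, ...] = DEFAULT_COMPOSITION
    n_networks: int = 1000
    n_shuffles: int = 1000
    variants: tuple[str, ...] = ("All",)
    seed: int = 0
    weights_threshold_mm: float = 16.0
    weights_scheme: str = "inverse_distance"

    def __post_init__(self) -> None:
        self.radii_mm = tuple(float(r) for r in np.atleast_1d(self.radii_mm))
        self.network_composition = tuple(int(c) for c in self.network_composition)
        if isinstance(self.variants, str):
            self.variants = (self.variants,)
        self.variants = tuple(self.variants)
        if sum(self.network_composition) != self.n_clusters:
            raise ConfigurationError(
                f"network_composition sums to {sum(self.network_composition)}, "
                f"expected n_clusters={self.n_clusters}"
            )
        if self.n_shuffles < 1:
            raise ConfigurationError("n_shuffles must be >= 1")
        if any(r <= 0 for r in self.radii_mm):
            raise ConfigurationError("radii must be positive")
        for v in self.variants:
            if v not in VARIANTS:
                raise ConfigurationError(f"unknown variant {v!r}; one of {VARIANTS}")

    def replace(self, **kwargs) -> "RunConfig":
        return dataclasses.replace(self, **kwargs)
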