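"""Data containers, file I/O, and shared preprocessing for developmental
expression series.

The central object is :class:`ExpressionDataset`: a gene-by-sample matrix of
expression values together with per-sample metadata (species, brain region,
age in postconception days).  All downstream stages — demarcation clustering,
dynamic-network-biomarker scanning, heterochrony, differential expression,
and co-expression networks — consume and return this type.

Expression matrices are plain TSV (genes in rows, header row of sample ids);
sample metadata is TSV with columns ``sample_id``, ``species``, ``region``,
``age_pcd`` and optional ``stage``; gene sets use the GMT format.
"""

from __future__ import annotations

import dataclasses
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

SPECIES = ("human", "macaque")
STAGES = ("early", "late")

#: Days per postconception week; ages are stored in postconception days (PCD).
DAYS_PER_PCW = 7.0


class DataError(ValueError):
    """Raised for malformed input data (bad files, inconsistent metadata)."""


@dataclass(frozen=True)
class SampleMeta:
    """Metadata for one expression profile.

    ``age_pcd`` is the age in postconception days; for postnatal samples the
    gestation length is included so that a single monotone developmental
    clock covers pre- and postnatal ages.
    """

    sample_id: str
    species: str
    region: str
    age_pcd: float
    stage: str | None = None

    def __post_init__(self) -> None:
        if self.species not in SPECIES:
            raise DataError(f"unknown species {self.species!r}; expected one of {SPECIES}")
        if not np.isfinite(self.age_pcd) or self.age_pcd <= 0:
            raise DataError(f"age_pcd must be a positive number, got {self.age_pcd!r}")
        if self.stage is not None and self.stage not in STAGES:
            raise DataError(f"stage must be one of {STAGES} or None, got {self.stage!r}")


@dataclass
class ExpressionDataset:
    """Gene-by-sample expression matrix with sample metadata.

    Parameters
    ----------
    values
        Array of shape ``(n_genes, n_samples)``.
    gene_ids
        Unique gene identifiers, one per row.
    samples
        One :class:`SampleMeta` per column, in column order.
    scale
        ``"linear"``, ``"log2"``, or ``"log2z"`` (log2 then per-gene
        z-scored).  Recorded so stages can enforce their preconditions.
    constant_genes
        Gene ids whose row was constant when z-scoring was applied (those
        rows are all-zero after the transform).
    """

    values: np.ndarray
    gene_ids: list[str]
    samples: list[SampleMeta]
    scale: str = "linear"
    constant_genes: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.gene_ids = list(self.gene_ids)
        self.samples = list(self.samples)
        if self.values.ndim != 2:
            raise DataError("values must be a 2-D matrix (genes x samples)")
        if self.values.shape[0] != len(self.gene_ids):
            raise DataError("row count does not match number of gene ids")
        if self.values.shape[1] != len(self.samples):
            raise DataError("column count does not match number of samples")
        if len(set(self.gene_ids)) != len(self.gene_ids):
            raise DataError("duplicate gene id")
        ids = [s.sample_id for s in self.samples]
        if len(set(ids)) != len(ids):
            raise DataError("duplicate sample id")
        if self.scale not in ("linear", "log2", "log2z"):
            raise DataError(f"unknown scale {self.scale!r}")

    # -- conveniences -----------------------------------------------------

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    @property
    def sample_ids(self) -> list[str]:
        return [s.sample_id for s in self.samples]

    @property
    def ages(self) -> np.ndarray:
        return np.array([s.age_pcd for s in self.samples], dtype=float)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.gene_ids, columns=self.sample_ids)

    def meta_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "sample_id": self.sample_ids,
                "species": [s.species for s in self.samples],
                "region": [s.region for s in self.samples],
                "age_pcd": self.ages,
                "stage": [s.stage if s.stage is not None else "" for s in self.samples],
            }
        )

    def subset_genes(self, gene_ids: Sequence[str]) -> "ExpressionDataset":
        index = {g: i for i, g in enumerate(self.gene_ids)}
        try:
            rows = [index[g] for g in gene_ids]
        except KeyError as exc:
            raise DataError(f"unknown gene id {exc.args[0]!r}") from None
        return dataclasses.replace(
            self,
            values=self.values[rows, :],
            gene_ids=list(gene_ids),
            constant_genes=self.constant_genes & set(gene_ids),
        )

    def subset_samples(self, indices: Sequence[int]) -> "ExpressionDataset":
        indices = list(indices)
        return dataclasses.replace(
            self,
            values=self.values[:, indices],
            samples=[self.samples[i] for i in indices],
        )

    def sorted_by_age(self) -> "ExpressionDataset":
        """Return a copy with columns stably sorted by increasing age."""
        order = np.argsort(self.ages, kind="stable")
        return self.subset_samples(order.tolist())


@dataclass
class GeneSetCollection:
    """Named gene sets (e.g. pathway, marker, or regulatory-region lists)."""

    sets: dict[str, list[str]]
    universe: list[str] | None = None

    def __post_init__(self) -> None:
        for name, members in self.sets.items():
            if not members:
                raise DataError(f"gene set {name!r} is empty")
            if len(set(members)) != len(members):
                raise DataError(f"gene set {name!r} has duplicate members")

    def restricted_to(self, universe: Iterable[str]) -> "GeneSetCollection":
        uni = list(dict.fromkeys(universe))
        uniset = set(uni)
        sets = {}
        for name, members in self.sets.items():
            kept = [g for g in members if g in uniset]
            if kept:
                sets[name] = kept
        return GeneSetCollection(sets=sets, universe=uni)


# ---------------------------------------------------------------------------
# File I/O
# ---------------------------------------------------------------------------

_META_REQUIRED = ("sample_id", "species", "region", "age_pcd")


def load_expression(matrix_path: str | Path, meta_path: str | Path) -> ExpressionDataset:
    """Load an expression TSV plus its sample-metadata TSV.

    The matrix must have gene ids in the first column and one header column
    per sample; the metadata must list exactly the samples present in the
    matrix.  Columns are reordered to follow the metadata row order.
    """
    matrix = pd.read_csv(matrix_path, sep="\t", index_col=0)
    meta = pd.read_csv(meta_path, sep="\t", dtype={"sample_id": str})
    missing = [c for c in _META_REQUIRED if c not in meta.columns]
    if missing:
        raise DataError(f"metadata missing column(s): {', '.join(missing)}")
    if matrix.index.duplicated().any():
        dupes = matrix.index[matrix.index.duplicated()].unique().tolist()
        raise DataError(f"duplicate gene id: {dupes[:5]}")
    non_numeric = [c for c in matrix.columns if not np.issubdtype(matrix[c].dtype, np.number)]
    if non_numeric or matrix.isna().any().any():
        raise DataError("non-numeric cell in expression matrix")

    matrix_ids = set(map(str, matrix.columns))
    meta_ids = list(meta["sample_id"])
    if len(set(meta_ids)) != len(meta_ids):
        raise DataError("duplicate sample id in metadata")
    if set(meta_ids) != matrix_ids:
        raise DataError(
            "sample mismatch between matrix and metadata: "
            f"matrix-only={sorted(matrix_ids - set(meta_ids))[:5]}, "
            f"meta-only={sorted(set(meta_ids) - matrix_ids)[:5]}"
        )

    samples = []
    for _, row in meta.iterrows():
        stage = row.get("stage")
        if pd.isna(stage) or stage == "":
            stage = None
        samples.append(
            SampleMeta(
                sample_id=str(row["sample_id"]),
                species=str(row["species"]),
                region=str(row["region"]),
                age_pcd=float(row["age_pcd"]),
                stage=stage,
            )
        )
    matrix = matrix[[s.sample_id for s in samples]]
    return ExpressionDataset(
        values=matrix.to_numpy(dtype=float),
        gene_ids=[str(g) for g in matrix.index],
        samples=samples,
    )


def write_expression(ds: ExpressionDataset, matrix_path: str | Path, meta_path: str | Path) -> None:
    """Write a dataset back to the TSV pair read by :func:`load_expression`."""
    ds.to_frame().to_csv(matrix_path, sep="\t", float_format="%.10g")
    ds.meta_frame().to_csv(meta_path, sep="\t", index=False, float_format="%.10g")


def read_gmt(path: str | Path) -> GeneSetCollection:
    sets: dict[str, list[str]] = {}
    for line in Path(path).read_text().splitlines():
        if not line.strip():
            continue
        parts = line.rstrip("\n").split("\t")
        if len(parts) < 3:
            raise DataError(f"malformed GMT line (need name, description, >=1 member): {line[:80]!r}")
        name, _description, *members = parts
        members = [m for m in members if m]
        if name in sets:
            raise DataError(f"duplicate gene-set name {name!r}")
        sets[name] = members
    return GeneSetCollection(sets=sets)


def write_gmt(collection: GeneSetCollection, path: str | Path, description: str = "") -> None:
    lines = [
        "\t".join([name, description, *members])
        for name, members in collection.sets.items()
    ]
    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# Preprocessing transforms
# ---------------------------------------------------------------------------


def filter_expressed(ds: ExpressionDataset, min_fraction: float = 0.8) -> ExpressionDataset:
    """Keep genes with expression > 0 in at least ``min_fraction`` of samples.

    This is the standard noise filter applied to linear-scale intensities
    before any log transform; gene order is preserved.  An empty result is
    allowed but triggers a warning.
    """
    if ds.scale != "linear":
        raise DataError("filter_expressed expects linear-scale values")
    frac = (ds.values > 0).mean(axis=1)
    keep = frac >= min_fraction
    if not keep.any():
        warnings.warn("filter_expressed removed every gene", stacklevel=2)
    kept_ids = [g for g, k in zip(ds.gene_ids, keep) if k]
    return dataclasses.replace(ds, values=ds.values[keep, :], gene_ids=kept_ids)


def log2_transform(ds: ExpressionDataset, pseudocount: float = 1.0) -> ExpressionDataset:
    """log2(x + pseudocount) on linear-scale values."""
    if ds.scale != "linear":
        raise DataError("log2_transform expects linear-scale values")
    if (ds.values < 0).any():
        raise DataError("negative expression value")
    return dataclasses.replace(ds, values=np.log2(ds.values + pseudocount), scale="log2")


def log2_z_transform(
    ds: ExpressionDataset,
    pseudocount: float = 1.0,
    population_sd: bool = True,
) -> ExpressionDataset:
    """log2 then per-gene z-transform (row mean 0, variance 1).

    The z-score divides by the population standard deviation by default
    (``ddof=0``); set ``population_sd=False`` for the sample-sd convention.
    Constant rows become all-zero rows and are recorded in
    ``constant_genes``.
    """
    logged = log2_transform(ds, pseudocount=pseudocount)
    vals = logged.values
    mean = vals.mean(axis=1, keepdims=True)
    sd = vals.std(axis=1, ddof=0 if population_sd else 1, keepdims=True)
    constant = sd[:, 0] < 1e-12
    safe_sd = np.where(constant[:, None], 1.0, sd)
    z = (vals - mean) / safe_sd
    z[constant, :] = 0.0
    flagged = frozenset(g for g, c in zip(ds.gene_ids, constant) if c)
    return dataclasses.replace(logged, values=z, scale="log2z", constant_genes=flagged)


def split_by_age(
    ds: ExpressionDataset, boundary_pcd: float
) -> tuple[ExpressionDataset, ExpressionDataset]:
    """Split samples into an early (age <= boundary) and late (>) dataset.

    A sample whose age equals the boundary goes to the early side — the
    demarcation age labels the last early time point.  Both sides must be
    non-empty, i.e. the boundary must lie inside the observed age range.
    """
    ages = ds.ages
    if boundary_pcd < ages.min() or boundary_pcd >= ages.max():
        raise DataError(
            f"boundary {boundary_pcd} outside observed age range "
            f"[{ages.min():g}, {ages.max():g})"
        )
    early_idx = np.flatnonzero(ages <= boundary_pcd)
    late_idx = np.flatnonzero(ages > boundary_pcd)
    if early_idx.size == 0 or late_idx.size == 0:
        raise DataError("split_by_age produced an empty side")

    def _with_stage(sub: ExpressionDataset, stage: str) -> ExpressionDataset:
        return dataclasses.replace(
            sub, samples=[dataclasses.replace(s, stage=stage) for s in sub.samples]
        )

    return (
        _with_stage(ds.subset_samples(early_idx.tolist()), "early"),
        _with_stage(ds.subset_samples(late_idx.tolist()), "late"),
    )
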