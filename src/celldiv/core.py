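"""Shared data model and file I/O.

The central container is :class:`ExpressionMatrix`: a gene x sample matrix of
non-negative expression values (counts, FPKM, CPM, or their log2(x+1)
transforms) together with a sample annotation table mapping each sample to a
cell population, an integer acquisition order (used to pick the most recent
replicates), and an optional neuronal flag.

Coordinate convention for junctions: positions are 0-based half-open; on the
'+' strand the donor is the smaller coordinate, on the '-' strand the larger.
Input junction tables are expected to already carry donor/acceptor columns,
so the convention only matters for how those columns were produced upstream.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import io as spio
from scipy import sparse

__all__ = [
    "ExpressionMatrix",
    "GeneTable",
    "PopulationMatrix",
    "GeneFamilyCollection",
    "JunctionTable",
    "load_expression",
    "load_gene_table",
    "load_gene_families",
    "write_gene_families",
    "load_junctions",
    "to_fpkm",
    "to_cpm",
    "log2p1",
    "population_means",
]

#: recognized expression units
UNITS = ("count", "fpkm", "cpm", "log2fpkm1", "log2cpm1")
LOG_UNITS = ("log2fpkm1", "log2cpm1")


class FormatError(ValueError):
    """Raised when an input file cannot be parsed into the expected shape."""


class ValidationError(ValueError):
    """Raised when parsed data violate a container invariant."""


@dataclass
class ExpressionMatrix:
    """Gene x sample expression matrix plus sample annotations.

    Parameters
    ----------
    values
        DataFrame indexed by gene id with one column per sample.
    samples
        DataFrame indexed by sample id with columns ``population`` (str),
        ``order`` (int acquisition rank) and optionally ``is_neuronal`` (bool).
    unit
        One of ``count, fpkm, cpm, log2fpkm1, log2cpm1``.
    """

    values: pd.DataFrame
    samples: pd.DataFrame
    unit: str = "count"

    def __post_init__(self) -> None:
        if self.unit not in UNITS:
            raise ValidationError(f"unknown unit {self.unit!r}; expected one of {UNITS}")
        if not self.values.index.is_unique:
            dup = self.values.index[self.values.index.duplicated()][:3].tolist()
            raise ValidationError(f"duplicate gene ids, e.g. {dup}")
        if not self.values.columns.is_unique:
            raise ValidationError("duplicate sample ids in matrix columns")
        missing = self.values.columns.difference(self.samples.index)
        if len(missing):
            raise ValidationError(
                f"samples absent from annotation table: {list(missing[:5])}"
            )
        if "population" not in self.samples.columns:
            raise ValidationError("sample table must have a 'population' column")
        if "order" not in self.samples.columns:
            self.samples = self.samples.assign(order=np.arange(len(self.samples)))
        # keep annotations aligned and restricted to the matrix columns
        self.samples = self.samples.loc[self.values.columns]
        vals = self.values.to_numpy()
        if not np.issubdtype(vals.dtype, np.number):
            raise FormatError("expression matrix contains non-numeric entries")
        if np.nanmin(vals) < 0:
            raise ValidationError("negative expression values")

    # -- convenience accessors -------------------------------------------------
    @property
    def genes(self) -> pd.Index:
        return self.values.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.values.columns

    @property
    def sample_population(self) -> pd.Series:
        return self.samples["population"]

    @property
    def sample_order(self) -> pd.Series:
        return self.samples["order"]

    @property
    def populations(self) -> list[str]:
        seen: dict[str, None] = {}
        for p in self.samples["population"]:
            seen.setdefault(p, None)
        return list(seen)

    def subset_samples(self, sample_ids) -> "ExpressionMatrix":
        return ExpressionMatrix(
            self.values[list(sample_ids)], self.samples.loc[list(sample_ids)], self.unit
        )

    def subset_genes(self, genes) -> "ExpressionMatrix":
        return ExpressionMatrix(self.values.loc[list(genes)], self.samples, self.unit)


@dataclass
class GeneTable:
    """Per-gene annotation: genomic length (bp) and optional family names."""

    table: pd.DataFrame  # indexed by gene id; columns: length[, ...]

    def __post_init__(self) -> None:
        if "length" not in self.table.columns:
            raise ValidationError("gene table must have a 'length' column")
        if not self.table.index.is_unique:
            raise ValidationError("duplicate gene ids in gene table")
        if (self.table["length"] < 1).any():
            raise ValidationError("gene lengths must be >= 1 bp")

    @property
    def lengths(self) -> pd.Series:
        return self.table["length"]

    def __len__(self) -> int:
        return len(self.table)


@dataclass
class PopulationMatrix:
    """Gene x population matrix of replicate-averaged expression."""

    values: pd.DataFrame  # genes x populations
    n_replicates: pd.Series  # per population
    unit: str = "fpkm"
    is_neuronal: pd.Series | None = None  # per population

    def __post_init__(self) -> None:
        if not self.values.columns.is_unique:
            raise ValidationError("duplicate population labels")
        self.n_replicates = self.n_replicates.loc[self.values.columns]
        if self.is_neuronal is not None:
            self.is_neuronal = self.is_neuronal.loc[self.values.columns].astype(bool)

    @property
    def populations(self) -> pd.Index:
        return self.values.columns

    @property
    def genes(self) -> pd.Index:
        return self.values.index


@dataclass
class GeneFamilyCollection:
    """Named gene families (GMT-style), e.g. curated gene groups."""

    families: dict[str, frozenset]
    source: str = ""

    def __post_init__(self) -> None:
        empty = [k for k, v in self.families.items() if not v]
        if empty:
            raise ValidationError(f"empty families: {empty[:5]}")

    def restricted_to(self, universe) -> "GeneFamilyCollection":
        """Intersect every family with a gene universe, dropping empty results."""
        uni = frozenset(universe)
        fams = {k: v & uni for k, v in self.families.items()}
        return GeneFamilyCollection({k: v for k, v in fams.items() if v}, self.source)

    def __getitem__(self, name: str) -> frozenset:
        return self.families[name]

    def __len__(self) -> int:
        return len(self.families)

    def items(self):
        return self.families.items()


@dataclass
class JunctionTable:
    """Splice-junction read counts, one row per (sample, junction).

    Columns: chrom, donor, acceptor, strand, sample, count and optionally gene.
    """

    table: pd.DataFrame

    REQUIRED = ("chrom", "donor", "acceptor", "strand", "sample", "count")

    def __post_init__(self) -> None:
        missing = [c for c in self.REQUIRED if c not in self.table.columns]
        if missing:
            raise ValidationError(f"junction table missing columns {missing}")
        if (self.table["count"] < 0).any():
            raise ValidationError("negative junction counts")
        if not self.table["strand"].isin(["+", "-"]).all():
            raise ValidationError("strand must be '+' or '-'")
        key = ["sample", "chrom", "strand", "donor", "acceptor"]
        if self.table.duplicated(subset=key).any():
            raise ValidationError("duplicate (sample, junction) rows")

    def __len__(self) -> int:
        return len(self.table)


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------

def _read_sample_table(samples_path) -> pd.DataFrame:
    df = pd.read_csv(samples_path, sep="\t")
    if "sample" not in df.columns or "population" not in df.columns:
        raise FormatError("sample table needs at least 'sample' and 'population' columns")
    df = df.set_index("sample")
    if "is_neuronal" in df.columns:
        df["is_neuronal"] = df["is_neuronal"].astype(bool)
    return df


def load_expression(
    matrix_path,
    samples_path,
    unit: str = "count",
    rows_path=None,
    cols_path=None,
) -> ExpressionMatrix:
    """Load an expression matrix with its sample annotation table.

    ``matrix_path`` is either a tab-delimited file (gene rows, sample columns,
    header row, first column gene id) or a matrix-market ``.mtx`` file with
    side files listing row (gene) and column (sample) ids one per line.  Side
    files default to ``<stem>_rows.txt`` / ``<stem>_cols.txt``.
    """
    matrix_path = Path(matrix_path)
    if matrix_path.suffix == ".mtx":
        rows_path = Path(rows_path) if rows_path else matrix_path.with_name(matrix_path.stem + "_rows.txt")
        cols_path = Path(cols_path) if cols_path else matrix_path.with_name(matrix_path.stem + "_cols.txt")
        genes = rows_path.read_text().split()
        cols = cols_path.read_text().split()
        mat = spio.mmread(matrix_path)
        if sparse.issparse(mat):
            mat = mat.toarray()
        mat = np.asarray(mat)
        if mat.shape != (len(genes), len(cols)):
            raise FormatError(
                f"matrix shape {mat.shape} does not match side files "
                f"({len(genes)} genes, {len(cols)} samples)"
            )
        values = pd.DataFrame(mat, index=pd.Index(genes, name="gene"), columns=cols)
    else:
        values = pd.read_csv(matrix_path, sep="\t", index_col=0)
        values.index.name = "gene"
    samples = _read_sample_table(samples_path)
    return ExpressionMatrix(values, samples, unit=unit)


def load_gene_table(path) -> GeneTable:
    """Read a tab-delimited gene annotation table with columns gene, length."""
    df = pd.read_csv(path, sep="\t")
    if "gene" not in df.columns:
        raise FormatError("gene table needs a 'gene' column")
    return GeneTable(df.set_index("gene"))


def load_gene_families(path, source: str | None = None) -> GeneFamilyCollection:
    """Read a GMT file: per line ``name <tab> description <tab> member...``."""
    fams: dict[str, frozenset] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            parts = line.split("\t")
            if len(parts) < 3 or not any(p.strip() for p in parts[2:]):
                warnings.warn(f"skipping empty family at line {lineno}")
                continue
            name = parts[0]
            members = frozenset(p for p in parts[2:] if p.strip())
            fams[name] = members
    return GeneFamilyCollection(fams, source or str(path))


def write_gene_families(fams: GeneFamilyCollection, path) -> None:
    with open(path, "w") as fh:
        for name, members in fams.items():
            fh.write("\t".join([name, fams.source or "na", *sorted(members)]) + "\n")


def load_junctions(path) -> JunctionTable:
    """Read a junction TSV: chrom, donor, acceptor, strand, sample, count[, gene]."""
    df = pd.read_csv(path, sep="\t")
    return JunctionTable(df)


# ---------------------------------------------------------------------------
# transforms
# ---------------------------------------------------------------------------

def to_fpkm(m: ExpressionMatrix, gene_table: GeneTable) -> ExpressionMatrix:
    """Convert raw counts to FPKM: count / (length/1e3) / (library/1e6)."""
    if m.unit != "count":
        raise ValidationError(f"to_fpkm expects counts, got unit {m.unit!r}")
    missing = m.genes.difference(gene_table.table.index)
    if len(missing):
        raise ValidationError(f"genes without length annotation: {list(missing[:5])}")
    lib = m.values.sum(axis=0)
    if (lib == 0).any():
        bad = lib.index[lib == 0].tolist()
        raise ValidationError(f"zero library size for samples {bad[:5]}")
    len_kb = gene_table.lengths.loc[m.genes] / 1e3
    vals = m.values.div(len_kb, axis=0).div(lib / 1e6, axis=1)
    return ExpressionMatrix(vals, m.samples, unit="fpkm")


def to_cpm(m: ExpressionMatrix) -> ExpressionMatrix:
    """Convert raw counts to counts-per-million."""
    if m.unit != "count":
        raise ValidationError(f"to_cpm expects counts, got unit {m.unit!r}")
    lib = m.values.sum(axis=0)
    if (lib == 0).any():
        raise ValidationError("zero library size")
    return ExpressionMatrix(m.values.div(lib / 1e6, axis=1), m.samples, unit="cpm")


def log2p1(m: ExpressionMatrix) -> ExpressionMatrix:
    """log2(x+1)-transform a linear-unit matrix (the log scale used throughout)."""
    if m.unit in LOG_UNITS:
        return m
    new_unit = {"fpkm": "log2fpkm1", "cpm": "log2cpm1", "count": "log2cpm1"}[m.unit]
    if m.unit == "count":
        warnings.warn("log-transforming raw counts; consider converting to CPM/FPKM first")
    return ExpressionMatrix(np.log2(m.values + 1.0), m.samples, unit=new_unit)


def select_recent_replicates(m: ExpressionMatrix, max_replicates: int) -> ExpressionMatrix:
    """Keep, per population, the ``max_replicates`` samples of highest order.

    Mirrors the study design of equalizing power by using the most recent
    two replicates of every population.
    """
    keep: list[str] = []
    for _, grp in m.samples.groupby("population", sort=False):
        ordered = grp.sort_values("order", kind="mergesort")
        keep.extend(ordered.index[-max_replicates:])
    keep = [s for s in m.sample_ids if s in set(keep)]
    return m.subset_samples(keep)


def population_means(
    m: ExpressionMatrix,
    log_transform: bool = False,
    max_replicates: int | None = None,
) -> PopulationMatrix:
    """Average replicates within each population.

    With ``log_transform`` values go through log2(x+1) first; with
    ``max_replicates`` only the most recent (highest ``order``) replicates of
    each population are used.
    """
    if max_replicates is not None:
        m = select_recent_replicates(m, max_replicates)
    if log_transform:
        m = log2p1(m)
    pops = m.populations
    cols = {}
    nrep = {}
    for pop in pops:
        ids = m.samples.index[m.samples["population"] == pop]
        if len(ids) == 0:
            raise ValidationError(f"population {pop!r} has no samples")
        cols[pop] = m.values[ids].mean(axis=1)
        nrep[pop] = len(ids)
    is_neu = None
    if "is_neuronal" in m.samples.columns:
        flags = m.samples.groupby("population", sort=False)["is_neuronal"].first()
        is_neu = flags.loc[pops]
    return PopulationMatrix(
        pd.DataFrame(cols, index=m.genes),
        pd.Series(nrep),
        unit=m.unit,
        is_neuronal=is_neu,
    )
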