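"""Typed containers and TSV readers/writers for the pipeline's tables.

Three table kinds flow through the analysis:

* gene-level TPM expression matrices (genes x samples), one per sequencing
  layer (metagenome ``MG`` or metatranscriptome ``MT``);
* a gene -> KEGG-module annotation table (a two-column projection of
  eggnog-mapper output);
* taxon relative-abundance tables (taxa x samples), Kraken2/Bracken style,
  with GTDB taxonomy strings.

All files are plain TSV, UTF-8, ``.`` decimal separator. Floats are written
with ``repr`` so a write/read round trip reproduces values bit-identically.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Literal

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

Layer = Literal["MG", "MT"]

#: The four KEGG modules of the rumen methanogenesis pathway:
#: methyl-coenzyme M reductase, acetoclastic, cofactor synthesis /
#: acetyl-CoA decarbonylase, and hydrogenotrophic / coenzyme M biosynthesis.
METHANOGENESIS_MODULES = frozenset({"M00356", "M00357", "M00563", "M00567"})


class ValidationError(ValueError):
    """Raised when a table violates a structural invariant."""


def _check_layer(layer: str) -> str:
    if layer not in ("MG", "MT"):
        raise ValidationError(f"layer must be 'MG' or 'MT', got {layer!r}")
    return layer


def _check_unique(names, what: str) -> None:
    seen: set[str] = set()
    for name in names:
        if name in seen:
            raise ValidationError(f"duplicate {what}: {name!r}")
        seen.add(name)


@dataclass
class ExpressionMatrix:
    """Gene-level TPM values for one sequencing layer.

    Parameters
    ----------
    gene_ids : list of str
        Unique gene identifiers, one per row.
    sample_ids : list of str
        Unique sample identifiers, one per column.
    values : ndarray of shape (n_genes, n_samples)
        Nonnegative, finite TPM values.
    layer : {"MG", "MT"}
        Sequencing layer the matrix was quantified from.
    """

    gene_ids: list[str]
    sample_ids: list[str]
    values: np.ndarray
    layer: Layer

    def __post_init__(self) -> None:
        _check_layer(self.layer)
        _check_unique(self.gene_ids, "gene ID")
        _check_unique(self.sample_ids, "sample ID")
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.gene_ids), len(self.sample_ids)):
            raise ValidationError(
                f"value matrix shape {self.values.shape} does not match "
                f"({len(self.gene_ids)} genes, {len(self.sample_ids)} samples)"
            )
        if self.values.size and not np.all(np.isfinite(self.values)):
            g, s = np.argwhere(~np.isfinite(self.values))[0]
            raise ValidationError(
                f"non-finite value at gene {self.gene_ids[g]!r}, "
                f"sample {self.sample_ids[s]!r}"
            )
        if self.values.size and self.values.min() < 0:
            g, s = np.argwhere(self.values < 0)[0]
            raise ValidationError(
                f"negative TPM at gene {self.gene_ids[g]!r}, "
                f"sample {self.sample_ids[s]!r}"
            )

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def to_frame(self) -> pd.DataFrame:
        """Return a genes x samples DataFrame view of the matrix."""
        return pd.DataFrame(self.values, index=self.gene_ids, columns=self.sample_ids)

    def subset_genes(self, gene_ids: list[str]) -> "ExpressionMatrix":
        """Return a copy restricted to ``gene_ids`` (kept in the given order)."""
        index = {g: i for i, g in enumerate(self.gene_ids)}
        missing = [g for g in gene_ids if g not in index]
        if missing:
            raise ValidationError(f"genes not in matrix: {missing[:5]}")
        rows = [index[g] for g in gene_ids]
        return ExpressionMatrix(
            list(gene_ids), list(self.sample_ids), self.values[rows], self.layer
        )


@dataclass
class ModuleCatalog:
    """Mapping from gene identifiers to the KEGG modules they belong to.

    A gene may belong to several modules; ``module_ids`` is the union of all
    assigned modules.
    """

    assignments: dict[str, frozenset[str]]
    module_ids: frozenset[str] = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        for gene, modules in self.assignments.items():
            if not modules:
                raise ValidationError(f"gene {gene!r} maps to no module")
            self.assignments[gene] = frozenset(modules)
        union = frozenset().union(*self.assignments.values()) if self.assignments else frozenset()
        if self.module_ids is None:
            self.module_ids = union
        elif frozenset(self.module_ids) != union:
            raise ValidationError("module_ids must equal the union of assignments")
        else:
            self.module_ids = frozenset(self.module_ids)

    def genes_in_module(self, module_id: str) -> list[str]:
        if module_id not in self.module_ids:
            raise ValidationError(f"unknown module: {module_id!r}")
        return sorted(g for g, m in self.assignments.items() if module_id in m)

    def genes_in_any(self, module_ids) -> set[str]:
        """Genes annotated to at least one of the given modules."""
        wanted = frozenset(module_ids)
        return {g for g, m in self.assignments.items() if m & wanted}


@dataclass
class TaxonTable:
    """Taxon relative abundances (fractions) for one sequencing layer.

    ``taxon_names`` are GTDB-style strings, e.g. ``"Treponema_D sp004554075"``;
    whitespace and suffixes are preserved verbatim and matching elsewhere is
    exact-string. ``uncultivated`` flags default to False and are derived
    later from GTDB placeholder name patterns.
    """

    taxon_names: list[str]
    sample_ids: list[str]
    abundance: np.ndarray
    layer: Layer
    uncultivated: np.ndarray = None  # type: ignore[assignment]

    def __post_init__(self) -> None:
        _check_layer(self.layer)
        _check_unique(self.taxon_names, "taxon name")
        _check_unique(self.sample_ids, "sample ID")
        self.abundance = np.asarray(self.abundance, dtype=float)
        if self.abundance.shape != (len(self.taxon_names), len(self.sample_ids)):
            raise ValidationError(
                f"abundance shape {self.abundance.shape} does not match "
                f"({len(self.taxon_names)} taxa, {len(self.sample_ids)} samples)"
            )
        if self.abundance.size and (
            not np.all(np.isfinite(self.abundance)) or self.abundance.min() < 0
        ):
            raise ValidationError("abundances must be finite and nonnegative")
        if self.abundance.size and self.abundance.max() > 1 + 1e-6:
            raise ValidationError("abundances must be fractions in [0, 1]")
        sums = self.abundance.sum(axis=0)
        if self.abundance.size and np.any(sums > 1 + 1e-6):
            bad = self.sample_ids[int(np.argmax(sums))]
            raise ValidationError(f"column sum exceeds 1 for sample {bad!r}")
        if self.uncultivated is None:
            self.uncultivated = np.zeros(len(self.taxon_names), dtype=bool)
        else:
            self.uncultivated = np.asarray(self.uncultivated, dtype=bool)
            if self.uncultivated.shape != (len(self.taxon_names),):
                raise ValidationError("uncultivated flags must match taxon count")

    @property
    def n_taxa(self) -> int:
        return len(self.taxon_names)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.abundance, index=self.taxon_names, columns=self.sample_ids
        )


# ---------------------------------------------------------------------------
# readers
# ---------------------------------------------------------------------------


def _read_tsv(path, index_name: str) -> pd.DataFrame:
    frame = pd.read_csv(
        path, sep="\t", header=0, dtype={0: str}, float_precision="round_trip"
    )
    if frame.columns[0] != index_name:
        raise ValidationError(
            f"{path}: first column must be {index_name!r}, got {frame.columns[0]!r}"
        )
    for col in frame.columns[1:]:
        coerced = pd.to_numeric(frame[col], errors="coerce")
        if coerced.isna().any() and not frame[col].isna().any():
            row = int(coerced.isna().idxmax())
            raise ValidationError(
                f"{path}: non-numeric value at row {row + 2}, column {col!r}"
            )
        frame[col] = coerced
    return frame


def read_expression_table(path, layer: Layer) -> ExpressionMatrix:
    """Read a gene-level TPM table (TSV, header ``gene_id<TAB>sample...``).

    Row and column order are preserved from the file. Duplicate gene or
    sample IDs, and negative or non-numeric cells, raise
    :class:`ValidationError` naming the offender.
    """
    frame = _read_tsv(path, "gene_id")
    return ExpressionMatrix(
        gene_ids=frame["gene_id"].tolist(),
        sample_ids=list(frame.columns[1:]),
        values=frame.iloc[:, 1:].to_numpy(dtype=float),
        layer=layer,
    )


def read_module_annotation(path) -> ModuleCatalog:
    """Read a gene -> module TSV (header ``gene_id<TAB>module_id``).

    One row per (gene, module) pair; genes on multiple rows aggregate into
    sets. The catalog is not restricted to the four methanogenesis modules.
    """
    frame = pd.read_csv(path, sep="\t", header=0, dtype=str, keep_default_na=False)
    expected = ["gene_id", "module_id"]
    if list(frame.columns[:2]) != expected:
        raise ValidationError(f"{path}: expected columns {expected}, got {list(frame.columns)}")
    assignments: dict[str, set[str]] = {}
    for i, (gene, module) in enumerate(zip(frame["gene_id"], frame["module_id"])):
        if not gene or not module:
            raise ValidationError(f"{path}: empty gene_id or module_id at line {i + 2}")
        assignments.setdefault(gene, set()).add(module)
    return ModuleCatalog({g: frozenset(m) for g, m in assignments.items()})


def read_taxon_table(path, layer: Layer) -> TaxonTable:
    """Read a taxon table (TSV, header ``taxon<TAB>sample...``).

    Columns may hold raw counts or fractions: any column whose sum exceeds
    1 + 1e-6 is renormalized to fractions (counts auto-detection) and a note
    is logged. Uncultivated flags are initialized to False.
    """
    frame = _read_tsv(path, "taxon")
    values = frame.iloc[:, 1:].to_numpy(dtype=float)
    if values.size and values.min() < 0:
        t, s = np.argwhere(values < 0)[0]
        raise ValidationError(
            f"{path}: negative abundance at taxon {frame.iloc[t, 0]!r}, "
            f"column {frame.columns[s + 1]!r}"
        )
    sums = values.sum(axis=0)
    needs_norm = sums > 1 + 1e-6
    if values.size and needs_norm.any():
        logger.info(
            "%s: %d column(s) look like counts; renormalizing to fractions",
            path,
            int(needs_norm.sum()),
        )
        values = values.copy()
        values[:, needs_norm] /= sums[needs_norm]
    return TaxonTable(
        taxon_names=frame["taxon"].tolist(),
        sample_ids=list(frame.columns[1:]),
        abundance=values,
        layer=layer,
    )


# ---------------------------------------------------------------------------
# writers
# ---------------------------------------------------------------------------


def _write_table(path, index_name: str, row_names, sample_ids, values) -> None:
    # repr() round-trips doubles exactly; pandas formatting does not guarantee it
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("\t".join([index_name, *sample_ids]) + "\n")
        for name, row in zip(row_names, values):
            fh.write(name + "\t" + "\t".join(repr(float(v)) for v in row) + "\n")


def write_expression_table(matrix: ExpressionMatrix, path) -> None:
    """Write an expression matrix as TSV with full-precision floats."""
    _write_table(path, "gene_id", matrix.gene_ids, matrix.sample_ids, matrix.values)


def write_taxon_table(table: TaxonTable, path) -> None:
    """Write a taxon table as TSV with full-precision floats."""
    _write_table(path, "taxon", table.taxon_names, table.sample_ids, table.abundance)


def write_module_annotation(catalog: ModuleCatalog, path) -> None:
    """Write a catalog as a (gene, module) pair table, sorted for stability."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("gene_id\tmodule_id\n")
        for gene in sorted(catalog.assignments):
            for module in sorted(catalog.assignments[gene]):
                fh.write(f"{gene}\t{module}\n")
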