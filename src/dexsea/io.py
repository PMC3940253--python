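"""Readers and writers for expression matrices, sample designs, GMT gene sets,
gene lists and homolog maps.

All tabular formats are plain TSV with a header line. Gene identifiers are
matched exactly (case-sensitive) after stripping surrounding whitespace.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

TISSUES = ("blood", "cerebellum")
GENOTYPES = ("transgenic", "wildtype")


class FormatError(ValueError):
    """Raised when an input file violates its format contract."""


@dataclass
class ExpressionMatrix:
    """Genes-by-samples expression values.

    ``data`` is a DataFrame with gene ids as the index and sample ids as
    columns. ``scale`` records whether values are linear intensities
    (non-negative) or log2.
    """

    data: pd.DataFrame
    scale: str = "linear"  # "linear" | "log2"

    def __post_init__(self) -> None:
        if self.scale not in ("linear", "log2"):
            raise ValueError(f"scale must be 'linear' or 'log2', got {self.scale!r}")
        idx = self.data.index
        cols = self.data.columns
        if idx.has_duplicates:
            dups = idx[idx.duplicated()].unique().tolist()
            raise FormatError(f"duplicate gene ids: {dups}")
        if cols.has_duplicates:
            dups = cols[cols.duplicated()].unique().tolist()
            raise FormatError(f"duplicate sample ids: {dups}")
        if self.data.isna().any().any():
            r, c = np.argwhere(self.data.isna().to_numpy())[0]
            raise FormatError(
                f"missing value at gene {idx[r]!r}, sample {cols[c]!r}"
            )
        if self.scale == "linear" and (self.data.to_numpy() < 0).any():
            raise FormatError("linear-scale matrix contains negative values")

    @property
    def gene_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.columns)

    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy(dtype=float)

    def to_log2(self) -> "ExpressionMatrix":
        """Return a log2-scale copy (log2(x + 1) on linear input)."""
        if self.scale == "log2":
            return self
        return ExpressionMatrix(np.log2(self.data + 1.0), scale="log2")


@dataclass
class SampleDesign:
    """Per-sample tissue and genotype factors."""

    table: pd.DataFrame  # index: sample id; columns: tissue, genotype

    def __post_init__(self) -> None:
        missing = {"tissue", "genotype"} - set(self.table.columns)
        if missing:
            raise FormatError(f"design is missing columns: {sorted(missing)}")
        if self.table.index.has_duplicates:
            raise FormatError("duplicate sample ids in design")
        bad_t = set(self.table["tissue"]) - set(TISSUES)
        if bad_t:
            raise FormatError(f"unknown tissue levels: {sorted(bad_t)}")
        bad_g = set(self.table["genotype"]) - set(GENOTYPES)
        if bad_g:
            raise FormatError(f"unknown genotype levels: {sorted(bad_g)}")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.table.index)

    def aligned_to(self, sample_ids: Sequence[str]) -> "SampleDesign":
        """Reorder to the given sample ids; they must match as a set."""
        if set(sample_ids) != set(self.table.index):
            raise FormatError("design sample ids do not match matrix sample ids")
        return SampleDesign(self.table.loc[list(sample_ids)])

    def subset(self, tissue: str) -> "SampleDesign":
        if tissue not in TISSUES:
            raise ValueError(f"unknown tissue {tissue!r}")
        return SampleDesign(self.table[self.table["tissue"] == tissue])


@dataclass
class GeneSetCollection:
    """Named gene sets: name -> (description, ordered unique member ids)."""

    sets: dict[str, tuple[str, list[str]]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, (_, members) in self.sets.items():
            if len(set(members)) != len(members):
                raise FormatError(f"duplicate members in set {name!r}")

    def names(self) -> list[str]:
        return list(self.sets)

    def members(self, name: str) -> list[str]:
        return self.sets[name][1]

    def __len__(self) -> int:
        return len(self.sets)

    def __contains__(self, name: str) -> bool:
        return name in self.sets


def read_expression(path: str | Path, scale_hint: str = "linear") -> ExpressionMatrix:
    """Read a gene-by-sample TSV matrix (first column gene id, header row).

    Non-numeric or missing cells and duplicated ids raise :class:`FormatError`
    with coordinates.
    """
    df = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    df.index = df.index.astype(str).str.strip()
    df.columns = df.columns.astype(str).str.strip()
    if df.index.has_duplicates:
        dups = df.index[df.index.duplicated()].unique().tolist()
        raise FormatError(f"{path}: duplicate gene ids: {dups}")
    try:
        num = df.astype(float)
    except ValueError:
        for r, gene in enumerate(df.index):
            for c, samp in enumerate(df.columns):
                cell = df.iat[r, c]
                try:
                    float(cell)
                except (TypeError, ValueError):
                    raise FormatError(
                        f"{path}: non-numeric value {cell!r} at gene {gene!r}"
                        f" (row {r + 2}), sample {samp!r} (column {c + 2})"
                    ) from None
        raise
    if num.isna().any().any():
        r, c = np.argwhere(num.isna().to_numpy())[0]
        raise FormatError(
            f"{path}: missing value at gene {num.index[r]!r}, sample "
            f"{num.columns[c]!r}"
        )
    return ExpressionMatrix(num, scale=scale_hint)


def write_expression(matrix: ExpressionMatrix, path: str | Path) -> None:
    out = matrix.data.copy()
    out.index.name = "gene"
    out.to_csv(path, sep="\t", float_format="%.17g")


def read_design(path: str | Path) -> SampleDesign:
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {"sample", "tissue", "genotype"}
    if not required <= set(df.columns):
        raise FormatError(
            f"{path}: design must have columns {sorted(required)}, "
            f"got {list(df.columns)}"
        )
    df = df.apply(lambda s: s.str.strip())
    return SampleDesign(df.set_index("sample")[["tissue", "genotype"]])


def write_design(design: SampleDesign, path: str | Path) -> None:
    out = design.table.copy()
    out.index.name = "sample"
    out.to_csv(path, sep="\t")


def read_gmt(path: str | Path) -> GeneSetCollection:
    """Parse a GMT file: one set per line, fields = name, description, members.

    Duplicate members within a line are dropped with a warning; a duplicate
    set name or a line with fewer than three fields is an error.
    """
    sets: dict[str, tuple[str, list[str]]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(
                    f"{path}:{lineno}: GMT line has {len(fields)} fields, "
                    "expected at least 3 (name, description, members...)"
                )
            name, desc = fields[0].strip(), fields[1]
            if name in sets:
                raise FormatError(f"{path}:{lineno}: duplicate set name {name!r}")
            members: list[str] = []
            seen: set[str] = set()
            n_dup = 0
            for m in fields[2:]:
                m = m.strip()
                if not m:
                    continue
                if m in seen:
                    n_dup += 1
                    continue
                seen.add(m)
                members.append(m)
            if n_dup:
                logger.warning(
                    "%s:%d: set %r had %d duplicate member(s), de-duplicated",
                    path, lineno, name, n_dup,
                )
            sets[name] = (desc, members)
    return GeneSetCollection(sets)


def write_gmt(collection: GeneSetCollection, path: str | Path) -> None:
    with open(path, "w") as fh:
        for name, (desc, members) in collection.sets.items():
            fh.write("\t".join([name, desc, *members]) + "\n")


def read_gene_list(path: str | Path) -> list[str]:
    """One gene symbol per line; blanks skipped; order preserved, de-duplicated."""
    out: list[str] = []
    seen: set[str] = set()
    with open(path) as fh:
        for line in fh:
            g = line.strip()
            if g and g not in seen:
                seen.add(g)
                out.append(g)
    return out


def read_homolog_map(path: str | Path) -> dict[str, list[str]]:
    """Two-column TSV (source id, target id) with header; one-to-many allowed."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    if df.shape[1] < 2:
        raise FormatError(f"{path}: homolog map needs two columns")
    mapping: dict[str, list[str]] = {}
    for src, dst in zip(df.iloc[:, 0].str.strip(), df.iloc[:, 1].str.strip()):
        mapping.setdefault(src, [])
        if dst not in mapping[src]:
            mapping[src].append(dst)
    return mapping


def translate_ids(genes: Iterable[str], mapping: Mapping[str, Sequence[str]]) -> list[str]:
    """Translate ids through a homolog map, expanding one-to-many and
    de-duplicating; unmapped ids are dropped with a logged count."""
    out: list[str] = []
    seen: set[str] = set()
    n_unmapped = 0
    for g in genes:
        targets = mapping.get(g)
        if not targets:
            n_unmapped += 1
            continue
        for t in targets:
            if t not in seen:
                seen.add(t)
                out.append(t)
    if n_unmapped:
        logger.warning("translate_ids: dropped %d unmapped id(s)", n_unmapped)
    return out


def filter_sets_by_size(
    collection: GeneSetCollection,
    measured_genes: Iterable[str],
    min_size: int = 15,
    max_size: int = 500,
) -> GeneSetCollection:
    """Restrict each set to measured genes, keep those with min_size <=
    |intersection| <= max_size.

    Set size is defined after intersection with the measured universe, so the
    enrichment statistic only ever sees genes present in the ranking.
    """
    if min_size < 1 or max_size < min_size:
        raise ValueError(f"invalid size bounds ({min_size}, {max_size})")
    measured = set(measured_genes)
    if not measured:
        raise ValueError("measured_genes is empty")
    kept: dict[str, tuple[str, list[str]]] = {}
    for name, (desc, members) in collection.sets.items():
        inter = [m for m in members if m in measured]
        if min_size <= len(inter) <= max_size:
            kept[name] = (desc, inter)
    return GeneSetCollection(kept)
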