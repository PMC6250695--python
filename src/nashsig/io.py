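"""Readers and writers for every on-disk artifact.

Formats are deliberately minimal: TSV for matrices and tables, GMT for
gene sets, GRP (one feature per line) for signature arms, JSON for result
objects.  All readers validate strictly and raise
:class:`~nashsig.core.FormatError` / :class:`~nashsig.core.ValidationError`
rather than coercing malformed input.  Writing then reading any valid
object is the identity.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .core import (
    DE_REQUIRED_COLUMNS,
    DEResultTable,
    ExpressionMatrix,
    FormatError,
    GeneSetCollection,
    OrthologMap,
    SampleDesign,
    ValidationError,
)

logger = logging.getLogger(__name__)


# -- expression matrices ----------------------------------------------------

def read_expression_matrix(path: str | Path, value_kind: str) -> ExpressionMatrix:
    """Read a genes x samples TSV (header: sample ids; first column: gene ids)."""
    path = Path(path)
    with open(path) as fh:
        header = fh.readline().rstrip("\n")
    if not header:
        raise FormatError(f"{path}: empty file")
    sample_ids = header.split("\t")[1:]
    seen: set[str] = set()
    for s in sample_ids:
        if s in seen:
            raise FormatError(f"{path}: duplicate sample id: {s!r}")
        seen.add(s)
    raw = pd.read_csv(path, sep="\t", index_col=0, dtype=str, keep_default_na=False)
    raw.columns = sample_ids  # undo pandas' silent header de-duplication
    dup = raw.index[raw.index.duplicated()]
    if len(dup):
        raise FormatError(f"{path}: duplicate gene id: {dup[0]!r}")
    coerced = raw.apply(pd.to_numeric, errors="coerce")
    bad = np.argwhere(coerced.isna().to_numpy())
    if bad.size:
        r, c = bad[0]
        raise FormatError(
            f"{path}: non-numeric value {raw.iat[r, c]!r} at row "
            f"{raw.index[r]!r}, column {raw.columns[c]!r}"
        )
    # numpy's parser is correctly rounded; pandas' fast path is not
    values = raw.to_numpy(dtype=np.str_).astype(np.float64)
    numeric = pd.DataFrame(values, index=raw.index.astype(str), columns=sample_ids)
    numeric.index.name = raw.index.name or "gene_id"
    return ExpressionMatrix(values=numeric, value_kind=value_kind)


def write_expression_matrix(matrix: ExpressionMatrix, path: str | Path) -> None:
    df = matrix.values.copy()
    df.index.name = df.index.name or "gene_id"
    if matrix.value_kind == "counts":
        df = df.astype(np.int64)
        df.to_csv(path, sep="\t")
    else:
        df.to_csv(path, sep="\t", float_format="%.17g")


# -- sample designs ---------------------------------------------------------

def read_sample_design(path: str | Path, group_order: Sequence[str] | None = None) -> SampleDesign:
    """Read a two-column TSV ``sample_id<TAB>group`` (header required)."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    for col in ("sample_id", "group"):
        if col not in df.columns:
            raise FormatError(f"{path}: design missing column {col!r}")
    if df["sample_id"].duplicated().any():
        d = df.loc[df["sample_id"].duplicated(), "sample_id"].iloc[0]
        raise FormatError(f"{path}: duplicate sample id: {d!r}")
    order = tuple(group_order) if group_order else tuple(dict.fromkeys(df["group"]))
    return SampleDesign(
        assignments=dict(zip(df["sample_id"], df["group"])), group_order=order
    )


def write_sample_design(design: SampleDesign, path: str | Path) -> None:
    rows = [(s, g) for s, g in design.assignments.items()]
    pd.DataFrame(rows, columns=["sample_id", "group"]).to_csv(path, sep="\t", index=False)


# -- gene sets (GMT) and signature arms (GRP) -------------------------------

def read_gmt(path: str | Path) -> GeneSetCollection:
    """Read a standard GMT file: ``name TAB description TAB member...``."""
    sets: dict[str, tuple[str, ...]] = {}
    descriptions: dict[str, str] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(
                    f"{path}: line {lineno}: expected >= 3 tab-separated fields"
                )
            name, desc, members = fields[0], fields[1], fields[2:]
            members = [m for m in members if m]
            if name in sets:
                raise FormatError(f"{path}: line {lineno}: duplicate set name {name!r}")
            unique = tuple(dict.fromkeys(members))
            if len(unique) < len(members):
                logger.warning(
                    "%s: line %d: set %r lists %d duplicate member(s); collapsed",
                    path, lineno, name, len(members) - len(unique),
                )
            sets[name] = unique
            descriptions[name] = desc
    return GeneSetCollection(sets=sets, descriptions=descriptions)


def write_gmt(collection: GeneSetCollection, path: str | Path) -> None:
    with open(path, "w") as fh:
        for name in collection.names():
            desc = collection.descriptions.get(name, "")
            fh.write("\t".join([name, desc, *collection[name]]) + "\n")


def read_grp(path: str | Path) -> tuple[str, ...]:
    """Read a GRP file: one feature id per line; '#' comments and blanks ignored."""
    out: list[str] = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if line and not line.startswith("#"):
                out.append(line)
    return tuple(out)


def write_grp(ids: Sequence[str], path: str | Path) -> None:
    with open(path, "w") as fh:
        for x in ids:
            fh.write(f"{x}\n")


# -- DE tables --------------------------------------------------------------

def read_de_table(path: str | Path) -> DEResultTable:
    df = pd.read_csv(path, sep="\t", float_precision="round_trip")
    for col in DE_REQUIRED_COLUMNS:
        if col not in df.columns:
            raise FormatError(f"{path}: DE table missing required column {col!r}")
    df["gene_id"] = df["gene_id"].astype(str)
    return DEResultTable(data=df)


def write_de_table(table: DEResultTable, path: str | Path) -> None:
    table.data.to_csv(path, sep="\t", index=False, float_format="%.17g")


# -- ortholog maps ----------------------------------------------------------

def read_ortholog_map(path: str | Path, policy: str = "one2one_only") -> OrthologMap:
    """Read a two-column TSV with header ``source_id<TAB>target_id``."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    for col in ("source_id", "target_id"):
        if col not in df.columns:
            raise FormatError(f"{path}: ortholog map missing column {col!r}")
    return OrthologMap(pairs=df[["source_id", "target_id"]], policy=policy)


def write_ortholog_map(omap: OrthologMap, path: str | Path) -> None:
    omap.pairs.to_csv(path, sep="\t", index=False)


# -- endpoint tables --------------------------------------------------------

HISTOLOGY_COLUMNS = ("animal_id", "group", "steatosis_pct", "foci_per_field",
                     "ballooning_category")


def read_histology_table(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    for col in HISTOLOGY_COLUMNS:
        if col not in df.columns:
            raise FormatError(f"{path}: histology table missing column {col!r}")
    if df["animal_id"].duplicated().any():
        d = df.loc[df["animal_id"].duplicated(), "animal_id"].iloc[0]
        raise FormatError(f"{path}: duplicate animal id: {d!r}")
    return df


CT_COLUMNS = ("sample_id", "group", "gene", "ct")


def read_ct_table(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    for col in CT_COLUMNS:
        if col not in df.columns:
            raise FormatError(f"{path}: Ct table missing column {col!r}")
    if df.duplicated(["sample_id", "gene"]).any():
        raise ValidationError(f"{path}: duplicate (sample, gene) Ct entries")
    return df
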