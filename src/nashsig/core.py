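"""Shared domain containers.

Every on-disk artifact the pipeline touches is loaded into one of the
validated containers defined here; downstream modules never see raw files.
Gene and sample identifiers are case-sensitive opaque strings throughout —
no symbol normalisation is ever applied, because silent case-folding
corrupts cross-species joins (an explicit ortholog map is required instead).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd


class NashsigError(Exception):
    """Base class for all errors raised by this package."""


class FormatError(NashsigError):
    """Malformed on-disk input (wrong shape, missing column, bad cell)."""


class ValidationError(NashsigError):
    """Well-formed input violating a domain invariant."""


class ConfigError(NashsigError):
    """Invalid configuration value."""


VALUE_KINDS = ("counts", "logexpr", "zscore")


def _check_unique(ids: Sequence[str], what: str) -> None:
    seen: set[str] = set()
    for x in ids:
        if x in seen:
            raise FormatError(f"duplicate {what} id: {x!r}")
        seen.add(x)


@dataclass(frozen=True)
class ExpressionMatrix:
    """Genes x samples numeric matrix with a declared value kind.

    Parameters
    ----------
    values
        DataFrame with gene ids as index and sample ids as columns.
    value_kind
        One of ``counts``, ``logexpr`` or ``zscore``.  ``counts`` entries
        must be finite non-negative integers (fractional or negative
        values are rejected, never coerced).
    """

    values: pd.DataFrame
    value_kind: str

    def __post_init__(self) -> None:
        if self.value_kind not in VALUE_KINDS:
            raise ValidationError(
                f"value_kind must be one of {VALUE_KINDS}, got {self.value_kind!r}"
            )
        _check_unique(list(self.values.index), "gene")
        _check_unique(list(self.values.columns), "sample")
        vals = self.values.to_numpy()
        if vals.size and not np.issubdtype(vals.dtype, np.number):
            raise FormatError("expression matrix contains non-numeric values")
        if vals.size and not np.all(np.isfinite(vals)):
            r, c = np.argwhere(~np.isfinite(vals))[0]
            raise ValidationError(
                "non-finite value at gene "
                f"{self.values.index[r]!r}, sample {self.values.columns[c]!r}"
            )
        if self.value_kind == "counts" and vals.size:
            if (vals < 0).any():
                r, c = np.argwhere(vals < 0)[0]
                raise ValidationError(
                    f"negative count at gene {self.values.index[r]!r}, "
                    f"sample {self.values.columns[c]!r}"
                )
            if (np.mod(vals, 1) != 0).any():
                r, c = np.argwhere(np.mod(vals, 1) != 0)[0]
                raise ValidationError(
                    f"fractional count at gene {self.values.index[r]!r}, "
                    f"sample {self.values.columns[c]!r}"
                )

    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def column(self, sample_id: str) -> pd.Series:
        if sample_id not in self.values.columns:
            raise ValidationError(f"unknown sample id: {sample_id!r}")
        return self.values[sample_id]


@dataclass(frozen=True)
class SampleDesign:
    """Sample-to-group assignment with an explicit group order."""

    assignments: Mapping[str, str]
    group_order: tuple[str, ...]

    def __post_init__(self) -> None:
        groups = set(self.assignments.values())
        missing = groups - set(self.group_order)
        if missing:
            raise ValidationError(f"groups missing from group_order: {sorted(missing)}")

    def samples_in(self, group: str) -> list[str]:
        if group not in self.group_order:
            raise ValidationError(f"unknown group: {group!r}")
        return [s for s, g in self.assignments.items() if g == group]

    def check_matches(self, matrix: ExpressionMatrix, min_per_group: int = 2) -> None:
        """Every matrix sample labelled exactly once; compared groups >= `min_per_group`."""
        unlabelled = [s for s in matrix.sample_ids if s not in self.assignments]
        if unlabelled:
            raise ValidationError(f"samples without group label: {unlabelled}")
        for g in self.group_order:
            n = len([s for s in self.samples_in(g) if s in matrix.sample_ids])
            if 0 < n < min_per_group:
                raise ValidationError(
                    f"group {g!r} has {n} sample(s); at least {min_per_group} required"
                )


DE_REQUIRED_COLUMNS = ("gene_id", "log2fc", "p", "p_adj")


@dataclass(frozen=True)
class DEResultTable:
    """Per-gene differential-expression results from one two-group contrast.

    Required columns: ``gene_id``, ``log2fc``, ``p`` (raw), ``p_adj``
    (BH-adjusted; may be missing for genes filtered before testing — such
    rows are excluded from all downstream set constructions).  Extra
    columns (for example ``base_mean``) are carried opaquely.
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        for col in DE_REQUIRED_COLUMNS:
            if col not in self.data.columns:
                raise FormatError(f"DE table missing required column {col!r}")
        _check_unique(list(self.data["gene_id"]), "gene")
        p = self.data["p"].to_numpy(dtype=float)
        if p.size and (np.isnan(p).any() or (p < 0).any() or (p > 1).any()):
            raise ValidationError("raw p-values must lie in [0, 1]")
        padj = self.data["p_adj"].to_numpy(dtype=float)
        finite = ~np.isnan(padj)
        if ((padj[finite] < 0) | (padj[finite] > 1)).any():
            raise ValidationError("adjusted p-values must lie in [0, 1]")
        # BH step-up can never shrink a p-value
        if (padj[finite] < p[finite] - 1e-12).any():
            i = int(np.flatnonzero(finite & (padj < p - 1e-12))[0])
            raise ValidationError(
                f"p_adj < p at gene {self.data['gene_id'].iloc[i]!r} "
                "(violates BH step-up invariant)"
            )
        lfc = self.data["log2fc"].to_numpy(dtype=float)
        if lfc.size and np.isnan(lfc).any():
            raise ValidationError("log2fc must not be missing")

    @property
    def gene_ids(self) -> list[str]:
        return list(self.data["gene_id"])

    def indexed(self) -> pd.DataFrame:
        return self.data.set_index("gene_id")


@dataclass(frozen=True)
class GeneSetCollection:
    """Named, non-empty gene sets (stand-in for curated pathway databases)."""

    sets: Mapping[str, tuple[str, ...]]
    descriptions: Mapping[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, members in self.sets.items():
            if not members:
                raise ValidationError(f"gene set {name!r} is empty")
            _check_unique(members, f"member of set {name!r}")

    def __len__(self) -> int:
        return len(self.sets)

    def __getitem__(self, name: str) -> tuple[str, ...]:
        return self.sets[name]

    def names(self) -> list[str]:
        return list(self.sets)


@dataclass(frozen=True)
class DirectionalSignature:
    """Paired ordered lists of most up- and most down-regulated features."""

    up: tuple[str, ...]
    down: tuple[str, ...]
    n_per_arm: int
    source: str = ""

    def __post_init__(self) -> None:
        if self.n_per_arm <= 0:
            raise ValidationError("n_per_arm must be positive")
        _check_unique(self.up, "up-arm")
        _check_unique(self.down, "down-arm")
        clash = set(self.up) & set(self.down)
        if clash:
            raise ValidationError(f"features in both arms: {sorted(clash)[:5]}")
        if len(self.up) > self.n_per_arm or len(self.down) > self.n_per_arm:
            raise ValidationError("arm exceeds configured n_per_arm cap")


@dataclass(frozen=True)
class ThresholdSet:
    """Up/down gene sets defined by an inclusive |log2fc| >= tau cut."""

    up: tuple[str, ...]
    down: tuple[str, ...]
    tau: float

    def __post_init__(self) -> None:
        if self.tau <= 0:
            raise ValidationError("tau must be positive")
        clash = set(self.up) & set(self.down)
        if clash:
            raise ValidationError(f"genes in both arms: {sorted(clash)[:5]}")


@dataclass(frozen=True)
class OrthologMap:
    """Source-to-target gene id pairs with an explicit resolution policy.

    ``one2one_only`` removes every source or target involved in a
    many-to-many relation before mapping; ``first_alphabetical`` keeps,
    for each source, the alphabetically first target.
    """

    pairs: pd.DataFrame  # columns: source_id, target_id
    policy: str = "one2one_only"

    def __post_init__(self) -> None:
        for col in ("source_id", "target_id"):
            if col not in self.pairs.columns:
                raise FormatError(f"ortholog map missing column {col!r}")
        if self.policy not in ("one2one_only", "first_alphabetical"):
            raise ValidationError(f"unknown ortholog policy {self.policy!r}")
        if self.pairs.duplicated(["source_id", "target_id"]).any():
            raise ValidationError("duplicate ortholog pairs")

    def resolved(self) -> pd.DataFrame:
        """Pairs after applying the resolution policy (source unique)."""
        df = self.pairs
        if self.policy == "one2one_only":
            src_counts = df["source_id"].value_counts()
            tgt_counts = df["target_id"].value_counts()
            keep = df["source_id"].map(src_counts).eq(1) & df["target_id"].map(
                tgt_counts
            ).eq(1)
            return df[keep].reset_index(drop=True)
        out = df.sort_values(["source_id", "target_id"], kind="mergesort")
        return out.drop_duplicates("source_id", keep="first").reset_index(drop=True)
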