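"""Desk-scale differential-expression stage.

Library sizes are estimated with the median-of-ratios algorithm; per-gene
two-group testing is a Welch t-test on ``log2(normalized count + 1)``
with Benjamini-Hochberg FDR control.  This is a deliberately simple,
self-contained stand-in for a full negative-binomial DE engine: it keeps
the pipeline end-to-end runnable on synthetic data, and externally
produced DE tables are accepted as first-class input everywhere a table
from :func:`de_test` is.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .core import (
    DEResultTable,
    ExpressionMatrix,
    SampleDesign,
    ValidationError,
)

PSEUDOCOUNT = 1.0


@dataclass(frozen=True)
class SizeFactors:
    """Per-sample library-size scale factors, geometric mean 1."""

    factors: pd.Series

    def __post_init__(self) -> None:
        f = self.factors.to_numpy(dtype=float)
        if (f <= 0).any() or not np.all(np.isfinite(f)):
            raise ValidationError("size factors must be positive and finite")
        gm = np.exp(np.mean(np.log(f)))
        if abs(gm - 1.0) > 1e-6:
            raise ValidationError(
                f"size factors must have geometric mean 1 (got {gm:.8f})"
            )

    def __getitem__(self, sample_id: str) -> float:
        return float(self.factors[sample_id])


def median_of_ratios(counts: ExpressionMatrix) -> SizeFactors:
    """Median-of-ratios library-size factors.

    For each sample, the factor is the median over reference-eligible
    genes (positive in every sample) of count / geometric-mean(count
    across samples); factors are then rescaled to geometric mean 1.
    """
    if counts.value_kind != "counts":
        raise ValidationError("median_of_ratios requires a counts matrix")
    vals = counts.values.to_numpy(dtype=float)
    eligible = (vals > 0).all(axis=1)
    if not eligible.any():
        raise ValidationError(
            "no gene has positive counts in every sample; "
            "filter to expressed genes before computing size factors"
        )
    ref = vals[eligible]
    log_geomean = np.mean(np.log(ref), axis=1, keepdims=True)
    ratios = np.exp(np.log(ref) - log_geomean)
    factors = np.median(ratios, axis=0)
    factors = factors / np.exp(np.mean(np.log(factors)))
    return SizeFactors(pd.Series(factors, index=counts.values.columns, name="size_factor"))


def normalized_counts(counts: ExpressionMatrix, size_factors: SizeFactors) -> pd.DataFrame:
    """Counts divided by per-sample size factors (genes x samples)."""
    f = size_factors.factors.reindex(counts.values.columns)
    if f.isna().any():
        raise ValidationError("size factors missing for some samples")
    return counts.values / f


def bh_adjust(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjustment, order-preserving with input."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if np.isnan(p).any() or (p < 0).any() or (p > 1).any():
        raise ValidationError("p-values must lie in [0, 1]")
    return stats.false_discovery_control(p, method="bh")


def de_test(
    counts: ExpressionMatrix,
    design: SampleDesign,
    group_a: str,
    group_b: str,
    size_factors: SizeFactors | None = None,
) -> DEResultTable:
    """Two-group Welch t-test on log2(normalized + 1), BH-adjusted.

    ``log2fc`` is the mean log2(normalized + 1) difference B - A.  Genes
    with zero counts in every sample get ``p = p_adj = 1`` and
    ``log2fc = 0`` so that the table stays complete for downstream
    universe accounting.
    """
    for group in (group_a, group_b):
        if group not in design.group_order:
            raise ValidationError(f"group {group!r} absent from design")
    a_samples = [s for s in design.samples_in(group_a) if s in counts.values.columns]
    b_samples = [s for s in design.samples_in(group_b) if s in counts.values.columns]
    if len(a_samples) < 2 or len(b_samples) < 2:
        raise ValidationError("each compared group needs at least 2 samples")
    if size_factors is None:
        sub = ExpressionMatrix(
            values=counts.values[a_samples + b_samples], value_kind=counts.value_kind
        )
        size_factors = median_of_ratios(sub)

    norm = normalized_counts(
        ExpressionMatrix(values=counts.values[a_samples + b_samples],
                         value_kind=counts.value_kind),
        size_factors,
    )
    log_norm = np.log2(norm.to_numpy(dtype=float) + PSEUDOCOUNT)
    xa = log_norm[:, : len(a_samples)]
    xb = log_norm[:, len(a_samples):]
    log2fc = xb.mean(axis=1) - xa.mean(axis=1)
    base_mean = norm.to_numpy().mean(axis=1)

    # degenerate (constant) rows are handled explicitly below; silence the
    # precision-loss warning scipy emits for them
    with np.errstate(invalid="ignore", divide="ignore"), warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        _, p = stats.ttest_ind(xb, xa, axis=1, equal_var=False)
    p = np.asarray(p, dtype=float)
    zero_var = (xa.std(axis=1) == 0) & (xb.std(axis=1) == 0)
    # degenerate rows: identical within-group values on both sides
    p[zero_var & (log2fc == 0)] = 1.0
    p[zero_var & (log2fc != 0)] = 0.0
    p = np.nan_to_num(p, nan=1.0)

    all_zero = (counts.values[a_samples + b_samples].to_numpy() == 0).all(axis=1)
    p[all_zero] = 1.0
    log2fc[all_zero] = 0.0

    table = pd.DataFrame({
        "gene_id": counts.gene_ids,
        "log2fc": log2fc,
        "p": p,
        "p_adj": bh_adjust(p),
        "base_mean": base_mean,
    })
    return DEResultTable(data=table)
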