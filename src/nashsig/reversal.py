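"""Treatment reversal of disease expression, per gene and per pathway.

A gene is a disease DEG when its disease-versus-healthy contrast is
significant (FDR <= alpha).  A disease DEG counts as *reversed* when the
treated-versus-disease contrast moves it in the opposite direction and
that movement is itself significant (FDR <= ``treated_alpha``); requiring
significance keeps sign flips that are pure within-noise wobble from
being credited to the treatment.  Two labelled variants are available:
``treated_alpha=None`` accepts any opposite-signed movement (the literal
sign rule), and ``strict=True`` additionally requires the treated level
to end up closer to healthy than the disease level was
(|log2fc_disease + log2fc_treated| < |log2fc_disease|).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import (
    DEResultTable,
    ExpressionMatrix,
    GeneSetCollection,
    SampleDesign,
    ValidationError,
)
from .diffexpr import PSEUDOCOUNT, SizeFactors, median_of_ratios, normalized_counts


@dataclass(frozen=True)
class ReversalResult:
    """Percent of a pathway's disease DEGs reversed by treatment."""

    pathway_name: str
    n_pathway_genes: int
    n_disease_degs: int
    n_reversed: int

    def __post_init__(self) -> None:
        if not 0 <= self.n_reversed <= self.n_disease_degs <= self.n_pathway_genes:
            raise ValidationError(
                "require 0 <= n_reversed <= n_disease_degs <= n_pathway_genes"
            )

    @property
    def percent_reversed(self) -> float | None:
        if self.n_disease_degs == 0:
            return None
        return 100.0 * self.n_reversed / self.n_disease_degs

    def to_dict(self) -> dict:
        return {
            "pathway_name": self.pathway_name,
            "n_pathway_genes": self.n_pathway_genes,
            "n_disease_degs": self.n_disease_degs,
            "n_reversed": self.n_reversed,
            "percent_reversed": self.percent_reversed,
        }


def classify_reversal(
    disease_vs_healthy: DEResultTable,
    treated_vs_disease: DEResultTable,
    alpha: float = 0.05,
    treated_alpha: float | None = 0.1,
    strict: bool = False,
) -> pd.DataFrame:
    """Per-gene disease-DEG and reversal status.

    Returns a DataFrame indexed by gene id with columns ``is_deg``,
    ``disease_log2fc``, ``treated_log2fc`` and ``is_reversed``.  Genes
    present in only one table are excluded (their count is available as
    ``df.attrs["n_excluded"]``); genes whose adjusted p is missing in the
    disease table are never DEGs.
    """
    dis = disease_vs_healthy.indexed()
    trt = treated_vs_disease.indexed()
    shared = dis.index.intersection(trt.index)
    n_excluded = (len(dis) - len(shared)) + (len(trt) - len(shared))

    d_lfc = dis.loc[shared, "log2fc"].to_numpy(dtype=float)
    t_lfc = trt.loc[shared, "log2fc"].to_numpy(dtype=float)
    d_padj = dis.loc[shared, "p_adj"].to_numpy(dtype=float)
    t_padj = trt.loc[shared, "p_adj"].to_numpy(dtype=float)

    is_deg = ~np.isnan(d_padj) & (d_padj <= alpha)
    opposed = (np.sign(t_lfc) == -np.sign(d_lfc)) & (d_lfc != 0) & (t_lfc != 0)
    reversed_ = is_deg & opposed
    if treated_alpha is not None:
        reversed_ &= ~np.isnan(t_padj) & (t_padj <= treated_alpha)
    if strict:
        reversed_ &= np.abs(d_lfc + t_lfc) < np.abs(d_lfc)

    out = pd.DataFrame(
        {
            "is_deg": is_deg,
            "disease_log2fc": d_lfc,
            "treated_log2fc": t_lfc,
            "is_reversed": reversed_,
        },
        index=pd.Index(shared, name="gene_id"),
    )
    out.attrs["n_excluded"] = int(n_excluded)
    return out


def pathway_percent_reversed(
    status: pd.DataFrame, pathways: GeneSetCollection
) -> list[ReversalResult]:
    """One :class:`ReversalResult` per pathway.

    Pathways with zero disease DEGs are reported with an undefined
    percent rather than dropped; pathway members not measured in the
    contrasts do not count toward ``n_pathway_genes``.
    """
    results = []
    for name in pathways.names():
        members = [g for g in pathways[name] if g in status.index]
        sub = status.loc[members]
        results.append(ReversalResult(
            pathway_name=name,
            n_pathway_genes=len(members),
            n_disease_degs=int(sub["is_deg"].sum()),
            n_reversed=int(sub["is_reversed"].sum()),
        ))
    return results


def overall_percent_reversed(status: pd.DataFrame) -> float | None:
    """Percent reversed over all measured disease DEGs."""
    n_deg = int(status["is_deg"].sum())
    if n_deg == 0:
        return None
    return 100.0 * int(status["is_reversed"].sum()) / n_deg


def marker_relative_matrix(
    counts: ExpressionMatrix,
    design: SampleDesign,
    markers: list[str],
    reference_group: str,
    size_factors: SizeFactors | None = None,
) -> tuple[pd.DataFrame, list[str]]:
    """Marker log2 expression per group relative to the reference-group mean.

    Entry (marker, group) is ``log2(group mean normalized + 1) -
    log2(reference mean normalized + 1)``, so the reference column is
    identically zero.  Markers absent from the matrix are omitted and
    returned in the second element.
    """
    if reference_group not in design.group_order:
        raise ValidationError(f"unknown reference group {reference_group!r}")
    if size_factors is None:
        size_factors = median_of_ratios(counts)
    norm = normalized_counts(counts, size_factors)
    present = [m for m in markers if m in norm.index]
    missing = [m for m in markers if m not in norm.index]
    group_means = {}
    for group in design.group_order:
        samples = [s for s in design.samples_in(group) if s in norm.columns]
        if not samples:
            continue
        group_means[group] = norm.loc[present, samples].mean(axis=1)
    if reference_group not in group_means:
        raise ValidationError(f"no samples in reference group {reference_group!r}")
    ref = np.log2(group_means[reference_group] + PSEUDOCOUNT)
    out = pd.DataFrame({
        g: np.log2(m + PSEUDOCOUNT) - ref for g, m in group_means.items()
    })
    out.index.name = "gene_id"
    return out, missing
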