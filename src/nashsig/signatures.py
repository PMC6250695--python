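"""Directional signature construction.

Covers the profile-processing steps of a connectivity-map query: robust
per-sample z-scoring of log-expression profiles, top-N-per-arm signature
extraction from a ranking key (log2 fold change or z), and inclusive
|log2fc| >= tau threshold sets.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .core import (
    DEResultTable,
    DirectionalSignature,
    ExpressionMatrix,
    ThresholdSet,
    ValidationError,
)

# Scale factor making the MAD a consistent estimator of a normal SD.
MAD_CONSISTENCY = 1.4826


def robust_z(profile: ExpressionMatrix) -> ExpressionMatrix:
    """Per-sample robust z-scores: (x - median) / (1.4826 * MAD).

    MAD is the median absolute deviation from the column median.  A
    column with MAD = 0 is degenerate (more than half its features share
    one value) and is rejected by name rather than producing infinities.
    """
    if profile.value_kind != "logexpr":
        raise ValidationError("robust_z expects a logexpr matrix")
    if profile.shape[0] < 3:
        raise ValidationError("robust_z needs at least 3 features per sample")
    vals = profile.values.to_numpy(dtype=float)
    med = np.median(vals, axis=0, keepdims=True)
    mad = np.median(np.abs(vals - med), axis=0)
    if (mad == 0).any():
        bad = profile.values.columns[int(np.argmax(mad == 0))]
        raise ValidationError(f"degenerate profile (MAD = 0) in sample {bad!r}")
    z = (vals - med) / (MAD_CONSISTENCY * mad)
    return ExpressionMatrix(
        values=pd.DataFrame(z, index=profile.values.index,
                            columns=profile.values.columns),
        value_kind="zscore",
    )


def _ranking_series(source: DEResultTable | pd.Series) -> pd.Series:
    if isinstance(source, DEResultTable):
        df = source.data
        keep = ~df["p_adj"].isna()   # genes filtered before testing are excluded
        s = pd.Series(df.loc[keep, "log2fc"].to_numpy(),
                      index=df.loc[keep, "gene_id"].to_numpy())
    else:
        s = source.dropna()
    return s.astype(float)


def extract_signature(
    source: DEResultTable | pd.Series,
    n_per_arm: int,
    source_label: str = "",
) -> DirectionalSignature:
    """Top ``n_per_arm`` most positive and most negative features.

    Only strictly positive values enter the up arm and strictly negative
    values the down arm, so arms are truncated when fewer qualify.  Ties
    at an arm boundary are broken by |value| descending then feature id
    ascending, which makes the extraction platform-independent.
    """
    if n_per_arm <= 0:
        raise ValidationError("n_per_arm must be positive")
    s = _ranking_series(source)
    df = pd.DataFrame({"id": s.index.astype(str), "value": s.to_numpy()})
    pos = df[df["value"] > 0].sort_values(
        ["value", "id"], ascending=[False, True], kind="mergesort"
    )
    neg = df[df["value"] < 0].sort_values(
        ["value", "id"], ascending=[True, True], kind="mergesort"
    )
    return DirectionalSignature(
        up=tuple(pos["id"].head(n_per_arm)),
        down=tuple(neg["id"].head(n_per_arm)),
        n_per_arm=n_per_arm,
        source=source_label,
    )


def threshold_set(table: DEResultTable, tau: float) -> ThresholdSet:
    """Genes with log2fc >= tau (up) or <= -tau (down), inclusive at the cut."""
    if tau <= 0:
        raise ValidationError("tau must be positive")
    df = table.data
    keep = ~df["p_adj"].isna()
    lfc = df.loc[keep, "log2fc"].to_numpy(dtype=float)
    ids = df.loc[keep, "gene_id"].to_numpy()
    return ThresholdSet(
        up=tuple(ids[lfc >= tau]),
        down=tuple(ids[lfc <= -tau]),
        tau=tau,
    )
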