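"""Non-transcriptomic study endpoints.

Implements the NAFLD activity score (NAS) rubric (steatosis 0-3,
lobular inflammation 0-3, hepatocyte ballooning 0-2, summed to 0-8),
rank-based and ANOVA group comparisons, comparative-Ct qPCR relative
quantification, and the mean +- 2 SD outlier rule.

Rubric boundary conventions (the printed bands leave 33 and 66
ambiguous): steatosis uses <5 -> 0, [5, 33) -> 1, [33, 66] -> 2 and
> 66 -> 3, reading "greater than 66%" literally; inflammation uses
0 foci -> 0, (0, 2) -> 1, [2, 4] -> 2, > 4 -> 3.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .core import ValidationError

BALLOONING_CATEGORIES = ("none", "few", "many")


@dataclass(frozen=True)
class HistologyRecord:
    """One animal's histology reads used by the NAS rubric."""

    animal_id: str
    group: str
    steatosis_pct: float
    foci_per_field: float
    ballooning_category: str

    def __post_init__(self) -> None:
        if not 0.0 <= self.steatosis_pct <= 100.0:
            raise ValidationError("steatosis_pct must lie in [0, 100]")
        if self.foci_per_field < 0:
            raise ValidationError("foci_per_field must be non-negative")
        if self.ballooning_category not in BALLOONING_CATEGORIES:
            raise ValidationError(
                f"ballooning_category must be one of {BALLOONING_CATEGORIES}"
            )


@dataclass(frozen=True)
class NASResult:
    steatosis_score: int
    inflammation_score: int
    ballooning_score: int

    def __post_init__(self) -> None:
        if self.steatosis_score not in range(4):
            raise ValidationError("steatosis score must be 0..3")
        if self.inflammation_score not in range(4):
            raise ValidationError("inflammation score must be 0..3")
        if self.ballooning_score not in range(3):
            raise ValidationError("ballooning score must be 0..2")

    @property
    def total(self) -> int:
        return self.steatosis_score + self.inflammation_score + self.ballooning_score


def nas_score(record: HistologyRecord) -> NASResult:
    """NAFLD activity score components and total for one animal."""
    s = record.steatosis_pct
    if s < 5:
        steatosis = 0
    elif s < 33:
        steatosis = 1
    elif s <= 66:
        steatosis = 2
    else:
        steatosis = 3
    f = record.foci_per_field
    if f == 0:
        inflammation = 0
    elif f < 2:
        inflammation = 1
    elif f <= 4:
        inflammation = 2
    else:
        inflammation = 3
    ballooning = BALLOONING_CATEGORIES.index(record.ballooning_category)
    return NASResult(steatosis_score=steatosis, inflammation_score=inflammation,
                     ballooning_score=ballooning)


def _midranks(values: np.ndarray) -> np.ndarray:
    """Midranks (average ranks for ties) computed by sorting, 1-based."""
    order = np.argsort(values, kind="mergesort")
    ranks = np.empty(len(values))
    i = 0
    sorted_vals = values[order]
    while i < len(values):
        j = i
        while j + 1 < len(values) and sorted_vals[j + 1] == sorted_vals[i]:
            j += 1
        ranks[order[i:j + 1]] = (i + j) / 2.0 + 1.0
        i = j + 1
    return ranks


def _exact_ranksum_p(ranks2: np.ndarray, n_a: int, w2_obs: int) -> float:
    """Exact two-sided p for the rank-sum over all C(N, nA) assignments.

    ``ranks2`` are doubled midranks (integers), so subset sums live on an
    integer lattice and the full permutation distribution is obtained by
    a subset-sum count (equivalent to enumerating every assignment, but
    feasible for moderate N).  Counts stay below 2**53, hence exact in
    float64.
    """
    total = int(ranks2.sum())
    dp = np.zeros((n_a + 1, total + 1))
    dp[0, 0] = 1.0
    for v in ranks2:
        v = int(v)
        for k_sel in range(n_a, 0, -1):   # descending: 0/1 knapsack ordering
            dp[k_sel, v:] += dp[k_sel - 1, : total + 1 - v]
    dist = dp[n_a]
    n = len(ranks2)
    mu2 = n_a * (n + 1)   # doubled mean of the rank-sum
    dev = abs(w2_obs - mu2)
    sums = np.arange(total + 1)
    count = dist[np.abs(sums - mu2) >= dev - 1e-9].sum()
    return float(count / math.comb(n, n_a))


def wilcoxon_ranksum(
    group_a: "np.typing.ArrayLike",
    group_b: "np.typing.ArrayLike",
    mode: str = "auto",
) -> tuple[float, float]:
    """Two-sided Wilcoxon rank-sum test; returns (rank-sum of A, p).

    ``mode="exact"`` enumerates the full permutation distribution of the
    midrank sum; ``mode="approx"`` uses the tie-corrected normal
    approximation; ``mode="auto"`` picks exact when nA + nB <= 12.
    When every pooled value is identical the test is degenerate and
    p = 1.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValidationError("both groups must be non-empty")
    if mode not in ("auto", "exact", "approx"):
        raise ValidationError(f"unknown mode {mode!r}")
    pooled = np.concatenate([a, b])
    ranks = _midranks(pooled)
    w = float(ranks[: a.size].sum())
    if np.all(pooled == pooled[0]):
        return w, 1.0
    if mode == "auto":
        mode = "exact" if pooled.size <= 12 else "approx"
    if mode == "exact":
        ranks2 = np.round(2.0 * ranks).astype(np.int64)
        p = _exact_ranksum_p(ranks2, a.size, int(round(2.0 * w)))
    else:
        _, p = stats.mannwhitneyu(a, b, alternative="two-sided", method="asymptotic")
        p = float(p)
    return w, min(p, 1.0)


@dataclass(frozen=True)
class AnovaLSDResult:
    f_statistic: float
    p_anova: float
    pairwise: pd.DataFrame   # columns: group_i, group_j, t, p

    def to_dict(self) -> dict:
        return {
            "f_statistic": self.f_statistic,
            "p_anova": self.p_anova,
            "pairwise": self.pairwise.to_dict(orient="records"),
        }


def anova_lsd(groups: dict[str, "np.typing.ArrayLike"]) -> AnovaLSDResult:
    """One-way ANOVA followed by Fisher's least-significant-difference test.

    The LSD comparisons are unadjusted two-sided t-tests using the pooled
    mean-square error with N - k degrees of freedom.
    """
    if len(groups) < 2:
        raise ValidationError("anova_lsd needs at least 2 groups")
    arrays = {g: np.asarray(v, dtype=float) for g, v in groups.items()}
    for g, v in arrays.items():
        if v.size < 2:
            raise ValidationError(f"group {g!r} has fewer than 2 values")
    names = list(arrays)
    n_total = sum(v.size for v in arrays.values())
    k = len(names)
    grand = np.concatenate(list(arrays.values())).mean()
    ss_between = sum(v.size * (v.mean() - grand) ** 2 for v in arrays.values())
    ss_within = sum(((v - v.mean()) ** 2).sum() for v in arrays.values())
    df_b, df_w = k - 1, n_total - k
    if ss_within == 0 and ss_between == 0:
        f_stat, p_anova = 0.0, 1.0
    elif ss_within == 0:
        f_stat, p_anova = float("inf"), 0.0
    else:
        f_stat = (ss_between / df_b) / (ss_within / df_w)
        p_anova = float(stats.f.sf(f_stat, df_b, df_w))
    mse = ss_within / df_w
    rows = []
    for gi, gj in itertools.combinations(names, 2):
        vi, vj = arrays[gi], arrays[gj]
        diff = vi.mean() - vj.mean()
        if mse == 0:
            t = 0.0 if diff == 0 else math.copysign(float("inf"), diff)
            p = 1.0 if diff == 0 else 0.0
        else:
            se = math.sqrt(mse * (1.0 / vi.size + 1.0 / vj.size))
            t = diff / se
            p = float(2.0 * stats.t.sf(abs(t), df_w))
        rows.append((gi, gj, t, p))
    pairwise = pd.DataFrame(rows, columns=["group_i", "group_j", "t", "p"])
    return AnovaLSDResult(f_statistic=float(f_stat), p_anova=float(p_anova),
                          pairwise=pairwise)


@dataclass(frozen=True)
class CtTable:
    """Long-format qPCR Ct measurements with a declared reference gene.

    The reference gene is a *required* argument with no default: the two
    usual housekeeping choices (ribosomal 18S and Rplp0) give different
    delta-Ct values, so the caller must state which one the assay used.
    """

    data: pd.DataFrame          # columns: sample_id, group, gene, ct
    reference_gene: str

    def __post_init__(self) -> None:
        for col in ("sample_id", "group", "gene", "ct"):
            if col not in self.data.columns:
                raise ValidationError(f"Ct table missing column {col!r}")
        with_target = set(
            self.data.loc[self.data["gene"] != self.reference_gene, "sample_id"]
        )
        with_ref = set(
            self.data.loc[self.data["gene"] == self.reference_gene, "sample_id"]
        )
        missing = sorted(with_target - with_ref)
        if missing:
            raise ValidationError(
                f"sample {missing[0]!r} has target Ct but no reference-gene "
                f"({self.reference_gene!r}) Ct"
            )


@dataclass(frozen=True)
class DdctResult:
    delta_ct: pd.Series      # per-sample Ct(target) - Ct(reference)
    ddct: float              # mean dCt(treated) - mean dCt(control)
    fold_change: float       # 2 ** (-ddct)


def ddct(
    table: CtTable,
    target: str,
    control_group: str,
    treated_group: str,
) -> DdctResult:
    """Comparative-Ct relative quantification of one target gene.

    delta-Ct = Ct(target) - Ct(reference) per sample; delta-delta-Ct is
    the arithmetic-mean difference treated minus control; the fold change
    is 2^(-ddCt).
    """
    df = table.data
    tgt = df[df["gene"] == target]
    if tgt.empty:
        raise ValidationError(f"target gene {target!r} absent from Ct table")
    ref = df[df["gene"] == table.reference_gene].set_index("sample_id")["ct"]
    missing = [s for s in tgt["sample_id"] if s not in ref.index]
    if missing:
        raise ValidationError(f"missing reference Ct for sample {missing[0]!r}")
    dct = pd.Series(
        tgt["ct"].to_numpy(dtype=float) - ref.loc[tgt["sample_id"]].to_numpy(dtype=float),
        index=tgt["sample_id"].to_numpy(),
        name="delta_ct",
    )
    group_of = tgt.set_index("sample_id")["group"]
    ctrl = dct[group_of.loc[dct.index] == control_group]
    trt = dct[group_of.loc[dct.index] == treated_group]
    if ctrl.empty or trt.empty:
        raise ValidationError("both compared groups need target-gene Ct values")
    dd = float(trt.mean() - ctrl.mean())
    return DdctResult(delta_ct=dct, ddct=dd, fold_change=float(2.0 ** (-dd)))


def outlier_mask(values: "np.typing.ArrayLike") -> np.ndarray:
    """Boolean mask of retained values under the mean +- 2 SD rule.

    Mean and sample SD (n-1 denominator) are computed once on all
    values — the rule is single-pass, never re-applied to the retained
    subset.  With SD = 0 every value is retained.
    """
    v = np.asarray(values, dtype=float)
    if v.size < 3:
        raise ValidationError("outlier_mask needs at least 3 values")
    sd = v.std(ddof=1)
    if sd == 0:
        return np.ones(v.size, dtype=bool)
    mean = v.mean()
    return np.abs(v - mean) <= 2.0 * sd
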