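"""Cross-species signature concordance and reversal tests.

Gene lists from two species are placed in one identifier space through
an explicit ortholog map, a 2x2 contingency table is formed over the
declared mappable-gene universe (genes measured in both studies and
resolvable under the map policy — anything larger silently inflates the
"in neither" cell), and overlap significance is assessed with Fisher's
exact test.  The odds ratio is the sample odds ratio (a*d)/(b*c), with a
Haldane 0.5 continuity correction applied to every cell iff any cell is
zero.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from scipy import stats

from .core import (
    DirectionalSignature,
    OrthologMap,
    ThresholdSet,
    ValidationError,
)


@dataclass(frozen=True)
class OverlapResult:
    """2x2 overlap table over a declared gene universe.

    a = in both lists, b = list1 only, c = list2 only, d = in neither.
    """

    a: int
    b: int
    c: int
    d: int
    odds_ratio: float
    p_value: float
    alternative: str

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValidationError("contingency cells must be non-negative")
        if self.alternative not in ("greater", "two_sided"):
            raise ValidationError(f"unknown alternative {self.alternative!r}")
        if self.odds_ratio < 0:
            raise ValidationError("odds ratio must be non-negative")

    @property
    def universe_n(self) -> int:
        return self.a + self.b + self.c + self.d

    def to_dict(self) -> dict:
        return {
            "a": self.a, "b": self.b, "c": self.c, "d": self.d,
            "universe_n": self.universe_n, "odds_ratio": self.odds_ratio,
            "p_value": self.p_value, "alternative": self.alternative,
        }


def apply_ortholog_map(
    ids: Sequence[str],
    ortholog_map: OrthologMap,
    direction: str = "source_to_target",
) -> tuple[list[str], list[str]]:
    """Map ids across species; unmapped ids are dropped and reported.

    Returns ``(mapped_ids, dropped_ids)``, both preserving input order.
    Under the ``one2one_only`` policy, ids involved in many-to-many
    relations are removed before mapping and therefore count as dropped.
    """
    if direction not in ("source_to_target", "target_to_source"):
        raise ValidationError(f"unknown direction {direction!r}")
    resolved = ortholog_map.resolved()
    if direction == "source_to_target":
        lut = dict(zip(resolved["source_id"], resolved["target_id"]))
    else:
        # reverse mapping must also be unique to be usable
        tgt_counts = resolved["target_id"].value_counts()
        unique_tgt = resolved[resolved["target_id"].map(tgt_counts).eq(1)]
        lut = dict(zip(unique_tgt["target_id"], unique_tgt["source_id"]))
    mapped, dropped = [], []
    for x in ids:
        if x in lut:
            mapped.append(lut[x])
        else:
            dropped.append(x)
    return mapped, dropped


def overlap_from_counts(a: int, b: int, c: int, d: int,
                        alternative: str = "greater") -> OverlapResult:
    """Fisher's exact test and sample odds ratio from raw 2x2 cells."""
    if min(a, b, c, d) < 0:
        raise ValidationError("contingency cells must be non-negative")
    scipy_alt = {"greater": "greater", "two_sided": "two-sided"}.get(alternative)
    if scipy_alt is None:
        raise ValidationError(f"unknown alternative {alternative!r}")
    _, p = stats.fisher_exact([[a, b], [c, d]], alternative=scipy_alt)
    if min(a, b, c, d) == 0:
        aa, bb, cc, dd = a + 0.5, b + 0.5, c + 0.5, d + 0.5
    else:
        aa, bb, cc, dd = a, b, c, d
    odds_ratio = (aa * dd) / (bb * cc)
    return OverlapResult(a=a, b=b, c=c, d=d, odds_ratio=float(odds_ratio),
                         p_value=float(p), alternative=alternative)


def fisher_overlap(
    list1: Iterable[str],
    list2: Iterable[str],
    universe: Iterable[str],
    alternative: str = "greater",
) -> OverlapResult:
    """Overlap of two gene lists against an explicit universe.

    Every list element must belong to the universe; out-of-universe
    elements are an error (they indicate a bookkeeping bug upstream),
    never silently dropped.
    """
    uni = set(universe)
    if not uni:
        raise ValidationError("empty universe")
    s1, s2 = set(list1), set(list2)
    for name, s in (("list1", s1), ("list2", s2)):
        stray = s - uni
        if stray:
            raise ValidationError(
                f"{name} element outside universe: {sorted(stray)[0]!r}"
            )
    a = len(s1 & s2)
    b = len(s1 - s2)
    c = len(s2 - s1)
    d = len(uni) - a - b - c
    return overlap_from_counts(a, b, c, d, alternative=alternative)


def mappable_universe(
    source_measured: Iterable[str],
    target_measured: Iterable[str],
    ortholog_map: OrthologMap,
) -> list[str]:
    """Target-space ids measured in both studies and resolvable 1:1 under the map."""
    resolved = ortholog_map.resolved()
    src, tgt = set(source_measured), set(target_measured)
    keep = resolved["source_id"].isin(src) & resolved["target_id"].isin(tgt)
    return sorted(resolved.loc[keep, "target_id"])


def concordance_test(
    human_sig: DirectionalSignature,
    mouse_set: ThresholdSet,
    universe: Iterable[str],
    ortholog_map: OrthologMap,
    alternative: str = "greater",
) -> tuple[OverlapResult, OverlapResult]:
    """Directional human-mouse concordance: up vs up, down vs down.

    Mouse ids are mapped into the human space; both species' lists are
    restricted to the shared mappable universe before testing.
    """
    uni = set(universe)
    if not uni:
        raise ValidationError("empty universe")
    mouse_up, _ = apply_ortholog_map(mouse_set.up, ortholog_map)
    mouse_down, _ = apply_ortholog_map(mouse_set.down, ortholog_map)
    up = fisher_overlap(
        [g for g in human_sig.up if g in uni],
        [g for g in mouse_up if g in uni],
        uni, alternative=alternative,
    )
    down = fisher_overlap(
        [g for g in human_sig.down if g in uni],
        [g for g in mouse_down if g in uni],
        uni, alternative=alternative,
    )
    return up, down


def reversal_test(
    human_up_arm: Sequence[str],
    mouse_treated_down: ThresholdSet | Sequence[str],
    universe: Iterable[str],
    ortholog_map: OrthologMap,
    alternative: str = "greater",
) -> OverlapResult:
    """Overlap of human disease-up genes with mouse treatment-down genes.

    A significant enrichment means the treatment pushes down, in the
    mouse, the genes that rise in the human disease — a cross-species
    reversal of the human disease signature.
    """
    uni = set(universe)
    if not uni:
        raise ValidationError("empty universe")
    down_ids = (mouse_treated_down.down
                if isinstance(mouse_treated_down, ThresholdSet)
                else tuple(mouse_treated_down))
    mouse_down, _ = apply_ortholog_map(down_ids, ortholog_map)
    human_in = [g for g in human_up_arm if g in uni]
    if not human_in:
        raise ValidationError("human up arm empty after mapping; no test possible")
    return fisher_overlap(
        human_in, [g for g in mouse_down if g in uni], uni, alternative=alternative
    )
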