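"""End-to-end workflow composition over the individual stages.

These helpers wire simulation, differential expression, signature
construction, cross-species testing and reversal quantification into the
two study workflows (prediction: signature -> connectivity screen;
validation: DE -> cross-species -> reversal), so that the command-line
interface, the test suite and downstream scripts all run exactly the
same code path.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .core import (
    DirectionalSignature,
    ExpressionMatrix,
    GeneSetCollection,
    OrthologMap,
    SampleDesign,
    ThresholdSet,
)
from . import cross_species, reversal as reversal_mod
from .diffexpr import de_test, median_of_ratios
from .simulate import (
    GroundTruth,
    SimulationConfig,
    simulate_human_cohort,
    simulate_ortholog_map,
    simulate_three_group_counts,
)
from .signatures import extract_signature, threshold_set


@dataclass(frozen=True)
class SimulatedStudy:
    """All transcriptomic artifacts of one simulated two-species study."""

    config: SimulationConfig
    mouse_counts: ExpressionMatrix
    mouse_design: SampleDesign
    mouse_truth: GroundTruth
    ortholog_map: OrthologMap
    human_counts: ExpressionMatrix
    human_design: SampleDesign
    human_truth: GroundTruth


def simulate_study(config: SimulationConfig) -> SimulatedStudy:
    mouse_counts, mouse_design, mouse_truth = simulate_three_group_counts(config)
    omap = simulate_ortholog_map(config, mouse_counts.gene_ids)
    human_counts, human_design, human_truth = simulate_human_cohort(
        config, mouse_truth, omap
    )
    return SimulatedStudy(
        config=config, mouse_counts=mouse_counts, mouse_design=mouse_design,
        mouse_truth=mouse_truth, ortholog_map=omap, human_counts=human_counts,
        human_design=human_design, human_truth=human_truth,
    )


@dataclass(frozen=True)
class CrossSpeciesReport:
    concordance_up: cross_species.OverlapResult
    concordance_down: cross_species.OverlapResult
    reversal: cross_species.OverlapResult
    universe_n: int

    def to_dict(self) -> dict:
        return {
            "universe_n": self.universe_n,
            "concordance_up": self.concordance_up.to_dict(),
            "concordance_down": self.concordance_down.to_dict(),
            "reversal": self.reversal.to_dict(),
        }


def cross_species_report(
    study: SimulatedStudy,
    n_per_arm: int = 250,
    tau: float = 0.5,
    alternative: str = "greater",
) -> CrossSpeciesReport:
    """Concordance and reversal tests on a simulated study's own contrasts."""
    sf = median_of_ratios(study.mouse_counts)
    disease = de_test(study.mouse_counts, study.mouse_design,
                      "healthy", "vehicle", size_factors=sf)
    treated = de_test(study.mouse_counts, study.mouse_design,
                      "vehicle", "treated", size_factors=sf)
    human_de = de_test(study.human_counts, study.human_design, "control", "nash")

    human_sig = extract_signature(human_de, n_per_arm, source_label="human cohort")
    mouse_disease_set = threshold_set(disease, tau)
    mouse_treated_set = threshold_set(treated, tau)

    universe = cross_species.mappable_universe(
        study.mouse_counts.gene_ids, study.human_counts.gene_ids, study.ortholog_map
    )
    up, down = cross_species.concordance_test(
        human_sig, mouse_disease_set, universe, study.ortholog_map,
        alternative=alternative,
    )
    rev = cross_species.reversal_test(
        human_sig.up, mouse_treated_set, universe, study.ortholog_map,
        alternative=alternative,
    )
    return CrossSpeciesReport(concordance_up=up, concordance_down=down,
                              reversal=rev, universe_n=len(universe))


def mouse_reversal_status(
    study: SimulatedStudy,
    alpha: float = 0.05,
    treated_alpha: float | None = 0.1,
    strict: bool = False,
) -> pd.DataFrame:
    """Per-gene reversal classification from a simulated study's contrasts."""
    sf = median_of_ratios(study.mouse_counts)
    disease = de_test(study.mouse_counts, study.mouse_design,
                      "healthy", "vehicle", size_factors=sf)
    treated = de_test(study.mouse_counts, study.mouse_design,
                      "vehicle", "treated", size_factors=sf)
    return reversal_mod.classify_reversal(
        disease, treated, alpha=alpha, treated_alpha=treated_alpha, strict=strict
    )


def percent_reversed_of_study(
    study: SimulatedStudy,
    alpha: float = 0.05,
    treated_alpha: float | None = 0.1,
) -> float | None:
    """Overall percent of disease DEGs reversed, over all measured genes."""
    status = mouse_reversal_status(study, alpha=alpha, treated_alpha=treated_alpha)
    return reversal_mod.overall_percent_reversed(status)
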