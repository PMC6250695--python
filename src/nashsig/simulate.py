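"""Synthetic study generator with known ground truth.

Emulates, at the expression level, a three-arm rodent NASH study
(healthy / disease-vehicle / treated), a concordant two-group human
cohort linked through an ortholog map, a landmark-space compound
z-score collection containing one implanted inverse-connectivity
compound, and per-animal histology / qPCR endpoint tables.

Counts are negative binomial with gene-wise log-normal baseline means
and a single dispersion parameter — the minimal model reproducing the
over-dispersion the downstream differential-expression stage assumes.
Treatment reversal is implanted on the mean of the treated group (a
reversed gene's treated mean is moved a fraction ``reversal_strength``
of the way back to the healthy mean), which makes the ground-truth
reversal direction exact rather than an artefact of resampling.

One global seed drives named per-purpose substreams, so adding a new
generator never perturbs the draws of an existing one.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field, asdict
from typing import NamedTuple

import numpy as np
import pandas as pd

from .core import (
    ConfigError,
    DirectionalSignature,
    ExpressionMatrix,
    GeneSetCollection,
    OrthologMap,
    SampleDesign,
    ValidationError,
)

MOUSE_GROUPS = ("healthy", "vehicle", "treated")
HUMAN_GROUPS = ("control", "nash")

# Marker genes carried by the qPCR endpoint table (inflammatory and
# fibrosis markers assayed in the study) and their baseline Ct offsets
# from the reference gene in the healthy group.
CT_MARKERS = {"Ifng": 12.0, "Tnf": 8.0, "Ccl2": 7.0, "Timp1": 5.0,
              "Col1a1": 3.0, "Tgfb1": 6.0}
# Group shifts of delta-Ct (negative = higher expression than healthy).
CT_GROUP_SHIFT = {"healthy": 0.0, "vehicle": -2.0, "treated": -0.8}
CT_REFERENCE_GENE = "Rplp0"


@dataclass(frozen=True)
class SimulationConfig:
    """Every knob of the synthetic study, with the study conditions as defaults.

    Fractions are in [0, 1]; effect sizes are in log2 units.  A fixed
    ``seed`` makes every generated artifact bit-reproducible.
    """

    seed: int = 0
    n_genes: int = 2000
    n_landmarks: int = 978
    samples_per_group: int = 4
    human_samples_per_group: int = 12
    dispersion: float = 0.1
    baseline_logmean_mean: float = 4.0   # natural-log mean of gene baselines
    baseline_logmean_sd: float = 1.5
    libsize_range: tuple[float, float] = (0.7, 1.4)
    de_fraction: float = 0.1
    effect_mean: float = 2.0
    effect_sd: float = 0.5
    effect_floor: float = 0.25
    reversal_fraction: float = 0.7
    reversal_strength: float = 1.0
    cross_species_concordance: float = 0.8
    mappable_fraction: float = 0.8
    one2many_fraction: float = 0.05
    human_extra_fraction: float = 0.1
    n_compounds: int = 400
    inverse_strength: float = 2.0
    cmap_arm_size: int = 50
    n_pathways: int = 6
    pathway_size: int = 40
    histology_n: tuple[int, int, int] = (7, 16, 7)   # healthy, vehicle, treated
    ct_samples_per_group: int = 8
    ct_noise_sd: float = 0.4
    ct_outliers: int = 0

    def __post_init__(self) -> None:
        for name in ("de_fraction", "reversal_fraction", "cross_species_concordance",
                     "mappable_fraction", "one2many_fraction", "human_extra_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigError(f"{name} must lie in [0, 1], got {v}")
        if not 0.0 < self.reversal_strength <= 1.0:
            raise ConfigError("reversal_strength must lie in (0, 1]")
        if self.n_landmarks <= 0:
            raise ConfigError("n_landmarks must be positive")
        if self.samples_per_group < 2 or self.human_samples_per_group < 2:
            raise ConfigError("at least 2 samples per group are required")
        if self.dispersion < 0:
            raise ConfigError("dispersion must be non-negative")
        lo, hi = self.libsize_range
        if not (0 < lo <= hi):
            raise ConfigError("libsize_range must satisfy 0 < low <= high")


def substream(seed: int, name: str) -> np.random.Generator:
    """Named, platform-stable RNG substream derived from the global seed."""
    return np.random.default_rng(
        np.random.SeedSequence(entropy=seed, spawn_key=(zlib.crc32(name.encode()),))
    )


@dataclass(frozen=True)
class GroundTruth:
    """Implanted truth flags enabling parameter-recovery tests.

    ``genes`` (per gene: is_de, direction, is_reversed), ``compounds``
    (per compound: is_inverse_hit) and ``pairs`` (per ortholog pair:
    is_concordant) are present for the generators that define them.
    """

    genes: pd.DataFrame | None = None
    compounds: pd.DataFrame | None = None
    pairs: pd.DataFrame | None = None


def _nb_draw(rng: np.random.Generator, mean: np.ndarray, dispersion: float) -> np.ndarray:
    if dispersion == 0:
        return rng.poisson(mean)
    size_param = 1.0 / dispersion
    p = size_param / (size_param + mean)
    return rng.negative_binomial(size_param, p)


def simulate_three_group_counts(
    config: SimulationConfig,
) -> tuple[ExpressionMatrix, SampleDesign, GroundTruth]:
    """Three-group NB counts with an implanted, partially reversed disease signature.

    The healthy group sits at gene-wise baselines; the disease group
    shifts ``de_fraction * n_genes`` genes by signed log2 effects drawn
    around ``effect_mean``; the treated group returns each reversed gene
    a fraction ``reversal_strength`` of the way back to healthy and
    leaves non-reversed disease genes at the disease level.
    """
    rng = substream(config.seed, "mouse_counts")
    g = config.n_genes
    genes = [f"mgene{i:05d}" for i in range(g)]

    baseline = np.exp(rng.normal(config.baseline_logmean_mean,
                                 config.baseline_logmean_sd, size=g))
    n_de = int(round(config.de_fraction * g))
    de_idx = rng.choice(g, size=n_de, replace=False)
    direction = np.zeros(g, dtype=int)
    direction[de_idx] = rng.choice([-1, 1], size=n_de)
    magnitude = np.zeros(g)
    magnitude[de_idx] = np.maximum(
        rng.normal(config.effect_mean, config.effect_sd, size=n_de),
        config.effect_floor,
    )
    n_rev = int(round(config.reversal_fraction * n_de))
    rev_idx = rng.choice(de_idx, size=n_rev, replace=False)
    is_reversed = np.zeros(g, dtype=bool)
    is_reversed[rev_idx] = True

    shift_disease = direction * magnitude
    shift_treated = shift_disease.copy()
    shift_treated[is_reversed] *= 1.0 - config.reversal_strength

    n = config.samples_per_group
    sample_ids, cols = [], []
    lo, hi = config.libsize_range
    for group, shift in zip(MOUSE_GROUPS,
                            (np.zeros(g), shift_disease, shift_treated)):
        means = baseline * np.power(2.0, shift)
        for i in range(n):
            lib = rng.uniform(lo, hi)
            cols.append(_nb_draw(rng, means * lib, config.dispersion))
            sample_ids.append(f"{group}_{i + 1}")
    values = pd.DataFrame(
        np.column_stack(cols).astype(np.int64), index=genes, columns=sample_ids
    )
    values.index.name = "gene_id"
    matrix = ExpressionMatrix(values=values, value_kind="counts")
    design = SampleDesign(
        assignments={s: s.rsplit("_", 1)[0] for s in sample_ids},
        group_order=MOUSE_GROUPS,
    )
    truth = GroundTruth(genes=pd.DataFrame(
        {"is_de": direction != 0, "direction": direction, "is_reversed": is_reversed},
        index=pd.Index(genes, name="gene_id"),
    ))
    return matrix, design, truth


def simulate_ortholog_map(config: SimulationConfig, gene_ids: list[str]) -> OrthologMap:
    """Ortholog map covering ``mappable_fraction`` of the given source genes.

    A fraction ``one2many_fraction`` of mapped sources receive a second
    target, exercising the downstream resolution policies.
    """
    rng = substream(config.seed, "ortholog_map")
    n_map = int(round(config.mappable_fraction * len(gene_ids)))
    src = sorted(rng.choice(len(gene_ids), size=n_map, replace=False))
    rows = []
    for j, i in enumerate(src):
        rows.append((gene_ids[i], f"HGENE{j:05d}"))
    n_multi = int(round(config.one2many_fraction * n_map))
    if n_multi:
        multi = rng.choice(n_map, size=n_multi, replace=False)
        for j in multi:
            rows.append((gene_ids[src[j]], f"HGENE{j:05d}B"))
    df = pd.DataFrame(rows, columns=["source_id", "target_id"])
    return OrthologMap(pairs=df.sort_values(["source_id", "target_id"])
                       .reset_index(drop=True))


def simulate_human_cohort(
    config: SimulationConfig,
    mouse_truth: GroundTruth,
    ortholog_map: OrthologMap,
) -> tuple[ExpressionMatrix, SampleDesign, GroundTruth]:
    """Two-group human cohort sharing concordant disease effects with the mouse study.

    A fraction ``cross_species_concordance`` of mapped mouse disease
    genes receive a same-direction log2 effect in the human disease
    group; all other human genes carry no effect.
    """
    if ortholog_map.pairs.empty:
        raise ValidationError("ortholog map is empty")
    if mouse_truth.genes is None:
        raise ValidationError("mouse ground truth with per-gene flags required")
    rng = substream(config.seed, "human_counts")

    pairs = ortholog_map.pairs.reset_index(drop=True)
    human_genes = list(dict.fromkeys(pairs["target_id"]))
    n_extra = int(round(config.human_extra_fraction * config.n_genes))
    human_genes += [f"HEXTRA{i:05d}" for i in range(n_extra)]

    mouse_de = mouse_truth.genes[mouse_truth.genes["is_de"]]
    de_pairs = pairs[pairs["source_id"].isin(mouse_de.index)]
    n_conc = int(round(config.cross_species_concordance * len(de_pairs)))
    full_pos = (rng.choice(de_pairs.index.to_numpy(), size=n_conc, replace=False)
                if n_conc else np.array([], dtype=int))
    is_concordant = np.zeros(len(pairs), dtype=bool)
    is_concordant[full_pos] = True

    direction = pd.Series(0, index=pd.Index(human_genes, name="gene_id"), dtype=int)
    magnitude = pd.Series(0.0, index=direction.index)
    for pos in full_pos:
        src, tgt = pairs.loc[pos, "source_id"], pairs.loc[pos, "target_id"]
        direction[tgt] = int(mouse_truth.genes.loc[src, "direction"])
        magnitude[tgt] = max(
            rng.normal(config.effect_mean, config.effect_sd), config.effect_floor
        )

    h = len(human_genes)
    baseline = np.exp(rng.normal(config.baseline_logmean_mean,
                                 config.baseline_logmean_sd, size=h))
    shift = direction.to_numpy() * magnitude.to_numpy()
    n = config.human_samples_per_group
    lo, hi = config.libsize_range
    sample_ids, cols = [], []
    for group, grp_shift in zip(HUMAN_GROUPS, (np.zeros(h), shift)):
        means = baseline * np.power(2.0, grp_shift)
        for i in range(n):
            lib = rng.uniform(lo, hi)
            cols.append(_nb_draw(rng, means * lib, config.dispersion))
            sample_ids.append(f"{group}_{i + 1}")
    values = pd.DataFrame(
        np.column_stack(cols).astype(np.int64), index=human_genes, columns=sample_ids
    )
    values.index.name = "gene_id"
    matrix = ExpressionMatrix(values=values, value_kind="counts")
    design = SampleDesign(
        assignments={s: s.rsplit("_", 1)[0] for s in sample_ids},
        group_order=HUMAN_GROUPS,
    )
    truth = GroundTruth(
        genes=pd.DataFrame(
            {"is_de": direction.to_numpy() != 0, "direction": direction.to_numpy()},
            index=direction.index,
        ),
        pairs=pairs.assign(is_concordant=is_concordant),
    )
    return matrix, design, truth


def landmark_feature_ids(n_landmarks: int) -> list[str]:
    return [f"L{i:04d}" for i in range(1, n_landmarks + 1)]


def simulate_landmark_signature(config: SimulationConfig) -> DirectionalSignature:
    """Random disjoint up/down tag lists over the landmark feature space."""
    rng = substream(config.seed, "landmark_signature")
    feats = landmark_feature_ids(config.n_landmarks)
    m = config.cmap_arm_size
    if 2 * m > len(feats):
        raise ValidationError("signature arms larger than landmark space")
    pick = rng.choice(len(feats), size=2 * m, replace=False)
    return DirectionalSignature(
        up=tuple(feats[i] for i in pick[:m]),
        down=tuple(feats[i] for i in pick[m:]),
        n_per_arm=m,
        source="simulated landmark disease signature",
    )


def simulate_compound_collection(
    config: SimulationConfig, disease_signature: DirectionalSignature
) -> tuple[ExpressionMatrix, GroundTruth]:
    """Compound z-score profiles over the landmark space with one implanted inverse hit.

    Profiles are standard-normal noise; the implanted compound subtracts
    ``inverse_strength`` from the signature's up-tag features and adds it
    to the down-tag features, i.e. it opposes the disease state.
    """
    feats = landmark_feature_ids(config.n_landmarks)
    missing = (set(disease_signature.up) | set(disease_signature.down)) - set(feats)
    if missing:
        raise ValidationError(
            f"signature features outside landmark space: {sorted(missing)[:5]}"
        )
    rng = substream(config.seed, "compounds")
    z = rng.standard_normal((config.n_landmarks, config.n_compounds))
    compounds = [f"CPD{i:04d}" for i in range(1, config.n_compounds + 1)]
    inv = int(rng.integers(config.n_compounds))
    fidx = {f: i for i, f in enumerate(feats)}
    up_rows = [fidx[f] for f in disease_signature.up]
    down_rows = [fidx[f] for f in disease_signature.down]
    z[up_rows, inv] -= config.inverse_strength
    z[down_rows, inv] += config.inverse_strength
    values = pd.DataFrame(z, index=feats, columns=compounds)
    values.index.name = "feature_id"
    truth = GroundTruth(compounds=pd.DataFrame(
        {"is_inverse_hit": [i == inv for i in range(config.n_compounds)]},
        index=pd.Index(compounds, name="compound_id"),
    ))
    return ExpressionMatrix(values=values, value_kind="zscore"), truth


def simulate_pathways(config: SimulationConfig, mouse_truth: GroundTruth) -> GeneSetCollection:
    """Gene sets emulating disease-perturbed pathways.

    Half the sets are enriched for implanted disease genes (their members
    are drawn mostly from the DE genes); the rest are background draws.
    """
    rng = substream(config.seed, "pathways")
    genes = mouse_truth.genes.index.to_numpy()
    de_genes = mouse_truth.genes.index[mouse_truth.genes["is_de"]].to_numpy()
    sets: dict[str, tuple[str, ...]] = {}
    descriptions: dict[str, str] = {}
    for i in range(config.n_pathways):
        name = f"PW{i + 1:02d}"
        if i < config.n_pathways // 2 and len(de_genes):
            n_hit = min(int(0.75 * config.pathway_size), len(de_genes))
            hit = rng.choice(de_genes, size=n_hit, replace=False)
            rest = rng.choice(genes, size=config.pathway_size - n_hit, replace=False)
            members = tuple(dict.fromkeys([*hit, *rest]))
            descriptions[name] = "disease-perturbed"
        else:
            members = tuple(dict.fromkeys(
                rng.choice(genes, size=config.pathway_size, replace=False)
            ))
            descriptions[name] = "background"
        sets[name] = members
    return GeneSetCollection(sets=sets, descriptions=descriptions)


class EndpointTables(NamedTuple):
    histology: pd.DataFrame
    ct: pd.DataFrame
    injected_outliers: list[tuple[str, str]]   # (sample_id, gene)


def simulate_endpoint_tables(config: SimulationConfig) -> EndpointTables:
    """Per-animal histology scores and a qPCR Ct table with a reference gene.

    Group distributions emulate a severe disease arm whose treatment
    benefit is driven by inflammation and ballooning rather than
    steatosis.  ``ct_outliers`` cells of the Ct table are displaced by
    five noise standard deviations to exercise the outlier rule.
    """
    rng = substream(config.seed, "endpoints")
    rows = []
    group_n = dict(zip(MOUSE_GROUPS, config.histology_n))
    for group, n in group_n.items():
        for i in range(n):
            if group == "healthy":
                steat = float(np.clip(abs(rng.normal(1.0, 1.0)), 0, 4))
                foci = 0
                ballooning = "none"
            elif group == "vehicle":
                steat = float(np.clip(rng.normal(40.0, 15.0), 5, 95))
                foci = int(rng.poisson(5.0))
                ballooning = "many" if rng.random() < 0.7 else "few"
            else:
                steat = float(np.clip(rng.normal(35.0, 15.0), 1, 95))
                foci = int(rng.poisson(1.2))
                ballooning = "few" if rng.random() < 0.5 else "none"
            rows.append((f"{group}_{i + 1}", group, round(steat, 2), foci, ballooning))
    histology = pd.DataFrame(rows, columns=[
        "animal_id", "group", "steatosis_pct", "foci_per_field", "ballooning_category"
    ])

    ct_rows = []
    for group in MOUSE_GROUPS:
        for i in range(config.ct_samples_per_group):
            sample = f"{group}_qpcr_{i + 1}"
            ref_ct = rng.normal(18.0, 0.3)
            ct_rows.append((sample, group, CT_REFERENCE_GENE, round(ref_ct, 3)))
            for gene, base_dct in CT_MARKERS.items():
                dct = base_dct + CT_GROUP_SHIFT[group] + rng.normal(0, config.ct_noise_sd)
                ct_rows.append((sample, group, gene, round(ref_ct + dct, 3)))
    ct = pd.DataFrame(ct_rows, columns=["sample_id", "group", "gene", "ct"])

    injected: list[tuple[str, str]] = []
    if config.ct_outliers:
        target_rows = ct.index[ct["gene"] != CT_REFERENCE_GENE].to_numpy()
        hit = rng.choice(target_rows, size=min(config.ct_outliers, len(target_rows)),
                         replace=False)
        for idx in hit:
            ct.loc[idx, "ct"] = round(ct.loc[idx, "ct"] + 5.0 * config.ct_noise_sd, 3)
            injected.append((ct.loc[idx, "sample_id"], ct.loc[idx, "gene"]))
    return EndpointTables(histology=histology, ct=ct, injected_outliers=injected)


def config_to_dict(config: SimulationConfig) -> dict:
    d = asdict(config)
    d["libsize_range"] = list(d["libsize_range"])
    d["histology_n"] = list(d["histology_n"])
    return d


def config_from_dict(d: dict) -> SimulationConfig:
    d = dict(d)
    if "libsize_range" in d:
        d["libsize_range"] = tuple(d["libsize_range"])
    if "histology_n" in d:
        d["histology_n"] = tuple(d["histology_n"])
    return SimulationConfig(**d)
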