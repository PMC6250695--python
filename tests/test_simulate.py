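"""Generator construction guarantees, determinism, and ground-truth wiring."""

import numpy as np
import pandas as pd
import pytest

from nashsig.core import ConfigError, ValidationError
from nashsig.endpoints import outlier_mask
from nashsig.simulate import (
    SimulationConfig,
    simulate_compound_collection,
    simulate_endpoint_tables,
    simulate_human_cohort,
    simulate_landmark_signature,
    simulate_ortholog_map,
    simulate_three_group_counts,
)


class TestConfig:
    @pytest.mark.parametrize("field,value", [
        ("de_fraction", 1.5),
        ("reversal_strength", 0.0),
        ("samples_per_group", 1),
        ("n_landmarks", 0),
        ("libsize_range", (0.0, 1.0)),
    ])
    def test_invalid_values_rejected(self, field, value):
        with pytest.raises(ConfigError):
            SimulationConfig(**{field: value})


class TestThreeGroupCounts:
    def test_de_gene_count_exact(self):
        cfg = SimulationConfig(seed=1, n_genes=2000, de_fraction=0.1)
        _, _, truth = simulate_three_group_counts(cfg)
        assert int(truth.genes["is_de"].sum()) == 200
        # reversed genes are a subset of DE genes, at the configured fraction
        assert int(truth.genes["is_reversed"].sum()) == 140
        assert (truth.genes.loc[truth.genes["is_reversed"], "is_de"]).all()

    def test_no_de_means_no_flags(self, small_config):
        cfg = SimulationConfig(seed=3, n_genes=200, de_fraction=0.0)
        _, _, truth = simulate_three_group_counts(cfg)
        assert not truth.genes["is_de"].any()

    def test_same_seed_identical(self, small_config):
        m1, _, _ = simulate_three_group_counts(small_config)
        m2, _, _ = simulate_three_group_counts(small_config)
        pd.testing.assert_frame_equal(m1.values, m2.values)

    def test_design_matches_matrix(self, small_config):
        matrix, design, _ = simulate_three_group_counts(small_config)
        design.check_matches(matrix)
        for group in design.group_order:
            assert len(design.samples_in(group)) == small_config.samples_per_group

    def test_disease_shift_visible_in_group_means(self):
        cfg = SimulationConfig(seed=5, n_genes=500, samples_per_group=8,
                               effect_mean=3.0)
        matrix, design, truth = simulate_three_group_counts(cfg)
        up_genes = truth.genes.index[truth.genes["direction"] == 1]
        healthy = matrix.values[design.samples_in("healthy")].loc[up_genes].mean(axis=1)
        vehicle = matrix.values[design.samples_in("vehicle")].loc[up_genes].mean(axis=1)
        assert (vehicle > healthy).mean() > 0.95


class TestHumanCohort:
    def test_full_concordance_with_bijective_map(self):
        cfg = SimulationConfig(seed=2, n_genes=300, cross_species_concordance=1.0,
                               one2many_fraction=0.0, human_samples_per_group=3)
        _, _, mouse_truth = simulate_three_group_counts(cfg)
        omap = simulate_ortholog_map(cfg, list(mouse_truth.genes.index))
        _, _, human_truth = simulate_human_cohort(cfg, mouse_truth, omap)
        pairs = human_truth.pairs
        mapped_de = pairs["source_id"].isin(
            mouse_truth.genes.index[mouse_truth.genes["is_de"]]
        )
        assert pairs.loc[mapped_de, "is_concordant"].all()
        # concordant targets carry the same implanted sign as their source
        for row in pairs[pairs["is_concordant"]].itertuples(index=False):
            assert (human_truth.genes.loc[row.target_id, "direction"]
                    == mouse_truth.genes.loc[row.source_id, "direction"])

    def test_zero_concordance_means_no_human_effects(self):
        cfg = SimulationConfig(seed=2, n_genes=300, cross_species_concordance=0.0,
                               human_samples_per_group=3)
        _, _, mouse_truth = simulate_three_group_counts(cfg)
        omap = simulate_ortholog_map(cfg, list(mouse_truth.genes.index))
        _, _, human_truth = simulate_human_cohort(cfg, mouse_truth, omap)
        assert not human_truth.genes["is_de"].any()

    def test_all_map_targets_measured(self, small_config):
        _, _, mouse_truth = simulate_three_group_counts(small_config)
        omap = simulate_ortholog_map(small_config, list(mouse_truth.genes.index))
        matrix, _, _ = simulate_human_cohort(small_config, mouse_truth, omap)
        assert set(omap.pairs["target_id"]) <= set(matrix.gene_ids)

    def test_empty_map_rejected(self, small_config):
        _, _, mouse_truth = simulate_three_group_counts(small_config)
        from nashsig.core import OrthologMap
        empty = OrthologMap(pairs=pd.DataFrame(
            {"source_id": pd.Series(dtype=str), "target_id": pd.Series(dtype=str)}
        ))
        with pytest.raises(ValidationError):
            simulate_human_cohort(small_config, mouse_truth, empty)


class TestCompoundCollection:
    def test_landmark_dimension_matches_config(self, small_config):
        sig = simulate_landmark_signature(small_config)
        profiles, _ = simulate_compound_collection(small_config, sig)
        assert profiles.shape == (small_config.n_landmarks, small_config.n_compounds)

    def test_exactly_one_inverse_hit(self, small_config):
        sig = simulate_landmark_signature(small_config)
        _, truth = simulate_compound_collection(small_config, sig)
        assert int(truth.compounds["is_inverse_hit"].sum()) == 1

    def test_implanted_shift_applied(self, small_config):
        sig = simulate_landmark_signature(small_config)
        profiles, truth = simulate_compound_collection(small_config, sig)
        inv = truth.compounds.index[truth.compounds["is_inverse_hit"]][0]
        col = profiles.values[inv]
        assert col.loc[list(sig.up)].mean() < -1.0
        assert col.loc[list(sig.down)].mean() > 1.0

    def test_zero_strength_compound_exchangeable(self, small_config):
        cfg = SimulationConfig(**{**small_config.__dict__, "inverse_strength": 0.0})
        sig = simulate_landmark_signature(cfg)
        profiles, truth = simulate_compound_collection(cfg, sig)
        inv = truth.compounds.index[truth.compounds["is_inverse_hit"]][0]
        col = profiles.values[inv]
        # no implanted shift: arm means stay at noise level
        assert abs(col.loc[list(sig.up)].mean()) < 1.0
        assert abs(col.loc[list(sig.down)].mean()) < 1.0

    def test_signature_outside_landmarks_rejected(self, small_config):
        from nashsig.core import DirectionalSignature
        sig = DirectionalSignature(up=("NOT_A_LANDMARK",), down=("L0001",), n_per_arm=1)
        with pytest.raises(ValidationError):
            simulate_compound_collection(small_config, sig)

    def test_same_seed_identical(self, small_config):
        sig = simulate_landmark_signature(small_config)
        p1, _ = simulate_compound_collection(small_config, sig)
        p2, _ = simulate_compound_collection(small_config, sig)
        pd.testing.assert_frame_equal(p1.values, p2.values)


class TestEndpointTables:
    def test_healthy_group_has_no_inflammation(self):
        tables = simulate_endpoint_tables(SimulationConfig(seed=4))
        healthy = tables.histology[tables.histology["group"] == "healthy"]
        assert (healthy["foci_per_field"] == 0).all()
        assert (healthy["ballooning_category"] == "none").all()

    def test_injected_outliers_flagged_by_mask(self):
        cfg = SimulationConfig(seed=4, ct_outliers=2)
        tables = simulate_endpoint_tables(cfg)
        assert len(tables.injected_outliers) == 2
        for sample, gene in tables.injected_outliers:
            sub = tables.ct[tables.ct["gene"] == gene]
            group = sub.loc[sub["sample_id"] == sample, "group"].iloc[0]
            vals = sub.loc[sub["group"] == group, "ct"].to_numpy()
            mask = outlier_mask(vals)
            idx = sub.loc[sub["group"] == group, "sample_id"].tolist().index(sample)
            assert not mask[idx]

    def test_reference_gene_present_for_every_sample(self):
        tables = simulate_endpoint_tables(SimulationConfig(seed=4))
        ct = tables.ct
        with_ref = set(ct.loc[ct["gene"] == "Rplp0", "sample_id"])
        assert set(ct["sample_id"]) == with_ref

    def test_same_seed_identical(self):
        t1 = simulate_endpoint_tables(SimulationConfig(seed=4))
        t2 = simulate_endpoint_tables(SimulationConfig(seed=4))
        pd.testing.assert_frame_equal(t1.histology, t2.histology)
        pd.testing.assert_frame_equal(t1.ct, t2.ct)


def test_substreams_are_independent_of_each_other():
    """Adding draws in one named stream never perturbs another stream."""
    from nashsig.simulate import substream
    a1 = substream(11, "alpha").standard_normal(5)
    _ = substream(11, "beta").standard_normal(1000)
    a2 = substream(11, "alpha").standard_normal(5)
    np.testing.assert_array_equal(a1, a2)
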