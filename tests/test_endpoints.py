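"""NAS rubric, rank-sum and ANOVA/LSD statistics, ddCt, outlier rule."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats
from scipy.stats import rankdata

from nashsig.core import ValidationError
from nashsig.endpoints import (
    CtTable,
    HistologyRecord,
    anova_lsd,
    ddct,
    nas_score,
    outlier_mask,
    wilcoxon_ranksum,
)


def _record(steatosis=0.0, foci=0.0, ballooning="none"):
    return HistologyRecord(animal_id="a", group="g", steatosis_pct=steatosis,
                           foci_per_field=foci, ballooning_category=ballooning)


class TestNasScore:
    @pytest.mark.parametrize("pct,expected", [
        (0, 0), (4.9, 0), (5, 1), (32.9, 1), (33, 2), (66, 2), (66.1, 3),
        (70, 3), (100, 3),
    ])
    def test_steatosis_bands(self, pct, expected):
        assert nas_score(_record(steatosis=pct)).steatosis_score == expected

    @pytest.mark.parametrize("foci,expected", [
        (0, 0), (1, 1), (1.9, 1), (2, 2), (4, 2), (5, 3), (12, 3),
    ])
    def test_inflammation_bands(self, foci, expected):
        assert nas_score(_record(foci=foci)).inflammation_score == expected

    @pytest.mark.parametrize("cat,expected", [("none", 0), ("few", 1), ("many", 2)])
    def test_ballooning(self, cat, expected):
        assert nas_score(_record(ballooning=cat)).ballooning_score == expected

    def test_total_is_component_sum(self):
        res = nas_score(_record(steatosis=70, foci=5, ballooning="many"))
        assert res.total == 8 == (res.steatosis_score + res.inflammation_score
                                  + res.ballooning_score)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValidationError):
            _record(steatosis=101)


def enumeration_oracle_p(a: np.ndarray, b: np.ndarray) -> float:
    """Two-sided rank-sum p by explicit enumeration of every assignment."""
    pooled = np.concatenate([a, b])
    ranks = rankdata(pooled)
    n, na = len(pooled), len(a)
    mu = na * (n + 1) / 2.0
    w_obs = ranks[:na].sum()
    count = total = 0
    for idx in itertools.combinations(range(n), na):
        w = ranks[list(idx)].sum()
        total += 1
        if abs(w - mu) >= abs(w_obs - mu) - 1e-9:
            count += 1
    return count / total


class TestWilcoxon:
    def test_most_extreme_split(self):
        w, p = wilcoxon_ranksum([1, 2], [3, 4])
        assert w == 3.0
        assert p == pytest.approx(2 / 6)

    def test_identical_groups_p_one(self):
        _, p = wilcoxon_ranksum([5, 5, 7], [5, 7, 5])
        assert p == 1.0

    def test_constant_data_p_one(self):
        _, p = wilcoxon_ranksum([3, 3], [3, 3, 3])
        assert p == 1.0

    @pytest.mark.parametrize("na,nb,tied", [
        (2, 2, False), (3, 3, False), (4, 4, False), (5, 5, False),
        (2, 5, False), (3, 4, True), (4, 6, True), (5, 5, True),
    ])
    def test_exact_matches_enumeration_oracle(self, na, nb, tied):
        rng = np.random.default_rng(na * 100 + nb + tied)
        if tied:
            a = rng.integers(0, 4, size=na).astype(float)
            b = rng.integers(0, 4, size=nb).astype(float)
        else:
            a, b = rng.standard_normal(na), rng.standard_normal(nb)
        if np.all(np.concatenate([a, b]) == a[0]):
            a[0] += 1.0
        _, p = wilcoxon_ranksum(a, b, mode="exact")
        assert p == pytest.approx(enumeration_oracle_p(a, b), abs=1e-12)

    def test_exact_and_approx_agree_at_moderate_n(self):
        rng = np.random.default_rng(42)
        a, b = rng.standard_normal(20), rng.standard_normal(20) + 0.4
        _, p_exact = wilcoxon_ranksum(a, b, mode="exact")
        _, p_approx = wilcoxon_ranksum(a, b, mode="approx")
        assert abs(p_exact - p_approx) < 0.02

    def test_empty_group_rejected(self):
        with pytest.raises(ValidationError):
            wilcoxon_ranksum([], [1.0])


class TestAnovaLsd:
    def test_constant_groups(self):
        res = anova_lsd({"a": [2, 2], "b": [2, 2], "c": [2, 2]})
        assert res.f_statistic == 0.0 and res.p_anova == 1.0
        assert (res.pairwise["p"] == 1.0).all()

    def test_two_groups_equals_pooled_t(self):
        rng = np.random.default_rng(3)
        a, b = rng.standard_normal(6), rng.standard_normal(8) + 0.5
        res = anova_lsd({"a": a, "b": b})
        t_stat, t_p = stats.ttest_ind(a, b, equal_var=True)
        assert res.f_statistic == pytest.approx(t_stat ** 2, rel=1e-10)
        assert res.p_anova == pytest.approx(t_p, rel=1e-10)
        assert res.pairwise["p"].iloc[0] == pytest.approx(t_p, rel=1e-10)

    def test_hand_computed_three_groups(self):
        # groups (1,2,3),(2,3,4),(6,7,8): SSB = 42, SSW = 6 => F = 21
        res = anova_lsd({"g1": [1, 2, 3], "g2": [2, 3, 4], "g3": [6, 7, 8]})
        assert res.f_statistic == pytest.approx(21.0, abs=1e-6)
        assert res.p_anova == pytest.approx(float(stats.f.sf(21.0, 2, 6)), abs=1e-9)

    def test_small_group_rejected(self):
        with pytest.raises(ValidationError):
            anova_lsd({"a": [1.0], "b": [1, 2]})


class TestDdct:
    def _table(self, ct_rows):
        df = pd.DataFrame(ct_rows, columns=["sample_id", "group", "gene", "ct"])
        return CtTable(data=df, reference_gene="Rplp0")

    def test_hand_computed_fold_change(self):
        # control dCt mean 5, treated dCt mean 7 => ddCt = 2, fold = 0.25
        table = self._table([
            ("c1", "ctrl", "Rplp0", 15.0), ("c1", "ctrl", "Ifng", 20.0),
            ("c2", "ctrl", "Rplp0", 16.0), ("c2", "ctrl", "Ifng", 21.0),
            ("t1", "trt", "Rplp0", 15.0), ("t1", "trt", "Ifng", 22.0),
            ("t2", "trt", "Rplp0", 16.0), ("t2", "trt", "Ifng", 23.0),
        ])
        res = ddct(table, "Ifng", control_group="ctrl", treated_group="trt")
        assert res.ddct == pytest.approx(2.0)
        assert res.fold_change == pytest.approx(0.25)

    def test_zero_ddct_fold_one(self):
        table = self._table([
            ("c1", "ctrl", "Rplp0", 15.0), ("c1", "ctrl", "Ifng", 20.0),
            ("t1", "trt", "Rplp0", 16.0), ("t1", "trt", "Ifng", 21.0),
        ])
        res = ddct(table, "Ifng", control_group="ctrl", treated_group="trt")
        assert res.fold_change == pytest.approx(1.0)

    def test_reciprocal_identity(self):
        table = self._table([
            ("c1", "ctrl", "Rplp0", 15.0), ("c1", "ctrl", "Ifng", 18.5),
            ("t1", "trt", "Rplp0", 16.0), ("t1", "trt", "Ifng", 22.25),
        ])
        fwd = ddct(table, "Ifng", control_group="ctrl", treated_group="trt")
        rev = ddct(table, "Ifng", control_group="trt", treated_group="ctrl")
        assert fwd.fold_change * rev.fold_change == pytest.approx(1.0)

    def test_missing_reference_named(self):
        with pytest.raises(ValidationError, match="t1"):
            self._table([
                ("c1", "ctrl", "Rplp0", 15.0), ("c1", "ctrl", "Ifng", 20.0),
                ("t1", "trt", "Ifng", 22.0),
            ])


class TestOutlierMask:
    def test_hand_computed_single_outlier(self):
        values = [1, 2, 3, 4, 5, 6, 7, 8, 9, 100]
        # mean 14.5, sample SD ~30.15 => only 100 exceeds 74.8
        mask = outlier_mask(values)
        assert mask.sum() == 9 and not mask[-1]

    def test_constant_vector_all_retained(self):
        assert outlier_mask([4, 4, 4]).all()

    def test_single_pass_not_reapplied(self):
        # after excluding 1000, the value 40 would fail a second pass;
        # the rule is single-pass so 40 must be retained
        values = np.array([1.0, 2, 3, 2, 1, 2, 3, 40, 1000])
        mask = outlier_mask(values)
        assert not mask[-1]
        assert mask[-2]
        retained = values[mask]
        second = outlier_mask(retained)
        assert not second[-1]   # confirms 40 is extreme on re-test, yet retained

    def test_too_few_values_rejected(self):
        with pytest.raises(ValidationError):
            outlier_mask([1.0, 2.0])
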