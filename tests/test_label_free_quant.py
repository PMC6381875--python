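import math

import numpy as np
import pytest
from scipy import integrate, stats

from phosphodiff import io as pio
from phosphodiff.models import GENOTYPE_CONTRAST, SEX_CONTRAST, SampleDescriptor
from phosphodiff.quant import (
    aggregate_observations,
    bias_scores,
    fold_change_scatter,
    group_sum_comparison,
    quant_contrast,
)

from conftest import make_design, make_obs


class TestAggregation:
    def test_fractions_summed_then_normalized(self):
        design = [SampleDescriptor("WT_F1", "WT", "F", 1.5)]
        obs = [
            make_obs("WT_F1", area=1e5, fraction=1),
            make_obs("WT_F1", area=2e5, fraction=2),
        ]
        qm = aggregate_observations(obs, design)
        assert qm.areas.iloc[0, 0] == pytest.approx(2e5)

    def test_met_ox_variants_combined(self, design8):
        obs = [
            make_obs("WT_F1", area=1e5, ox=0),
            make_obs("WT_F1", area=3e5, ox=1),
        ]
        qm = aggregate_observations(obs, design8)
        assert qm.areas.shape[0] == 1
        assert qm.areas.loc[str(obs[0].key()), "WT_F1"] == pytest.approx(4e5)

    def test_phospho_states_stay_separate(self, design8):
        obs = [
            make_obs("WT_F1", seq="ASPSK", offsets=(2,), area=1e5),
            make_obs("WT_F1", seq="ASPSK", offsets=(2, 4), area=1e5),
        ]
        qm = aggregate_observations(obs, design8)
        assert qm.areas.shape[0] == 2

    def test_fraction_split_additivity(self, design8):
        """Splitting any observation across extra fractions leaves the
        matrix unchanged."""
        whole = [make_obs("WT_F1", area=6e5, fraction=1)]
        split = [
            make_obs("WT_F1", area=1e5, fraction=1),
            make_obs("WT_F1", area=2e5, fraction=2),
            make_obs("WT_F1", area=3e5, fraction=3),
        ]
        a = aggregate_observations(whole, design8)
        b = aggregate_observations(split, design8)
        assert a.areas.equals(b.areas)

    def test_shared_sequence_maps_to_all_proteins(self, design8):
        obs = [
            make_obs("WT_F1", acc="P1", gene="G1"),
            make_obs("WT_F2", acc="P2", gene="G2"),
        ]
        qm = aggregate_observations(obs, design8)
        key = str(obs[0].key())
        assert qm.areas.shape[0] == 1  # one peptide-level row
        assert qm.accessions[key] == frozenset({"P1", "P2"})

    def test_zero_area_cell_is_missing(self, design8):
        qm = aggregate_observations([make_obs("WT_F1", area=0.0)], design8)
        assert qm.areas.isna().all().all()


class TestBiasScores:
    def build(self, wt_areas, ko_areas, design):
        obs = []
        wt = [s.sample_id for s in design if s.genotype == "WT"]
        ko = [s.sample_id for s in design if s.genotype == "KO"]
        for sid, area in zip(wt, wt_areas):
            obs.append(make_obs(sid, area=area))
        for sid, area in zip(ko, ko_areas):
            obs.append(make_obs(sid, area=area))
        return aggregate_observations(obs, design)

    def test_equal_groups_score_zero(self, design8):
        qm = self.build([2.0] * 4, [2.0] * 4, design8)
        scores = bias_scores(qm, GENOTYPE_CONTRAST)
        assert scores["score_a"].iloc[0] == pytest.approx(0.0)
        assert scores["score_b"].iloc[0] == pytest.approx(0.0)

    def test_twofold_group_mean_gives_ln2(self, design8):
        # group A mean 2e6 vs grand mean 1e6 -> ln 2 = 0.693
        qm = self.build([0.0001e6] * 4, [2e6] * 4, design8)  # KO is group A
        scores = bias_scores(qm, GENOTYPE_CONTRAST)
        grand = qm.areas.mean(axis=1).iloc[0]
        assert scores["score_a"].iloc[0] == pytest.approx(math.log(2e6 / grand))
        assert round(math.log(2.0), 3) == 0.693

    def test_swapping_groups_swaps_scores(self, design8):
        qm = self.build([1.0] * 4, [3.0] * 4, design8)
        scores = bias_scores(qm, GENOTYPE_CONTRAST)
        flipped = bias_scores(
            qm,
            type(GENOTYPE_CONTRAST)("flip", "genotype", "WT", "KO"),
        )
        assert scores["score_a"].iloc[0] == pytest.approx(flipped["score_b"].iloc[0])
        assert scores["score_b"].iloc[0] == pytest.approx(flipped["score_a"].iloc[0])

    def test_score_difference_identity(self, small_sim):
        """score_a - score_b == ln(mean_a) - ln(mean_b) for every key."""
        design = pio.read_design(small_sim["paths"]["design"])
        obs = pio.read_observations(small_sim["paths"]["observations"], design)
        qm = aggregate_observations(obs, design)
        scores = bias_scores(qm, SEX_CONTRAST)
        f, m = qm.group_samples(SEX_CONTRAST)
        for ks in scores.index:
            diff = scores.at[ks, "score_a"] - scores.at[ks, "score_b"]
            expected = math.log(qm.areas.loc[ks, f].mean()) - math.log(
                qm.areas.loc[ks, m].mean()
            )
            assert diff == pytest.approx(expected, abs=1e-12)


class TestQuantContrast:
    def build_groups(self, a_vals, b_vals, design):
        """Feed exp(values) so the ln transform recovers the given numbers;
        group A of the genotype contrast is KO."""
        ko = [s.sample_id for s in design if s.genotype == "KO"]
        wt = [s.sample_id for s in design if s.genotype == "WT"]
        obs = [make_obs(sid, area=math.exp(v)) for sid, v in zip(ko, a_vals)]
        obs += [make_obs(sid, area=math.exp(v)) for sid, v in zip(wt, b_vals)]
        return aggregate_observations(obs, design)

    def test_identical_groups(self, design8):
        qm = self.build_groups([1, 2, 3], [1, 2, 3], make_design(3))
        (r,) = quant_contrast(qm, GENOTYPE_CONTRAST)
        assert r.t == pytest.approx(0.0)
        assert r.p_two_sided == pytest.approx(1.0)

    def test_pooled_t_worked_example(self):
        # {1,2,3} vs {4,5,6} on the ln scale: t = -3.674, df = 4, p = 0.0213
        qm = self.build_groups([1, 2, 3], [4, 5, 6], make_design(3))
        (r,) = quant_contrast(qm, GENOTYPE_CONTRAST)
        assert r.t == pytest.approx(-3.674, abs=5e-4)
        assert r.p_two_sided == pytest.approx(0.0213, abs=5e-5)
        assert r.direction == "WT"

    def test_p_matches_t_density_integration(self):
        qm = self.build_groups([1, 2, 3], [4, 5, 6], make_design(3))
        (r,) = quant_contrast(qm, GENOTYPE_CONTRAST)
        df = 4
        tail, _ = integrate.quad(lambda x: stats.t.pdf(x, df), abs(r.t), np.inf)
        assert r.p_two_sided == pytest.approx(2 * tail, abs=1e-9)

    def test_below_min_per_group_not_tested(self):
        qm = self.build_groups([1, 2], [4, 5], make_design(2))
        assert quant_contrast(qm, GENOTYPE_CONTRAST, min_per_group=3) == []

    def test_zero_variance_unequal_means_degenerate(self):
        qm = self.build_groups([1, 1, 1], [2, 2, 2], make_design(3))
        (r,) = quant_contrast(qm, GENOTYPE_CONTRAST)
        assert r.degenerate and r.p_two_sided == 0.0

    def test_welch_flag_changes_statistic(self):
        qm = self.build_groups([1.0, 2.0, 3.5], [4.0, 5.5, 6.0, 7.0], make_design(4))
        (pooled,) = quant_contrast(qm, GENOTYPE_CONTRAST)
        (welch,) = quant_contrast(qm, GENOTYPE_CONTRAST, welch=True)
        assert pooled.p_two_sided != welch.p_two_sided


class TestGroupSums:
    def test_identical_groups_t_zero(self, design8):
        obs = [make_obs(s.sample_id, area=5.0) for s in design8]
        qm = aggregate_observations(obs, design8)
        out = group_sum_comparison(qm, GENOTYPE_CONTRAST, list(qm.areas.index))
        assert out["t"] == pytest.approx(0.0)

    def test_empty_subset_rejected(self, design8):
        qm = aggregate_observations([make_obs("WT_F1")], design8)
        with pytest.raises(ValueError):
            group_sum_comparison(qm, GENOTYPE_CONTRAST, [])

    def test_planted_bias_detected(self, design8):
        obs = []
        for s in design8:
            area = 10.0 if s.sex == "F" else 1.0
            obs.append(make_obs(s.sample_id, area=area * (1 + 0.01 * int(s.sample_id[-1]))))
        qm = aggregate_observations(obs, design8)
        out = group_sum_comparison(qm, SEX_CONTRAST, list(qm.areas.index))
        assert out["mean_a"] > out["mean_b"]
        assert out["p_two_sided"] < 0.05


class TestFoldChangeScatter:
    def test_e_squared_ratio_flagged(self, design8):
        obs = []
        for s in design8:
            area = math.e**2 if s.genotype == "KO" else 1.0
            obs.append(make_obs(s.sample_id, area=area))
        qm = aggregate_observations(obs, design8)
        scatter = fold_change_scatter(qm, GENOTYPE_CONTRAST, SEX_CONTRAST)
        row = scatter.iloc[0]
        assert row["ln_ratio_genotype"] == pytest.approx(2.0)
        assert row["flag_genotype"] and not row["flag_sex"]

    def test_no_difference_unflagged(self, design8):
        obs = [make_obs(s.sample_id, area=7.0) for s in design8]
        qm = aggregate_observations(obs, design8)
        row = fold_change_scatter(qm, GENOTYPE_CONTRAST, SEX_CONTRAST).iloc[0]
        assert row["ln_ratio_genotype"] == pytest.approx(0.0)
        assert row["ln_ratio_sex"] == pytest.approx(0.0)
        assert not row["flag_genotype"] and not row["flag_sex"]

    def test_missing_group_mean_omitted(self, design8):
        obs = [make_obs(s.sample_id) for s in design8 if s.genotype == "WT"]
        qm = aggregate_observations(obs, design8)
        assert fold_change_scatter(qm, GENOTYPE_CONTRAST, SEX_CONTRAST).empty

    def test_cutoff_is_about_2_7_fold(self):
        assert math.exp(1.0) == pytest.approx(2.718, abs=5e-4)
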