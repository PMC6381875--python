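import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import integrate, stats

from phosphodiff.detection import (
    DegenerateProportionsError,
    build_detection_matrix,
    detection_frequency_summary,
    exclusive_peptides,
    one_sided_p,
    pairwise_repeatability,
    two_proportion_z,
)
from phosphodiff.models import GENOTYPE_CONTRAST, SEX_CONTRAST

from conftest import make_design, make_obs


class TestTwoProportionZ:
    @pytest.mark.parametrize(
        "x1,n1,x2,n2,expected,places",
        [
            (3, 8, 0, 8, 1.92, 2),  # the canonical 3-of-8 vs 0-of-8 cut-off
            (2, 8, 0, 8, 1.5119, 4),
            (3, 8, 1, 8, 1.1547, 4),  # pooled formula value for 3/8 vs 1/8
            (4, 8, 4, 8, 0.0, 10),
        ],
    )
    def test_worked_values(self, x1, n1, x2, n2, expected, places):
        assert round(two_proportion_z(x1, n1, x2, n2), places) == expected

    @pytest.mark.parametrize("x1,x2", [(0, 0), (8, 8)])
    def test_degenerate_pooled_variance(self, x1, x2):
        with pytest.raises(DegenerateProportionsError):
            two_proportion_z(x1, 8, x2, 8)

    @pytest.mark.parametrize("bad", [(-1, 8, 0, 8), (9, 8, 0, 8), (1, 0, 0, 8)])
    def test_invalid_counts(self, bad):
        with pytest.raises(ValueError):
            two_proportion_z(*bad)

    @settings(max_examples=200, derandomize=True)
    @given(
        x1=st.integers(0, 12),
        n1=st.integers(1, 12),
        x2=st.integers(0, 12),
        n2=st.integers(1, 12),
    )
    def test_antisymmetry(self, x1, n1, x2, n2):
        if x1 > n1 or x2 > n2 or x1 + x2 == 0 or x1 + x2 == n1 + n2:
            return
        assert two_proportion_z(x1, n1, x2, n2) == pytest.approx(
            -two_proportion_z(x2, n2, x1, n1), abs=1e-12
        )

    def test_strictly_increasing_in_x1(self):
        values = [two_proportion_z(x, 8, 2, 8) for x in range(0, 7)]
        assert all(b > a for a, b in zip(values, values[1:]))


class TestOneSidedP:
    @pytest.mark.parametrize(
        "z,expected,places",
        [(1.9215, 0.027, 3), (0.0, 0.5, 10), (-1.9215, 0.973, 3)],
    )
    def test_worked_values(self, z, expected, places):
        assert round(one_sided_p(z), places) == expected

    def test_symmetry_identity(self):
        for z in np.linspace(-6, 6, 25):
            assert one_sided_p(z) + one_sided_p(-z) == pytest.approx(1.0, abs=1e-12)

    def test_matches_numerical_integration(self):
        """Oracle: integrate the standard normal density directly."""
        for z in (-3.0, -1.0, 0.0, 0.5, 1.9215, 3.5):
            oracle, _ = integrate.quad(
                lambda t: math.exp(-t * t / 2) / math.sqrt(2 * math.pi), z, np.inf
            )
            assert one_sided_p(z) == pytest.approx(oracle, abs=1e-6)


class TestDetectionMatrix:
    def test_fraction_only_detection_counts(self, design8):
        obs = [make_obs("WT_F1", fraction=2)]
        matrix = build_detection_matrix(obs, design8)
        key = str(obs[0].key())
        assert bool(matrix.detected.loc[key, "WT_F1"])
        assert matrix.detected.loc[key].sum() == 1

    def test_phospho_states_are_distinct_rows(self, design8):
        obs = [
            make_obs("WT_F1", seq="ASPSK", offsets=(2,)),
            make_obs("WT_F1", seq="ASPSK", offsets=(2, 4)),
        ]
        matrix = build_detection_matrix(obs, design8)
        assert matrix.detected.shape[0] == 2

    def test_no_observations_gives_all_false(self, design8):
        matrix = build_detection_matrix([], design8)
        assert matrix.detected.shape == (0, 8)

    def test_idempotent_under_duplication(self, design8):
        obs = [make_obs("WT_F1"), make_obs("KO_M2", fraction=3)]
        m1 = build_detection_matrix(obs, design8)
        m2 = build_detection_matrix(obs + obs, design8)
        assert m1.detected.equals(m2.detected)


class TestExclusivePeptides:
    def build(self, detect_map, design):
        obs = []
        for seq, samples in detect_map.items():
            for sid in samples:
                obs.append(make_obs(sid, seq=seq, offsets=(seq.index("S") + 1,)))
        return build_detection_matrix(obs, design)

    def test_exclusive_called_with_direction(self, design16):
        wt = [s.sample_id for s in design16 if s.genotype == "WT"][:4]
        matrix = self.build({"ASPK": wt}, design16)
        results = exclusive_peptides(matrix, GENOTYPE_CONTRAST)
        assert len(results) == 1
        r = results[0]
        assert r.direction == "WT" and r.significant
        assert (r.x1, r.n1, r.x2, r.n2) == (0, 8, 4, 8)

    def test_two_of_eight_not_called(self, design16):
        wt = [s.sample_id for s in design16 if s.genotype == "WT"][:2]
        matrix = self.build({"ASPK": wt}, design16)
        assert exclusive_peptides(matrix, GENOTYPE_CONTRAST) == []

    def test_ubiquitous_key_not_called(self, design16):
        matrix = self.build({"ASPK": [s.sample_id for s in design16]}, design16)
        assert exclusive_peptides(matrix, GENOTYPE_CONTRAST) == []

    def test_p_matches_integration_oracle(self, design16):
        wt = [s.sample_id for s in design16 if s.genotype == "WT"][:3]
        matrix = self.build({"ASPK": wt}, design16)
        (r,) = exclusive_peptides(matrix, GENOTYPE_CONTRAST)
        oracle, _ = integrate.quad(stats.norm.pdf, abs(r.z), np.inf)
        assert r.p_one_sided == pytest.approx(oracle, abs=1e-6)

    def test_two_sided_flag_doubles_p(self, design16):
        wt = [s.sample_id for s in design16 if s.genotype == "WT"][:4]
        matrix = self.build({"ASPK": wt}, design16)
        (one,) = exclusive_peptides(matrix, GENOTYPE_CONTRAST)
        (two,) = exclusive_peptides(matrix, GENOTYPE_CONTRAST, two_sided=True)
        assert two.p_one_sided == pytest.approx(2 * one.p_one_sided)


class TestDetectionFrequency:
    def test_all_detected_everywhere(self, design8):
        group = [s.sample_id for s in design8 if s.genotype == "WT"]
        obs = [make_obs(sid) for sid in group]
        matrix = build_detection_matrix(obs, design8)
        assert detection_frequency_summary(matrix, group) == {
            k: 1.0 for k in range(1, len(group) + 1)
        }

    def test_single_key_detected_once(self, design16):
        group = [s.sample_id for s in design16 if s.genotype == "WT" and s.sex == "F"]
        matrix = build_detection_matrix([make_obs(group[0])], design16)
        assert detection_frequency_summary(matrix, group) == {1: 1.0, 2: 0.0, 3: 0.0, 4: 0.0}

    def test_matches_brute_force_enumeration(self, design16):
        rng = np.random.default_rng(0)
        group = [s.sample_id for s in design16 if s.genotype == "KO"]
        obs = []
        for i in range(40):
            seq = "A" + "S" + "".join(rng.choice(list("ACDEFGHIK"), size=5)) + "K"
            for sid in rng.choice(group, size=rng.integers(1, 9), replace=False):
                obs.append(make_obs(sid, seq=seq, offsets=(2,)))
        matrix = build_detection_matrix(obs, design16)
        summary = detection_frequency_summary(matrix, group)
        counts = matrix.detected[group].sum(axis=1)
        counts = counts[counts >= 1]
        for k, frac in summary.items():
            assert frac == pytest.approx(sum(c >= k for c in counts) / len(counts))
        assert all(
            summary[k] >= summary[k + 1] for k in range(1, len(group))
        ), "non-increasing in k"


class TestRepeatability:
    def test_identical_sets_full_overlap(self, design8):
        group = [s.sample_id for s in design8 if s.genotype == "WT"]
        obs = [make_obs(sid, seq=seq, offsets=(2,)) for sid in group for seq in ("ASPK", "TSIR")]
        matrix = build_detection_matrix(obs, design8)
        assert pairwise_repeatability(matrix, group) == [100.0] * 6

    def test_min_denominator_overlap(self, design8):
        # A = {a,b,c}, B = {b,c,d}: 2 shared / min(3,3) = 66.7%
        seqs = {"ASPKA": "ab", "BSPKB": "ab", "CSPKC": "a", "DSPKD": "b"}
        mapping = {"a": "WT_F1", "b": "WT_F2"}
        obs = []
        for seq, samples in seqs.items():
            for tag in samples:
                obs.append(make_obs(mapping[tag], seq=seq, offsets=(2,)))
        matrix = build_detection_matrix(obs, design8)
        (overlap,) = pairwise_repeatability(matrix, ["WT_F1", "WT_F2"])
        assert overlap == pytest.approx(200 / 3)

    def test_disjoint_sets(self, design8):
        obs = [
            make_obs("WT_F1", seq="ASPKA", offsets=(2,)),
            make_obs("WT_F2", seq="BSPKB", offsets=(2,)),
        ]
        matrix = build_detection_matrix(obs, design8)
        (overlap,) = pairwise_repeatability(matrix, ["WT_F1", "WT_F2"])
        assert overlap == 0.0

    def test_pair_count_for_group_of_eight(self, default_study):
        import phosphodiff.io as pio

        design = pio.read_design(default_study["paths"]["design"])
        obs = pio.read_observations(default_study["paths"]["observations"], design)
        matrix = build_detection_matrix(obs, design)
        group = [s.sample_id for s in design if s.genotype == "WT"]
        vals = pairwise_repeatability(matrix, group)
        assert len(vals) == 28  # C(8, 2)
        assert all(0 <= v <= 100 for v in vals)

    def test_protein_level_collapses_keys(self, design8):
        obs = [
            make_obs("WT_F1", seq="ASPKA", offsets=(2,), acc="P9"),
            make_obs("WT_F2", seq="BSPKB", offsets=(2,), acc="P9"),
        ]
        matrix = build_detection_matrix(obs, design8)
        (peptide,) = pairwise_repeatability(matrix, ["WT_F1", "WT_F2"], level="peptide")
        (protein,) = pairwise_repeatability(matrix, ["WT_F1", "WT_F2"], level="protein")
        assert peptide == 0.0 and protein == 100.0
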