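"""Band/offset scoring rules, totals, ranking."""

import itertools
import math
from types import SimpleNamespace

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from herblike import (
    CompoundRecord,
    DescriptorSet,
    default_rules,
    max_score,
    min_score,
    rank_library,
    score_compound,
    score_continuous,
    score_discrete,
)
from herblike.descriptors import ALL_DESCRIPTORS, CONTINUOUS_DESCRIPTORS, DISCRETE_DESCRIPTORS

# Published band scores: every continuous descriptor scores
# (1.5, 1.0, 0.5, -1.0) per SD band except log P, which is doubled inside
# three SD. Offset tables for the counts, with the heavy charge weighting.
EXPECTED_CONTINUOUS = {
    "molar_mass": (1.5, 1.0, 0.5, -1.0),
    "aromatic_pct": (1.5, 1.0, 0.5, -1.0),
    "psa": (1.5, 1.0, 0.5, -1.0),
    "logd74": (1.5, 1.0, 0.5, -1.0),
    "logs": (1.5, 1.0, 0.5, -1.0),
    "logp": (3.0, 2.0, 1.0, -1.0),
}
EXPECTED_DISCRETE = {
    "rotatable_bonds": ({-2: 0.5, -1: 1.0, 0: 1.5, 1: 1.0, 2: 0.5}, -1.0),
    "hba74": ({-2: 0.5, -1: 1.0, 0: 1.5, 1: 1.0, 2: 0.5}, -1.0),
    "hbd74": ({-2: 0.5, -1: 1.0, 0: 1.5, 1: 1.0, 2: 0.5}, -1.0),
    "formal_charge74": ({-2: 1.0, -1: 2.0, 0: 3.0, 1: 2.0, 2: -3.0}, -1.0),
}

BAND_REPRESENTATIVE_Z = (0.5, 1.5, 2.5, 3.5)
OFFSET_CLASSES = (-2, -1, 0, 1, 2, 3)  # 3 stands for the |offset| > 2 catch-all


def _fake_descriptors(model, cont_z, disc_off):
    """Descriptor values hitting the requested band/offset classes."""
    values = {}
    for name, z in zip(CONTINUOUS_DESCRIPTORS, cont_z):
        mean, sd = model.continuous_stats[name]
        values[name] = mean + z * sd
    for name, off in zip(DISCRETE_DESCRIPTORS, disc_off):
        values[name] = model.discrete_modes[name] + off
    return SimpleNamespace(**values)


class TestScoreContinuous:
    @pytest.mark.parametrize("name", CONTINUOUS_DESCRIPTORS)
    @pytest.mark.parametrize("z, band_idx", [
        (0.0, 0), (0.99, 0), (1.0, 0),        # within 1 SD, boundary inclusive
        (1.5, 1), (2.0, 1),                    # within 2 SD
        (2.5, 2), (3.0, 2),                    # within 3 SD
        (3.0000001, 3), (10.0, 3),             # beyond
    ])
    def test_every_band_cell(self, published_model, rules, name, z, band_idx):
        mean, sd = published_model.continuous_stats[name]
        bands = rules.continuous_bands[name]
        score, _ = score_continuous(mean + z * sd, mean, sd, bands)
        assert score == EXPECTED_CONTINUOUS[name][band_idx]
        assert bands == EXPECTED_CONTINUOUS[name]

    def test_logp_at_published_mean_scores_double_weight(self, rules):
        score, band = score_continuous(2.9, 2.9, 1.5, rules.continuous_bands["logp"])
        assert (score, band) == (3.0, "within_1sd")

    def test_two_sd_cell(self, rules):
        score, _ = score_continuous(317 + 1.5 * 88, 317, 88, rules.continuous_bands["molar_mass"])
        assert score == 1.0

    @given(
        d=st.floats(min_value=0, max_value=50, allow_nan=False),
        mean=st.floats(-100, 100),
        sd=st.floats(0.01, 50),
    )
    @settings(max_examples=200, deadline=None)
    def test_band_symmetry_about_the_mean(self, d, mean, sd):
        bands = (1.5, 1.0, 0.5, -1.0)
        assert score_continuous(mean + d, mean, sd, bands) == score_continuous(
            mean - d, mean, sd, bands
        )

    @given(st.lists(st.floats(0, 20, allow_nan=False), min_size=2, max_size=20))
    @settings(max_examples=100, deadline=None)
    def test_band_index_monotone_in_distance(self, distances):
        bands = (1.5, 1.0, 0.5, -1.0)
        order = {"within_1sd": 0, "within_2sd": 1, "within_3sd": 2, "beyond_3sd": 3}
        labels = [order[score_continuous(5 + d, 5, 1, bands)[1]] for d in sorted(distances)]
        assert labels == sorted(labels)

    def test_zero_sd_degenerate_cases(self, rules):
        bands = rules.continuous_bands["logs"]
        assert score_continuous(-3.5, -3.5, 0.0, bands)[0] == 1.5
        assert score_continuous(-3.4, -3.5, 0.0, bands) == (-1.0, "beyond_3sd")

    def test_negative_sd_rejected(self):
        with pytest.raises(ValueError, match="sd"):
            score_continuous(1.0, 0.0, -1.0, (1.5, 1.0, 0.5, -1.0))


class TestScoreDiscrete:
    @pytest.mark.parametrize("name", DISCRETE_DESCRIPTORS)
    @pytest.mark.parametrize("offset", [-3, -2, -1, 0, 1, 2, 3, 7])
    def test_every_offset_cell(self, published_model, rules, name, offset):
        mode = published_model.discrete_modes[name]
        offsets, otherwise = EXPECTED_DISCRETE[name]
        expected = offsets[offset] if abs(offset) <= 2 else otherwise
        score, _ = score_discrete(mode + offset, mode, rules.discrete_offsets[name])
        assert score == expected

    def test_positive_double_charge_heavily_penalised(self, rules):
        assert score_discrete(2, 0, rules.discrete_offsets["formal_charge74"])[0] == -3.0

    def test_donor_count_at_mode(self, rules):
        assert score_discrete(0, 0, rules.discrete_offsets["hbd74"]) == (1.5, "mode+0")

    def test_rotatable_bonds_far_from_mode_hits_catch_all(self, rules):
        assert score_discrete(9, 5, rules.discrete_offsets["rotatable_bonds"])[0] == -1.0

    def test_strict_hba_policy_scores_na_cells_with_catch_all(self):
        strict = default_rules(hba_na_policy="strict").discrete_offsets["hba74"]
        assert strict.score(-1) == -1.0 and strict.score(-2) == -1.0
        assert strict.score(1) == 1.0 and strict.score(0) == 1.5


class TestScoreCompound:
    def test_worked_cases_match_hand_sums(self, published_model, rules, worked_cases):
        for case in worked_cases:
            bd = score_compound(case.record.descriptors, published_model, rules)
            assert bd.total == case.expected_total, case.record.compound_id
            assert bd.scores() == dict(case.expected_scores), case.record.compound_id

    def test_total_is_exact_sum_of_parts(self, published_model, rules, worked_cases):
        for case in worked_cases:
            bd = score_compound(case.record.descriptors, published_model, rules)
            parts = [s for _lab, s in bd.per_descriptor.values()]
            assert bd.total == sum(parts)
            assert (2 * bd.total).is_integer()  # half-point arithmetic

    def test_sampled_class_combinations_match_table_lookup(self, published_model, rules):
        # seeded sample of the band/offset class cross-product; the full
        # exhaustive sweep lives in the acceptance suite
        rng = np.random.default_rng(0)
        for _ in range(5000):
            cont_z = rng.choice(BAND_REPRESENTATIVE_Z, size=6)
            disc_off = rng.choice(OFFSET_CLASSES, size=4)
            ds = _fake_descriptors(published_model, cont_z, disc_off)
            expected = sum(
                EXPECTED_CONTINUOUS[n][BAND_REPRESENTATIVE_Z.index(z)]
                for n, z in zip(CONTINUOUS_DESCRIPTORS, cont_z)
            ) + sum(
                EXPECTED_DISCRETE[n][0][o] if abs(o) <= 2 else EXPECTED_DISCRETE[n][1]
                for n, o in zip(DISCRETE_DESCRIPTORS, disc_off)
            )
            assert score_compound(ds, published_model, rules).total == expected

    @given(
        cont=st.tuples(*[st.floats(-1000, 1000) for _ in range(4)]),
        mm=st.floats(1, 2000),
        arom=st.floats(0, 100),
        counts=st.tuples(*[st.integers(0, 30) for _ in range(3)]),
        charge=st.integers(-5, 5),
    )
    @settings(max_examples=300, deadline=None)
    def test_default_totals_bounded(self, published_model, rules, cont, mm, arom, counts, charge):
        ds = DescriptorSet(
            molar_mass=mm, aromatic_pct=arom, psa=abs(cont[0]), logd74=cont[1],
            logs=cont[2], logp=cont[3], rotatable_bonds=counts[0],
            hba74=counts[1], hbd74=counts[2], formal_charge74=charge,
        )
        total = score_compound(ds, published_model, rules).total
        assert -12.0 <= total <= 18.0


class TestMaxMinScore:
    def test_published_maximum_is_18(self, rules):
        assert max_score(rules) == 18.0

    def test_minimum_matches_brute_force(self, rules):
        assert min_score(rules) == -12.0

    def test_unweighting_logp_lowers_the_maximum(self, rules):
        bands = dict(rules.continuous_bands)
        bands["logp"] = (1.5, 1.0, 0.5, -1.0)
        from herblike import ScoringRules

        assert max_score(ScoringRules(bands, rules.discrete_offsets)) == 16.5

    def test_all_zero_rules_give_zero(self, rules):
        from herblike import DiscreteRule, ScoringRules

        zero = ScoringRules(
            {n: (0.0, 0.0, 0.0, 0.0) for n in CONTINUOUS_DESCRIPTORS},
            {n: DiscreteRule({o: 0.0 for o in range(-2, 3)}, 0.0) for n in DISCRETE_DESCRIPTORS},
        )
        assert max_score(zero) == 0.0 and min_score(zero) == 0.0


class TestRankLibrary:
    def test_single_ideal_compound_ranks_first_with_18(self, published_model, rules, worked_cases):
        result = rank_library([worked_cases[0].record], published_model, rules)
        assert result.table.loc[0, "rank"] == 1
        assert result.table.loc[0, "total"] == 18.0

    def test_sorted_descending_with_id_tie_break(self, published_model, rules, worked_cases):
        result = rank_library([c.record for c in reversed(worked_cases)], published_model, rules)
        ids = result.table["compound_id"].tolist()
        assert ids == ["HL-MAX", "HL-TIE-A", "HL-TIE-B", "HL-FAR3SD", "HL-CHG2", "HL-WORST"]
        totals = result.table["total"].tolist()
        assert totals == sorted(totals, reverse=True)

    def test_threshold_shortlist(self, published_model, rules, worked_cases):
        result = rank_library(
            [c.record for c in worked_cases], published_model, rules, threshold=17
        )
        assert result.shortlist == ["HL-MAX", "HL-TIE-A", "HL-TIE-B"]
        assert result.n_above_threshold == 3

    def test_unscorable_records_collected_not_fatal(self, published_model, rules, worked_cases):
        records = [worked_cases[0].record, CompoundRecord("NO-DESC", smiles="C")]
        result = rank_library(records, published_model, rules)
        assert len(result.table) == 1
        assert [r.compound_id for r in result.rejects] == ["NO-DESC"]
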