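import dataclasses

import numpy as np
import pytest

from hrdscar.scars import (
    AICounts,
    CriteriaSet,
    classify_hr_status,
    count_loh,
    count_lst,
    count_tai,
    get_preset,
    quantify_scars,
)
from hrdscar.segments import extract_ai, smooth_segments

from conftest import build_profile, random_profile
from oracles import oracle_quantify

OVA = get_preset("ovaHRDscar")
TNBC = get_preset("tnbcHRDscar")


class TestPresets:
    @pytest.mark.parametrize("name,expected", [
        ("telli2016", (15.0, 50.0, 12.0, 1.0, 1.0, 42)),
        ("takaya2020", (15.0, 50.0, 12.0, 1.0, 1.0, 63)),
        ("ovaHRDscar", (15.0, 50.0, 12.0, 1.0, 1.0, 54)),
        ("tnbcHRDscar", (10.0, 30.0, 5.0, 2.0, 1.0, 53)),
    ])
    def test_published_parameters(self, name, expected):
        c = get_preset(name)
        assert (c.loh_min_mb, c.loh_max_mb, c.lst_min_segment_mb,
                c.lst_max_gap_mb, c.tai_min_mb, c.cutoff) == expected

    def test_case_insensitive(self):
        assert get_preset("OVAhrdSCAR").cutoff == 54

    def test_unknown_preset_lists_valid(self):
        with pytest.raises(KeyError, match="ovaHRDscar"):
            get_preset("nope")

    def test_invalid_criteria_rejected(self):
        with pytest.raises(ValueError):
            CriteriaSet("bad", 50, 15, 12, 1, 1, 42)
        with pytest.raises(ValueError):
            CriteriaSet("bad", 15, 50, 0, 1, 1, 42)


def _ai(profile, assembly):
    return extract_ai(smooth_segments(profile), assembly)


class TestCountLOH:
    def test_20mb_inside_window(self, toy_assembly):
        profile = build_profile([("1", 1, 20_000_000, 2, 0),
                                 ("1", 20_000_001, 99_000_000, 1, 1)])
        assert count_loh(_ai(profile, toy_assembly), OVA) == 1

    def test_boundaries_strict(self, toy_assembly):
        ten_mb = build_profile([("1", 1, 10_000_000, 2, 0),
                                ("1", 10_000_001, 99_000_000, 1, 1)])
        eleven_mb = build_profile([("1", 1, 11_000_000, 2, 0),
                                   ("1", 11_000_001, 99_000_000, 1, 1)])
        assert count_loh(_ai(ten_mb, toy_assembly), OVA) == 0
        assert count_loh(_ai(ten_mb, toy_assembly), TNBC) == 0  # exactly 10, strict
        assert count_loh(_ai(eleven_mb, toy_assembly), TNBC) == 1

    def test_whole_chromosome_excluded(self, toy_assembly):
        profile = build_profile([("1", 1, 30_000_000, 2, 0)])
        assert count_loh(_ai(profile, toy_assembly), OVA) == 0

    def test_empty_input(self):
        assert count_loh([], OVA) == 0


class TestCountLST:
    def test_basic_transition(self, sim_assembly):
        # q arm of chromosome 1 starts at 90 Mb: 13 Mb 2/0, 0.5 Mb gap, 14 Mb 3/1
        profile = build_profile([
            ("1", 91_000_000, 104_000_000 - 1, 2, 0),
            ("1", 104_500_000, 118_500_000 - 1, 3, 1),
        ])
        assert count_lst(profile, sim_assembly, OVA) == 1

    def test_gap_too_wide_under_ova_but_not_tnbc(self, sim_assembly):
        profile = build_profile([
            ("1", 91_000_000, 104_000_000 - 1, 2, 0),
            ("1", 105_500_000, 119_500_000 - 1, 3, 1),  # 1.5 Mb gap
        ])
        assert count_lst(profile, sim_assembly, OVA) == 0
        assert count_lst(profile, sim_assembly, TNBC) == 1

    def test_short_flank_excluded(self, sim_assembly):
        profile = build_profile([
            ("1", 91_000_000, 102_000_000 - 1, 2, 0),  # 11 Mb < s=12
            ("1", 102_000_000, 116_000_000 - 1, 3, 1),
        ])
        assert count_lst(profile, sim_assembly, OVA) == 0

    def test_centromere_breakpoint_not_counted(self, sim_assembly):
        # chromosome 1 centromere: 80-90 Mb; junction buried inside it
        profile = build_profile([
            ("1", 60_000_000, 85_000_000, 2, 0),
            ("1", 85_000_001, 110_000_000, 3, 1),
        ])
        assert count_lst(profile, sim_assembly, OVA) == 0

    def test_transition_between_non_ai_states_counts(self, sim_assembly):
        # LSTs are state transitions, not AI transitions: 1/1 -> 2/2 counts
        profile = build_profile([
            ("1", 91_000_000, 104_000_000 - 1, 1, 1),
            ("1", 104_000_000, 118_000_000 - 1, 2, 2),
        ])
        assert count_lst(profile, sim_assembly, OVA) == 1


class TestCountTAI:
    def test_telomeric_ai(self, sim_assembly):
        profile = build_profile([("1", 1, 5_000_000, 2, 1),
                                 ("1", 5_000_001, 200_000_000, 1, 1)])
        assert count_tai(_ai(profile, sim_assembly), OVA) == 1

    def test_crossing_centromere_excluded(self, sim_assembly):
        profile = build_profile([("1", 1, 95_000_000, 2, 1),
                                 ("1", 95_000_001, 200_000_000, 1, 1)])
        assert count_tai(_ai(profile, sim_assembly), OVA) == 0

    def test_below_k_excluded(self, sim_assembly):
        profile = build_profile([("1", 1, 800_000, 2, 1),
                                 ("1", 800_001, 200_000_000, 1, 1)])
        assert count_tai(_ai(profile, sim_assembly), OVA) == 0

    def test_q_telomere_counts(self, sim_assembly):
        profile = build_profile([("1", 1, 195_000_000, 1, 1),
                                 ("1", 195_000_001, 200_000_000, 3, 1)])
        assert count_tai(_ai(profile, sim_assembly), OVA) == 1

    def test_whole_chromosome_excluded(self, sim_assembly):
        profile = build_profile([("1", 1, 200_000_000, 2, 1)])
        assert count_tai(_ai(profile, sim_assembly), OVA) == 0


class TestQuantifyAndClassify:
    def test_empty_profile(self, sim_assembly):
        counts = quantify_scars(build_profile([]), sim_assembly, OVA)
        assert (counts.n_loh, counts.n_lst, counts.n_tai, counts.levels) == (0, 0, 0, 0)

    def test_additivity_of_examples(self, sim_assembly):
        # thin balanced 2/2 shoulders isolate each planted event so it hits
        # exactly one counter
        profile = build_profile([
            # telomeric AI on 1p
            ("1", 1, 5_000_000, 2, 1),
            ("1", 5_000_001, 90_999_999, 1, 1),
            # LST pair on 1q (13 Mb 2/1, 0.5 Mb gap, 14 Mb 3/1)
            ("1", 91_000_000, 91_200_000 - 1, 2, 2),
            ("1", 91_200_000, 104_200_000 - 1, 2, 1),
            ("1", 104_700_000, 118_700_000 - 1, 3, 1),
            ("1", 118_700_000, 118_900_000 - 1, 2, 2),
            ("1", 118_900_000, 200_000_000, 1, 1),
            # interstitial 20 Mb LOH on 2
            ("2", 1, 500_000, 1, 1),
            ("2", 500_001, 700_000, 2, 2),
            ("2", 700_001, 20_700_000, 2, 0),
            ("2", 20_700_001, 20_900_000, 2, 2),
            ("2", 20_900_001, 59_000_000, 1, 1),
        ])
        counts = quantify_scars(profile, sim_assembly, OVA)
        assert (counts.n_loh, counts.n_lst, counts.n_tai) == (1, 1, 1)
        assert counts.levels == 3

    def test_classification_boundaries(self):
        assert classify_hr_status(AICounts("s", 54, 0, 0), OVA).status == "HRD"
        assert classify_hr_status(AICounts("s", 53, 0, 0), OVA).status == "HRP"
        assert classify_hr_status(AICounts("s", 42, 0, 0), get_preset("telli2016")).status == "HRD"

    def test_telli_and_ova_levels_identical(self, random_profile_factory, sim_assembly):
        telli = get_preset("telli2016")
        for seed in range(25):
            profile = random_profile_factory(seed)
            a = quantify_scars(profile, sim_assembly, telli)
            b = quantify_scars(profile, sim_assembly, OVA)
            assert a.levels == b.levels


class TestOracleEquivalence:
    def test_counters_match_brute_force(self, random_profile_factory, sim_assembly):
        criteria = [OVA, TNBC,
                    CriteriaSet("wide", 1, float("inf"), 3, 3, 0.2, 10)]
        for seed in range(150):
            profile = random_profile_factory(seed)
            rows = [(s.chromosome, s.start_bp, s.end_bp, s.major_cn, s.minor_cn)
                    for s in profile.segments]
            for crit in criteria:
                counts = quantify_scars(profile, sim_assembly, crit)
                expected = oracle_quantify(rows, sim_assembly, crit)
                assert (counts.n_loh, counts.n_lst, counts.n_tai) == expected, (
                    f"seed {seed}, criteria {crit.name}"
                )


class TestMonotonicity:
    def test_loh_window_narrowing(self, random_profile_factory, sim_assembly):
        for seed in range(40):
            profile = random_profile_factory(seed)
            ai = _ai(profile, sim_assembly)
            wide = count_loh(ai, dataclasses.replace(OVA, loh_min_mb=5, loh_max_mb=60))
            narrow = count_loh(ai, dataclasses.replace(OVA, loh_min_mb=10, loh_max_mb=40))
            assert narrow <= wide

    def test_lst_s_up_m_down(self, random_profile_factory, sim_assembly):
        for seed in range(40):
            profile = smooth_segments(random_profile_factory(seed))
            base = count_lst(profile, sim_assembly, OVA)
            harder_s = count_lst(profile, sim_assembly,
                                 dataclasses.replace(OVA, lst_min_segment_mb=15.0))
            harder_m = count_lst(profile, sim_assembly,
                                 dataclasses.replace(OVA, lst_max_gap_mb=0.5))
            assert harder_s <= base
            assert harder_m <= base

    def test_tai_k_up(self, random_profile_factory, sim_assembly):
        for seed in range(40):
            ai = _ai(random_profile_factory(seed), sim_assembly)
            assert count_tai(ai, dataclasses.replace(OVA, tai_min_mb=5.0)) <= \
                count_tai(ai, OVA)


class TestSplitSmoothInvariance:
    def test_counts_invariant(self, random_profile_factory, sim_assembly):
        rng = np.random.default_rng(1234)
        for seed in range(40):
            profile = random_profile_factory(seed)
            counts = quantify_scars(profile, sim_assembly, OVA)
            rows = []
            for seg in profile.segments:
                if seg.length_bp >= 100 and rng.random() < 0.6:
                    cut = int(rng.integers(seg.start_bp + 49, seg.end_bp - 49))
                    rows.append((seg.chromosome, seg.start_bp, cut, seg.major_cn, seg.minor_cn))
                    rows.append((seg.chromosome, cut + 1, seg.end_bp, seg.major_cn, seg.minor_cn))
                else:
                    rows.append((seg.chromosome, seg.start_bp, seg.end_bp,
                                 seg.major_cn, seg.minor_cn))
            split = build_profile(rows, sample_id=profile.sample_id)
            split_counts = quantify_scars(split, sim_assembly, OVA)
            assert (counts.n_loh, counts.n_lst, counts.n_tai) == \
                (split_counts.n_loh, split_counts.n_lst, split_counts.n_tai)
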