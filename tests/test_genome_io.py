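import numpy as np
import pytest

from hrdscar.genome import AssemblyLookupError, get_assembly
from hrdscar.segments import (
    Segment,
    SegmentFormatError,
    SegmentProfile,
    SegmentValidationError,
    extract_ai,
    read_segments,
    smooth_segments,
    write_segments,
)

from conftest import build_profile, random_profile


class TestAssemblies:
    def test_bundled_builds_load(self):
        for build in ("hg19", "hg38"):
            asm = get_assembly(build)
            assert len(asm.chromosomes) == 23  # autosomes + X by default
            for c in asm.chromosomes:
                assert 0 < c.centromere_start_bp < c.centromere_end_bp < c.length_bp

    def test_include_y(self):
        asm = get_assembly("hg38", include_y=True)
        assert "Y" in asm

    def test_chr_prefix_normalized(self):
        asm = get_assembly("hg38")
        assert asm["chr17"].length_bp == asm["17"].length_bp

    def test_unknown_build(self):
        with pytest.raises(AssemblyLookupError):
            get_assembly("mm10")

    def test_unknown_chromosome_lookup(self):
        asm = get_assembly("hg38")
        with pytest.raises(AssemblyLookupError):
            asm["Z"]


class TestReadWrite:
    def _write(self, tmp_path, text, name="segs.tsv"):
        path = tmp_path / name
        path.write_text(text)
        return path

    def test_generic_identity_read(self, tmp_path):
        path = self._write(
            tmp_path,
            "sample\tchromosome\tstart\tend\tmajor_cn\tminor_cn\n"
            "S1\t2\t1\t500\t2\t1\n"
            "S1\t1\t1000\t2000\t2\t0\n"
            "S1\t1\t1\t999\t1\t1\n",
        )
        profiles = read_segments(path, dialect="generic_seg")
        assert len(profiles) == 1
        segs = profiles[0].segments
        assert [(s.chromosome, s.start_bp) for s in segs] == [("1", 1), ("1", 1000), ("2", 1)]

    @pytest.mark.parametrize("dialect,header,row", [
        ("generic_seg", "sample\tchromosome\tstart\tend\tmajor_cn\tminor_cn",
         "S1\t1\t100\t200\t2\t1"),
        ("gdc_allele_specific",
         "GDC_Aliquot\tChromosome\tStart\tEnd\tCopy_Number\tMajor_Copy_Number\tMinor_Copy_Number",
         "S1\tchr1\t100\t200\t3\t2\t1"),
        ("ascat_output", "sample\tchr\tstartpos\tendpos\tnMajor\tnMinor",
         "S1\t1\t100\t200\t2\t1"),
    ])
    def test_dialects(self, tmp_path, dialect, header, row):
        path = self._write(tmp_path, header + "\n" + row + "\n")
        (profile,) = read_segments(path, dialect=dialect)
        seg = profile.segments[0]
        assert (seg.chromosome, seg.start_bp, seg.end_bp) == ("1", 100, 200)
        assert (seg.major_cn, seg.minor_cn) == (2, 1)

    def test_round_trip_field_identical(self, tmp_path, sim_assembly):
        rng = np.random.default_rng(7)
        profiles = [random_profile(rng, sim_assembly, sample_id=f"S{i}") for i in range(4)]
        out = tmp_path / "rt.tsv"
        write_segments(profiles, out)
        back = read_segments(out, valid_chromosomes=sim_assembly.names)
        assert {p.sample_id for p in back} == {p.sample_id for p in profiles}
        by_id = {p.sample_id: p for p in back}
        for p in profiles:
            assert by_id[p.sample_id].segments == p.segments

    def test_round_trip_bit_exact(self, tmp_path, sim_assembly):
        profiles = [random_profile(np.random.default_rng(3), sim_assembly)]
        a, b = tmp_path / "a.tsv", tmp_path / "b.tsv"
        write_segments(profiles, a)
        write_segments(read_segments(a, valid_chromosomes=sim_assembly.names), b)
        assert a.read_bytes() == b.read_bytes()

    def test_missing_column(self, tmp_path):
        path = self._write(tmp_path, "sample\tchromosome\tstart\tend\tmajor_cn\nS\t1\t1\t2\t1\n")
        with pytest.raises(SegmentFormatError, match="minor_cn"):
            read_segments(path)

    def test_unknown_dialect(self, tmp_path):
        path = self._write(tmp_path, "x\n1\n")
        with pytest.raises(SegmentFormatError, match="dialect"):
            read_segments(path, dialect="nope")

    def test_minor_exceeds_major(self, tmp_path):
        path = self._write(
            tmp_path,
            "sample\tchromosome\tstart\tend\tmajor_cn\tminor_cn\nS1\t1\t1\t10\t1\t2\n",
        )
        with pytest.raises(SegmentValidationError, match="minor_cn"):
            read_segments(path)

    def test_non_integer_copy_number(self, tmp_path):
        path = self._write(
            tmp_path,
            "sample\tchromosome\tstart\tend\tmajor_cn\tminor_cn\nS1\t1\t1\t10\t1.5\t1\n",
        )
        with pytest.raises(SegmentValidationError, match="non-integer"):
            read_segments(path)

    def test_overlap_rejected(self, tmp_path):
        path = self._write(
            tmp_path,
            "sample\tchromosome\tstart\tend\tmajor_cn\tminor_cn\n"
            "S1\t1\t1\t100\t1\t1\nS1\t1\t50\t200\t2\t1\n",
        )
        with pytest.raises(SegmentValidationError, match="overlap"):
            read_segments(path)

    def test_unknown_chromosome_rows_rejected_with_report(self, tmp_path):
        path = self._write(
            tmp_path,
            "sample\tchromosome\tstart\tend\tmajor_cn\tminor_cn\n"
            "S1\t1\t1\t100\t1\t1\nS1\tGL000219\t1\t100\t1\t1\n",
        )
        with pytest.warns(UserWarning, match="rejected 1 row"):
            (profile,) = read_segments(path)
        assert len(profile.segments) == 1


class TestSmoothing:
    def test_tiny_fragment_absorbed(self):
        profile = build_profile([
            ("1", 1, 10_000_000, 2, 1),
            ("1", 10_000_001, 10_000_040, 3, 0),
            ("1", 10_000_041, 20_000_040, 2, 1),
        ])
        out = smooth_segments(profile)
        assert len(out.segments) == 1
        seg = out.segments[0]
        assert (seg.start_bp, seg.end_bp, seg.state) == (1, 20_000_040, (2, 1))

    def test_no_short_segments_unchanged(self):
        profile = build_profile([("1", 1, 1000, 2, 1), ("1", 1001, 2000, 3, 1)])
        assert smooth_segments(profile).segments == profile.segments

    def test_exactly_50bp_retained(self):
        profile = build_profile([("1", 1, 1000, 2, 1), ("1", 2001, 2050, 3, 0)])
        out = smooth_segments(profile)
        assert len(out.segments) == 2

    def test_49bp_removed(self):
        profile = build_profile([("1", 1, 1000, 2, 1), ("1", 2001, 2049, 3, 0)])
        assert len(smooth_segments(profile).segments) == 1

    def test_negative_threshold_rejected(self):
        profile = build_profile([("1", 1, 1000, 1, 1)])
        with pytest.raises(ValueError):
            smooth_segments(profile, min_length_bp=-1)

    def test_idempotent_and_never_grows(self, random_profile_factory):
        for seed in range(30):
            profile = random_profile_factory(seed)
            once = smooth_segments(profile)
            assert len(once.segments) <= len(profile.segments)
            assert smooth_segments(once).segments == once.segments

    def test_split_then_smooth_restores(self, random_profile_factory):
        rng = np.random.default_rng(99)
        for seed in range(30):
            profile = smooth_segments(random_profile_factory(seed))
            split_rows = []
            for seg in profile.segments:
                # both halves must survive the 50 bp filter for the
                # transformation to be an exact inverse
                if seg.length_bp >= 100 and rng.random() < 0.7:
                    cut = int(rng.integers(seg.start_bp + 49, seg.end_bp - 49))
                    split_rows.append((seg.chromosome, seg.start_bp, cut,
                                       seg.major_cn, seg.minor_cn))
                    split_rows.append((seg.chromosome, cut + 1, seg.end_bp,
                                       seg.major_cn, seg.minor_cn))
                else:
                    split_rows.append((seg.chromosome, seg.start_bp, seg.end_bp,
                                       seg.major_cn, seg.minor_cn))
            rebuilt = smooth_segments(build_profile(split_rows, sample_id=profile.sample_id))
            assert rebuilt.segments == profile.segments


class TestExtractAI:
    def test_2_1_is_ai_in_both_modes(self, toy_assembly):
        profile = build_profile([("1", 1, 1_000_000, 2, 1), ("1", 1_000_001, 99_000_000, 1, 1)])
        for mode in ("allele_specific", "total_cn"):
            ai = extract_ai(profile, toy_assembly, mode=mode)
            assert [(a.start_bp, a.end_bp) for a in ai] == [(1, 1_000_000)]

    def test_copy_neutral_loh_mode_dependent(self, toy_assembly):
        profile = build_profile([("1", 1, 1_000_000, 2, 0), ("1", 1_000_001, 99_000_000, 1, 1)])
        assert len(extract_ai(profile, toy_assembly, mode="allele_specific")) == 1
        assert len(extract_ai(profile, toy_assembly, mode="total_cn")) == 0

    def test_balanced_diploid_not_ai(self, toy_assembly):
        profile = build_profile([("1", 1, 1_000_000, 1, 1)])
        assert extract_ai(profile, toy_assembly, mode="allele_specific") == []
        assert extract_ai(profile, toy_assembly, mode="total_cn") == []

    def test_flags_against_covered_extent(self, toy_assembly):
        profile = build_profile([
            ("1", 500, 10_000_000, 2, 0),
            ("1", 10_000_001, 80_000_000, 3, 1),
            ("1", 80_000_001, 99_000_000, 2, 1),
        ])
        ai = extract_ai(profile, toy_assembly)
        p_seg, mid_seg, q_seg = ai
        assert p_seg.touches_p_telomere and not p_seg.touches_q_telomere
        assert not p_seg.crosses_centromere
        assert mid_seg.crosses_centromere  # spans 10M-80M over cen 45-55M
        assert q_seg.touches_q_telomere and not q_seg.touches_p_telomere

    def test_whole_chromosome_flag(self, toy_assembly):
        profile = build_profile([("1", 100, 99_000_000, 2, 0)])
        (seg,) = extract_ai(profile, toy_assembly)
        assert seg.spans_whole_chromosome
        assert seg.touches_p_telomere and seg.touches_q_telomere

    def test_unknown_chromosome(self, toy_assembly):
        profile = build_profile([("9", 1, 100, 2, 1)])
        with pytest.raises(AssemblyLookupError):
            extract_ai(profile, toy_assembly)

    def test_loh_excludes_homozygous_deletion(self, toy_assembly):
        profile = build_profile([("1", 1, 1_000_000, 0, 0), ("1", 1_000_001, 2_000_000, 1, 0),
                                 ("1", 2_000_001, 99_000_000, 1, 1)])
        # 0/0 is balanced in the allele-specific convention (not an AI);
        # in total-CN mode it is an AI but still not LOH.
        ai = extract_ai(profile, toy_assembly, mode="allele_specific")
        assert [a.is_loh for a in ai] == [True]
        ai_total = extract_ai(profile, toy_assembly, mode="total_cn")
        assert [a.is_loh for a in ai_total] == [False, True]


class TestProfileInvariants:
    def test_segments_sorted_on_construction(self):
        profile = build_profile([("1", 1000, 2000, 2, 1), ("1", 1, 999, 1, 1)])
        assert profile.segments[0].start_bp == 1

    def test_purity_bounds(self):
        with pytest.raises(SegmentValidationError):
            SegmentProfile(sample_id="S", segments=(Segment("1", 1, 2, 1, 1),), purity=1.2)

    def test_length_mb(self):
        seg = Segment("1", 1, 1_000_000, 2, 1)
        assert seg.length_mb == 1.0
        assert seg.length_bp == 1_000_000
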