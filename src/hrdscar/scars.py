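"""Counting of HRD-associated allelic imbalances (LOH, LST, TAI).

Three counters over a smoothed segment profile, a parametric criteria set
(`l_min`, `l_max`, `s`, `m`, `k` + cutoff), the four published presets, and
the dichotomous HR-status call.

Conventions (all deliberate and tested):

* length comparisons are strict (``> l_min``, ``< l_max``, ``> s``,
  ``< m``, ``> k``); the cutoff comparison is inclusive (levels >= cutoff
  => HRD);
* LOH requires minor = 0 and major >= 1 (0/0 homozygous deletions are loss,
  not retained-allele imbalance) and must not span the whole covered
  chromosome extent;
* LST breakpoints are evaluated per chromosome arm between consecutive
  segments of different (major, minor) state; the gap is the uncovered
  distance between the flanks, and breakpoints inside the centromere are
  never counted (a segment crossing the centromere contributes its clipped
  parts to both arms);
* a TAI touches either covered chromosome terminus, does not cross the
  centromere and does not span the whole chromosome.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Iterable, Sequence

from .genome import GenomeAssembly
from .segments import (
    BP_PER_MB,
    AISegment,
    Segment,
    SegmentProfile,
    extract_ai,
    smooth_segments,
)

__all__ = [
    "CriteriaSet",
    "AICounts",
    "HRStatusCall",
    "PRESETS",
    "get_preset",
    "count_loh",
    "count_lst",
    "count_tai",
    "quantify_scars",
    "classify_hr_status",
    "arm_segments",
]


@dataclass(frozen=True)
class CriteriaSet:
    """The five scar-selection parameters plus the HRD/HRP cutoff.

    Lengths in Mb: ``loh_min_mb``/``loh_max_mb`` bound LOH length (strict),
    ``lst_min_segment_mb`` is the minimum flanking-segment length for an LST
    breakpoint, ``lst_max_gap_mb`` the maximum uncovered gap between the
    flanks, ``tai_min_mb`` the minimum TAI length.
    """

    name: str
    loh_min_mb: float
    loh_max_mb: float
    lst_min_segment_mb: float
    lst_max_gap_mb: float
    tai_min_mb: float
    cutoff: int

    def __post_init__(self) -> None:
        if not (0 <= self.loh_min_mb < self.loh_max_mb):
            raise ValueError(f"{self.name}: need 0 <= loh_min_mb < loh_max_mb")
        if self.lst_min_segment_mb <= 0:
            raise ValueError(f"{self.name}: lst_min_segment_mb must be > 0")
        if self.lst_max_gap_mb < 0 or self.tai_min_mb < 0:
            raise ValueError(f"{self.name}: lst_max_gap_mb and tai_min_mb must be >= 0")
        if self.cutoff < 0:
            raise ValueError(f"{self.name}: cutoff must be >= 0")


PRESETS: dict[str, CriteriaSet] = {
    "telli2016": CriteriaSet("telli2016", 15.0, 50.0, 12.0, 1.0, 1.0, 42),
    "takaya2020": CriteriaSet("takaya2020", 15.0, 50.0, 12.0, 1.0, 1.0, 63),
    "ovahrdscar": CriteriaSet("ovaHRDscar", 15.0, 50.0, 12.0, 1.0, 1.0, 54),
    "tnbchrdscar": CriteriaSet("tnbcHRDscar", 10.0, 30.0, 5.0, 2.0, 1.0, 53),
}


def get_preset(name: str) -> CriteriaSet:
    """Return a published criteria preset by (case-insensitive) name."""
    try:
        return PRESETS[name.lower()]
    except KeyError:
        valid = ", ".join(p.name for p in PRESETS.values())
        raise KeyError(f"unknown preset {name!r}; valid presets: {valid}") from None


@dataclass(frozen=True)
class AICounts:
    sample_id: str
    n_loh: int
    n_lst: int
    n_tai: int

    @property
    def levels(self) -> int:
        """Scar level: the sum of the three event counts."""
        return self.n_loh + self.n_lst + self.n_tai


@dataclass(frozen=True)
class HRStatusCall:
    sample_id: str
    levels: int
    cutoff: int

    @property
    def status(self) -> str:
        return "HRD" if self.levels >= self.cutoff else "HRP"


def count_loh(ai_segments: Iterable[AISegment], criteria: CriteriaSet) -> int:
    """Count LOH segments with l_min < length < l_max (strict), excluding
    whole-chromosome events."""
    lo_bp = criteria.loh_min_mb * BP_PER_MB
    hi_bp = criteria.loh_max_mb * BP_PER_MB
    n = 0
    for seg in ai_segments:
        if not seg.is_loh or seg.spans_whole_chromosome:
            continue
        if lo_bp < seg.length_bp and (math.isinf(hi_bp) or seg.length_bp < hi_bp):
            n += 1
    return n


def arm_segments(
    profile: SegmentProfile, assembly: GenomeAssembly
) -> dict[tuple[str, str], list[Segment]]:
    """Clip the profile's segments to chromosome arms.

    The p arm runs up to the base before the centromere start, the q arm
    from the base after the centromere end. A segment crossing the
    centromere is split; its clipped parts keep the original copy-number
    state. Empty clips are dropped.
    """
    arms: dict[tuple[str, str], list[Segment]] = {}
    for chrom in profile.chromosomes():
        spec = assembly[chrom]
        p_hi = spec.centromere_start_bp - 1
        q_lo = spec.centromere_end_bp + 1
        for seg in profile.by_chromosome(chrom):
            if seg.start_bp <= p_hi:
                clipped = replace(seg, end_bp=min(seg.end_bp, p_hi))
                arms.setdefault((chrom, "p"), []).append(clipped)
            if seg.end_bp >= q_lo:
                clipped = replace(seg, start_bp=max(seg.start_bp, q_lo))
                arms.setdefault((chrom, "q"), []).append(clipped)
    return arms


def lst_breakpoint_candidates(
    profile: SegmentProfile, assembly: GenomeAssembly
) -> list[tuple[int, int, int]]:
    """All per-arm junctions between consecutive segments of different state.

    Returns ``(left_length_bp, right_length_bp, gap_bp)`` triples; the LST
    criteria are applied on top of these.
    """
    out: list[tuple[int, int, int]] = []
    for segs in arm_segments(profile, assembly).values():
        for left, right in zip(segs, segs[1:]):
            if left.state == right.state:
                continue
            gap_bp = right.start_bp - left.end_bp - 1
            out.append((left.length_bp, right.length_bp, gap_bp))
    return out


def count_lst(
    profile: SegmentProfile, assembly: GenomeAssembly, criteria: CriteriaSet
) -> int:
    """Count large-scale state transitions on a smoothed profile.

    A junction counts when both flanking (arm-clipped) segments are longer
    than ``s`` Mb and the uncovered gap between them is shorter than ``m`` Mb.
    """
    s_bp = criteria.lst_min_segment_mb * BP_PER_MB
    m_bp = criteria.lst_max_gap_mb * BP_PER_MB
    n = 0
    for left_bp, right_bp, gap_bp in lst_breakpoint_candidates(profile, assembly):
        if left_bp > s_bp and right_bp > s_bp and gap_bp < m_bp:
            n += 1
    return n


def count_tai(ai_segments: Iterable[AISegment], criteria: CriteriaSet) -> int:
    """Count telomeric AIs longer than ``k`` Mb that touch either covered
    chromosome terminus without crossing the centromere or spanning the
    whole chromosome."""
    k_bp = criteria.tai_min_mb * BP_PER_MB
    n = 0
    for seg in ai_segments:
        if seg.spans_whole_chromosome or seg.crosses_centromere:
            continue
        if not (seg.touches_p_telomere or seg.touches_q_telomere):
            continue
        if seg.length_bp > k_bp:
            n += 1
    return n


def quantify_scars(
    profile: SegmentProfile,
    assembly: GenomeAssembly,
    criteria: CriteriaSet,
    mode: str = "allele_specific",
    smooth_min_bp: int = 50,
) -> AICounts:
    """Smooth the profile, then count LOH, LST and TAI events."""
    smoothed = smooth_segments(profile, min_length_bp=smooth_min_bp)
    ai = extract_ai(smoothed, assembly, mode=mode)
    return AICounts(
        sample_id=profile.sample_id,
        n_loh=count_loh(ai, criteria),
        n_lst=count_lst(smoothed, assembly, criteria),
        n_tai=count_tai(ai, criteria),
    )


def classify_hr_status(counts: AICounts, criteria: CriteriaSet) -> HRStatusCall:
    """HRD iff levels >= cutoff."""
    return HRStatusCall(sample_id=counts.sample_id, levels=counts.levels, cutoff=criteria.cutoff)


def quantify_cohort(
    profiles: Sequence[SegmentProfile],
    assembly: GenomeAssembly,
    criteria: CriteriaSet,
    mode: str = "allele_specific",
    smooth_min_bp: int = 50,
):
    """Convenience: scar counts + status for many profiles as a DataFrame."""
    import pandas as pd

    rows = []
    for profile in profiles:
        counts = quantify_scars(profile, assembly, criteria, mode=mode, smooth_min_bp=smooth_min_bp)
        call = classify_hr_status(counts, criteria)
        rows.append(
            (profile.sample_id, counts.n_loh, counts.n_lst, counts.n_tai,
             counts.levels, criteria.cutoff, call.status)
        )
    return pd.DataFrame(
        rows, columns=["sample", "n_loh", "n_lst", "n_tai", "levels", "cutoff", "status"]
    )
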