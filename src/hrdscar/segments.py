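"""Allele-specific copy-number segment profiles: I/O, validation, smoothing
and classification of segments into allelic-imbalance (AI) segments.

Coordinates are 1-based inclusive (seg-file convention); a segment of
``start == end`` spans one base and lengths are ``end - start + 1`` bp.

Three table dialects are read and a single canonical dialect
(``generic_seg``) is written back, bit-exact on round trip:

* ``generic_seg``:          sample, chromosome, start, end, major_cn, minor_cn
* ``gdc_allele_specific``:  GDC_Aliquot, Chromosome, Start, End, Copy_Number,
  Major_Copy_Number, Minor_Copy_Number
* ``ascat_output``:         sample, chr, startpos, endpos, nMajor, nMinor
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

from .genome import DEFAULT_CHROMOSOMES, GenomeAssembly, normalize_chromosome

__all__ = [
    "Segment",
    "SegmentProfile",
    "AISegment",
    "SegmentFormatError",
    "SegmentValidationError",
    "read_segments",
    "write_segments",
    "smooth_segments",
    "extract_ai",
    "DIALECTS",
]

BP_PER_MB = 1_000_000


class SegmentFormatError(ValueError):
    """Malformed segment table (missing columns, unknown dialect)."""


class SegmentValidationError(ValueError):
    """Segment content violates the profile invariants."""


@dataclass(frozen=True, order=True)
class Segment:
    """One allele-specific copy-number segment (1-based inclusive coords)."""

    chromosome: str
    start_bp: int
    end_bp: int
    major_cn: int
    minor_cn: int

    @property
    def length_bp(self) -> int:
        return self.end_bp - self.start_bp + 1

    @property
    def length_mb(self) -> float:
        return self.length_bp / BP_PER_MB

    @property
    def total_cn(self) -> int:
        return self.major_cn + self.minor_cn

    @property
    def state(self) -> tuple[int, int]:
        return (self.major_cn, self.minor_cn)


@dataclass(frozen=True)
class SegmentProfile:
    """Ordered, validated collection of segments for one sample."""

    sample_id: str
    segments: tuple[Segment, ...] = field(default_factory=tuple)
    build_label: str = "custom"
    purity: float | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "segments", tuple(sorted(self.segments)))
        if self.purity is not None and not (0.0 < self.purity <= 1.0):
            raise SegmentValidationError(
                f"sample {self.sample_id}: purity {self.purity} outside (0, 1]"
            )
        _validate_segments(self.sample_id, self.segments)

    def chromosomes(self) -> tuple[str, ...]:
        seen: dict[str, None] = {}
        for seg in self.segments:
            seen.setdefault(seg.chromosome, None)
        return tuple(seen)

    def by_chromosome(self, chromosome: str) -> tuple[Segment, ...]:
        return tuple(s for s in self.segments if s.chromosome == chromosome)

    def covered_extent(self, chromosome: str) -> tuple[int, int]:
        """First and last covered base of ``chromosome`` in this profile."""
        segs = self.by_chromosome(chromosome)
        if not segs:
            raise SegmentValidationError(
                f"sample {self.sample_id}: no segments on chromosome {chromosome}"
            )
        return segs[0].start_bp, segs[-1].end_bp


def _validate_segments(sample_id: str, segments: Sequence[Segment]) -> None:
    prev: Segment | None = None
    for seg in segments:
        if seg.start_bp > seg.end_bp:
            raise SegmentValidationError(
                f"sample {sample_id}, {seg.chromosome}:{seg.start_bp}-{seg.end_bp}: "
                "start > end"
            )
        if seg.major_cn < 0 or seg.minor_cn < 0:
            raise SegmentValidationError(
                f"sample {sample_id}, {seg.chromosome}:{seg.start_bp}: negative copy number"
            )
        if seg.minor_cn > seg.major_cn:
            raise SegmentValidationError(
                f"sample {sample_id}, {seg.chromosome}:{seg.start_bp}: "
                f"minor_cn {seg.minor_cn} > major_cn {seg.major_cn}"
            )
        if prev is not None and seg.chromosome == prev.chromosome and seg.start_bp <= prev.end_bp:
            raise SegmentValidationError(
                f"sample {sample_id}, chromosome {seg.chromosome}: segment at "
                f"{seg.start_bp} overlaps previous segment ending at {prev.end_bp}"
            )
        prev = seg


# --------------------------------------------------------------------------
# Table dialects
# --------------------------------------------------------------------------

#: dialect -> (sample column candidates, chromosome, start, end, major, minor)
DIALECTS: dict[str, dict[str, tuple[str, ...]]] = {
    "generic_seg": {
        "sample": ("sample",),
        "chromosome": ("chromosome",),
        "start": ("start",),
        "end": ("end",),
        "major": ("major_cn",),
        "minor": ("minor_cn",),
    },
    "gdc_allele_specific": {
        "sample": ("GDC_Aliquot", "Sample", "sample"),
        "chromosome": ("Chromosome",),
        "start": ("Start",),
        "end": ("End",),
        "major": ("Major_Copy_Number",),
        "minor": ("Minor_Copy_Number",),
    },
    "ascat_output": {
        "sample": ("sample",),
        "chromosome": ("chr",),
        "start": ("startpos",),
        "end": ("endpos",),
        "major": ("nMajor",),
        "minor": ("nMinor",),
    },
}


def _resolve_columns(df: pd.DataFrame, dialect: str) -> dict[str, str]:
    try:
        spec = DIALECTS[dialect]
    except KeyError:
        raise SegmentFormatError(
            f"unknown dialect {dialect!r}; valid: {', '.join(DIALECTS)}"
        ) from None
    resolved: dict[str, str] = {}
    for role, candidates in spec.items():
        for cand in candidates:
            if cand in df.columns:
                resolved[role] = cand
                break
        else:
            raise SegmentFormatError(
                f"dialect {dialect!r}: required column "
                f"{' / '.join(candidates)!r} not found in table"
            )
    return resolved


def _as_int(value: object, what: str, context: str) -> int:
    try:
        f = float(value)
    except (TypeError, ValueError):
        raise SegmentValidationError(f"{context}: non-numeric {what} {value!r}") from None
    if f != int(f):
        raise SegmentValidationError(f"{context}: non-integer {what} {value!r}")
    return int(f)


def read_segments(
    path: str | Path,
    dialect: str = "generic_seg",
    valid_chromosomes: Iterable[str] | None = None,
) -> list[SegmentProfile]:
    """Read a segment table and return one validated profile per sample.

    Rows on chromosomes outside ``valid_chromosomes`` (default: autosomes + X)
    are rejected with a warning that reports how many rows were dropped.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path, sep="\t", dtype=str)
    cols = _resolve_columns(df, dialect)
    allowed = {
        normalize_chromosome(c)
        for c in (valid_chromosomes if valid_chromosomes is not None else DEFAULT_CHROMOSOMES)
    }

    per_sample: dict[str, list[Segment]] = {}
    n_rejected = 0
    rejected_chroms: set[str] = set()
    for row in df.itertuples(index=False):
        sample = str(getattr(row, cols["sample"]))
        chrom = normalize_chromosome(getattr(row, cols["chromosome"]))
        if chrom not in allowed:
            n_rejected += 1
            rejected_chroms.add(chrom)
            continue
        context = f"sample {sample}, {chrom}"
        seg = Segment(
            chromosome=chrom,
            start_bp=_as_int(getattr(row, cols["start"]), "start", context),
            end_bp=_as_int(getattr(row, cols["end"]), "end", context),
            major_cn=_as_int(getattr(row, cols["major"]), "major_cn", context),
            minor_cn=_as_int(getattr(row, cols["minor"]), "minor_cn", context),
        )
        per_sample.setdefault(sample, []).append(seg)
    if n_rejected:
        warnings.warn(
            f"{path.name}: rejected {n_rejected} row(s) on unknown chromosome(s) "
            f"{sorted(rejected_chroms)}",
            stacklevel=2,
        )
    return [SegmentProfile(sample_id=s, segments=tuple(v)) for s, v in per_sample.items()]


def write_segments(profiles: Iterable[SegmentProfile], path: str | Path) -> None:
    """Write profiles as a ``generic_seg`` TSV (round-trips bit-exactly)."""
    rows = []
    for profile in profiles:
        for seg in profile.segments:
            rows.append(
                (profile.sample_id, seg.chromosome, seg.start_bp, seg.end_bp,
                 seg.major_cn, seg.minor_cn)
            )
    df = pd.DataFrame(
        rows, columns=["sample", "chromosome", "start", "end", "major_cn", "minor_cn"]
    )
    df.to_csv(path, sep="\t", index=False)


# --------------------------------------------------------------------------
# Smoothing
# --------------------------------------------------------------------------

def smooth_segments(profile: SegmentProfile, min_length_bp: int = 50) -> SegmentProfile:
    """Drop segments strictly shorter than ``min_length_bp`` and merge
    consecutive same-state segments on the same chromosome.

    A merged segment spans from the first to the last constituent, i.e. tiny
    dropped fragments in between are absorbed. Idempotent; never increases
    the segment count.
    """
    if min_length_bp < 0:
        raise ValueError(f"min_length_bp must be >= 0, got {min_length_bp}")
    kept = [s for s in profile.segments if s.length_bp >= min_length_bp]
    merged: list[Segment] = []
    for seg in kept:
        if merged and merged[-1].chromosome == seg.chromosome and merged[-1].state == seg.state:
            merged[-1] = replace(merged[-1], end_bp=seg.end_bp)
        else:
            merged.append(seg)
    return replace(profile, segments=tuple(merged))


# --------------------------------------------------------------------------
# AI extraction
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class AISegment:
    """An allelic-imbalance segment with positional flags.

    Telomere contact is defined against the profile's covered extent on the
    chromosome (first/last covered bp), not the physical chromosome end —
    arrays and WGS segmentations never reach physical telomeres.
    """

    chromosome: str
    start_bp: int
    end_bp: int
    major_cn: int
    minor_cn: int
    is_loh: bool
    touches_p_telomere: bool
    touches_q_telomere: bool
    crosses_centromere: bool

    @property
    def length_bp(self) -> int:
        return self.end_bp - self.start_bp + 1

    @property
    def length_mb(self) -> float:
        return self.length_bp / BP_PER_MB

    @property
    def spans_whole_chromosome(self) -> bool:
        return self.touches_p_telomere and self.touches_q_telomere


def _is_ai(segment: Segment, mode: str) -> bool:
    if mode == "allele_specific":
        return segment.major_cn != segment.minor_cn
    if mode == "total_cn":
        return segment.total_cn != 2
    raise ValueError(f"unknown AI mode {mode!r}; valid: allele_specific, total_cn")


def extract_ai(
    profile: SegmentProfile,
    assembly: GenomeAssembly,
    mode: str = "allele_specific",
) -> list[AISegment]:
    """Classify the profile's segments into AI segments.

    ``allele_specific``: AI iff major != minor (includes copy-neutral LOH).
    ``total_cn``: AI iff major + minor != 2.
    """
    out: list[AISegment] = []
    for chrom in profile.chromosomes():
        spec = assembly[chrom]  # raises AssemblyLookupError for unknown chromosomes
        first_bp, last_bp = profile.covered_extent(chrom)
        for seg in profile.by_chromosome(chrom):
            if not _is_ai(seg, mode):
                continue
            out.append(
                AISegment(
                    chromosome=seg.chromosome,
                    start_bp=seg.start_bp,
                    end_bp=seg.end_bp,
                    major_cn=seg.major_cn,
                    minor_cn=seg.minor_cn,
                    is_loh=(seg.minor_cn == 0 and seg.major_cn >= 1),
                    touches_p_telomere=(seg.start_bp == first_bp),
                    touches_q_telomere=(seg.end_bp == last_bp),
                    crosses_centromere=(
                        seg.start_bp < spec.centromere_start_bp
                        and seg.end_bp > spec.centromere_end_bp
                    ),
                )
            )
    return out
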