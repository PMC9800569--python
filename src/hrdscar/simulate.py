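"""Synthetic allele-specific segment cohorts with class-conditional
(HRD-like vs HRP-like) allelic-imbalance event structure, plus matched
synthetic survival data.

Profiles are built on a balanced 1/1 diploid background covering each
chromosome end to end. Planted event types:

* interstitial LOH events (minor copy 0);
* interstitial non-LOH AI events;
* telomeric AI events anchored at a covered chromosome terminus;
* adjacent pairs of long AI segments in different states separated by a
  small uncovered gap (each pair plants exactly one large-scale state
  transition when shielding is on).

With ``shield_events`` (default), every planted event is wrapped in thin
balanced 2/2 shoulders. The shoulders are not allelic imbalances in the
allele-specific convention, but they are too short to act as transition
flanks, so planted events of one type never leak into another counter:
planted counts are recovered exactly by the scar counters when event
lengths are drawn inside the counting windows and the noise rate is zero.

Sub-50 bp fragment noise (removed by smoothing) exercises the smoothing
path. Each sample draws from its own deterministic substream, so growing
the cohort never reshuffles existing samples.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .genome import Chromosome, GenomeAssembly
from .segments import Segment, SegmentProfile
from .survival import SurvivalRecord

__all__ = [
    "CapacityError",
    "LengthModel",
    "EventModel",
    "ClassConfig",
    "SimulationConfig",
    "default_assembly",
    "default_config",
    "simulate_cohort",
    "simulate_survival",
]

_SHIELD_BP = 100_000
_END_MARGIN_BP = 300_000
_MAX_PLACEMENT_TRIES = 2000
_MAX_LENGTH_REDRAWS = 25

_AI_STATES = ((2, 1), (3, 1), (3, 2))
_LOH_STATES = ((1, 0), (2, 0))
_NOISE_STATES = ((2, 0), (3, 1), (1, 0))


class CapacityError(RuntimeError):
    """The configured event load cannot be placed on the genome."""


@dataclass(frozen=True)
class LengthModel:
    """Event length distribution in Mb: lognormal(a=log-mu, b=log-sigma)
    or uniform(a=min_mb, b=max_mb)."""

    distribution: str
    a: float
    b: float

    def __post_init__(self) -> None:
        if self.distribution not in ("lognormal", "uniform"):
            raise ValueError(f"unknown length distribution {self.distribution!r}")
        if self.distribution == "lognormal" and self.b <= 0:
            raise ValueError("lognormal log-sigma must be > 0")
        if self.distribution == "uniform" and not (0 < self.a < self.b):
            raise ValueError("uniform bounds must satisfy 0 < min < max")

    def draw_mb(self, rng: np.random.Generator) -> float:
        if self.distribution == "lognormal":
            return float(np.exp(rng.normal(self.a, self.b)))
        return float(rng.uniform(self.a, self.b))


@dataclass(frozen=True)
class EventModel:
    """Expected (Poisson) event count per sample and its length model."""

    rate: float
    length: LengthModel

    def __post_init__(self) -> None:
        if self.rate < 0:
            raise ValueError("event rate must be >= 0")


@dataclass(frozen=True)
class ClassConfig:
    """Event load for one class (HRD-like or HRP-like)."""

    loh: tuple[EventModel, ...] = ()
    interstitial: tuple[EventModel, ...] = ()
    telomeric: tuple[EventModel, ...] = ()
    lst_pairs: tuple[EventModel, ...] = ()
    lst_gap_max_mb: float = 0.8

    def __post_init__(self) -> None:
        if self.lst_gap_max_mb < 0:
            raise ValueError("lst_gap_max_mb must be >= 0")


@dataclass(frozen=True)
class SimulationConfig:
    assembly: GenomeAssembly
    hrd: ClassConfig
    hrp: ClassConfig
    noise_rate: float = 0.0
    shield_events: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if self.noise_rate < 0:
            raise ValueError("noise_rate must be >= 0")


def default_assembly() -> GenomeAssembly:
    """Small 3-chromosome genome (200/150/100 Mb, centromeres at 40-45% of
    length) — big enough for realistic event loads, small enough for
    brute-force oracles."""
    return GenomeAssembly(
        build_label="sim3",
        chromosomes=(
            Chromosome("1", 200_000_000, 80_000_000, 90_000_000),
            Chromosome("2", 150_000_000, 60_000_000, 67_500_000),
            Chromosome("3", 100_000_000, 40_000_000, 45_000_000),
        ),
    )


def default_config(seed: int = 0, noise_rate: float = 2.0) -> SimulationConfig:
    """HRD-like class: frequent LOH in the 15-50 Mb window, long adjacent
    transition pairs and telomeric AIs; HRP-like class: sparse, mostly
    short events."""
    log = np.log
    hrd = ClassConfig(
        loh=(EventModel(3.0, LengthModel("lognormal", log(22.0), 0.25)),),
        interstitial=(EventModel(3.0, LengthModel("lognormal", log(3.0), 0.5)),),
        telomeric=(EventModel(2.0, LengthModel("lognormal", log(5.0), 0.4)),),
        lst_pairs=(EventModel(2.0, LengthModel("lognormal", log(16.0), 0.15)),),
    )
    hrp = ClassConfig(
        loh=(EventModel(1.0, LengthModel("lognormal", log(4.0), 0.5)),),
        interstitial=(EventModel(3.0, LengthModel("lognormal", log(3.0), 0.5)),),
        telomeric=(EventModel(0.4, LengthModel("lognormal", log(3.0), 0.4)),),
        lst_pairs=(EventModel(0.3, LengthModel("lognormal", log(14.0), 0.2)),),
    )
    return SimulationConfig(
        assembly=default_assembly(), hrd=hrd, hrp=hrp, noise_rate=noise_rate, seed=seed
    )


# --------------------------------------------------------------------------
# Placement machinery
# --------------------------------------------------------------------------

class _ChromState:
    """Mutable per-chromosome placement state during simulation."""

    def __init__(self, spec: Chromosome) -> None:
        self.spec = spec
        self.placed: list[Segment] = []  # event + noise segments
        self.holes: list[tuple[int, int]] = []  # deliberately uncovered gaps
        self.blocked: list[tuple[int, int]] = []  # reserved spans incl. shields
        self.p_telomere_used = False
        self.q_telomere_used = False

    def overlaps(self, start: int, end: int) -> bool:
        return any(not (end < lo or start > hi) for lo, hi in self.blocked)

    def block(self, start: int, end: int) -> None:
        self.blocked.append((start, end))


def _crosses_centromere(spec: Chromosome, start: int, end: int) -> bool:
    return start <= spec.centromere_end_bp and end >= spec.centromere_start_bp


def _pick_state(rng: np.random.Generator, states) -> tuple[int, int]:
    return states[int(rng.integers(0, len(states)))]


def _draw_count(rng: np.random.Generator, rate: float) -> int:
    """Poisson draw truncated at ~+2 sigma so pathological tail samples do
    not exceed the genome's capacity."""
    cap = int(np.ceil(rate + 2.0 * np.sqrt(rate)))
    return min(int(rng.poisson(rate)), cap)


def _free_intervals(st: _ChromState) -> list[tuple[int, int]]:
    """Unblocked intervals inside the chromosome arms, away from the ends."""
    spec = st.spec
    arms = [
        (1 + _END_MARGIN_BP, spec.centromere_start_bp - 1),
        (spec.centromere_end_bp + 1, spec.length_bp - _END_MARGIN_BP),
    ]
    blocked = sorted(st.blocked)
    out = []
    for arm_lo, arm_hi in arms:
        cursor = arm_lo
        for lo, hi in blocked:
            if hi < cursor or lo > arm_hi:
                continue
            if lo > cursor:
                out.append((cursor, lo - 1))
            cursor = max(cursor, hi + 1)
        if cursor <= arm_hi:
            out.append((cursor, arm_hi))
    return out


def _place_interstitial(
    rng: np.random.Generator,
    chroms: dict[str, _ChromState],
    parts_bp: Sequence[int],
) -> tuple[str, int] | None:
    """Pick a start for a span of sum(parts) bp that stays inside one arm,
    away from the chromosome ends, overlapping nothing.

    Enumerates the free intervals that can hold the span and draws a start
    uniformly over all feasible positions, so placement fails only when the
    genome genuinely has no room.
    """
    span = sum(parts_bp)
    slots: list[tuple[str, int, int]] = []  # (chromosome, slot start, capacity)
    for name, st in chroms.items():
        for lo, hi in _free_intervals(st):
            capacity = hi - lo + 1 - span + 1
            if capacity > 0:
                slots.append((name, lo, capacity))
    if not slots:
        return None
    weights = np.array([c for _, _, c in slots], dtype=float)
    idx = int(rng.choice(len(slots), p=weights / weights.sum()))
    name, lo, capacity = slots[idx]
    start = lo + int(rng.integers(0, capacity))
    return name, start


def _layout(
    st: _ChromState, start: int, parts: Sequence[tuple[int, int | None, int | None]],
) -> None:
    """Place consecutive parts ``(length_bp, major, minor)``; ``major=None``
    marks an uncovered hole."""
    pos = start
    for length, major, minor in parts:
        end = pos + length - 1
        if major is None:
            st.holes.append((pos, end))
        else:
            st.placed.append(Segment(st.spec.name, pos, end, major, minor))
        pos = end + 1
    st.block(start, pos - 1)


def _mb_to_bp(mb: float, minimum: int = 60) -> int:
    return max(int(round(mb * 1_000_000)), minimum)


def _simulate_sample(
    sample_id: str,
    cls: ClassConfig,
    config: SimulationConfig,
    rng: np.random.Generator,
) -> SegmentProfile:
    chroms = {c.name: _ChromState(c) for c in config.assembly.chromosomes}
    shield = config.shield_events
    pad = _SHIELD_BP if shield else 0

    def shielded(core: list[tuple[int, int | None, int | None]]):
        if not shield:
            return core
        return [(_SHIELD_BP, 2, 2)] + core + [(_SHIELD_BP, 2, 2)]

    # Adjacent transition pairs (each plants one LST when shielded)
    for model in cls.lst_pairs:
        for _ in range(_draw_count(rng, model.rate)):
            state_a = _pick_state(rng, _AI_STATES)
            state_b = state_a
            while state_b == state_a:
                state_b = _pick_state(rng, _AI_STATES)
            for attempt in range(_MAX_LENGTH_REDRAWS):
                len_a = _mb_to_bp(model.length.draw_mb(rng))
                len_b = _mb_to_bp(model.length.draw_mb(rng))
                gap = int(round(rng.uniform(0.0, cls.lst_gap_max_mb) * 1_000_000))
                core: list[tuple[int, int | None, int | None]] = [(len_a, *state_a)]
                if gap > 0:
                    core.append((gap, None, None))
                core.append((len_b, *state_b))
                parts = shielded(core)
                found = _place_interstitial(rng, chroms, [p[0] for p in parts])
                if found is not None:
                    break
            if found is None:
                raise CapacityError(f"{sample_id}: cannot place transition pair")
            name, start = found
            _layout(chroms[name], start, parts)

    # Interstitial LOH events
    for model in cls.loh:
        for _ in range(_draw_count(rng, model.rate)):
            state = _pick_state(rng, _LOH_STATES)
            for attempt in range(_MAX_LENGTH_REDRAWS):
                length = _mb_to_bp(model.length.draw_mb(rng))
                parts = shielded([(length, state[0], state[1])])
                found = _place_interstitial(rng, chroms, [p[0] for p in parts])
                if found is not None:
                    break
            if found is None:
                raise CapacityError(f"{sample_id}: cannot place LOH event")
            name, start = found
            _layout(chroms[name], start, parts)

    # Interstitial non-LOH AI events
    for model in cls.interstitial:
        for _ in range(_draw_count(rng, model.rate)):
            state = _pick_state(rng, _AI_STATES)
            for attempt in range(_MAX_LENGTH_REDRAWS):
                length = _mb_to_bp(model.length.draw_mb(rng))
                parts = shielded([(length, state[0], state[1])])
                found = _place_interstitial(rng, chroms, [p[0] for p in parts])
                if found is not None:
                    break
            if found is None:
                raise CapacityError(f"{sample_id}: cannot place AI event")
            name, start = found
            _layout(chroms[name], start, parts)

    # Telomeric AI events. The per-sample telomeric load saturates at two
    # events per chromosome (one per covered terminus); draws beyond the
    # number of free termini are silently truncated.
    for model in cls.telomeric:
        n_events = int(rng.poisson(model.rate))
        for _ in range(n_events):
            free_sides = [
                (name, side)
                for name, st in chroms.items()
                for side, used in (("p", st.p_telomere_used), ("q", st.q_telomere_used))
                if not used
            ]
            if not free_sides:
                break
            length = _mb_to_bp(model.length.draw_mb(rng))
            state = _pick_state(rng, _AI_STATES)
            # try the free termini in random order; the drawn length is
            # clipped to the room actually available on each side
            order = rng.permutation(len(free_sides))
            placed = False
            for pos in order:
                name, side = free_sides[int(pos)]
                st = chroms[name]
                spec = st.spec
                if side == "p":
                    room = min(
                        (lo - 1 for lo, _ in st.blocked), default=spec.length_bp
                    )
                    end = min(length, spec.centromere_start_bp - 1 - pad, room - pad)
                    if end < 150_000:
                        continue
                    parts: list[tuple[int, int | None, int | None]] = [(end, *state)]
                    if shield:
                        parts.append((_SHIELD_BP, 2, 2))
                    _layout(st, 1, parts)
                    st.p_telomere_used = True
                else:
                    room_lo = max(
                        (hi + 1 for _, hi in st.blocked), default=1
                    )
                    begin = max(
                        spec.length_bp - length + 1,
                        spec.centromere_end_bp + 1 + pad,
                        room_lo + pad,
                    )
                    if spec.length_bp - begin + 1 < 150_000:
                        continue
                    lo = begin - pad
                    parts = []
                    if shield:
                        parts.append((_SHIELD_BP, 2, 2))
                    parts.append((spec.length_bp - begin + 1, *state))
                    _layout(st, lo, parts)
                    st.q_telomere_used = True
                placed = True
                break
            if not placed:
                raise CapacityError(f"{sample_id}: cannot place telomeric event")

    # Sub-50 bp fragment noise (smoothed away by quantification)
    names = list(chroms)
    for _ in range(rng.poisson(config.noise_rate)):
        for _try in range(_MAX_PLACEMENT_TRIES):
            name = names[int(rng.integers(0, len(names)))]
            st = chroms[name]
            length = int(rng.integers(10, 50))
            start = int(rng.integers(1 + _END_MARGIN_BP, st.spec.length_bp - _END_MARGIN_BP))
            end = start + length - 1
            if st.overlaps(start, end):
                continue
            state = _pick_state(rng, _NOISE_STATES)
            st.placed.append(Segment(name, start, end, state[0], state[1]))
            st.block(start, end)
            break

    # Fill everything not placed and not a hole with the 1/1 background
    segments: list[Segment] = []
    for name, st in chroms.items():
        items: list[tuple[int, int, int | None, int | None]] = [
            (s.start_bp, s.end_bp, s.major_cn, s.minor_cn) for s in st.placed
        ] + [(lo, hi, None, None) for lo, hi in st.holes]
        items.sort()
        cursor = 1
        for lo, hi, major, minor in items:
            if cursor < lo:
                segments.append(Segment(name, cursor, lo - 1, 1, 1))
            if major is not None:
                segments.append(Segment(name, lo, hi, major, minor))
            cursor = hi + 1
        if cursor <= st.spec.length_bp:
            segments.append(Segment(name, cursor, st.spec.length_bp, 1, 1))

    purity = float(rng.uniform(0.25, 0.95))
    return SegmentProfile(
        sample_id=sample_id,
        segments=tuple(segments),
        build_label=config.assembly.build_label,
        purity=purity,
    )


def simulate_cohort(
    config: SimulationConfig, n_hrd: int, n_hrp: int
) -> tuple[list[SegmentProfile], dict[str, str]]:
    """Generate ``n_hrd + n_hrp`` profiles and their true class labels.

    Deterministic given ``config.seed``; sample ``i`` of each class draws
    from substream ``(seed, class_index, i)``.
    """
    if n_hrd < 0 or n_hrp < 0:
        raise ValueError("cohort sizes must be >= 0")
    profiles: list[SegmentProfile] = []
    labels: dict[str, str] = {}
    for class_idx, (label, cls, n) in enumerate(
        (("HRD", config.hrd, n_hrd), ("HRP", config.hrp, n_hrp))
    ):
        for i in range(n):
            rng = np.random.default_rng([config.seed, class_idx, i])
            sample_id = f"{label}_{i:03d}"
            profiles.append(_simulate_sample(sample_id, cls, config, rng))
            labels[sample_id] = label
    return profiles, labels


def simulate_survival(
    labels: Mapping[str, str],
    baseline_median_months: float = 24.0,
    hazard_ratio_hrd: float = 0.5,
    censoring_rate: float = 0.0,
    seed: int | None = None,
) -> list[SurvivalRecord]:
    """Exponential survival times matched to class labels.

    HRP hazard is ``log(2) / baseline_median_months``; HRD hazard is that
    times ``hazard_ratio_hrd``. Each subject is independently censored with
    probability ``censoring_rate`` at a uniform time before its event.
    """
    if hazard_ratio_hrd <= 0:
        raise ValueError("hazard_ratio_hrd must be > 0")
    if not (0.0 <= censoring_rate < 1.0):
        raise ValueError("censoring_rate must be in [0, 1)")
    if baseline_median_months <= 0:
        raise ValueError("baseline_median_months must be > 0")
    scale_hrp = baseline_median_months / np.log(2.0)
    rng = np.random.default_rng(seed)
    records: list[SurvivalRecord] = []
    for sample_id, label in labels.items():
        if label not in ("HRD", "HRP"):
            raise ValueError(f"label for {sample_id!r} must be HRD or HRP, got {label!r}")
        scale = scale_hrp / hazard_ratio_hrd if label == "HRD" else scale_hrp
        t = float(rng.exponential(scale))
        event = True
        if censoring_rate > 0 and rng.random() < censoring_rate:
            t = float(rng.uniform(0.0, t))
            event = False
        t = max(t, 1e-6)
        records.append(
            SurvivalRecord(patient_id=sample_id, time_months=t, event=event, group=label)
        )
    return records
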