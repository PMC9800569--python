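"""Criteria optimization: decision-stump balanced accuracy, one-tailed
rank-sum scoring, exhaustive grid search over scar parameters, and
bootstrap cutoff selection.

The stump is the exhaustive max-balanced-accuracy threshold (orientation
fixed as ``count >= split => HRD``, ties broken toward the lowest
qualifying split). The rank-sum p-value is computed by exact permutation
enumeration for small samples (both classes <= ``exact_max_n``) and by the
tie- and continuity-corrected normal approximation otherwise.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, replace
from itertools import combinations
from typing import Mapping, Sequence

import numpy as np
from scipy.stats import gaussian_kde, mannwhitneyu, rankdata

from .genome import GenomeAssembly
from .scars import CriteriaSet, get_preset, lst_breakpoint_candidates
from .segments import BP_PER_MB, SegmentProfile, extract_ai, smooth_segments

__all__ = [
    "StumpResult",
    "CriteriaScore",
    "CutoffEvaluation",
    "stump_balanced_accuracy",
    "rank_sum_p_greater",
    "score_criteria",
    "grid_search_criteria",
    "select_cutoff",
    "default_grid",
]


@dataclass(frozen=True)
class StumpResult:
    split_point: float
    tpr: float
    tnr: float

    @property
    def ba(self) -> float:
        return (self.tpr + self.tnr) / 2.0


@dataclass(frozen=True)
class CriteriaScore:
    parameters: CriteriaSet
    p_one_tailed: float
    ba: float

    @property
    def score(self) -> float:
        return -math.log10(self.p_one_tailed) * self.ba


@dataclass(frozen=True)
class CutoffEvaluation:
    candidates: tuple[int, ...]
    median_ba: tuple[float, ...]
    ci95_low: tuple[float, ...]
    ci95_high: tuple[float, ...]
    selected_cutoff: int
    n_boot: int
    seed: int | None


def _to_bool_labels(labels: Sequence) -> np.ndarray:
    """Accept 'HRD'/'HRP' strings or booleans; True means HRD."""
    out = []
    for lab in labels:
        if isinstance(lab, (bool, np.bool_)):
            out.append(bool(lab))
        elif str(lab).upper() == "HRD":
            out.append(True)
        elif str(lab).upper() == "HRP":
            out.append(False)
        else:
            raise ValueError(f"unrecognized label {lab!r}; expected HRD/HRP or bool")
    return np.asarray(out, dtype=bool)


def stump_balanced_accuracy(counts: Sequence[float], labels: Sequence) -> StumpResult:
    """Best single-threshold classifier under balanced accuracy.

    Evaluates every achievable split (each distinct observed count, plus
    one past the maximum for the all-HRP rule) with the fixed orientation
    ``count >= split => HRD`` and returns the split maximizing
    (TPR + TNR) / 2; the lowest qualifying split wins ties.
    """
    x = np.asarray(counts, dtype=float)
    is_hrd = _to_bool_labels(labels)
    if x.shape != is_hrd.shape:
        raise ValueError("counts and labels must have equal length")
    if is_hrd.all() or not is_hrd.any():
        raise ValueError("both classes (HRD and HRP) must be present")

    hrd, hrp = x[is_hrd], x[~is_hrd]
    splits = np.unique(x)
    splits = np.append(splits, splits[-1] + 1.0)  # all-HRP rule
    best: StumpResult | None = None
    for split in splits:
        tpr = float(np.mean(hrd >= split))
        tnr = float(np.mean(hrp < split))
        result = StumpResult(split_point=float(split), tpr=tpr, tnr=tnr)
        if best is None or result.ba > best.ba:
            best = result
    assert best is not None
    return best


def _exact_rank_sum_p_greater(x: np.ndarray, y: np.ndarray) -> float:
    """P(U >= U_obs) by full enumeration of label assignments (midranks,
    so ties are handled exactly)."""
    n1, n = len(x), len(x) + len(y)
    ranks = rankdata(np.concatenate([x, y]))
    u_obs = ranks[:n1].sum() - n1 * (n1 + 1) / 2.0
    count = 0
    total = 0
    for idx in combinations(range(n), n1):
        u = ranks[list(idx)].sum() - n1 * (n1 + 1) / 2.0
        if u >= u_obs - 1e-9:
            count += 1
        total += 1
    return count / total


def rank_sum_p_greater(
    counts_hrd: Sequence[float], counts_hrp: Sequence[float], exact_max_n: int = 8
) -> float:
    """One-tailed Mann-Whitney p-value (alternative: HRD stochastically
    greater than HRP)."""
    x = np.asarray(counts_hrd, dtype=float)
    y = np.asarray(counts_hrp, dtype=float)
    if len(x) == 0 or len(y) == 0:
        raise ValueError("both classes must be non-empty")
    if len(x) <= exact_max_n and len(y) <= exact_max_n:
        return _exact_rank_sum_p_greater(x, y)
    res = mannwhitneyu(x, y, alternative="greater", use_continuity=True, method="asymptotic")
    return float(res.pvalue)


def score_criteria(
    counts_hrd: Sequence[float], counts_hrp: Sequence[float],
    parameters: CriteriaSet | None = None, exact_max_n: int = 8,
) -> CriteriaScore:
    """Score a criteria set: -log10(one-tailed rank-sum p) x stump BA."""
    x = list(counts_hrd)
    y = list(counts_hrp)
    if len(x) < 2 or len(y) < 2:
        raise ValueError("each class needs >= 2 samples")
    p = rank_sum_p_greater(x, y, exact_max_n=exact_max_n)
    stump = stump_balanced_accuracy(x + y, ["HRD"] * len(x) + ["HRP"] * len(y))
    if parameters is None:
        parameters = get_preset("ovaHRDscar")
    return CriteriaScore(parameters=parameters, p_one_tailed=p, ba=stump.ba)


# --------------------------------------------------------------------------
# Grid search
# --------------------------------------------------------------------------

def default_grid(feature: str) -> dict[str, list[float]]:
    """Default parameter grids per scar feature (all configurable)."""
    if feature == "loh":
        return {
            "l_min": [float(v) for v in range(1, 21)],
            "l_max": [float(v) for v in range(20, 61)] + [math.inf],
        }
    if feature == "lst":
        return {"s": [float(v) for v in range(1, 21)], "m": [0.5, 1.0, 2.0, 3.0]}
    if feature == "tai":
        return {"k": [0.5] + [float(v) for v in range(1, 21)]}
    raise ValueError(f"unknown feature {feature!r}; valid: loh, lst, tai")


def _loh_candidate_lengths(profile, assembly, smooth_min_bp) -> np.ndarray:
    smoothed = smooth_segments(profile, min_length_bp=smooth_min_bp)
    ai = extract_ai(smoothed, assembly, mode="allele_specific")
    return np.array(
        [seg.length_bp for seg in ai if seg.is_loh and not seg.spans_whole_chromosome],
        dtype=float,
    )


def _tai_candidate_lengths(profile, assembly, smooth_min_bp) -> np.ndarray:
    smoothed = smooth_segments(profile, min_length_bp=smooth_min_bp)
    ai = extract_ai(smoothed, assembly, mode="allele_specific")
    return np.array(
        [
            seg.length_bp
            for seg in ai
            if (seg.touches_p_telomere or seg.touches_q_telomere)
            and not seg.crosses_centromere
            and not seg.spans_whole_chromosome
        ],
        dtype=float,
    )


def _lst_candidates(profile, assembly, smooth_min_bp) -> np.ndarray:
    smoothed = smooth_segments(profile, min_length_bp=smooth_min_bp)
    cands = lst_breakpoint_candidates(smoothed, assembly)
    return np.array(cands, dtype=float).reshape(-1, 3)


def grid_search_criteria(
    profiles: Sequence[SegmentProfile],
    assembly: GenomeAssembly,
    labels: Mapping[str, str],
    feature: str,
    grid: Mapping[str, Sequence[float]] | None = None,
    base_criteria: CriteriaSet | None = None,
    smooth_min_bp: int = 50,
    exact_max_n: int = 8,
) -> tuple[list[CriteriaScore], CriteriaScore]:
    """Exhaustively score every grid point for one scar feature.

    Per grid point, the feature is counted per sample and scored by
    -log10(one-tailed rank-sum p) x stump balanced accuracy. Returns all
    scores ranked by score descending (ties broken toward smaller
    parameters) and the best point. Degenerate LOH points
    (``l_min >= l_max``) are skipped with a warning.
    """
    grid = dict(grid) if grid is not None else default_grid(feature)
    base = base_criteria or get_preset("ovaHRDscar")
    is_hrd = _to_bool_labels([labels[p.sample_id] for p in profiles])
    if is_hrd.all() or not is_hrd.any():
        raise ValueError("both classes must be present in labels")

    # Pre-extract per-sample structures once; each grid point is then a
    # vectorized filter.
    if feature == "loh":
        per_sample = [_loh_candidate_lengths(p, assembly, smooth_min_bp) for p in profiles]
        points = [
            (lo, hi) for lo in sorted(grid["l_min"]) for hi in sorted(grid["l_max"])
        ]
    elif feature == "lst":
        per_sample = [_lst_candidates(p, assembly, smooth_min_bp) for p in profiles]
        points = [(s, m) for s in sorted(grid["s"]) for m in sorted(grid["m"])]
    elif feature == "tai":
        per_sample = [_tai_candidate_lengths(p, assembly, smooth_min_bp) for p in profiles]
        points = [(k,) for k in sorted(grid["k"])]
    else:
        raise ValueError(f"unknown feature {feature!r}; valid: loh, lst, tai")

    results: list[CriteriaScore] = []
    for point in points:
        if feature == "loh":
            lo, hi = point
            if lo >= hi:
                warnings.warn(f"skipping degenerate LOH grid point l_min={lo}, l_max={hi}")
                continue
            counts = np.array(
                [np.sum((v > lo * BP_PER_MB) & (v < hi * BP_PER_MB)) for v in per_sample]
            )
            params = replace(base, name=f"grid_loh_{lo}_{hi}", loh_min_mb=lo, loh_max_mb=hi)
        elif feature == "lst":
            s, m = point
            counts = np.array(
                [
                    np.sum(
                        (v[:, 0] > s * BP_PER_MB)
                        & (v[:, 1] > s * BP_PER_MB)
                        & (v[:, 2] < m * BP_PER_MB)
                    )
                    for v in per_sample
                ]
            )
            params = replace(base, name=f"grid_lst_{s}_{m}",
                             lst_min_segment_mb=s, lst_max_gap_mb=m)
        else:
            (k,) = point
            counts = np.array([np.sum(v > k * BP_PER_MB) for v in per_sample])
            params = replace(base, name=f"grid_tai_{k}", tai_min_mb=k)
        results.append(
            score_criteria(
                counts[is_hrd], counts[~is_hrd], parameters=params, exact_max_n=exact_max_n
            )
        )
    if not results:
        raise ValueError("grid produced no valid points")

    def sort_key(cs: CriteriaScore):
        p = cs.parameters
        if feature == "loh":
            tie = (p.loh_min_mb, p.loh_max_mb)
        elif feature == "lst":
            tie = (p.lst_min_segment_mb, p.lst_max_gap_mb)
        else:
            tie = (p.tai_min_mb, 0.0)
        return (-cs.score, *tie)

    ranked = sorted(results, key=sort_key)
    return ranked, ranked[0]


# --------------------------------------------------------------------------
# Cutoff selection
# --------------------------------------------------------------------------

def _kde_intersection(hrd: np.ndarray, hrp: np.ndarray) -> float | None:
    """x where the two class KDEs cross between the class medians."""
    try:
        f_hrd = gaussian_kde(hrd)
        f_hrp = gaussian_kde(hrp)
    except (np.linalg.LinAlgError, ValueError):
        return None
    lo = min(hrd.min(), hrp.min())
    hi = max(hrd.max(), hrp.max())
    xs = np.linspace(lo, hi, 2048)
    diff = f_hrd(xs) - f_hrp(xs)
    sign_changes = np.nonzero(np.diff(np.sign(diff)) != 0)[0]
    if sign_changes.size == 0:
        return None
    crossings = (xs[sign_changes] + xs[sign_changes + 1]) / 2.0
    target = (np.median(hrd) + np.median(hrp)) / 2.0
    return float(crossings[np.argmin(np.abs(crossings - target))])


def select_cutoff(
    levels: Sequence[float],
    labels: Sequence,
    candidates: Sequence[int],
    n_boot: int = 10_000,
    resample_per_class: int = 29,
    seed: int | None = None,
    replace: bool = True,
) -> CutoffEvaluation:
    """Bootstrap cutoff selection.

    Per replicate, ``resample_per_class`` samples are drawn with replacement
    from each class; for every candidate cutoff the balanced accuracy of
    the rule ``levels >= cutoff => HRD`` is computed. The candidate with the
    highest median BA wins; candidates tied on median BA are broken toward
    the one closest to the intersection of the two classes' level KDEs
    (falling back to the largest tied candidate).

    ``replace=False`` with ``resample_per_class`` equal to the class sizes
    degenerates to the plug-in BA curve (useful as a sanity anchor).
    """
    x = np.asarray(levels, dtype=float)
    is_hrd = _to_bool_labels(labels)
    if x.shape != is_hrd.shape:
        raise ValueError("levels and labels must have equal length")
    hrd, hrp = x[is_hrd], x[~is_hrd]
    if hrd.size < 2 or hrp.size < 2:
        raise ValueError("each class needs >= 2 samples")
    cand = tuple(int(c) for c in candidates)
    if not cand:
        raise ValueError("candidates must be non-empty")
    lo, hi = x.min(), x.max()
    outside = [c for c in cand if c <= lo or c > hi]
    if outside:
        warnings.warn(
            f"{len(outside)} candidate cutoff(s) lie outside the observed level "
            f"range ({lo:g}..{hi:g}); their BA is still computable"
        )

    rng = np.random.default_rng(seed)
    if replace:
        boot_hrd = rng.choice(hrd, size=(n_boot, resample_per_class), replace=True)
        boot_hrp = rng.choice(hrp, size=(n_boot, resample_per_class), replace=True)
    else:
        boot_hrd = np.stack(
            [rng.choice(hrd, size=resample_per_class, replace=False) for _ in range(n_boot)]
        )
        boot_hrp = np.stack(
            [rng.choice(hrp, size=resample_per_class, replace=False) for _ in range(n_boot)]
        )

    medians, ci_lo, ci_hi = [], [], []
    for c in cand:
        tpr = (boot_hrd >= c).mean(axis=1)
        tnr = (boot_hrp < c).mean(axis=1)
        ba = (tpr + tnr) / 2.0
        medians.append(float(np.median(ba)))
        lo_q, hi_q = np.percentile(ba, [2.5, 97.5])
        ci_lo.append(float(lo_q))
        ci_hi.append(float(hi_q))

    best_ba = max(medians)
    tied = [c for c, m in zip(cand, medians) if m == best_ba]
    if len(tied) == 1:
        selected = tied[0]
    else:
        crossing = _kde_intersection(hrd, hrp)
        if crossing is None:
            selected = max(tied)
        else:
            # nearest tied candidate to the density intersection; larger
            # candidate wins exact distance ties
            selected = max(tied, key=lambda c: (-abs(c - crossing), c))
    return CutoffEvaluation(
        candidates=cand,
        median_ba=tuple(medians),
        ci95_low=tuple(ci_lo),
        ci95_high=tuple(ci_hi),
        selected_cutoff=selected,
        n_boot=n_boot,
        seed=seed,
    )
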