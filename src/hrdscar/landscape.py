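"""Descriptive AI landscape across cohorts.

Per-sample AI burden inside a length window, per-cohort feature vectors
(median burden, median length, length skewness) with hierarchical
clustering, and per-length-bin two-cohort differential abundance tests.
The total-copy-number AI rule (total != 2) is the default here, matching
how the pan-cancer characterization selects AIs; whole-chromosome AIs are
always excluded.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy.cluster.hierarchy import linkage
from scipy.spatial.distance import pdist
from scipy.stats import mannwhitneyu

from .genome import GenomeAssembly
from .segments import SegmentProfile, extract_ai, smooth_segments

__all__ = [
    "SampleAIBurden",
    "CancerTypeFeatures",
    "DifferentialBin",
    "Dendrogram",
    "sample_skewness",
    "ai_burden_summary",
    "cancer_type_features",
    "cluster_cancer_types",
    "differential_ai_by_length",
]


@dataclass(frozen=True)
class SampleAIBurden:
    sample_id: str
    cohort_label: str | None
    n_ai_in_window: int
    median_ai_length_mb: float | None


@dataclass(frozen=True)
class CancerTypeFeatures:
    cohort_label: str
    median_ai_count: float
    median_ai_length_mb: float
    length_skewness: float


@dataclass(frozen=True)
class DifferentialBin:
    bin_low_mb: float
    bin_high_mb: float
    p_two_sided: float
    fold_change: float | None  # mean(A)/mean(B) - 1; None when mean(B) == 0


def sample_skewness(values: Sequence[float]) -> float:
    """Fisher-Pearson sample skewness g1 = m3 / m2^(3/2)."""
    x = np.asarray(values, dtype=float)
    if x.size < 2:
        raise ValueError("skewness requires at least 2 values")
    d = x - x.mean()
    m2 = np.mean(d**2)
    if m2 == 0.0:
        return 0.0
    return float(np.mean(d**3) / m2**1.5)


def _window_lengths(
    profile: SegmentProfile,
    assembly: GenomeAssembly,
    min_mb: float,
    max_mb: float,
    mode: str,
    loh_only: bool,
    smooth_min_bp: int,
) -> np.ndarray:
    smoothed = smooth_segments(profile, min_length_bp=smooth_min_bp)
    lengths = [
        seg.length_mb
        for seg in extract_ai(smoothed, assembly, mode=mode)
        if not seg.spans_whole_chromosome
        and (not loh_only or seg.is_loh)
        and min_mb < seg.length_mb < max_mb
    ]
    return np.asarray(lengths, dtype=float)


def ai_burden_summary(
    profiles: Sequence[SegmentProfile],
    assembly: GenomeAssembly,
    min_mb: float = 3.0,
    max_mb: float = 50.0,
    mode: str = "total_cn",
    loh_only: bool = False,
    labels: Mapping[str, str] | None = None,
    smooth_min_bp: int = 50,
) -> list[SampleAIBurden]:
    """Per-sample count and median length of AIs inside (min_mb, max_mb)."""
    if min_mb >= max_mb:
        raise ValueError(f"min_mb ({min_mb}) must be < max_mb ({max_mb})")
    out = []
    for profile in profiles:
        lengths = _window_lengths(profile, assembly, min_mb, max_mb, mode, loh_only, smooth_min_bp)
        out.append(
            SampleAIBurden(
                sample_id=profile.sample_id,
                cohort_label=labels.get(profile.sample_id) if labels else None,
                n_ai_in_window=int(lengths.size),
                median_ai_length_mb=float(np.median(lengths)) if lengths.size else None,
            )
        )
    return out


def cancer_type_features(
    profiles_by_cohort: Mapping[str, Sequence[SegmentProfile]],
    assembly: GenomeAssembly,
    min_mb: float = 3.0,
    max_mb: float = 50.0,
    mode: str = "total_cn",
    loh_only: bool = False,
    skewness_scope: str = "pooled",
) -> list[CancerTypeFeatures]:
    """Summarize each cohort by median AI burden, median pooled AI length
    and length skewness.

    ``skewness_scope='pooled'`` computes skewness over all AI lengths in the
    cohort; ``'per_sample'`` over per-sample median lengths.
    """
    if skewness_scope not in ("pooled", "per_sample"):
        raise ValueError("skewness_scope must be 'pooled' or 'per_sample'")
    out = []
    for label, profiles in profiles_by_cohort.items():
        per_sample = [
            _window_lengths(p, assembly, min_mb, max_mb, mode, loh_only, 50)
            for p in profiles
        ]
        pooled = np.concatenate(per_sample) if per_sample else np.array([])
        if pooled.size < 2:
            raise ValueError(f"cohort {label!r}: needs >= 2 AI lengths for skewness")
        if skewness_scope == "pooled":
            skew = sample_skewness(pooled)
        else:
            medians = [float(np.median(v)) for v in per_sample if v.size]
            skew = sample_skewness(medians)
        out.append(
            CancerTypeFeatures(
                cohort_label=label,
                median_ai_count=float(np.median([v.size for v in per_sample])),
                median_ai_length_mb=float(np.median(pooled)),
                length_skewness=skew,
            )
        )
    return out


@dataclass(frozen=True)
class Dendrogram:
    """Agglomerative clustering result: scipy linkage matrix + leaf labels."""

    labels: tuple[str, ...]
    linkage_matrix: np.ndarray

    def to_newick(self) -> str:
        """Serialize as a Newick tree with merge heights as branch lengths."""
        n = len(self.labels)
        nodes: dict[int, tuple[str, float]] = {
            i: (self.labels[i], 0.0) for i in range(n)
        }
        for i, (a, b, height, _) in enumerate(self.linkage_matrix):
            (name_a, h_a), (name_b, h_b) = nodes[int(a)], nodes[int(b)]
            branch_a = max(height - h_a, 0.0)
            branch_b = max(height - h_b, 0.0)
            nodes[n + i] = (f"({name_a}:{branch_a:.6g},{name_b}:{branch_b:.6g})", height)
        return nodes[n + len(self.linkage_matrix) - 1][0] + ";"


def cluster_cancer_types(
    features: Sequence[CancerTypeFeatures], method: str = "complete"
) -> Dendrogram:
    """Agglomerative clustering of cohorts on z-scored feature vectors.

    Euclidean distance, complete linkage by default. Constant features
    z-score to zero. Deterministic given input order.
    """
    if len(features) < 2:
        raise ValueError("clustering requires >= 2 cohorts")
    X = np.array(
        [[f.median_ai_count, f.median_ai_length_mb, f.length_skewness] for f in features],
        dtype=float,
    )
    if not np.all(np.isfinite(X)):
        raise ValueError("non-finite feature values")
    std = X.std(axis=0)
    std[std == 0.0] = 1.0
    Z = (X - X.mean(axis=0)) / std
    lm = linkage(pdist(Z, metric="euclidean"), method=method)
    return Dendrogram(labels=tuple(f.cohort_label for f in features), linkage_matrix=lm)


def differential_ai_by_length(
    cohort_a: Sequence[SegmentProfile],
    cohort_b: Sequence[SegmentProfile],
    assembly: GenomeAssembly,
    bin_edges_mb: Sequence[float] | None = None,
    mode: str = "total_cn",
    loh_only: bool = False,
    bh_correct: bool = False,
) -> list[DifferentialBin]:
    """Per length bin, two-sided rank-sum test on per-sample AI counts and
    fold change = mean(A)/mean(B) - 1.

    Bins are half-open ``[low, high)``; the default is 1 Mb bins from 3 to
    50 Mb. ``bh_correct`` replaces raw p-values with Benjamini-Hochberg
    adjusted ones.
    """
    if not cohort_a or not cohort_b:
        raise ValueError("both cohorts must contain at least one sample")
    edges = np.asarray(
        bin_edges_mb if bin_edges_mb is not None else np.arange(3.0, 51.0, 1.0), dtype=float
    )
    if edges.size < 2 or np.any(np.diff(edges) <= 0):
        raise ValueError("bin_edges_mb must be increasing with >= 2 edges")

    def per_sample_counts(profiles: Sequence[SegmentProfile]) -> np.ndarray:
        counts = np.zeros((len(profiles), edges.size - 1), dtype=int)
        for i, profile in enumerate(profiles):
            lengths = _window_lengths(
                profile, assembly, -math.inf, math.inf, mode, loh_only, 50
            )
            if lengths.size:
                idx = np.searchsorted(edges, lengths, side="right") - 1
                for j in idx[(idx >= 0) & (idx < edges.size - 1)]:
                    counts[i, j] += 1
        return counts

    counts_a = per_sample_counts(cohort_a)
    counts_b = per_sample_counts(cohort_b)

    p_values = []
    folds: list[float | None] = []
    for j in range(edges.size - 1):
        a, b = counts_a[:, j], counts_b[:, j]
        pooled = np.concatenate([a, b])
        if np.all(pooled == pooled[0]):
            p = 1.0  # no variation at all: no evidence of difference
        else:
            p = float(mannwhitneyu(a, b, alternative="two-sided").pvalue)
        p_values.append(p)
        mean_b = b.mean()
        folds.append(float(a.mean() / mean_b - 1.0) if mean_b > 0 else None)

    if bh_correct:
        p_values = _benjamini_hochberg(p_values)

    return [
        DifferentialBin(
            bin_low_mb=float(edges[j]),
            bin_high_mb=float(edges[j + 1]),
            p_two_sided=p_values[j],
            fold_change=folds[j],
        )
        for j in range(edges.size - 1)
    ]


def _benjamini_hochberg(p_values: Sequence[float]) -> list[float]:
    p = np.asarray(p_values, dtype=float)
    order = np.argsort(p, kind="stable")
    m = p.size
    adjusted = np.empty(m)
    running_min = 1.0
    for rank_from_top in range(m - 1, -1, -1):
        i = order[rank_from_top]
        running_min = min(running_min, p[i] * m / (rank_from_top + 1))
        adjusted[i] = running_min
    return adjusted.tolist()
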