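"""Independent brute-force reference implementations used as oracles.

Deliberately written as plain loops over the stated definitions, sharing no
code with the package internals beyond the data containers.
"""

from __future__ import annotations

import math
from itertools import combinations

import numpy as np

MB = 1_000_000


def oracle_smooth(segments, min_bp=50):
    """Reference smoothing: drop fragments < min_bp, then merge runs of
    identical states per chromosome. Input/output: (chrom, start, end, maj,
    mnr) tuples sorted by (chrom, start)."""
    kept = [s for s in segments if s[2] - s[1] + 1 >= min_bp]
    kept.sort(key=lambda s: (s[0], s[1]))
    out = []
    for seg in kept:
        if out and out[-1][0] == seg[0] and out[-1][3:] == seg[3:]:
            prev = out[-1]
            out[-1] = (prev[0], prev[1], seg[2], prev[3], prev[4])
        else:
            out.append(seg)
    return out


def _extent(segments):
    ext = {}
    for chrom, start, end, *_ in segments:
        lo, hi = ext.get(chrom, (math.inf, -math.inf))
        ext[chrom] = (min(lo, start), max(hi, end))
    return ext


def oracle_count_loh(segments, assembly, l_min_mb, l_max_mb):
    ext = _extent(segments)
    n = 0
    for chrom, start, end, maj, mnr in segments:
        if not (mnr == 0 and maj >= 1):
            continue
        first, last = ext[chrom]
        if start == first and end == last:
            continue
        length = end - start + 1
        if length > l_min_mb * MB and length < l_max_mb * MB:
            n += 1
    return n


def oracle_count_tai(segments, assembly, k_mb):
    ext = _extent(segments)
    n = 0
    for chrom, start, end, maj, mnr in segments:
        if maj == mnr:
            continue
        first, last = ext[chrom]
        touch_p = start == first
        touch_q = end == last
        if not (touch_p or touch_q) or (touch_p and touch_q):
            continue
        spec = assembly[chrom]
        if start < spec.centromere_start_bp and end > spec.centromere_end_bp:
            continue
        if end - start + 1 > k_mb * MB:
            n += 1
    return n


def oracle_count_lst(segments, assembly, s_mb, m_mb):
    per_chrom = {}
    for seg in segments:
        per_chrom.setdefault(seg[0], []).append(seg)
    n = 0
    for chrom, segs in per_chrom.items():
        spec = assembly[chrom]
        p_hi = spec.centromere_start_bp - 1
        q_lo = spec.centromere_end_bp + 1
        for arm_lo, arm_hi in ((1, p_hi), (q_lo, spec.length_bp)):
            arm = []
            for _, start, end, maj, mnr in sorted(segs, key=lambda s: s[1]):
                a = max(start, arm_lo)
                b = min(end, arm_hi)
                if a <= b:
                    arm.append((a, b, maj, mnr))
            for (a1, b1, j1, n1), (a2, b2, j2, n2) in zip(arm, arm[1:]):
                if (j1, n1) == (j2, n2):
                    continue
                if (b1 - a1 + 1) > s_mb * MB and (b2 - a2 + 1) > s_mb * MB \
                        and (a2 - b1 - 1) < m_mb * MB:
                    n += 1
    return n


def oracle_quantify(segments, assembly, criteria, smooth_bp=50):
    """Smooth then count all three scar classes; returns (loh, lst, tai)."""
    sm = oracle_smooth(segments, smooth_bp)
    return (
        oracle_count_loh(sm, assembly, criteria.loh_min_mb, criteria.loh_max_mb),
        oracle_count_lst(sm, assembly, criteria.lst_min_segment_mb, criteria.lst_max_gap_mb),
        oracle_count_tai(sm, assembly, criteria.tai_min_mb),
    )


def oracle_best_stump_ba(counts, is_hrd):
    """Exhaustive threshold search for max balanced accuracy (>= => HRD)."""
    counts = np.asarray(counts, dtype=float)
    is_hrd = np.asarray(is_hrd, dtype=bool)
    thresholds = sorted(set(counts)) + [max(counts) + 1]
    best = -1.0
    for t in thresholds:
        tpr = np.mean(counts[is_hrd] >= t)
        tnr = np.mean(counts[~is_hrd] < t)
        best = max(best, (tpr + tnr) / 2.0)
    return best


def oracle_exact_u_p_greater(x, y):
    """Exact one-tailed rank-sum p by enumerating every label assignment."""
    x = list(map(float, x))
    y = list(map(float, y))
    combined = x + y
    # midranks
    order = sorted(range(len(combined)), key=lambda i: combined[i])
    ranks = [0.0] * len(combined)
    i = 0
    while i < len(order):
        j = i
        while j < len(order) and combined[order[j]] == combined[order[i]]:
            j += 1
        mid = (i + j + 1) / 2.0
        for k in range(i, j):
            ranks[order[k]] = mid
        i = j
    n1 = len(x)
    u_obs = sum(ranks[:n1]) - n1 * (n1 + 1) / 2.0
    hits = total = 0
    for idx in combinations(range(len(combined)), n1):
        u = sum(ranks[i] for i in idx) - n1 * (n1 + 1) / 2.0
        if u >= u_obs - 1e-9:
            hits += 1
        total += 1
    return hits / total


def oracle_complete_linkage_merges(points):
    """Naive agglomerative complete-linkage clustering on z-scored rows.

    Returns the sorted pair of member sets merged at each step, for
    comparison against a linkage-matrix implementation.
    """
    X = np.asarray(points, dtype=float)
    std = X.std(axis=0)
    std[std == 0] = 1.0
    Z = (X - X.mean(axis=0)) / std
    clusters = [frozenset([i]) for i in range(len(Z))]

    def dist(c1, c2):
        return max(np.linalg.norm(Z[i] - Z[j]) for i in c1 for j in c2)

    merges = []
    while len(clusters) > 1:
        best = None
        for a, b in combinations(range(len(clusters)), 2):
            d = dist(clusters[a], clusters[b])
            if best is None or d < best[0] - 1e-12:
                best = (d, a, b)
        d, a, b = best
        merged = clusters[a] | clusters[b]
        merges.append((frozenset(clusters[a]), frozenset(clusters[b]), d))
        clusters = [c for i, c in enumerate(clusters) if i not in (a, b)] + [merged]
    return merges
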