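"""Agreement and concordance statistics, intra/inter-patient level
variability, TP53-VAF tumor purity estimation, and patient-level
anatomical-site prioritization.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import combinations
from typing import Mapping, Sequence

import numpy as np
from scipy.stats import mannwhitneyu

from .scars import CriteriaSet

__all__ = [
    "TumorPurityEstimate",
    "AgreementResult",
    "PatientLevelCall",
    "SampleLevel",
    "lin_ccc",
    "agreement",
    "pairwise_level_differences",
    "estimate_purity_tp53",
    "resolve_patient_level",
]


def lin_ccc(x: Sequence[float], y: Sequence[float]) -> float:
    """Lin's concordance correlation coefficient.

    ccc = 2 cov(x,y) / (var(x) + var(y) + (mean x - mean y)^2), with
    population (n-denominator) moments.
    """
    a = np.asarray(x, dtype=float)
    b = np.asarray(y, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("x and y must be 1-D vectors of equal length")
    if a.size < 2:
        raise ValueError("need at least 2 observations")
    if not (np.all(np.isfinite(a)) and np.all(np.isfinite(b))):
        raise ValueError("non-finite values in input")
    var_a = a.var()
    var_b = b.var()
    shift = a.mean() - b.mean()
    denom = var_a + var_b + shift**2
    if denom == 0.0:
        raise ValueError("degenerate input: both vectors constant with equal means")
    cov = np.mean((a - a.mean()) * (b - b.mean()))
    return float(2.0 * cov / denom)


@dataclass(frozen=True)
class AgreementResult:
    percent_agreement: float
    cohen_kappa: float
    contingency: dict[tuple[str, str], int]


def agreement(calls_a: Mapping[str, str], calls_b: Mapping[str, str]) -> AgreementResult:
    """Percent agreement and Cohen's kappa between two binary call sets.

    ``calls_a`` and ``calls_b`` map sample ids to categories (e.g.
    HRD/HRP); samples present in both are compared.
    """
    shared = sorted(set(calls_a) & set(calls_b))
    if not shared:
        raise ValueError("no overlapping sample ids between the two call sets")
    cats = sorted({calls_a[s] for s in shared} | {calls_b[s] for s in shared})
    table = {(ca, cb): 0 for ca in cats for cb in cats}
    for s in shared:
        table[(calls_a[s], calls_b[s])] += 1
    n = len(shared)
    p_o = sum(table[(c, c)] for c in cats) / n
    p_e = sum(
        (sum(table[(c, cb)] for cb in cats) / n) * (sum(table[(ca, c)] for ca in cats) / n)
        for c in cats
    )
    kappa = 1.0 if p_e == 1.0 else (p_o - p_e) / (1.0 - p_e)
    return AgreementResult(
        percent_agreement=100.0 * p_o, cohen_kappa=float(kappa), contingency=table
    )


def pairwise_level_differences(
    levels: Mapping[tuple[str, str], float],
) -> tuple[list[float], list[float], float | None]:
    """Absolute pairwise level differences within and between patients.

    ``levels`` is keyed by ``(patient_id, sample_id)``. Returns
    ``(intra_diffs, inter_diffs, two-sided rank-sum p)``; p is None (with a
    warning) when either group of pairs is empty.
    """
    keys = list(levels)
    if len(keys) < 2:
        raise ValueError("need at least 2 samples")
    intra: list[float] = []
    inter: list[float] = []
    for (pa, sa), (pb, sb) in combinations(keys, 2):
        diff = abs(levels[(pa, sa)] - levels[(pb, sb)])
        (intra if pa == pb else inter).append(diff)
    if not intra or not inter:
        warnings.warn("one of the pair groups is empty; p-value undefined")
        return intra, inter, None
    p = float(mannwhitneyu(intra, inter, alternative="two-sided").pvalue)
    return intra, inter, p


@dataclass(frozen=True)
class TumorPurityEstimate:
    sample_id: str | None
    cn: float
    vaf: float
    purity: float


def estimate_purity_tp53(
    vaf: float, cn: float, sample_id: str | None = None
) -> TumorPurityEstimate:
    """Tumor purity from the truncal TP53 VAF and local absolute copy number.

    purity = 2 / ((CN / VAF) - (CN - 2)). Values in (1, 1.05] are clamped
    to 1 (rounding slack); anything else outside (0, 1] is rejected as
    inconsistent input.
    """
    if not (0.0 < vaf <= 1.0):
        raise ValueError(f"vaf {vaf} outside (0, 1]")
    if cn <= 0:
        raise ValueError(f"cn {cn} must be > 0")
    denom = (cn / vaf) - (cn - 2.0)
    if denom <= 0:
        raise ValueError(f"inconsistent input: denominator {denom:g} <= 0")
    purity = 2.0 / denom
    if 1.0 < purity <= 1.05:
        purity = 1.0
    if not (0.0 < purity <= 1.0):
        raise ValueError(
            f"inconsistent input: purity {purity:g} outside (0, 1.05] for "
            f"vaf={vaf}, cn={cn}"
        )
    return TumorPurityEstimate(sample_id=sample_id, cn=cn, vaf=vaf, purity=purity)


@dataclass(frozen=True)
class SampleLevel:
    """One sample's scar level with sampling metadata."""

    sample_id: str
    level: float
    site: str = "other"
    phase: str | None = None
    purity: float | None = None


@dataclass(frozen=True)
class PatientLevelCall:
    patient_id: str
    strategy: str
    level: float
    status: str


def _site_group(site: str) -> str:
    s = site.strip().upper().replace("/", "_")
    if s.startswith(("OVA", "ADN")):
        return "ova_adn"
    if s.startswith("OME"):
        return "omentum"
    return "other"


_STRATEGIES = ("mean_all", "ome_then_ova", "ova_then_ome")


def resolve_patient_level(
    patient_id: str,
    samples: Sequence[SampleLevel],
    strategy: str,
    criteria: CriteriaSet,
    purity_floor: float = 0.30,
) -> PatientLevelCall:
    """Collapse a patient's samples to one level and HR status.

    Samples below ``purity_floor`` are dropped (unknown purity passes).
    ``mean_all`` averages all eligible samples; ``ova_then_ome`` /
    ``ome_then_ova`` average the preferred anatomical site, falling back to
    the other, then to the mean of everything eligible.
    """
    if strategy not in _STRATEGIES:
        raise ValueError(f"unknown strategy {strategy!r}; valid: {_STRATEGIES}")
    eligible = [s for s in samples if s.purity is None or s.purity >= purity_floor]
    if not eligible:
        raise ValueError(
            f"patient {patient_id}: no sample passes the purity floor {purity_floor}"
        )
    if strategy == "mean_all":
        chosen = eligible
    else:
        order = (
            ("ova_adn", "omentum") if strategy == "ova_then_ome" else ("omentum", "ova_adn")
        )
        chosen = []
        for group in order:
            chosen = [s for s in eligible if _site_group(s.site) == group]
            if chosen:
                break
        if not chosen:
            chosen = eligible
    level = float(np.mean([s.level for s in chosen]))
    status = "HRD" if level >= criteria.cutoff else "HRP"
    return PatientLevelCall(patient_id=patient_id, strategy=strategy, level=level, status=status)
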