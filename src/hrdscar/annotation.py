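"""Multi-omics ground-truth labeling of samples as HRD / HRP / undefined.

A sample is HRD when it carries a qualifying alteration (pathogenic
somatic/germline mutation, strong deletion, or promoter hypermethylation)
in one of the trigger genes (BRCA1/2 and the RAD51 paralogs by default).
HRP requires all three omics layers to be available, no qualifying
alteration, and no strong deletion in any HR-pathway gene. Everything
else — including manually excluded outliers — is undefined.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

__all__ = [
    "ALTERATION_CATEGORIES",
    "DEFAULT_HRD_TRIGGER_GENES",
    "AlterationRecord",
    "OmicsAvailability",
    "MethylationSummary",
    "CohortAnnotation",
    "InsufficientDataError",
    "call_promoter_hypermethylation",
    "annotate_cohort",
]

ALTERATION_CATEGORIES = frozenset(
    {"somatic_mutation", "germline_mutation", "strong_deletion",
     "promoter_hypermethylation", "amplification"}
)

#: BRCA1/2 plus the RAD51 paralogs. A config-level default, not hard-coded
#: biology: every entry point accepts a custom gene set.
DEFAULT_HRD_TRIGGER_GENES = frozenset(
    {"BRCA1", "BRCA2", "RAD51", "RAD51B", "RAD51C", "RAD51D", "XRCC2", "XRCC3"}
)

_MUTATION_CATEGORIES = frozenset({"somatic_mutation", "germline_mutation"})
_HRD_QUALIFYING = _MUTATION_CATEGORIES | {"strong_deletion", "promoter_hypermethylation"}


class InsufficientDataError(ValueError):
    """No usable measurements for the requested call."""


@dataclass(frozen=True)
class AlterationRecord:
    sample_id: str
    gene: str
    category: str
    pathogenic: bool = True

    def __post_init__(self) -> None:
        if self.category not in ALTERATION_CATEGORIES:
            raise ValueError(
                f"unknown alteration category {self.category!r}; "
                f"valid: {sorted(ALTERATION_CATEGORIES)}"
            )
        if not self.gene:
            raise ValueError("gene must be non-empty")


@dataclass(frozen=True)
class OmicsAvailability:
    sample_id: str
    has_methylation: bool = True
    has_gene_deletion: bool = True
    has_somatic_mutation: bool = True

    @property
    def complete(self) -> bool:
        return self.has_methylation and self.has_gene_deletion and self.has_somatic_mutation


@dataclass(frozen=True)
class MethylationSummary:
    """Promoter methylation probes for one gene in one sample.

    ``probe_positions_bp`` are signed offsets relative to the transcription
    start site (positive = downstream); betas are fractions in [0, 1].
    """

    sample_id: str
    gene: str
    probe_positions_bp: tuple[int, ...]
    probe_betas: tuple[float, ...]

    def __post_init__(self) -> None:
        if len(self.probe_positions_bp) != len(self.probe_betas):
            raise ValueError("positions and betas must have equal length")
        for beta in self.probe_betas:
            if not (0.0 <= beta <= 1.0):
                raise ValueError(f"beta value {beta} outside [0, 1]")


def call_promoter_hypermethylation(
    summary: MethylationSummary,
    window_bp: int = 1500,
    threshold: float = 0.75,
    signed_window: bool = False,
) -> bool:
    """True iff the mean beta of in-window probes is >= ``threshold``.

    The window is 0..``window_bp`` downstream of the TSS by default (as the
    rule is stated); ``signed_window`` widens it to +/- ``window_bp`` around
    the TSS, the conventional promoter-probe placement.
    """
    if signed_window:
        in_window = [b for p, b in zip(summary.probe_positions_bp, summary.probe_betas)
                     if abs(p) <= window_bp]
    else:
        in_window = [b for p, b in zip(summary.probe_positions_bp, summary.probe_betas)
                     if 0 <= p <= window_bp]
    if not in_window:
        raise InsufficientDataError(
            f"sample {summary.sample_id}, gene {summary.gene}: "
            f"no probe within {window_bp} bp of the TSS"
        )
    return sum(in_window) / len(in_window) >= threshold


@dataclass(frozen=True)
class CohortAnnotation:
    """Per-sample label (HRD / HRP / undefined) plus supporting evidence."""

    labels: dict[str, str] = field(default_factory=dict)
    evidence: dict[str, tuple[AlterationRecord, ...]] = field(default_factory=dict)

    def label_of(self, sample_id: str) -> str:
        return self.labels[sample_id]

    def samples(self, label: str | None = None) -> list[str]:
        if label is None:
            return list(self.labels)
        return [s for s, v in self.labels.items() if v == label]


def _qualifies_hrd(record: AlterationRecord, trigger_genes: frozenset[str]) -> bool:
    if record.gene not in trigger_genes:
        return False
    if record.category in _MUTATION_CATEGORIES:
        return record.pathogenic
    return record.category in _HRD_QUALIFYING


def annotate_cohort(
    alterations: Iterable[AlterationRecord],
    availability: Iterable[OmicsAvailability] | Mapping[str, OmicsAvailability],
    hrd_trigger_genes: Iterable[str] = DEFAULT_HRD_TRIGGER_GENES,
    hr_pathway_genes: Iterable[str] = (),
    manual_exclusions: Iterable[str] = (),
) -> CohortAnnotation:
    """Partition the cohort into HRD / HRP / undefined.

    ``hr_pathway_genes`` is the broader HR pathway gene set used only for
    the no-deletion requirement on HRP samples; the trigger genes are
    implicitly part of it. ``manual_exclusions`` forces samples to
    undefined regardless of evidence (e.g. burden outliers).
    """
    triggers = frozenset(hrd_trigger_genes)
    if not triggers:
        raise ValueError("hrd_trigger_genes must be non-empty")
    pathway = frozenset(hr_pathway_genes) | triggers
    excluded = frozenset(manual_exclusions)

    if isinstance(availability, Mapping):
        avail_map = dict(availability)
    else:
        avail_map = {a.sample_id: a for a in availability}

    per_sample: dict[str, list[AlterationRecord]] = {s: [] for s in avail_map}
    for record in alterations:
        if record.sample_id not in avail_map:
            raise ValueError(
                f"sample {record.sample_id!r} has alterations but no omics "
                "availability record"
            )
        per_sample[record.sample_id].append(record)

    labels: dict[str, str] = {}
    evidence: dict[str, tuple[AlterationRecord, ...]] = {}
    for sample_id, records in per_sample.items():
        hrd_evidence = tuple(r for r in records if _qualifies_hrd(r, triggers))
        if sample_id in excluded:
            labels[sample_id] = "undefined"
            continue
        if hrd_evidence:
            labels[sample_id] = "HRD"
            evidence[sample_id] = hrd_evidence
            continue
        avail = avail_map[sample_id]
        has_pathway_deletion = any(
            r.category == "strong_deletion" and r.gene in pathway for r in records
        )
        if avail.complete and not has_pathway_deletion:
            labels[sample_id] = "HRP"
        else:
            labels[sample_id] = "undefined"
    return CohortAnnotation(labels=labels, evidence=evidence)
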