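# hrdscar

Quantification of homologous-recombination-deficiency (HRD) genomic scars —
LOH, large-scale state transitions (LST) and telomeric allelic imbalances
(TAI) — from allele-specific copy-number segments, together with the
machinery used to *derive* such a scar score: multi-omics ground-truth
annotation, exhaustive criteria grid search, bootstrap cutoff selection,
agreement/concordance statistics and survival analysis. A synthetic-cohort
generator makes every part testable without any external data.

## What's inside

| Module | Purpose |
|---|---|
| `hrdscar.genome` | Assembly model (chromosome lengths + centromeres); hg19/hg38 bundled |
| `hrdscar.segments` | Segment-table I/O (generic seg / GDC allele-specific / ASCAT dialects), validation, 50 bp smoothing, AI extraction with telomere/centromere flags |
| `hrdscar.scars` | LOH/LST/TAI counters, parametric `CriteriaSet`, the four published presets (`telli2016`, `takaya2020`, `ovaHRDscar`, `tnbcHRDscar`), HR-status calls |
| `hrdscar.landscape` | Per-sample AI burden, per-cohort feature vectors + hierarchical clustering, per-length-bin differential tests |
| `hrdscar.annotation` | HRD / HRP / undefined labeling from mutations, deletions and promoter hypermethylation |
| `hrdscar.optimize` | Decision-stump balanced accuracy, one-tailed rank-sum scoring (exact for small n), criteria grid search, bootstrap cutoff selection |
| `hrdscar.concordance` | Lin's CCC, Cohen's kappa, intra/inter-patient level differences, TP53-VAF purity, patient-level site prioritization |
| `hrdscar.survival` | Log-rank, Cox PH (lifelines-backed), bootstrap median-survival fold change |
| `hrdscar.simulate` | Class-conditional synthetic segment profiles + matched survival data |

## CLI

Everything is reachable through a single `hrdscar` entry point:

```sh
# generate a synthetic cohort (segments, labels, survival, assembly table)
hrdscar simulate --n-hrd 50 --n-hrp 50 --seed 7 --out-dir cohort/

# count scars and call HR status
hrdscar quantify --segments cohort/segments.tsv --assembly cohort/assembly.tsv \
    --preset ovaHRDscar --out scars.tsv

# cohort landscape, criteria grid search, cutoff bootstrap
hrdscar landscape --segments cohort/segments.tsv --labels cohort/labels.tsv \
    --assembly cohort/assembly.tsv --out-prefix land
hrdscar optimize --segments cohort/segments.tsv --labels cohort/labels.tsv \
    --assembly cohort/assembly.tsv --feature loh --out grid.tsv
hrdscar cutoff --levels scars.tsv --labels cohort/labels.tsv \
    --candidates 1:120 --nboot 10000 --seed 7 --out cutoff.json

# agreement between two call sets; patient-level site prioritization
hrdscar concordance --calls-a scars.tsv --calls-b other_calls.tsv
hrdscar patient-level --levels patient_levels.tsv --strategy ova_then_ome \
    --preset ovaHRDscar --out patients.tsv

# survival comparison of HRD vs HRP
hrdscar survive --clinical cohort/survival.tsv --calls calls.tsv \
    --covariates residual_tumor --nboot 1000 --seed 7 --out survival.json
```

Real data: `--segments` accepts GDC allele-specific tables
(`--dialect gdc_allele_specific`) and ASCAT output (`--dialect ascat_output`)
with `--assembly hg19|hg38`.

## Conventions

* Coordinates are 1-based inclusive; lengths are `end − start + 1`.
* Length criteria are strict inequalities; the HRD cutoff is inclusive
  (levels ≥ cutoff ⇒ HRD).
* Telomere contact is defined against the profile's covered extent per
  chromosome, not the physical chromosome end.
* Default chromosome set is autosomes + X (Y configurable).
* No ploidy normalization is applied anywhere.
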