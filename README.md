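# bbs-workbench

Analysis toolkit for family studies of the 15q11.2 BP1-BP2 microdeletion
(Burnside-Butler syndrome). The deletion removes one copy of *TUBGCP5*,
*CYFIP1*, *NIPA1* and *NIPA2*; studies of affected families ask (a) whether
rare, potentially damaging variants elsewhere in the exome modify symptom
expression, and (b) whether affected individuals show measurable motor
differences such as increased postural sway. This package implements both
desk-side analyses for researchers who already have called, annotated trio
exomes and raw force-platform recordings:

1. **Variant arm** — reads multi-sample VCF (GT/DP/GQ plus gene,
   consequence, max allele frequency and SIFT/PolyPhen/Grantham INFO
   annotations) together with a pedigree extended by a deletion-carrier
   flag; applies a hard-filter cascade selecting *potentially damaging
   variants* (PDVs); classifies each child PDV as de novo, inherited from
   the deleted or non-deleted parent, or unknown; and summarizes per-child
   burden, consequence spectrum, gene-panel overrepresentation
   (hypergeometric + Benjamini-Hochberg) and protein-interaction
   neighbours of the four deleted genes.
2. **Posture arm** — derives center-of-pressure (COP) series from force
   and moment channels, trims/resamples/filters them, computes sway
   metrics, and compares affected vs control groups with Cohen's *d*.
3. **Synthetic-data module** — generates annotated trio VCFs with planted
   inheritance categories and single-fault cascade failures, and
   Ornstein-Uhlenbeck sway trials with known stationary variability, so
   the full pipeline runs and is testable with no external data.

## The core procedures

**PDV cascade.** A variant call in an affected child is retained iff all
of the following hold: the variant lies in a protein-coding transcript;
the child carries ≥ 1 alternate allele; genotype quality GQ ≥ 20; read
depth DP ≥ 10 for SNVs, ≥ 28X for indels up to 5 bp and ≥ 42X for indels
of 5–200 bp; maximum reference-population allele frequency < 0.01 %
(unobserved variants count as rare); the predicted consequence is
moderately (inframe indel, missense, protein-altering) or highly
(splice-site, stop gained/lost, start lost, frameshift) damaging; and —
for missense or start-loss SNVs — SIFT < 0.05, PolyPhen ≥ 0.70 and
Grantham ≥ 100. Parents failing genotype QC are demoted to missing rather
than discarding the variant.

**Inheritance.** With hard trio genotypes (child *c*, deleted-parent *d*,
non-deleted parent *n*): any missing parent → unknown (missing parent);
child hom-alt with a parent lacking the alt → unknown (improbable
homozygous de novo); child het with neither parent carrying → de novo;
exactly one carrier parent → inherited from that parent; both carriers →
inherited-ambiguous when biparental transmission can produce the child's
genotype, otherwise a Mendelian violation.

**Effect sizes.** Group contrasts use Cohen's *d* with the study sign
convention,

    d = (mean_control − mean_affected) / sqrt((sd_affected² + sd_control²) / 2),

i.e. control minus affected over the unweighted root-mean-square of the
two group SDs; negative *d* means more sway in the affected group.

## Worked example

Everything below runs offline from simulated inputs:

```bash
workbench run-all --seed 7 --out demo
# variant arm: 100 PDVs; posture arm: 35 usable trials; outputs under demo
```

The variant manifest (`demo/variants/manifest.json`) shows 150 input
variant records reduced to 100 PDVs — the 50 removed records are the
generator's planted single-fault failures (non-coding biotype, low GQ/DP,
common allele, non-damaging consequence, benign scores) — with category
counts exactly matching the planted truth table
(`demo/sim/truth.tsv`):

```
{'DE_NOVO': 25, 'INHERITED_AMBIGUOUS': 10, 'INHERITED_DELETED_PARENT': 20,
 'INHERITED_NONDELETED_PARENT': 25, 'UNKNOWN_IMPROBABLE_HOM_DENOVO': 5,
 'UNKNOWN_MENDELIAN_VIOLATION': 5, 'UNKNOWN_MISSING_PARENT': 10}
```

`demo/posture/group_comparison.tsv` holds the group table; with the
default generator settings the affected group is simulated with larger
sway, so every Cohen's *d* is negative (e.g. ml_sd_log: affected
−0.56 ± 0.04 vs control −0.88 ± 0.03, d = −9.6 — the synthetic cohort has
no between-participant variability, so synthetic effect sizes are far
larger than real ones).

From Python, the effect-size routine can be applied directly to published
summary statistics (COP path length, affected vs control children):

```python
>>> from bbs_workbench import cohens_d
>>> round(cohens_d(35.74, 21.37, 6, 23.81, 15.36, 6), 3)
-0.641
```

## Command-line interface

```
workbench simulate trios|sway     # synthetic inputs + truth tables
workbench variants load|prioritize|classify|report
workbench posture run             # trials dir + groups TSV -> metrics, comparison
workbench run-all                 # simulate both arms and run end to end
```

See `docs/methods.md` for the models, parameter choices and limitations.
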