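# Methods

## Variant arm

### Input model

The package consumes *already-called, already-annotated* variants: a
multi-sample VCF v4.2 with per-genotype `GT`/`DP`/`GQ` and per-variant
INFO annotations, plus a PED pedigree extended with a seventh column
flagging the parent who carries the 15q11.2 BP1-BP2 deletion. Alignment,
joint genotyping, genotype refinement and annotation (VEP/SnpEff, SIFT,
PolyPhen, Grantham) are upstream and out of scope; their outputs are
input fields here. Default INFO keys are `GENE`, `BIOTYPE`, `CSQCLASS`
(`&`-joined controlled terms), `MAX_AF`, `SIFT`, `POLYPHEN`, `GRANTHAM`;
`AnnotationKeys.from_yaml` remaps them for other annotation dialects.

Multi-allelic records are decomposed before any filtering: each
(record, alt) pair becomes one bi-allelic record, genotype indices are
remapped so the retained alt is 1 and every other allele (including other
alts) is 0, and per-alt (`Number=A`) INFO values are split. Decomposition
conserves total alt dosage. DP and GQ are copied to all decomposed
records. All chromosomes are treated as diploid; hemizygous-looking
(haploid) calls are logged and demoted to missing. Out-of-range genotype
allele indices are demoted to missing by htslib; structurally malformed
genotype strings raise a parse error naming the file line.

### PDV cascade

Stage order: protein-coding biotype → child carries ≥ 1 alt → genotype QC
→ rarity → consequence severity → deleteriousness triage. Thresholds
(`FilterConfig`, all YAML-overridable):

| parameter | default | meaning |
| --- | --- | --- |
| `gq_min` | 20.0 | genotype quality; GQ < 20 excluded |
| `snv_dp_min` | 10 | SNV read depth (inclusive) |
| `indel_dp_min_short` | 28 | indels ≤ 5 bp |
| `indel_dp_min_long` | 42 | indels of 5–200 bp |
| `indel_len_max` | 200 | longer indels never pass |
| `max_af_threshold` | 1e-4 | max reference-population AF, strict `<` |
| `sift_max` | 0.05 | strict `<` |
| `polyphen_min` | 0.70 | inclusive `≥` |
| `grantham_min` | 100 | inclusive `≥` |

Numerical/edge choices, each deliberate:

- The two indel depth rules overlap at exactly 5 bp; the laxer 28X rule
  wins there, and 1 bp indels also use the 28X rule.
- Absent `MAX_AF` means "not observed in any reference population" and
  passes rarity — otherwise no de novo variant could ever survive.
- The three missense scores are combined with AND; an absent score on a
  missense/start-loss SNV fails triage (conservative: unscored missense
  cannot flood the PDV set). Non-missense qualifying consequences skip
  triage entirely.
- QC applies to the child call and to each present parent call, but a
  parent failing QC is demoted to missing for inheritance purposes
  instead of discarding the variant: QC filters calls, not variants.

### Inheritance classification

Classification is from hard genotypes; posterior-probability genotype
refinement is upstream and not reproduced, so "de novo" here means
"child het, both parents confidently homozygous reference after QC".
Decision order (first match wins): missing parent → unknown-missing;
child hom-alt with a parent lacking the alt → improbable homozygous de
novo; child het with no carrier parent → de novo; exactly one carrier
parent → inherited from that parent's role; both carriers → ambiguous if
biparental transmission can yield the child genotype, otherwise an
uncharacterized Mendelian violation (the only fully-observed inconsistent
configuration under bi-allelic diploid genotypes is child het with both
parents hom-alt). The categories partition the PDV set; swapping the two
parents' genotypes together with their roles mirrors only the two
parent-attributed categories.

Gene-level exclusivity (all of a gene's classified calls de novo, or all
inherited from the non-deleted parent) is computed across children;
children with no parental data contribute counts but cannot veto or
establish exclusivity.

### Burden, spectrum, enrichment, interactors

Per-child burden counts PDVs, distinct genes, and distinct genes per
panel; cohort statistics are means with sample SDs (n−1). The consequence
spectrum assigns each PDV a single primary class by severity-ordered
priority (frameshift, stop gained/lost, start lost, splice site, inframe
insertion/deletion, missense, protein altering), as proportions of all
PDVs. Panel overrepresentation is the hypergeometric upper tail
P(X ≥ k) with Benjamini-Hochberg correction across the tested panels,
significant at adjusted p ≤ 0.05. The enrichment universe defaults to
the number of distinct genes bearing any variant pre-cascade — the
natural "drawable" set when the input is an exome's called variants.
Interaction analysis is declarative: a user-supplied edge list
(gene_a, gene_b, relation ∈ {PP, C, CO}) is cross-referenced for
protein-protein neighbours of *CYFIP1*, *TUBGCP5*, *NIPA1*, *NIPA2*; no
network inference is performed.

## Posture arm

COP is derived from force-platform channels as `cop_ml = −My/Fz`,
`cop_ap = Mx/Fz` (moments in N·m over vertical force in N, converted to
cm; plate-origin offsets configurable). A vertical load near zero marks
the trial unusable (participant left the plate). Processing: drop the
first 5 s, keep the next 20 s, down-sample to 100 Hz (anti-aliased FIR
decimation for integral ratios, polyphase resampling otherwise), then
low-pass with a 4th-order Butterworth at 6 Hz applied forward and
backward. "Fourth-order double-pass" is read as a 4th-order *design* run
twice (effective 8th-order magnitude, |H(6 Hz)|² = ½), not two cascaded
2nd-order passes. Filtering pads reflectively with 3× the filter order
(12 samples); metrics use the full 2,000-sample window. Trials shorter
than 25 s are unusable; participants with fewer than two usable trials
are excluded; per-participant metrics are the arithmetic mean of
per-trial metrics (pooling all samples was the alternative; mean-of-trials
keeps trials exchangeable).

Metrics per trial: COP path length Σ√(Δml² + Δap²) in cm, and the natural
log of the per-channel sample SD (log base is a documented knob; it
shifts both groups equally and leaves effect sizes unchanged).
Zero-variance channels make log-SD undefined and the trial unusable.

Group comparison reports per-metric group means, SDs and Cohen's *d*
computed as (control − affected) / √((sd_a² + sd_c²)/2). The denominator
is the *unweighted* RMS of the two group SDs, not the n-weighted pooled
SD; with unequal group sizes the two disagree, and the test suite
contains a discrimination test showing only the unweighted form
reproduces the published unequal-n COP-length effect size. Inference
stops at effect sizes (small/medium/large at 0.2/0.5/0.8); no p-values,
by design, given the sample sizes such studies have.

## Synthetic data

**Trios.** Genotypes are constructed to realize each requested
inheritance category's defining trio configuration; annotation fields are
drawn from a consequence mixture dominated by missense (~41%) and
frameshift (~18%) classes, negative-binomial depths (mean 60), normal GQ
clipped to [20, 99] (mean 85), and an allele-frequency distribution with
a 0.5 point mass at "absent" and the rest strictly below the rarity
threshold. Planted failures are single-fault: each failing variant
violates exactly one cascade stage, so stage-level diagnostics are
attributable. The truth table records every variant's family, planted
category, targeted failure stage and expected cascade outcome. Five
families with one carrier parent each (four mothers, one father) mirror
the study design; cohort sizes are desk-scale by construction.

**Sway.** Each axis of each trial is an exact-discretization stationary
Ornstein-Uhlenbeck process: mean-reverting rate θ (default 1/s), noise σ,
stationary SD σ/√(2θ), recorded as truth. Defaults give affected-group
stationary SDs of ~0.61 cm (ML) and ~0.73 cm (AP) versus ~0.47/0.66 cm
for controls — magnitudes consistent with quiet-standing sway in case
and control groups. Trials are written as force/moment CSVs by exactly
inverting the COP derivation under a constant 600 N load (or as COP CSVs
directly). Unusable trials are realized as truncated 10 s recordings.
Every output file derives from its own seeded generator, so files are
independently reproducible and the whole bundle is byte-identical under a
fixed seed.

What the generators do *not* model — and therefore what passing tests do
not show about real data: linkage and site-frequency structure,
genotyping error correlated with depth, mosaicism, X-chromosome dosage
(trio generator); between-participant variability, non-stationarity,
fatigue or balance-loss dynamics (sway generator). In particular,
synthetic group effect sizes are much larger than published ones because
all simulated participants of a group share identical sway parameters.

A note on estimating sway variability from the simulator: the mean of
per-trial sample SDs is *not* a consistent estimator of the OU stationary
SD (per-trial mean-centering over a 20 s window removes slow sway, a ~6%
downward bias at θ = 1/s, plus ~1% filter loss). The parameter-recovery
test therefore pools processed samples across trials around the grand
mean, which is consistent; ratio comparisons between groups are
bias-cancelling either way.

## Problem sizes

The test suite and reproduction script run at desk scale by choice:
simulated cohorts of 150–1,000 variants across five families (the
cascade-vs-brute-force equivalence check uses twenty seeded 1,000-variant
cohorts), 700-variant planted inheritance cohorts (100 per category), and
~50 sway trials per group for variability recovery. The published cohort
quantities that depend on the families' unreleased sequence data (total
variant and PDV counts, per-child averages) are structural properties
here, exercised by the planted-truth tests rather than as numeric
targets.

## Known limitations

- Inheritance is called from hard genotypes; no use of genotype
  likelihoods, so borderline parental calls route to "unknown" rather
  than being rescued probabilistically.
- Gene symbols are matched after case normalization only; no synonym or
  alias resolution.
- The enrichment universe is a modeling choice (distinct pre-cascade
  genes by default); results should be read as sensitive to it.
- No phasing, mosaicism detection or X-specific handling.
- Posturography is limited to SD- and path-length-based measures; no
  frequency-domain or entropy measures.
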