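# Methods

## Scope and design

`fhscreen` implements a biobank FH-screening analysis as composable stages
over plain files (delimited text, VCF v4.2, BED). Each stage is a library
module with a thin CLI subcommand; the `pipeline` module chains them and
records provenance (a hash of the scientific configuration, the seed, and the
included/excluded counts). Because the cohorts such analyses run on are
access-controlled, the `simulate` module is a first-class, tested component
that generates a cohort with the assumed statistical structure together with
its ground truth, so every downstream estimator can be checked for parameter
recovery rather than merely for not crashing.

## DLCN scoring

Only questionnaire-derivable items are scored: family history of
coronary/vascular disease in a first-degree relative (1 point), premature
coronary artery disease (2), premature cerebral or peripheral vascular
disease (1), plus the pre-treatment LDL-C band (1/3/5/8 points). Clinical-exam
items (tendon xanthomas, corneal arcus) and the genetic-test item of the full
DLCN are out of scope for biobank questionnaires, so the maximum score is 12.

Numerical choices:

* **Band edges.** Printed LDL-C bands of the form "4.0–4.9", "5.0–6.4" leave
  gaps (4.95 would fall nowhere). We use contiguous half-open intervals
  [4.0, 5.0), [5.0, 6.5), [6.5, 8.5), [8.5, ∞), which keep every printed edge
  at its printed points and leave no gaps.
* **Definite/probable boundary.** A score of exactly 8 is classified
  *probable* by default (definite strictly > 8); the `definite_at_8` switch
  moves the boundary down for the alternative reading of the criteria.
* **Premature events.** Interpreted as event age < 55 (men) / < 60 (women);
  in the synthetic cohort the premature flags are generated directly.
* **Missing LDL-C** excludes the participant (never imputed); exclusions are
  reported alongside class counts, which always partition the included set.
* **Correction factors** are a required two-column table (medication class →
  multiplier ≥ 1); unspecified medication defaults to 1.43 = 1/(1 − 0.30),
  i.e. an assumed 30% on-treatment reduction.

## Carrier analysis and penetrance

Variant keys are chrom/pos/ref/alt, 1-based, normalized to the minimal
left-aligned representation before matching; multi-allelic VCF records are
split per ALT. Missing genotypes shrink the allele-frequency denominator
(allele-number convention) rather than counting as reference. Estimated
clinical penetrance is `affected carriers / all carriers` for dominant genes
(*LDLR*, *APOB*, *PCSK9*; any zygosity) and `affected homozygotes / all
homozygotes` for recessive genes (*LDLRAP1*, *ABCG5*, *ABCG8*, *LIPA*), where
"affected" means DLCN class definite, probable, or possible. A variant with
no informative carriers returns an explicit undefined marker, distinct from
zero penetrance. Mutation-positive status (used to stratify the polygenic
analysis) requires ≥ 1 pathogenic/likely-pathogenic variant in the dominant
gene set.

## SV consensus

Reciprocal overlap of two same-type, same-chromosome intervals is
`min(|a∩b|/|a|, |a∩b|/|b|)` on 1-based inclusive coordinates (BED inputs are
converted on read). Per-individual consensus requires a pair of calls, one
per caller, with reciprocal overlap **strictly** greater than the threshold
(default 0.8); matching is greedy by descending overlap with each call used
at most once, ties broken by smaller start. The consensus interval averages
the two callers' breakpoints (rounded half up); multi-sample clustering
applies the same rule across samples with median breakpoints as the
representative. Size filtering (50 bp–10 Mb) is applied before merging;
breakend records are excluded with a logged count. Greedy matching can differ
from a globally optimal matching on adversarial interval geometries, but for
calls that arise as jittered observations of well-separated true events —
the regime the callers operate in — it attains the maximum matching
cardinality, which the test suite verifies against a brute-force oracle.
Gene disruption is any ≥ 1 base intersection with the gene span (whole-gene
coverage is flagged separately).

## LDL-C SNP score

The score is the raw weighted sum of effect-allele dosages over an 11-SNP
table (per-allele betas in mmol/L); no division by SNP or allele count, since
the group means the assessment operates on are on the raw-sum scale. Missing
genotypes are imputed as 2× the cohort effect-allele frequency and flagged
(strict drop available); a SNP absent from the VCF is skipped for everyone
with a logged notice. Strand-ambiguous (A/T, C/G) weight rows are rejected at
load. The bottom-quartile threshold is the type-7 (linear-interpolation)
25th percentile of the unlikely-FH score distribution; the polygenic call is
`score > threshold` among mutation-negative definite-or-probable
participants. Group comparison uses classical one-way ANOVA.

## Statistics layer

* Prevalence: k/n with a rounded one-in-N reciprocal (undefined at k = 0).
* Odds ratio: (a·d)/(b·c) with the Woolf log-scale interval
  `exp(ln OR ± z₁₋α/₂ √(1/a+1/b+1/c+1/d))`; tables with an empty cell get
  the Haldane–Anscombe +0.5 on all cells and are flagged. The Woolf interval
  was chosen because it reproduces the published carriage interval from the
  reconstructed counts; its null coverage is verified by simulation
  (94–96% over 2,000 OR = 1 tables at n = 500/arm).
* Chi-square: Pearson without continuity correction by default (Yates by
  flag), undefined on a zero margin.
* Report percentages are rounded half away from zero to integers for parity
  with published tables; raw proportions are always retained.

## The synthetic cohort

Defaults are the study conditions the analysis assumes: n = 6,140 adults aged
18–88 (right-skewed, median ≈ 38), 56.9% female, 13.4% on lipid-lowering
therapy with a true 30% LDL-C reduction masking their observed values, and
2% symmetric misreport noise on questionnaire fields.

* **LDL-C.** True pre-treatment LDL-C is log-normal, log-mean ln(2.9) and
  log-SD 0.35, with small age (+0.004/yr on the log scale) and sex (−0.04 for
  women) shifts, plus the centered SNP-score deviation and any penetrant
  rare-variant effect; floored at 0.3 mmol/L. The log-SD was calibrated once
  so the observed ≥ 4.9 mmol/L tail is a few percent of the cohort and the
  age-banded counts of LDL ≥ 4 are non-trivial; the source cohort's LDL
  distribution is only known through band counts, so these are calibration
  choices, not estimates.
* **Rare variants** are planted in Hardy–Weinberg proportions at their stated
  allele frequencies; a carrier (dominant) or homozygote (recessive)
  expresses with the variant's penetrance, adding its LDL effect
  (3–3.5 mmol/L by default) and enriching family-history fields. Defaults
  emulate the observed spectrum: high-penetrance *LDLR* alleles, one
  zero-penetrance allele, one recessive *ABCG8* allele.
* **SNP score.** Eleven LDL-raising SNPs (rsIDs from the 12-SNP score
  literature minus the *HFE* SNP, which the analysis drops) with illustrative
  frequencies/betas giving Σ2fβ ≈ 0.756 and score SD ≈ 0.183, so the
  unlikely-FH distribution sits near 0.76 ± 0.18. The published GWAS weights
  are not reproduced here; all tests use the synthetic table.
* **Treatment assignment** is propensity-weighted by true LDL-C
  (exp(0.8·(LDL−3.5)₊)), normalized to the target treated fraction, so
  treatment correlates with severity as in real cohorts.
* **SV call sets.** ~5% of samples carry 1–3 true events (300 bp–30 kb);
  each "caller" observes them with ≤ 0.5% breakpoint jitter and its own
  miss rate (5%/10%), plus private false positives and a few deliberately
  out-of-size calls. Sample 1 always carries the 1.03 Mb whole-*PCSK9*
  duplication in both call sets.
* **Determinism.** One master seed spawns named per-component substreams
  (ages, sex, LDL, PRS, planted variants, penetrance, treatment, history,
  noise, SV), so identical parameters and seed give bit-identical files and
  adding a component does not perturb the others.

What the generator does **not** emulate: sequencing/genotyping error,
relatedness and consanguinity (which inflate homozygote counts in the real
population), ancestry structure, assay noise on LDL-C, and realistic
questionnaire error structure — the symmetric 2% flip dominates counts of
rare events such as premature CAD, where real misreport is asymmetric.
Passing recovery tests therefore show the estimators are correct under the
stated model, not that the model captures every feature of real biobank data.

## Parameter-recovery calibration

The penetrance recovery test needs the probability *s* that a penetrant
carrier is classified possible-or-worse. *s* is estimated by an independent
Monte Carlo (`penetrant_case_probability`): fresh draws from the generative
model, pushed through treatment masking, correction, and DLCN scoring — never
the realized carriers — so the check that the estimator's numerator falls in
the central 99% interval of Bin(k, π·s) is non-circular. Analogously, the
cohort mean SNP score is checked against its Hardy–Weinberg expectation
Σ2fβ, and group-mean ordering is checked on groups drawn at the published
sizes (49/334/5,757) and spreads.

## Problem sizes

Tests run the generator at n = 400–20,000 (20,000 only for the
Hardy–Weinberg check), the coverage simulation at 2,000 replicates, and the
ANOVA power check at 200 replicates of the full group sizes; the analysis
scripts default to the full n = 6,140 cohort. These sizes were chosen so the
statistical checks have the stated resolution while the whole suite runs in
well under a minute.

## Known limitations

* The definite/probable boundary and the premature-age convention are
  configurable because the source criteria admit two readings; defaults are
  documented above.
* Greedy SV matching is not globally optimal on adversarial geometries (see
  above); with a strict 0.8 threshold the discrepancy requires near-threshold
  call triplets that jittered observations of separated events do not
  produce.
* Penetrance estimates from a handful of carriers are reported as fractions
  with explicit numerator/denominator; no interval is attached, mirroring
  standard practice for case-series penetrance.
* The OR for "possible vs unlikely" carriage in small cohorts frequently has
  zero cells; the Haldane correction is flagged in the output rather than
  silently applied.
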