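# Methods

`aneuvar` re-implements, as a tested pipeline, the variant-level analyses
used in family/cohort exome studies of unruptured intracranial aneurysm
(UIA) and aneurysmal subarachnoid hemorrhage (aSAH): a reported-risk-gene
screen over allele-frequency tiers, a four-stage family-based candidate
filter, an ACMG/AMP evidence/classification engine, categorical
cosegregation assessment, carrier-based association tests, and PHASES
rupture-risk scoring.  This note records the models, the tunable
parameters, the numerical choices, and what the packaged fixtures and
synthetic cohorts do and do not establish.

## Data model

A variant is identified by (gene symbol, RefSeq transcript, HGVS c.
description); genomic coordinates (1-based, closed, forward strand) are
optional pass-through.  This choice makes published variant tables — which
carry HGVS but not coordinates — sufficient to reconstruct a cohort.
Nucleotide numbering uses +1 as the A of the ATG initiation codon.

Population frequencies follow the gnomAD reporting convention: an
`allele_count` (AC, alternate alleles observed), a homozygote count
(nhomalt) and `total_alleles` (AN), with MAF = AC/AN.  The parser enforces
2·nhomalt ≤ AC ≤ AN and MAF–count consistency to a relative 1e-3
(published tables round frequencies to about four significant figures, so
an absolute machine-precision check would reject correctly transcribed
rows).  Missing scores and frequencies are stored as absent, never as 0 —
an absent control frequency and a frequency of zero are deliberately
distinguishable, because the screen treats both as "unknown (MAF = 0)"
*for filtering* while the annotation layer preserves which one was
observed.

Genotypes live in a samples × variants matrix over {ref, het, hom}.
Missing genotypes (`./.`) count as non-carrier but are tallied and logged,
so carrier-based denominators remain defined and silent data loss is
impossible.  Multi-allelic VCF records are rejected rather than guessed
at; they must be split upstream.

## Frequency tiers and the risk-gene screen

MAF tiers partition [0, 1] with boundaries in the lower tier: unknown
{0}, very rare (0, 0.001], rare (0.001, 0.01], low-frequency (0.01,
0.05], common (0.05, 1].  The screen retains a variant when (i) its gene
is in the configured panel (default: the eight reported risk genes
ADAMTS15, ANGPTL6, ARHGEF17, LOXL2, PCNT, RNF213, THSD1, TMEM132B),
(ii) its MAF in the screening source (default `gnomad_all`, configurable)
is ≤ the cutoff (default 0.05), where a variant with no record in the
source counts as MAF = 0 and is retained with a warning, and (iii) at
least one cohort sample carries it.  Recurrence (≥ 2 carriers) and
concomitance (≥ 2 retained variants in one sample) are derived views.
Haplotype phase (cis/trans) of concomitant variants is only ever copied
from an input annotation; the pipeline has no phasing logic.

## Family-based candidate filter

For one family, four sequential predicates:

1. **Sharing** — carried (het or hom; a dominant model with possible
   homozygous carriage) by every affected, genotyped member.  Individuals
   with only *probable* affection are excluded from the mandatory-sharing
   set by default (configurable), since their phenotype rests on weaker
   documentation.
2. **Novelty** — MAF strictly 0 (no record, or an explicit zero) in every
   named control source (default: gnomAD plus a combined population-based
   control set, labels `gnomad_all` / `popgen_ikmb`).  An epsilon
   parameter can relax strict zero; default 0.
3. **Consequence** — synonymous, missense, nonsense, frameshift indel, or
   intronic change within ±2 of an exon–intron junction.
4. **Prediction** — missense: ≥ 2 of the four pathogenicity scores (CADD
   ≥ 20, REVEL ≥ 0.5, M-CAP ≥ 0.025, ClinPred ≥ 0.5, all inclusive,
   counted over *available* scores) at threshold; nonsense/frameshift:
   CADD at or above its threshold; synonymous: splicing impact called by
   > 1 of the four splice predictors (HSF, NetGene2, MaxEntScan, BDGP).
   Near-boundary intronic variants are not addressed by the published
   wording; they use the synonymous rule, because splicing is their only
   plausible mechanism, and the trace labels them
   `intronic-as-synonymous`.

Every input variant receives a trace record: retained, or removed at
exactly one stage (the first failed predicate in pipeline order).  The
stages after sharing are independent predicates, so the retained set is
invariant to their order — a property the tests exercise.

## ACMG/AMP engine

Evidence assignment and rule combination are deliberately separable: the
combiner can run directly on published evidence strings (`"PM1+PP3"`),
decoupling classification tallies from assignment ambiguities.

Assignment rules (all configurable through `CriteriaConfig`):

* **PM2** — MAF ≤ `pm2_maf_threshold` (or no record) in the designated
  control source.  Default 1.05e-4: the study's tables assign PM2 at
  gnomAD MAF 1.048e-4 but not at 1.097e-4, so the default sits at the
  midpoint of the separating interval.  One table row (ADAMTS15
  c.1258G>A, MAF 6.09e-5, printed without PM2) is inconsistent with any
  threshold and is a documented exception.
* **PP3** — strict majority of available predictor scores at threshold,
  or splice impact called by > 1 predictor.
* **BP4** — strict majority of available scores below threshold *and* at
  most one splice-impact call.  Three published rows (two with BP4
  despite three splice-impact calls, one with a 2-of-4 tie) are not
  reproduced by these rules; the fixture test for the assigner excludes
  exactly those rows, while the classification tallies (which use the
  printed strings) are unaffected.
* **PM1** — variant carries a domain tag listed in the gene's hotspot
  configuration (e.g. the EGF-like domain of EDIL3).
* **BP1 / PP2** — gene-level missense policies (e.g. BP1 for pericentrin,
  where truncating variants are the known disease mechanism; PP2 for
  RNF213, a missense-constrained gene); a gene can carry only one.
* **BS4** — only from an explicitly supplied "refuted" cosegregation
  result; the engine never scans pedigrees itself.

Combination implements the published rule table (pathogenic, likely
pathogenic, benign, likely benign); any co-occurrence of pathogenic-side
and benign-side evidence, and any mixture meeting no rule, yields VUS.
Codes without assignment rules (PVS1, PS1–4, PM3–6, PP1/4/5, BA1, BS1–3,
BP2/3/5–7) still parse and combine correctly.

## Cosegregation

Categorical verdicts only (no LOD or Bayesian quantification, matching
the study design): *refuted* if any genotyped affected relative lacks the
variant; *supported* if at least one additional affected relative carries
it and none lacks it; *uninformative* otherwise.  Unaffected carriers
never refute (incomplete penetrance is expected for aneurysm risk
alleles) but are counted and reported.  Probable-affected relatives can
refute only when a flag is set (default off).  Hom and het carriage are
equivalent.

## Association tests

* **Fisher's exact test** on a 2×2 carrier table uses the two-sided
  minimum-likelihood convention: the sum of hypergeometric point
  probabilities ≤ that of the observed table (relative tolerance 1e-7 on
  the comparison).  The implementation delegates to
  `scipy.stats.fisher_exact`, which implements this convention; the test
  suite checks it against an exact-rational enumeration oracle on random
  tables up to N = 200.  The headline comparison — cohort carriers of
  qualifying (MAF ≤ 0.001) candidate-gene missense variants vs reference
  individuals — is reconstructed at carrier level as
  [[3, 70], [326, 64277]]; an allele-level construction is possible and
  exposed to the caller, but carrier-level is the default.
* **Cumulative carrier frequency** is qualifying-variant carriers divided
  by individuals (0.0411 = 3/73 cohort; 0.00505 = 326/64,603 reference).
* **Burden test** — statistic is the squared score of the weighted
  per-sample dosage sum against intercept-only phenotype residuals;
  **SKAT-style test** — Q = rᵀGW²Gᵀr with r the centered phenotype, G the
  dosage matrix, W diagonal weights.  With one variant and unit weight
  the two statistics coincide exactly, which the tests verify to 1e-10.
  Default weights are flat 1.0; Beta(MAF; 1, 25) weights are available.
  p-values come from phenotype-label permutation with the add-one
  estimator p = (1 + #{perm ≥ obs}) / (1 + B), hence strictly positive
  and seed-deterministic; default B = 99,999.  For the SKAT statistic a
  moment-matched p (scaled χ² matching the permutation mean and
  variance, Satterthwaite-style) is reported alongside.  The p-values an
  external association package printed for the original cohort are not
  reproducible without its internals and covariate handling; instead the
  test suite verifies the statistic identity, seed determinism, and
  type-I error calibration — over 500 null cohorts (73 cases / 100
  controls, six variants with MAF drawn from 0.01–0.05, genotypes
  independent of phenotype, 999 permutations each) the empirical
  rejection rate at α = 0.05 must fall inside the binomial 99%
  confidence band 0.025–0.075.  These sizes keep the calibration suite
  around a few seconds while giving the band useful power.

## PHASES scoring

The additive point table (population 0/3/5; hypertension 0/1; age ≥ 70
0/1; size < 7 mm 0, 7–9.9 mm 3, 10–19.9 mm 6, ≥ 20 mm 10; earlier SAH
from another aneurysm 0/1; site ICA 0, MCA 2, ACA/Pcom/posterior 4) ships
as a data file (`data/phases_points.json`) verified against the published
score.  Size bins are half-open, closed on the left.  The attainable
range over the component grid is [0, 22]; the per-patient score is the
maximum over that patient's aneurysms.  The source cohort's per-aneurysm
inputs are not published, so cohort-level reproduction of the reported
mean is out of scope; the scoring path is exercised on synthetic tables.

## Synthetic data and fixtures

`generate_cohort` builds case/control cohorts in which planted carrier
configurations are realized *exactly* (seeded sampling without
replacement inside the target group, avoiding positional bias), decoy
variants each violate exactly one named filtering rule, and filler
variants draw control MAFs from a log-uniform spectrum over [1e-5, 0.5]
(spanning every frequency tier) with genotypes binomial in that
frequency.  Identical configurations serialize byte-identically.

Two packaged fixtures reconstruct the study's printed variant tables: the
screen fixture (every published variant–carrier assignment, 38-sample
cohort, all panel carriage heterozygous, plus 16 decoys violating the
panel/frequency/carrier rules one at a time) and the family fixture
(three affected siblings sharing the five published candidates, all
absent from every control source, plus 12 decoys removed one stage each).
Sample identifiers reuse the published labels so reports are
cross-checkable.  The published tables give each patient's qualifying
variants but not the rest of their exome; fixture genotypes therefore
contain only the listed assignments plus decoy carriage — which is
exactly the information the screen and filter consume.

What passing on these inputs shows: the *logic* of every stage matches
the published tallies and filters.  What it does not show: robustness to
upstream caller artifacts, multi-allelic splitting, annotation
disagreement between transcript sets, population stratification, or
relatedness beyond declared pedigrees — all out of scope by design.

## Numerical and degenerate-input choices

* Threshold comparisons are inclusive (≥) everywhere, matching the
  published "CADD (≥ 20)" notation.
* A family with a single affected genotyped member degenerates to that
  member's carried set in the sharing stage (logged, not an error); zero
  affected genotyped members is an error.
* All-zero genotype matrices give statistic 0 and permutation p = 1.
* Odds ratios on zero cells are reported as ∞ with a Haldane-corrected
  (add 0.5 to each cell) companion value.
* Report serialization sorts rows by (gene, transcript, HGVS c.) and JSON
  keys lexicographically; re-serializing unchanged inputs is
  byte-identical.  All pipeline randomness derives from one top-level
  seed expanded per stage.

## Known limitations

No variant normalization or HGVS validation against transcript
sequences; no compound-heterozygous or de novo inheritance models; no
kinship inference; no covariate-adjusted association null; no exact
mixture-of-χ² inversion for the SKAT p-value (permutation and moment
matching stand in); connective-tissue exclusion panels are supported
generically through the panel mechanism but no curated panel content is
shipped.
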