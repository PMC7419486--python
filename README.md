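# aneuvar

Rare-variant prioritization and association testing for exome studies of
unruptured intracranial aneurysm (UIA) and aneurysmal subarachnoid
hemorrhage (aSAH).

Genetic risk for UIA/aSAH is spread over candidate genes reported by
family-based exome studies (*ADAMTS15*, *ANGPTL6*, *ARHGEF17*, *LOXL2*,
*PCNT*, *RNF213*, *THSD1*, *TMEM132B*).  Validating those reports in a new
cohort, and nominating new genes from multiplex families, needs the same
few analyses done carefully: a panel screen over minor-allele-frequency
(MAF) tiers, a multi-rule filter over variants shared by affected
relatives, ACMG/AMP evidence combination, cosegregation checks, and
carrier-based association tests.  `aneuvar` implements that pipeline as a
reusable, seeded, fully tested library with a thin CLI, for genetic
epidemiologists and clinical-genetics analysts working from VCF/PED files
and annotation tables.

## What it computes

* **MAF tiers and risk-gene screen** — unknown (MAF = 0), very rare
  (≤ 0.1%), rare (0.1–1%), low-frequency (1–5%); retain panel-gene
  variants with MAF ≤ 5% carried by ≥ 1 patient; per-gene tallies,
  recurrent variants, concomitant carriers.
* **Family filter** — keep variants (i) shared by all affected members,
  (ii) absent from every control source, (iii) of a qualifying
  consequence class, (iv) supported in silico: missense need ≥ 2 of
  {CADD ≥ 20, REVEL ≥ 0.5, M-CAP ≥ 0.025, ClinPred ≥ 0.5}; truncating
  need CADD ≥ 20; synonymous need > 1 splice predictor calling impact.
* **ACMG/AMP engine** — configurable assignment of PM1/PM2/PP3/BP4,
  gene-policy BP1/PP2 and segregation-driven BS4, plus the full published
  combining table into pathogenic / likely pathogenic / VUS / likely
  benign / benign.
* **Cosegregation** — categorical supported / refuted / uninformative
  verdicts under a dominant model with incomplete penetrance.
* **Association** — two-sided Fisher's exact test on carrier tables,
  cumulative carrier frequencies, and permutation burden / SKAT-style
  tests (statistic Q = rᵀGW²Gᵀr) with the add-one p estimator.
* **PHASES** — additive rupture-risk score per aneurysm, per-patient
  maximum, and cohort summarization.

Synthetic cohorts with exactly realized carrier configurations, plus
packaged fixtures reconstructed from the published variant tables, make
every stage testable offline.  See `docs/methods.md` for models,
parameters and limitations.

## Worked example

```bash
$ python analysis/02_risk_gene_screen.py
retained 20 variants in 6 of 8 panel genes; 18 distinct carriers
  ADAMTS15: 1 variants / 1 patients
  ANGPTL6: 2 variants / 3 patients
  PCNT: 9 variants / 9 patients
  RNF213: 4 variants / 3 patients
  THSD1: 3 variants / 6 patients
  TMEM132B: 1 variants / 1 patients
recurrent (>=2 carriers): THSD1 c.871C>T x4, ANGPTL6 c.287A>G x2, PCNT c.4354G>A x2, PCNT c.7652C>T x2
concomitant carriers: IA17 (2, unknown), IA54 (2, unknown), IA61 (2, unknown), IA63 (2, trans), IA78 (3, unknown), IA79 (2, unknown), IA85 (2, unknown)
```

Of the 38-exome cohort, 20 heterozygous missense variants pass the 5%
screen, concentrated in 6 genes; the most recurrent variant (*THSD1*
c.871C>T) is carried by 4 patients, and 7 patients carry two or more
qualifying variants (for IA63 the two *PCNT* variants are annotated in
trans).  The family filter and association steps continue the analysis:

```bash
$ python analysis/04_family_prioritization.py
candidates (5): NEK4 c.190A>T, EDIL3 c.383G>A, EDNRB c.891T>G, DNAH9 c.13304T>C, GGA3 c.16G>A
...
$ python analysis/05_association_tests.py --seed 1
cumulative carrier frequency: cohort 0.0411, reference 0.00505
Fisher's exact (two-sided): p = 0.00624, Haldane OR = 9.8
```

Three of 73 index cases carry an unknown/very-rare *EDIL3* missense
variant versus a cumulative 326/64,603 qualifying carriers in the
reference population — a significant enrichment (p = 0.00624).

The same stages are available as a CLI (`aneuvar screen`,
`aneuvar family-filter`, `aneuvar classify`, `aneuvar segregate`,
`aneuvar associate`, `aneuvar phases`, `aneuvar summarize`,
`aneuvar simulate`, `aneuvar run`) and as one orchestrated run:

```bash
aneuvar run --seed 1 --out-dir run1   # consolidated report.json + TSVs
```

## Repository layout

```
src/aneuvar/      library: types, io, screen, family, acmg, segregation,
                  association, clinical, simulate, pipeline, cli
src/aneuvar/data/ packaged fixture tables and the PHASES point table
analysis/         numbered drivers reproducing each analysis, writing
                  tables under results/
tests/            unit, property and acceptance suites
```

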