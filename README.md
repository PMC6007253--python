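# netdlnc

A Python library for studying long non-coding RNA (lncRNA) dynamics during
**neuroendocrine transdifferentiation (NEtD)** of prostate cancer — the
adaptive transition of adenocarcinoma (AD) to neuroendocrine prostate
cancer (NEPC) under androgen deprivation therapy (ADT). It is written for
computational biologists who want a tested, reusable implementation of the
full analysis arc connecting a patient-derived-xenograft (PDX) castration
time series to clinical cohorts:

1. **Read QC** — Sickle-style windowed-adaptive quality trimming of paired
   FASTQ libraries (Q20 threshold, two-thirds retained-length rule,
   removal of highly repetitive sequences above 2% of the library).
2. **Catalogue** — lncRNA catalogue construction from Ensembl-style GTF:
   the antisense, lincRNA and pseudogene subclasses are kept,
   immunoglobulin/T-cell-receptor pseudogenes removed, expression values
   below 0.1 floored to zero, and transcript keys unified across cohorts
   as (Ensembl id, length) pairs.
3. **Differential expression** — two-sample Student's *t* with the
   field-standard gate (fold change ≥ 2 in either direction **and**
   *P* < 0.05), five clinical contrasts (NEPC vs AD, NEPC vs NHT, CRPC vs
   AD, NHT vs naive, and their combination), BH/Bonferroni adjustment
   reported alongside.
4. **Temporal classification** — every transcript in the three-stage PDX
   series (AD → postTX → NEPC) is assigned one of four classes from its
   step ratios *r₁* = postTX/AD and *r₂* = NEPC/postTX:
   **I Deactivated** (monotone decline), **II Activated** (single-step
   rise), **III Persistent** (rise at both steps), **IV Transient**
   (maximum at postTX), else Unclassified. Classes are then intersected
   with the clinical gates to yield the per-class NEtD lncRNA sets.
5. **Signature** — cross-cohort NEPC signature: top fifth percentile of
   transcripts by SD of log2 expression per cohort, intersection,
   unsupervised hierarchical re-clustering (1 − Pearson, average linkage),
   k = 2 cut purity against the NEPC/AD phenotype, and ranking with a
   concordant ≥ 10-fold flag.
6. **TFBS enrichment** — exact IUPAC consensus scanning of promoter
   sequences (both strands, overlaps counted) and motif
   over-representation with the continuity-corrected z-score
   **z = (x − E − 0.5)/S**, |z| > 2 significant (two-sided normal
   *P* ≈ 0.05); class-unique and common-to-all motif logic.
7. **Clinical outcomes** — class-specific candidate ranking by clinical
   fold change, microarray probe liftover by strict exon containment,
   rapid-metastasis (< 36 months post-ADT) ROC/AUC via the Mann-Whitney
   rank statistic, Kaplan-Meier median-split stratification with the
   two-group log-rank test, and ΔΔCt qPCR arithmetic
   (fold change = 2^(−ΔΔCt)).
8. **Synthetic data** — deterministic generators for every input above
   with planted, recoverable structure and truth tables, so the whole
   pipeline is validated end to end by parameter recovery.

## Worked example

Classify the PDX time series and recover the planted temporal classes
(`examples/03_temporal_classes.py`):

```
assigned class counts:
class_label
Unclassified      520
I_Deactivated      20
II_Activated       20
III_Persistent     20
IV_Transient       20

planted-class recovery: 100.0% of 80 planted transcripts
```

With the default conditions (fourfold step dynamics, 0.25 log2-unit
multiplicative noise, duplicate terminal stages and single postTX
samples), all 80 planted transcripts land in their planted class and the
remaining 520 transcripts — nulls plus the signature/outcome roles, which
are flat across the PDX stages — stay Unclassified.

Stratify the ADT outcome cohort (`examples/07_outcome.py`):

```
   treated arm: rapid-met AUC = 0.986 (n=76), median-split log-rank p = 0.0000
 untreated arm: rapid-met AUC = 0.577 (n=73), median-split log-rank p = 0.7111
```

The planted transcript predicts rapid metastasis only in the arm where
the hazard was attached (ADT-treated); the untreated arm behaves as a
null control.

Each script in `examples/` exercises one capability the same way:
generate a small input, run the method, print what it computes.

The one shell entry point is the read trimmer:

```bash
netdlnc-trim R1.fastq R2.fastq out_R1.fastq out_R2.fastq --q 20
```

## Layout

```
src/netdlnc/        library modules (catalogue, read_qc, diffexp,
                    temporal, signature, tfbs, clinical, synthetic_data)
examples/           one narrative script per capability
tests/              pytest suite incl. oracle-based validation
scripts/acceptance.py   headline-quantity reproduction
docs/methods.md     models, assumptions, parameter choices, limitations
```
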