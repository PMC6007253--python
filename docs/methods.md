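# Methods

This note documents the models and procedures implemented in `netdlnc`,
the assumptions behind them, the parameters that matter, and what the
synthetic-data validation does and does not establish.

## Pipeline model

The package models an integrative lncRNA study design: a
patient-derived-xenograft (PDX) castration time series provides the
*temporal* axis of neuroendocrine transdifferentiation (NEtD), clinical
cohorts provide the *population* axis, and candidates must survive both.
The stages and their governing rules are:

### Read QC (`read_qc`)

Windowed-adaptive trimming. A window of size
`max(1, round(window_frac · L))` (default `window_frac = 0.1`) slides over
each read; the retained interval runs from the first window whose mean
Phred quality reaches the threshold (default Q20, i.e. 99% base-call
accuracy, `Q = −10·log10(1 − accuracy)`) to the end of the last such
window. Reads whose retained length falls below two-thirds of the
original (fractional rule; an absolute override is provided because some
cohorts are better served by a fixed cutoff, e.g. 30 nt on 50-nt
libraries vs 60 nt on 100-nt libraries) are discarded, and a pair is
dropped whenever either mate fails so that mate files stay synchronized.
Note the windowed-mean rule resolves cut points only to window
resolution: up to one window's worth of low-quality bases can survive at
a retained edge. After trimming, any exact sequence exceeding 2% of the
library is treated as highly repetitive and removed entirely; exact
string identity is the simplest reproducible operationalization of
"highly repetitive" and is applied per mate file with pair
synchronization. Phred+33 encoding is fixed on I/O; adapter trimming is
out of scope.

### Catalogue (`catalogue`)

Ensembl biotypes are aggregated into subclass groups; the catalogue keeps
antisense, lincRNA and pseudogene transcripts (the three subclasses that
carry the NEPC/AD separation signal), with the pseudogene group pooling
the eight Ensembl pseudogene biotypes and excluding immunoglobulin and
T-cell-receptor pseudogenes by biotype prefix (`IG_`, `TR_`) — the exact
biotype strings behind that removal are not enumerable from the study
design, so a prefix filter is the declared rule. Expression values
strictly below 0.1 (a known quantification artifact level of the
upstream estimator) are floored to zero; the boundary is strict, so 0.1
itself survives. Cross-cohort transcript identity is the pair
(Ensembl transcript id, assembled length): the same id assembled at two
lengths is deliberately kept as two keys. Uncharacterized clone-style
identifiers (RP##-…, AC######.# and similar) are removed by configurable
regular expressions; the default pattern set covers the RP/AC/AL/AP/CT
prefixes because the convention is open-ended. Genomic coordinates are
0-based half-open throughout, matching BED and making probe-containment
tests direct.

### Differential expression (`diffexp`)

Classical two-sample equal-variance Student's *t* (df = n₁ + n₂ − 2);
equal-variance rather than Welch is the declared test of the pipeline.
Fold changes are linear ratios on normalized expression with a
pseudocount (default 0.1, the flooring constant) guarding zero means.
The gate is `fold_change ≥ 2 or ≤ 0.5` **and** raw `p < 0.05`. Gating on
raw p mirrors a filter-down design in which false discovery is
controlled biologically — by requiring candidates to survive a cascade of
independent contrasts and the model–clinic intersection — rather than by
mathematical FDR correction; Benjamini-Hochberg and Bonferroni adjusted
values are nonetheless always computed and reported. The combined
contrast (NHT vs naive **in combination with** NEPC vs NHT) is the
intersection of its two constituent gates, consistent with it producing
a far smaller list than either constituent. Degenerate inputs: zero
pooled variance with equal means yields (t = 0, p = 1); groups smaller
than two are an error.

### Temporal classification (`temporal`)

Stage summaries are arithmetic means on linear expression: AD and NEPC
replicates average within stage, and the 8- and 12-week post-castration
samples pool into a single postTX stage. Class assignment uses two step
ratios with pseudocount 0.1 and a symmetric fold threshold
(`step_fold = 2`, matching the ubiquitous 2-fold gate; the threshold is a
parameter because the temporal rule itself does not pin it):

| pattern (step1, step2)        | class |
|-------------------------------|-------|
| up, up                        | III Persistent |
| up, down                      | IV Transient |
| up, flat / flat, up           | II Activated |
| down, down / down, flat / flat, down, with net AD→NEPC decline ≥ step_fold | I Deactivated |
| anything else (incl. down, up) | Unclassified |

III is checked before the single-step patterns so (up, up) can never be
read as Activated; the net-decline requirement on Class I prevents
borderline (down, flat) drifts from qualifying; a minimum at postTX has
no class and stays Unclassified. Labels are invariant under global
rescaling of a profile (at pseudocount 0) and partition the transcript
set.

Model-to-clinic integration retains a class member when it passes the
gate of at least one comparison wired to its class: Class I with a
down-gate in NEPC vs AD, CRPC vs AD or NHT vs naive; Class II with an
up-gate in NEPC vs AD or NEPC vs NHT; Class III with an up-gate in NEPC
vs AD; Class IV with the combined contrast. The wiring is configurable
because variant designs differ here.

### Signature (`signature`)

Transcripts are ranked by row SD of `log2(x + 0.1)` — the log2 scale is
used for both the SD ranking and the pre-clustering scaling so one
transform governs both steps — and the top `ceil(0.05·n)` taken per
cohort (sample SD with n−1; percentile-boundary ties broken by key order
for determinism). After removing uncharacterized ids, the per-cohort
lists are intersected and each cohort is re-clustered on the
intersection: rows are z-scored and clipped to [−2, 2] (constant rows
map to zero), samples are clustered with 1 − Pearson distance and
average linkage (Euclidean/Ward is provided for microarray cohorts), and
the dendrogram is cut at k = 2. "Distinct segregation" of NEPC from AD —
a visual judgement in practice — is operationalized as the purity of
that cut against the binary NEPC/AD phenotype. Signature members are
ranked by NEPC-vs-AD fold change per cohort; the high-confidence flag
requires concordant direction and at least 10-fold magnitude in both
cohorts. The intersection operates on the transcript keys supplied;
with gene-level keys it reproduces a gene-name-level intersection.

### TFBS enrichment (`tfbs`)

Motifs are IUPAC consensus strings matched exactly: every position is
tested, overlapping matches count, and with both-strands scanning the
reverse-complement pattern is scanned over the same forward sequence (a
palindromic motif therefore counts twice per site — exhaustive-scan
semantics, chosen for determinism). This consensus matcher is a
deliberate simplification relative to weighted-matrix scanners with
similarity thresholds; consensus matching is exact and reproducible but
blind to weak/partial matrix matches, so absolute z-scores are not
comparable with matrix-based engines. Over-representation uses the
continuity-corrected z = (x − E − 0.5)/S with |z| > 2 significant
(two-sided normal P ≈ 0.0455). The background is binomial per position
(E = n·p, S = √(n·p·(1−p))) with p either supplied per motif or derived
from the motif's degeneracy under a uniform base composition; externally
supplied (E, S) pairs are used verbatim, since promoter-background and
genome-background expectations are legitimate alternatives that only the
data provider can choose. S = 0 motifs are unscorable and skipped. A
motif significant in exactly one class is class-unique; significant in
every class, common. The per-class presence-distribution table reports,
for each motif, the fraction of its presences falling in each class
(rows sum to 1).

### Clinical outcomes (`clinical`)

Candidate ranking per class: Class I by the **minimum** fold change over
its three down contrasts (the strongest decline), Classes II/III by the
NEPC-vs-AD fold change maximized across cohorts, Class IV by the larger
fold-change magnitude of its two transient contrasts — in all cases the
strongest deregulation ranks first (a literal "increasing order" reading
for the up-classes would favor the least-changed transcript, so
descending magnitude is used and documented here). The top 20 per class
plus a signature group (top 10 up + top 10 down) give 5 × 20 = 100
selections, with a de-duplicated union reported separately. The
"NHT vs AD" contrast in the Class I rule is read as NHT vs naive, the
only NHT-versus-untreated contrast defined; the mapping is configurable.

Probe liftover: a probe-set region maps to a transcript iff its
[start, end) interval is fully contained in one exon; straddling or
intergenic probes are excluded, and a transcript's array-side expression
is the mean of its mapped probes. ROC AUC is the Mann-Whitney
probability with midrank tie handling, identical to the threshold-sweep
trapezoid on tie-free data. Rapid-metastasis labels: positive =
ADT-treated with a metastasis event before 36 months; negative =
ADT-treated, metastasis-free, with at least 120 months of follow-up;
everyone else excluded. Kaplan-Meier stratification splits one treatment
arm at the median expression (ties to the low group — a convention this
package fixes, as either choice is defensible) and compares the two
product-limit curves with the standard two-group log-rank chi-square
(1 df, unstratified). ΔΔCt: triplicate Ct values are averaged, ΔCt taken
against the housekeeper, ΔΔCt against the reference sample, fold change
= 2^(−ΔΔCt).

## Synthetic data: what it emulates

`synthetic_data` reproduces the study design as its defaults: a
six-sample PDX series (duplicate AD and NEPC terminals, single 8- and
12-week postTX samples — forcing the classifier to cope with n = 1
stages), a four-group discovery cohort (56 AD-naive / 14 NHT / 5 CRPC /
5 NEPC), a two-group second cohort (30 AD / 7 NEPC), and a 200-patient
ADT outcome cohort with 10–20-year administrative follow-up and ~60%
censoring.

Expression noise is multiplicative log2-normal around class-pattern
means (`value = mean · 2^N(0, σ)`, default σ = 0.25): positive,
right-skewed values like FPKM, with exactly Gaussian log2 fold changes.
Planted temporal classes step by `class_effect_fold = 4` per stage;
planted clinical echoes use fold 4 (comfortably above the 2-fold gate);
planted signature transcripts separate NEPC from AD by
`signature_fold = 64` in both cohorts, the tens-of-fold tier of the
strongest NEPC markers, which makes them the top-variance stratum by a
wide margin — the percentile-intersection derivation presumes signature
members dominate the variance ranking, and the default transcript count
(600) makes the fifth percentile exactly hold the 30-member signature.
Event times are exponential with log-hazard linear in the latent risk
factor expressed by the planted predictive transcripts, attached only in
the treated arm; the baseline rate is solved (by bisection on the
closed-form censoring probability under uniform administrative
censoring) to hit the configured censoring fraction, and because
administrative censoring starts at 120 months every censored patient
automatically satisfies the 10-year clean-follow-up rule for the
negative outcome group. Truth tables accompany every output; planted
and null sets partition the transcript list, and a fixed configuration
reproduces byte-identical outputs.

What the generator does **not** emulate: transcript-length and
library-depth biases, correlated co-expression structure, batch effects,
mixed histology or contaminating stroma, isoform-level redundancy, and
overdispersed count noise. Parameter-recovery results therefore
demonstrate the correctness and calibration of the procedures under
their own assumptions, not their power on real cohorts; in particular
the near-perfect recovery rates reflect planted effect sizes chosen at
the strength the design targets, and real-data candidate lists are
expected to be noisier.

## Numerical choices

- Pseudocount 0.1 (the flooring constant) in all fold-change and
  log-transform contexts.
- Sample (n − 1) standard deviations everywhere.
- Deterministic tie-breaks: percentile boundary by key order; median
  split ties to the low group; AUC midranks.
- Zero-variance columns are dropped (with a warning) before Pearson
  distances; constant rows z-score to zero.
- Fold change with both means zero and no pseudocount returns 1.
- The repetitive-sequence filter never removes singletons: in a library
  smaller than 1/max_frac reads every unique sequence exceeds the
  threshold arithmetically, but a sequence seen once is by definition
  not repetitive.
- All generator randomness flows through `numpy.random.default_rng`
  seeded from `(seed, per-generator offset)`, so the generators are
  independently deterministic.

## Problem sizes used in validation

The test suite and `scripts/acceptance.py` run the generators at their
default sizes (600 transcripts, 80 + 37 clinical samples, 200 outcome
patients), with 20-seed replication for recovery metrics, 50 runs for
log-rank detection, and 1000 replicates for the trimmer-oracle and
null-calibration checks — sizes at which every Monte-Carlo band is
stable from seed to seed on a single CPU.

## Known limitations

- The consensus motif scanner is not a matrix-similarity scanner;
  externally computed (E, S) backgrounds should be supplied when
  comparability with matrix-based results matters.
- Isoform de-duplication across classes is not modelled: class totals
  are transcript-level counts.
- The equal-variance *t*-test and exponential event-time model are the
  declared pipeline choices, not robustness-optimal ones (no Welch, no
  Cox regression, no covariate adjustment).
- Count-based differential models, batch correction and heatmap
  rendering are out of scope.
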