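# Methods

`microseek` detects microbial (bacterial and viral) gene expression in
short-read human RNA-seq and carries the detections through cohort-level
statistics. This note documents the models, the synthetic data the package
is exercised on, the numerical choices, and the places where the design was
genuinely open.

## Read-origin classification

Reads of 75 or 76 bases are classified as human, viral, or bacterial from
sequence alone. The classifier is a compact convolutional network written
in numpy: one-hot 76 x 4 input (A, C, G, T), conv(64 filters, width 8,
ReLU), max-pool 2, conv(32, width 8, ReLU), global max-pool, dense(64,
ReLU), dense(3, softmax), trained with cross-entropy and Adam
(learning rate 1e-3, batch 128). The convolutions are implemented as
im2col matmuls; at fixture scale training takes seconds on one CPU.
Across epochs the checkpoint with the best mean one-vs-all AUPRC on the
validation split is kept.

Training examples are segments cut from labeled reference sequences.
References are split into train/validation/test *before* segmentation, so
no substring of a held-out reference can reach training. Per-class strides
(defaults human 26, viral 2, bacterial 130) exist to balance per-class
segment counts when the class collections have very different total
lengths, roughly 13 : 1 : 65; the synthetic fixtures have equal totals per
class, so fixture configs use equal strides instead.

Before scoring, reads pass three rules: more than one N excludes the read;
a single N is replaced by a seeded-random nucleotide *in the scoring copy
only* (the stored read keeps its N so assembly can use the wildcard rule);
75-base reads get one random 3' nucleotide appended, again for scoring
only. The random draws come from a dedicated per-sample stream, and the
replacement base is recorded so a contig that still carries the N at the
end can resolve it consistently.

AUROC uses average ranks (tied pairs count half) and AUPRC is average
precision computed over tie groups; both reduce to the usual step-curve
areas for distinct scores and are verified against brute-force pair
enumeration in the tests. Chance levels on balanced three-class data are
0.5 (AUROC) and ~1/3 (AUPRC, the positive fraction).

## Seed-and-extend assembly

Reads with a bacterial or viral score of at least 0.46 are seeds. Seeds
are processed bacterial-first in descending bacterial score, then viral in
descending viral score, ties broken by read id; a read whose bacterial
score reaches the threshold is classed bacterial even when its viral score
is higher. Each seed is extended greedily at both ends by reads whose
overlap with the contig end is at least `min_overlap` (default 24) bases
and exactly matches, with N on either side matching any base and the
non-N base kept. Several choices the underlying method leaves open were
fixed as follows:

* **Candidate choice.** Among overlap candidates at an end, the read giving
  the longest extension wins; ties break by higher seed-class score, then
  read id. This makes assembly fully deterministic.
* **Read reuse.** A read joins at most one contig; a read consumed by an
  earlier contig is skipped as a later seed.
* **Whole-contig absorption.** When a contig finishes, every unused read
  that aligns wholly within it (wildcard-exact) is absorbed as a member.
  Greedy longest-extension deliberately skips intermediate tiling reads;
  without absorption those reads would re-seed redundant fragments of a
  transcript that is already assembled.
* **No mismatch tolerance** beyond the N wildcard, and no
  reverse-complement overlaps (reads are treated single-stranded).
* `max_contig_length` defaults to 2000 bases; an unresolvable N in a
  finished contig is replaced by the same random base used in scoring and
  the contig is flagged `n_resolved_random`.

Candidate lookup uses a hash index over length-`min_overlap` read prefixes
and suffixes, with a read's single N expanded to all four bases inside the
indexed word.

## Annotation

Contigs are assigned a species and genus by nucleotide search (top hit with
e-value < 0.01) and a protein family by translated six-frame search
(e-value < 1e-5). The default backend is a built-in ungapped
seed-and-extend local aligner: word size 11 for nucleotides with match
+2 / mismatch -3, word size 3 with BLOSUM62 for translated search, X-drop
20, both strands for nucleotide queries. Significance uses Karlin-Altschul
E = K m n exp(-lambda S); the nucleotide lambda is solved numerically from
the scoring scheme under uniform composition (~0.634 for +2/-3) with
K = 0.1, and BLOSUM62 uses the standard ungapped constants
(lambda 0.3176, K 0.134). Within a search, E-values are strictly monotone
in the raw score, which is what the top-hit ranking relies on; parity with
gapped BLAST statistics is not attempted. Ties on e-value break by bit
score, then lexicographically smallest accession. An external BLAST+
backend with the same contract can be selected in config (`blastn` is
invoked with masking off, since the built-in aligner does none); the two
backends agree on top-hit accession for high-identity contigs, which is
verified in the tests. Hits whose genus appears in a configured contaminant
list are screened out and logged, and per-sample hits are pooled to
distinct genera (or protein families) for the statistics.

## Prevalence statistics

Per-sample presence is pooled to patients by OR (a patient is positive if
any of their samples is). Features reaching 10% prevalence in either
cohort enter a one-tailed binomial test: the null probability is the
control-cohort prevalence clamped to [0.0001, 0.9999] (exactly 0 or 1
would force p = 0), the direction is "greater" or "less" by the sign of
the case-control prevalence difference (ties count as "greater"), and
Benjamini-Hochberg FDR runs across features.

The confounder-corrected analysis weights patients by inverse probability
of their observed cohort, with the propensity estimated by boosted
logistic regression (gradient boosting with logistic loss) on race, age,
sex, weight, smoking and sequencing depth. Four choices here matter and
were made deliberately:

* **Cross-fitting.** Propensities are 5-fold cross-fitted: each patient is
  scored by a model not trained on them. In-sample boosted fits overfit
  (in-sample AUC far above the true separability), and weights built from
  overfit propensities fail to balance the covariates.
* **Balance-criterion stopping.** Depth-1 trees, learning rate 0.05, up to
  800 rounds, with the number of rounds chosen as the stage whose weights
  minimize the maximum standardized mean difference across covariates --
  the stopping rule used by the twang approach to boosted propensity
  scores. Deviance-grown fits systematically under-fit the propensity
  tails and leave residual imbalance.
* **Stabilized, truncated weights.** Weights are multiplied by the observed
  group's marginal probability (so they sum to about the sample size) and
  truncated at their [1st, 99th] percentiles.
* **Per-group effective sample size.** The chi-squared statistic (df = 1)
  is computed on the 2x2 table after rescaling each cohort row to its
  group's Kish effective sample size, sum(w)^2 / sum(w^2). Weighted cell
  sums are not multinomial counts: the variance of a weighted proportion
  is p(1-p)/ESS of its own group, and without the rescaling the test
  rejects well above nominal even for features independent of everything.
  With unit weights the rescaling is a no-op, so the statistic reduces
  exactly to the plain Pearson chi-squared.

Each guard can be disabled in `IPWConfig`. The corrected analysis tests
all features with any prevalence (no 10% filter). Features with an
undefined statistic (a zero weighted margin) are reported with missing p.

Simulation at the package's study conditions (400 cases / 400 controls,
age shifted 1.0 SD between cohorts, null features whose log-odds depend on
standardized age with slope 1.0) shows the unweighted test rejecting
essentially always while the IPW test stays near nominal, with weighted
covariate SMDs well under 0.1 — the numbers are recomputed by
`scripts/acceptance.py` and by the test suite, not quoted here.

## Survival and host-expression screens

Features with at least 5 positive and 5 negative patients (after dropping
patients without clinical data) are screened per endpoint (overall and
disease-free survival) with a two-group log-rank test: observed-minus-
expected event counts with hypergeometric variance at each distinct event
time, chi-squared with 1 df; BH FDR runs per endpoint over tested features
only. The implementation is verified against lifelines to 1e-8 on random
fixtures. Kaplan-Meier curve data (time, at-risk, survival) can be
exported for plotting.

Host genes are screened against a designated patient grouping (for
example, the union of patients positive for any of a list of protein
families) with a two-sided Wilcoxon-Mann-Whitney test (normal
approximation with tie correction). A gene is called upregulated iff the
unadjusted p-value is below 0.05, the median z-score in the positive group
exceeds 0.2, and the median z-score in the negative group is below 0;
z-scores are per-gene across patients, so the selection is invariant to
monotone per-gene rescaling. Gene-set over-representation of the selected
list is a one-sided hypergeometric tail against user-supplied sets, with
BH FDR across sets.

## Synthetic data

All fixtures are generated in-package; the real inputs the method targets
(tumor and healthy-tissue RNA-seq with patient covariates) are
access-controlled.

* **Origin sources.** Each class is an order-2 Markov chain over
  {A,C,G,T}. Every class gets a random context-to-preferred-base map with
  the preferred base at ~55% probability (weight exp(1.3)), then a G/C
  column tilt is calibrated by bisection so the stationary GC fraction
  hits the class target (human 0.50, viral 0.40, bacterial 0.65). Over a
  76-base window this is an overwhelming class signal, while per-base
  entropy stays high enough that two unrelated sequences from the same
  source essentially never share a 24-mer; sharper preferences lock all of
  a class's sequences onto one near-deterministic context cycle, and the
  resulting spurious shared words let assembly chimerize transcripts in a
  way unrelated real genomes never show. The generator does not model
  codon structure, repeats, homopolymer artifacts, or phylogenetic
  relatedness — classifier results on fixtures bound what the architecture
  can learn from composition, not real-data performance.
* **Reads.** Poisson read counts per planted transcript
  (coverage x length / read length), uniform start positions, optional
  per-base N corruption (rate <= 0.05), constant 'I' quality. No
  substitution errors, no paired ends, no expression-level variation.
  Under uniform starts the transcript termini are only covered by reads
  starting exactly there, so coverage guarantees apply to the interior;
  recovery criteria use an 80%-of-length rule for this reason.
* **Cohorts.** Covariates are drawn with cohort-dependent shifts:
  continuous covariates (age, weight, sequencing depth) are shifted by a
  configurable number of SDs for cases; binary covariates (sex, smoking)
  and race get log-odds shifts. A 1.0 SD shift gives propensity AUC ~0.74.
  Shifts much beyond ~1 SD at a few hundred patients break positivity --
  there are no case patients in the control-typical covariate range, and
  then no weighting scheme (not even true-propensity weights, which was
  verified directly) can balance the cohorts.
* **Survival.** Exponential event times with per-patient hazard
  base x exp(sum of feature log-HRs), median 1000 days (OS) and 600 days
  (DFS); censoring replaces the time by a uniform fraction of it with the
  configured probability (non-informative).

The end-to-end fixture is 2 cohorts x 10 patients (two patients contribute
two samples to exercise OR pooling), 3 bacterial genera with one
case-enriched genus (planted in 80% of cases vs 20% of controls), one
survival-linked protein family (log HR = log 3), coverage 20, read length
75, N rate 0.005, 150 host reads per sample. These sizes keep a full
pipeline run to about half a minute; larger studies only change runtime.

## Determinism

Every stage takes an explicit seed. The pipeline derives per-stage child
seeds from one root seed via CRC-32 of "seed:stage-name" (kept below
2^31), so a stage re-run in isolation matches its in-pipeline behavior and
two identical runs produce byte-identical outputs; result tables are
written with a fixed float format.

## Known limitations

* The synthetic origin sources are far easier to separate than real
  human/viral/bacterial sequence; fixture AUPRCs near 1.0 say nothing
  about performance on real reference databases.
* The built-in aligner is ungapped; contigs with indels relative to the
  reference will fragment into shorter HSPs and may lose identity. The
  BLAST+ backend is the escape hatch.
* Host filtering is exact full-read matching, valid because synthetic
  origins are disjoint; real data needs an external aligner behind the
  same interface.
* The IPW analysis assumes covariate overlap between cohorts; under
  near-complete separation (propensity AUC ~1) weights are untrustworthy
  regardless of truncation, and the corrected results should be read as
  diagnostics, not estimates.
* Log-rank screens are presence-based only; no Cox adjustment is offered.
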