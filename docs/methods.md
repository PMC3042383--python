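# Methods

## Scope and model

`fragbench` benchmarks per-read ("is there a gene in this read, and
where?") prokaryotic gene prediction and Boolean ensembles of predictors.
The read-level detection model is binary: a read is a positive if its
ground truth contains any coding sequence (fragment types A, B, C) and a
negative if it is fully intergenic (type D). A predictor's call is
positive if it reports at least one coding interval on the read. Coordinate
quality is assessed separately through the annotation-error statistic.

## Synthetic genomes

A genome is an alternating sequence of intergenic stretches and planted
genes, starting and ending intergenic, so every base outside an annotated
gene is genuinely non-coding — the property the fragment types rely on.

* **Intergenic sequence** is i.i.d. over {A,C,G,T} at the target GC
  (default 0.5, a typical mid-range prokaryotic value).
* **Genes** are `ATG` + body codons + one stop codon, with no in-frame
  internal stop. Body codons are drawn from a mixture
  `(1−w)·Q_gc + w·B`, where `Q_gc` is the background codon distribution at
  the target GC and `B` a fixed "preferred codon" table (frozen log-normal
  weights); `w = codon_bias_strength` clipped to [0, 1]. One scalar thus
  controls how separable genes are from background by codon statistics.
  The default 0.6 puts the built-in baseline in a realistic 80–95%
  accuracy regime rather than at a ceiling.
* **The zero-bias subtlety.** Restricting the at-GC product distribution
  to the 61 sense codons would shift the mononucleotide marginal by ~1%,
  making "unbiased" genes statistically distinguishable from intergenic
  background. Instead each stop codon's probability mass is redistributed
  uniformly over the sense codons with the same base multiset
  (TAA → {AAT, ATA}; TAG, TGA → {AGT, ATG, GAT, GTA}). Permutations of a
  multiset share the same product probability, so the marginal base
  composition of gene bodies equals the background *exactly* at `w = 0`,
  while gene bodies remain stop-free. Consequence: even at zero bias, ten
  codons carry structurally non-zero log-odds (the three stops, ATG from
  gene starts, and the six mass-absorbing codons); tests account for this.
* **Lengths** are Gaussian around the configured mean (sd = mean/4),
  clipped to [min, max]; gene lengths are rounded down to multiples of 3.
  Defaults (genes ~900 bp, intergenic gaps as configured) approximate
  typical prokaryotic gene length; the generator does not model operons,
  overlapping genes, RBS motifs, or phylogenetic diversity.
* **Strands.** Genes go on the forward strand by default;
  `both_strands=True` assigns strands uniformly and stores the reverse
  complement of the drawn coding sequence.

Random streams are hierarchical (`numpy.random.SeedSequence.spawn`): each
genome, each benchmark stratum, and each mock predictor draws from its own
child stream, so changing one stage's sampling never perturbs another.

## Fragment simulation

Candidate enumeration is exhaustive per (genome, read length, type):

* **A** anchors at the gene's 5' start: the window covers `L/2` bp of
  purely intergenic upstream flank followed by the gene's first `L/2` bp.
  Each qualifying gene contributes exactly one candidate per read length.
* **C** mirrors A at the gene's 3' end.
* **B** windows are every position fully inside a gene, so start/stop
  codons appear only when the window abuts a gene boundary.
* **D** windows are every position in a fully intergenic stretch.

Anchoring A/C at the gene boundaries (rather than any in-gene offset) is a
fixed design choice; it makes the truth interval exactly half the read and
is the variant consistent with "half upstream, half gene start". Reads
from reverse-strand genes are reverse-complemented so the coding strand is
the read's forward strand.

Sampling is uniform **without replacement** over the pooled candidates of
all genomes — duplicate reads would silently inflate rates. A pool smaller
than the request is an error unless `allow_replacement` is set (then it
falls back to with-replacement and logs a warning). Read lengths must be
even (the half/half gene-edge design).

The canonical design — 7 read lengths × 4 types × 1000 reads — requires
≥1000 candidates per stratum. The binding constraints are type A/C at
700 bp (needs ≥1000 genes ≥350 bp with ≥350 bp clean flank) and type D at
700 bp (needs long intergenic runs). The default genome set (20 × 110 kb,
genes ~900 bp, gaps ~800 bp) yields ~1300 genes and comfortable pools for
every stratum while building the full 28,000-read sample in seconds.

## Predictors

* **Ingestion:** GFF3 (seqid = read id, one feature per interval) or TSV
  (`read_id start end strand score`), 1-based inclusive on disk, 0-based
  half-open in memory. A read with no row is a non-coding call.
* **Codon log-odds baseline:** scores every stop-free codon run in all six
  frames (including runs truncated by the read edges, since short
  metagenomic reads usually carry incomplete ORFs) by mean per-codon
  log₂(coding frequency / background frequency); emits runs with score ≥
  `score_threshold` (default 0.1 bits/codon) and length ≥ `min_orf_len`
  (default 60 bp, a common minimal ORF cutoff). The coding table is
  tallied in-frame over annotated genes; the background is the product of
  genome-wide mononucleotide frequencies; both are pseudocount-smoothed so
  all 64 scores are finite. This baseline deliberately has no ORF-linking
  dynamic program, RBS model, or learned component — it exists to exercise
  the framework end-to-end, not to compete with production gene finders.
* **Mocks:** per coding read, emit the truth interval with probability
  `sens` (endpoints optionally perturbed by rounded Gaussian noise, sd in
  bp, clipped to the read); per non-coding read, emit a uniformly random
  interval with probability `1−spec`. Deterministic given the seed;
  different seeds give statistically independent error patterns, which is
  what the ensemble closed forms assume.

When a read has several predicted intervals, the one used for coordinate
work is the maximal-overlap interval against the truth when truth is
available, otherwise the highest-scoring (ties: longest, then leftmost).

## Combination

Binary: AND = all members coding, OR = any, CONSENSUS = strict majority
(odd member count ≥ 3 required). Coordinates: AND intersects the members'
selected intervals — an empty intersection keeps the positive binary call
but yields no interval; such "disjoint" reads are excluded from
annotation-error averaging and tallied separately, not penalized.
OR takes the enclosing hull. CONSENSUS takes the coordinate-wise lower
median over coding members — robust to a single outlying predictor, which
is the point of voting. The upper-bound analysis is per-read: correct iff
≥1 member's binary call matches truth.

## Metrics

Rates with zero denominators propagate as missing values (`None`/NaN),
never as 0 — an all-coding stratum simply has no specificity. The
f-measure is the harmonic mean of sensitivity and **specificity** (not
precision/recall); this nonstandard pairing is intentional and documented
because the package's purpose is the sensitivity-vs-specificity trade-off.

Annotation error for a read with reference coding interval `[L_ref,R_ref)`
and predicted interval `[L_p,R_p)` is
`100·(|L_p−L_ref| + |R_p−R_ref|)/|F_ref|`, where `|F_ref|` is the length
of the reference coding segment *within the read* (so `L` for type B,
`L/2` for types A/C). The alternative normalizer (full read length) is
available via `normalize_by_read_length=True`. The error is uncapped and
insensitive to the open/closed endpoint convention, since both endpoints
are compared in the same convention.

The ROC here is unusual and worth stating plainly: there is no score
threshold to sweep — each **read length** contributes one operating point
(1−specificity, sensitivity), the points are sorted by FPR, anchored at
(0,0) and (1,1), and integrated by the trapezoid rule. The AUC therefore
summarizes a method across read lengths, not across decision thresholds.

## Pipeline

A YAML config drives genomes → benchmark → predictors → combinations →
report. Replicates (default in the canonical design: 2) draw independent
benchmark samples from spawned seeds; the summary table reports mean and
standard deviation across replicates. The report includes per-type
accuracy (averaged over read lengths), upper-bound error per read length,
ROC/AUC tables, and a "suggested method per read length" table that picks
the accuracy-maximizing method with mean annotation error as tie-break —
encoding the trade-off that a method weaker in detection may be preferred
if it annotates coordinates better. A manifest (config hash, seed,
version) makes any table reproducible.

Type inference on truth-free reads uses edge-touching of the selected
interval: coding reaching only the right edge ⇒ gene start present
(A-like); only the left edge ⇒ gene end (C-like); both edges or internal ⇒
B-like; no call ⇒ D.

## What the synthetic conditions do and do not show

Mock predictors have independent, homogeneous per-read errors; real gene
finders err in correlated, sequence-dependent ways, so real ensemble gains
will be smaller than the independent-voter closed forms. Synthetic genomes
have clean annotations, no sequencing error, no RBS/operon structure, and
a single global codon bias; the baseline's absolute rates on them say
nothing about real-data rates. What the tests *do* establish is the
correctness of the machinery: candidate enumeration, truth bookkeeping,
metric formulas, combination logic, and the exact inequalities (OR
sensitivity / AND specificity dominance, upper-bound flooring) that hold
for any predictors, real or mocked.

## Numerical and degenerate-input choices

* Internal coordinates 0-based half-open everywhere; GFF3 and the TSV
  dialects are 1-based inclusive.
* Even-count medians in consensus coordinates take the lower median
  (integer-valued, within the members' endpoint range).
* Pseudocount 1.0 on both codon tables before the log ratio.
* An empty candidate pool, an odd read length, a degenerate length
  distribution, out-of-bounds GFF3 features, and truth rows violating the
  type invariant all raise typed errors naming the offending stratum or
  feature rather than producing partial output.
* Ties in the suggested-method table break deterministically (accuracy
  desc, annotation error asc, method name asc) so reruns are
  byte-identical.
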