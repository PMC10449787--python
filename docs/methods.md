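# Methods

## Model

`arcvir` treats archaeal-virus identification as binary classification of
contigs already known to be viral.  The unit of observation is a contig; its
representation is a 27-dimensional feature vector combining genomic
attributes of its gene calls with summaries of three homology searches.  The
classifier is a bootstrap-aggregated decision-tree ensemble (scikit-learn
`RandomForestClassifier`); the reported probability for a contig is the
fraction of trees whose terminal leaf votes for the archaeal class, not the
ensemble-averaged leaf distribution.  The two readings differ for shallow or
impure trees; the vote fraction is used because it is the quantity the 0.80
calling threshold is defined against, and because it makes the probability
an exact multiple of 1/n_trees, directly testable against a manual per-tree
count.  Probabilities are taken from the model refit on the training split
(not from out-of-bag votes); the out-of-bag accuracy is recorded separately
in the training summary.

Assumptions inherited from the problem setting: inputs are dsDNA viral
contigs (the model has no "not a virus" class — cellular contamination can
only surface as false positives, which is exactly what the contamination
benchmark measures); contigs are long enough to carry several genes
(recommended > 10 kb); and the user-supplied reference sets carry a
two-column target→class metadata map, since nothing in the pipeline guesses
a taxon from free-text subject lines at classification time.

## Feature catalog (version `arcvir-27f-v1`)

Nine genomic attributes: mean and median gene length (nucleotides — gene
lengths here are nucleotide spans, recorded in the model metadata), gene
density (genes/kb), coding fraction (union of gene intervals over contig
length), strand bias (majority-strand fraction; 1.0 by convention for
zero-gene contigs), strand-switch rate (adjacent gene pairs on opposite
strands), contig length, GC content (over unambiguous bases), mean
intergenic gap (clamped at zero for overlapping genes).  For each of the
three search sources (protein-vs-protein, profile-HMM, iterative profile):
ORFs with a hit, annotated-ORF fraction, archaea-affiliated and
phage-affiliated best-hit counts, and mean best-hit bitscore — the best hit
per ORF per source is chosen by max bitscore, ties by min e-value, then
lexicographic target id, so summaries are permutation-invariant.  Three
aggregates: the raw (not best-per-ORF) iterative-profile hit count — the
count feature and its best-per-ORF variant are both exposed, since either
reading of "hits to the reference" is defensible — the archaeal fraction
among ORFs annotated by any source (decided by each ORF's single best hit
across sources), and a no-genes flag.  Absent evidence is encoded as 0 plus
the flag, never as a missing value; zero-gene contigs are kept and flagged
rather than dropped.

E-value ceilings are strict (<): 1e-5 for the protein search, 1e-10 on the
full-sequence e-value of the profile-HMM search ("full protein length" is
read as the full-sequence column of the tabular output, versus per-domain),
1e-5 for the iterative search.  Iterative searches default to three rounds.

Co-correlation pruning removes, in fixed catalog order, any later column
whose |Pearson r| with an already-kept column exceeds 0.95.  The absolute
value is used (a perfect negative correlate is as redundant as a positive
one); Pearson rather than rank correlation is the default reading of a
correlation threshold on numeric features.  Zero-variance columns have
undefined r and are retained with a warning.  The scan is greedy and
deterministic, hence idempotent, and the removal log names the kept partner.

## Training procedure

Stratified 70:30 split with per-class largest-remainder quotas, so the train
size is exactly round(0.7·n); classes with fewer than five members are
rejected (they cannot be stratified five-fold downstream).  RFE: at each
step the current feature set's five-fold cross-validated F1 (positive class
= archaeal virus) is recorded, a forest is refit on all training rows, and
the lowest-mean-Gini feature is dropped, down to a floor of five.  The
selected step maximises mean F1 with ties resolved toward fewer features —
the trace keeps every step, so both the plateau point and the full set
remain inspectable.  Defaults: 1000 trees in production (tests and examples
use 100–300 for speed; the statistic is insensitive beyond a few hundred
trees on these problem sizes), a mandatory integer seed, stratified folds.

Thresholding: a contig is called archaeal when p ≥ t (so at an exact tie of
p = 0.5 the archaeal call requires t ≤ 0.5).  The default t = 0.80 trades
recall for a low false-detection rate.

Proximity analysis: prox(i,j) is the fraction of trees in which rows i and j
share a leaf; average-linkage hierarchical clustering on 1 − prox is cut
into two clusters, each cluster takes its majority label, and rows
disagreeing with their cluster's majority are flagged as candidate
mislabels or poorly covered sequences.

## Metrics and curves

TPR = TP/(TP+FN), SPEC = TN/(TN+FP), ACC = (TP+TN)/total,
FDR = FP/(FP+TP), MCC = (TP·TN − FP·FN)/√((TP+FP)(TP+FN)(TN+FP)(TN+FN)),
F1 = 2TP/(2TP+FP+FN); a zero denominator yields a null (flagged) metric,
never a propagated NaN.  Curves use thresholds at the unique scores plus
{0, 1}, predicted-positive at score ≥ t, with equal scores grouped into one
step; AUROC is the trapezoid over the grouped ROC points, which equals the
concordant-pair rank statistic with ties counted half (asserted against a
brute-force oracle in the tests).  AUPRC is the trapezoid over the PR
points, anchored at recall 0 with the precision of the most stringent
non-empty step.

## Perturbation benchmarks

Fragmentation cuts each contig into exact, non-overlapping 5′-anchored
windows of the target size (window placement is otherwise unspecified in the
protocol; the 5′ anchor keeps it deterministic), drops the terminal
remainder, and subsamples the fragment pool back to the original sequence
count (seeded).  On synthetic datasets fragmentation is dataset-aware: an
ORF survives only if wholly contained in a window, and a hit survives with
its ORF — homology evidence on broken genes is lost, which is the
degradation mechanism fragmentation exercises.  Contamination spiking adds
round(p/(1−p)·n_viral) microbial fragments so they form proportion p of the
final dataset, drawn half from archaea and half from bacteria without
replacement, each fragment required to be 10–200 kb; microbial rows keep
their cellular label so they count as negatives in the FDR.  Across a
proportion grid the contaminant draws are nested per seed, so the FDR is
monotone by construction for a fixed model and threshold and grid points are
paired.  Subsampling is a seeded simple random sample of round(f·n) contigs.
The subsample grid default is {0.05, 0.25, 0.50, 0.75}; a {0.10…0.95} grid
is equally valid and configurable.

## Synthetic data: what it emulates, and what it does not

Per class, contigs (default 10–50 kb) carry planted complete ORFs (start
codon, stop-free codon body, stop; ~900 ± 300 nt; strand runs with
persistence 0.75) separated by short gaps.  Hit tables are generated
directly rather than by running real searches against synthetic proteins —
the unit under test is the pipeline, not an aligner — with e-values and
bitscores drawn so every planted hit passes the filters.  Class profiles:
archaeal viruses have an annotated-ORF fraction of 0.27 ± 0.23 of which
0.71 ± 0.21 affiliate archaeally, and Poisson(18) iterative-profile hits;
phages 0.70 ± 0.33 annotated, 0.02 ± 0.06 archaeal, Poisson(0.5)
iterative-profile hits (the phage rate is a configurable near-zero default;
no phage-specific published rate exists).  Contaminants are 10–200 kb
fragments, half archaea / half bacteria, with ~12× wider intergenic gaps,
annotated fraction 0.30, near-zero viral-database and iterative-profile hit
rates; archaeal fragments affiliate archaeally (0.80) when annotated.

Consequences for interpreting the tests: the planted signal is strong and
clean, so the forest reaches near-perfect held-out metrics — passing shows
the machinery is correct, not that real archaeal viruses are this easy.  In
particular, because contaminants here have almost no viral-database
evidence, the trained forest routes them to the phage side and the
contamination FDR stays near zero across the grid (the monotonicity
property then holds via the nested draws).  Real cellular archaea share
genes with their viruses and do get called archaeal at high contamination;
that failure mode requires real reference databases and is outside what the
generator emulates.  Likewise the generator does not attempt sequence
evolution, codon usage, partial genes at contig edges, or correlated
annotation noise.

## Gene calling

The external adapter shells out to Prodigal in metagenome mode and parses
its protein-FASTA coordinate headers verbatim (1-based inclusive
coordinates throughout the package).  The built-in fallback scanner needs no
binary: complete ORFs ≥ 90 nt from the first start codon
({ATG, GTG, TTG}) after the previous in-frame stop to the next stop, both
strands, with ambiguous bases terminating extension.  It approximates the
external caller for fixtures and is verified exactly against a six-frame
brute-force oracle; it is not claimed equivalent to the external caller's
scoring model.

## Legacy rule set

Gates: homology annotations need bitscore > 50 and e-value < 0.001 — the
published gate reads "> 0.001", inconsistent with every other filter's
direction, so the ceiling reading is the default and the literal floor
reading remains selectable — domain-model annotations need bitscore > 40 and
e-value < 1e-5; homology wins when both exist.  Category 1 requires the
archaeal fraction of annotated genes to exceed 2/3 strictly (avoiding the
66.0-vs-66.7 ambiguity of a percentage threshold), category 2 exceeds 1/2
strictly; additionally the best archaeal-affiliated bitscore must exceed 75
and strictly beat the best phage-affiliated bitscore (the gate is applied to
the best hit, not per gene).

## Numerical and design notes

* Degenerate inputs: zero-ORF contigs get conventional attribute values and
  a flag; single-class training data, one-class ROC inputs, sub-five-member
  classes, and empty subsamples raise errors rather than degrade silently.
* Problem sizes in the shipped tests and acceptance run — 400 contigs per
  class, 10 seeds for the perturbation medians, 20 repetitions for the
  permutation null and RFE retention, 100–300 trees — were chosen as the
  smallest sizes at which the measured statistics are stable.
* Model archives store the forest, feature catalog version, seed, tree
  count, split record, Gini importances and RFE trace; prediction refuses a
  table built under a different catalog version.
* Known limitations: no "cellular" third class (upstream viral
  identification is assumed); the protein-search external backend is not
  wired (hits are ingested from standard 12-column tabular output, the
  HMMER-based searches can also run as subprocesses); probabilities are
  vote fractions, uncalibrated beyond that.
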