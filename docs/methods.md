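# Methods

## Sequence representation

Windows are 0-based half-open intervals. Two extraction modes are
supported: `midpoint300` (the 300-bp window symmetric around a peak
midpoint, for open-chromatin hotspots and TF ChIP peaks) and `tss`
(−250/+50 bp around a transcription start site, the core-promoter
window). Minus-strand promoter windows are reverse-complemented before
tokenization so the downstream TATA positional convention (~+30 from the
window start in a −250/+50 frame) is preserved; this flip is a package
convention, since either choice is defensible.

Every k-mer is collapsed with its reverse complement into a canonical
token (the lexicographic minimum of the pair), making features
strand-symmetric. Windows containing any non-ACGT symbol are skipped,
never imputed. Two token views are produced:

* the **bag stream**: all (L−k)+1 overlapping k-mers at 1-bp stride;
* **sentences**: the k phase-shifted non-overlapping tokenizations
  (offset j takes positions j, j+k, j+2k, …, trailing partial windows
  dropped). Sequences shorter than 2k are rejected for the sentence view
  (no token co-occurrence exists) but allowed down to length k for the
  bag view.

## Control selection

Each regulatory window is paired with a random window of the same length
whose G+C content matches within a tolerance (default 0.02, absolute)
and which overlaps neither regulatory regions nor previously chosen
controls. Candidates are drawn uniformly at random (seeded, up to 10,000
attempts per phase) first within ±100 kb of the target, then anywhere on
the chromosome; a target with no acceptable control on its chromosome is
reported and skipped. Random draws rather than exhaustive scans match
the "randomly chosen" design and bound the runtime. Train/holdout splits
are label-stratified at a default 80/20; holdouts are assembled at 1:1
(balanced) or 1:10 (unbalanced) control ratios.

## Low-complexity filtering

The complexity of a k-mer is the Shannon entropy of its within-k-mer
symbol frequencies over the 4-letter alphabet, −Σ p_i log2 p_i ∈ [0, 2]
bits (0·log 0 := 0). Note this is composition entropy, not positional
information content. Entropy is invariant under reverse complement, so
filtering commutes with canonicalization.

A filtering threshold can be derived empirically from a motif-consensus
collection: every length-k window of every consensus contributes its
entropy, and the threshold is a low percentile (default 5th) of that
distribution — real binding sites are rarely low-complexity, so this
keeps essentially all motif-like words while removing homopolymeric and
short-period tokens. When no collection is supplied a documented default
of 1.3 bits (k=8) is used. Threshold 0 disables filtering ("full"
vocabulary); the filtered vocabulary defines the "filtered" models.

## Bag-of-k-mers model

Raw token counts per sequence are TF·IDF-weighted. The default follows
the scikit-learn convention — idf = ln((1+|S|)/(1+df)) + 1 with L2 row
normalization — the de-facto standard implementation of this weighting;
a `raw` switch computes the plain product f(t)·ln((1+|S|)/(df+1)) with
no normalization for exact worked-value checks. Both variants are
first-class. Document frequencies are frozen at
training time and reused when transforming holdout or genome-scan data.

The classifier is an L2-penalized logistic regression (liblinear); the
inverse regularization strength C is chosen by stratified five-fold
cross-validated grid search on accuracy over {10⁻³ … 10³} (7 log-spaced
points) and the model is refit on the full training set. Training is
always balanced; imbalance is handled at evaluation time, not by class
weighting.

Per-base score profiles assign each 1-bp-stride k-window the β of its
canonical token (0 if filtered out or N-containing) and report, at each
base, the mean over the windows covering it (the per-base aggregation
rule is unspecified upstream; the mean is the package's choice).

## Vector-k-mers model

Architecture: CBOW (the context window predicts the target token)
with hierarchical softmax over a Huffman tree built from token
frequencies, no negative sampling, window 5, min_count 0. Full-scale
defaults are dimension 300 and 30 epochs. Training is implemented
in-package (numba kernels): in-order corpus traversal, a fixed
(non-shrinking) context window, learning rate decaying linearly from
0.025 to 10⁻⁴ per processed token, single-threaded — bit-reproducible
under (corpus, seed). Each token's initial vector is hash-seeded from
(token, seed), so a token shared by the two class corpora starts from
the same point in both spaces and likelihood differences reflect learned
co-occurrence structure rather than initialization noise.

**Desk-scale training budget.** The synthetic corpora used by the tests
and the acceptance script (500 sequences/class ≈ 1.5·10⁵ tokens) are
roughly two orders of magnitude smaller than the real-scale corpora the
30-epoch default is meant for. At that size tens of passes memorize
singleton contexts (training accuracy 1.0 with holdout at chance), so
desk-scale runs use 3 epochs and dimension 32 — the corpus-size-matched
analogue of the full-scale configuration. The library defaults are
unchanged.

Scoring: a sequence's k sentences are scored in each space as the mean
over sliding context windows (training window size) of the
hierarchical-softmax log-probability of each target token given its
context; out-of-vocabulary tokens are dropped, and a sentence with fewer
than two known tokens is flagged undefined rather than silently scored.
Sentence log-likelihoods are averaged in log space (the linear/log
choice is ambiguous upstream; log-space averaging is the composite-
likelihood reading) over sentences defined in both spaces, and the class
posterior is computed by log-sum-exp Bayes inversion with uniform prior
1/C, C = 2.

Analytics: cosine nearest-neighbour lists (ties broken
lexicographically, query excluded); window and corpus centroids (mean of
member token vectors) with cosine distance 1 − cos ∈ [0, 2]; rank-list
contrast between the two spaces as Jaccard dissimilarity of truncated
top-N lists (a deliberately simple, reproducible contrast; rank-weighted
variants are out of scope).

## Evaluation

Confusion metrics follow the textbook definitions with the positive
class = regulatory; ratios with zero denominators are reported as
undefined, not 0. ROC and PR points come from full threshold sweeps
(no intermediate-point dropping, so the trapezoidal ROC area equals the
Mann–Whitney pair-counting statistic with ties counted ½). Areas are
trapezoidal. The PR curve's artificial recall-0 endpoint reuses the
precision at the highest threshold instead of interpolating to (0, 1);
auPRC values depend on this convention, so it is fixed and tested.
Operating points for genome scanning are calibrated on the unbalanced
holdout as the highest threshold whose recall still reaches a target
(default 60%).

## Genome scanning and transfer

Chromosomes are tiled into non-overlapping 300-bp windows (trailing
remainder dropped); windows overlapping a repeat or coding mask by ≥1 bp
(configurable to fractional overlap) are excluded; the rest are scored
and called at the calibrated probability cut-off (defaults: bag ≥0.85,
vector ≥0.95, the operating points recovering ~60% of known regulatory
windows). Calls are monotone in the threshold.

Cross-genome transfer scores 300-bp windows at 150-bp stride across a
4-kb span centered on each alignment hit: windows are first filtered by
bag probability (default ≥0.85), then ranked by cosine distance between
their token centroid and the reference regulatory centroid; ties go to
the leftmost window. When no window passes the filter the ranking falls
back to all windows in the span, so every hit receives a prediction. A
prediction
intersects its hit when at least half a window length lies inside the
hit interval. Even at zero divergence the top-1 intersection fraction is
slightly below 1: when a motif cluster sits near a region edge, the
closest-centroid window can overlap the region by under 150 bp. Spans
clipped at chromosome ends are logged.

## Synthetic data

The generator emulates the real study design, not generic random DNA:

* 300-bp regulatory windows = i.i.d. background (default G+C 0.47,
  maize-like) with, for each of 2 consensus motifs (TFBS-like, lengths
  8–12, per-position substitution rate 0.1), 1–3 instances planted on
  random strands at non-overlapping positions; optional poly(dA:dT)
  tracts at fixed offsets emulate the structural low-complexity features
  of open chromatin;
* controls = i.i.d. background matched to each regulatory partner's
  realized G+C;
* genome pairs = a source chromosome carrying planted regulatory
  windows (one per equal slot, so loci are separated the way alignment
  hits are), low-complexity repeat tracts and coding intervals, plus a
  target derived by i.i.d. substitutions at the chosen divergence and
  sparse 1–3-bp indels, with the regulatory coordinates mapped through
  the edits as ground-truth hits.

What passing tests on these data do and do not show: the generators
reproduce the *statistical contrasts* the models exploit (motif-token
enrichment, GC matching, local co-occurrence, repeat contamination,
divergence), so they validate the machinery end-to-end; they do not
contain transposon families, methylation, chromatin signal, or the
pervasive compositional heterogeneity of real regulatory regions, so
absolute synthetic accuracies are not forecasts of real-data accuracy.

## Numerical choices

* Hierarchical-softmax log-probabilities use numerically stable
  log-sigmoid; posteriors use log-sum-exp.
* Huffman tree ties break by insertion order (deterministic); a
  single-token vocabulary gets probability 1 (empty path).
* TF·IDF logarithms are natural throughout.
* Vocabulary indices are lexicographically sorted for stable
  serialization; embedding token order is by descending count, then
  token.
* Models persist as compressed npz archives (token table + arrays +
  JSON config, versioned); embedding spaces also export the plain
  word2vec text format.

## Known limitations

* Gapped k-mers, skip-gram training, negative sampling and multi-class
  labels are out of scope.
* The word2vec scorer is a composite likelihood, not a normalized
  sequence model; only likelihood *differences* between the two spaces
  are meaningful.
* Control selection matches G+C and locality but not repeat content or
  distance-to-gene beyond the vicinity rule.
* Positional densities count both strands (consistent with canonical
  tokens); single-strand counting would differ for non-palindromic
  tokens.
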