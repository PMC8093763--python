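# Methods

## The problem

Urban microbiome samples carry weak but real geographic signal: different
cities host measurably different microbial communities. Given a sample ×
taxon abundance table with known city labels, the task is to predict the
source city of new samples. The data are compositional (per-sample
proportions summing to 1), high-dimensional (taxa outnumber samples),
imbalanced (city sample counts differ several-fold) and poorly separated
(city clouds overlap in ordination space). No single classifier is reliably
best on such data; which one wins depends on the preprocessing and profiling
choices upstream.

## The adaptive ensemble

`microgeo`'s core is an ensemble built by stratified bagging and weighted
rank aggregation. With training data (X, y), N bootstrap replicates, M
candidate classifiers and K performance measures:

1. draw bootstrap replicate j (size n, with replacement, every class
   represented; the unsampled complement is the out-of-bag (OOB) set);
2. fit all M candidates on the replicate;
3. predict the OOB samples and compute the K measures for each candidate;
4. each measure orders the M candidates, giving K ranked lists with the
   measure values as importance weights;
5. aggregate the K lists into a consensus ordering; the top candidate is
   bootstrap j's winner, and its fitted model (not a refit) joins the
   ensemble.

Prediction is majority voting over the N winners; vote ties are broken by
the higher total training frequency of the tied classes, then
lexicographically. Because each winner is selected on data its candidates
never saw (the OOB set), the ensemble adapts to whichever candidate suits
the data without overfitting the selection, and in practice tracks the best
stand-alone candidate without knowing it in advance.

OOB evaluation has one sharp edge: an OOB draw can lack classes. All
measures here are computed over the classes present in the OOB truth, with
a logged note, so every bootstrap yields well-defined scores.

### Performance measures

Three chance-aware multiclass measures drive the selection (plain accuracy
is nearly blind to rare cities):

- **Cohen's κ** = (P₀ − P_E)/(1 − P_E), observed vs. chance-expected
  agreement. Undefined when P_E = 1 (single-class truth and prediction);
  this is raised as an error, never silently reported as 0.
- **G-mean** = (∏ᵢ Recallᵢ)^{1/K}; one fully missed class annihilates it.
- **MAUC** (Hand–Till) = mean over ordered class pairs (i, j) of AUC(i, j),
  the probability that a class-i sample outranks a class-j sample on the
  class-i score column, ties counted half (midranks). MAUC is invariant to
  strictly monotone transforms of each score column, so uncalibrated SVM
  decision margins are as valid an input as probabilities; the SVM candidate
  contributes margins.

### Rank aggregation

The consensus ordering δ minimises Σₖ wₖ · d(δ, Lₖ), where d is the
weighted Spearman footrule: Σ over candidates of |rank in δ − rank in Lₖ|
times the candidate's importance weight, min-max-normalised within the list
(a constant-weight list normalises to all ones, not all zeros, so that
every displacement still costs). List weights wₖ default to equal.

The objective is separable over (candidate, position) pairs, so exact
minimisation is a linear assignment problem. For M ≤ 8 the package
enumerates all M! permutations with a deterministic tie-break (lexicographic
candidate id); above that it solves the assignment exactly with the
Hungarian algorithm. There is no stochastic search anywhere, so aggregation
is exact and reproducible at any roster size.

### Candidate roster

Nine candidates, mirroring the classifiers most used for microbiome source
classification: random forest (RF, 200 trees), RBF-kernel SVM, a single
CART-style decision tree (RPart), gradient-boosted trees (XGBoost, 100
rounds), a one-hidden-layer MLP (64 units), plus composites that project
onto 10 principal components (PCA+RF) or 10 supervised partial-least-squares
components fitted against one-hot labels (PLS+RF, PLS+RPart, PLS+XGB).
Component counts are capped at min(n−1, p) on small partitions.
Hyperparameters are library defaults, deliberately untuned: the ensemble's
job is to choose among imperfect candidates, and tuning each would multiply
cost without changing the construction. The five-candidate "standard"
roster (no composites) is the default for desk-scale work.

## Imbalance handling

Two treatments, both applied strictly after any train/test or bootstrap
split (applying them before would leak synthetic or reweighted copies of
test information into training):

- **Class weights** w_c = 1/n_c, left unnormalised (only relative
  magnitudes matter to the weight-aware fitters; a mean-1 normalisation
  flag exists for scale-sensitive ones). Passed as per-sample weights to
  candidates that accept them; the MLP does not and is fitted unweighted
  with a logged note.
- **GaussNoise oversampling**: every minority class is brought up to the
  majority count by sampling its members uniformly and adding independent
  per-feature Gaussian noise with sd = `sigma_scale` × the within-class
  per-feature sd (default `sigma_scale` 0.05 — small enough to stay inside
  the class cloud, large enough to avoid exact duplicates). Negative
  synthetic abundances are clipped to 0; original rows are never modified.

Neither adds information; both redistribute errors toward minority classes.
The package's tests verify the directional claim (weighting raises minority
recall) rather than any absolute gain.

## Downstream filtering

Counts tables are denoised in two ordered passes before renormalisation:
taxa present (count > 0) in fewer than 1% of samples are dropped (strict
less-than), then taxa with fewer than 10 reads in total are dropped. The
10-read threshold is read as a total over all samples — the conventional
reading for abundance-table denoising — with a per-sample variant behind a
flag. Samples left all-zero are dropped with a warning; surviving rows are
renormalised to sum to 1.

## Distance-based predictors

- **KL projection**: divergence of a query composition from every training
  sample, after adding a pseudocount (default 1e-6; zeros are inevitable in
  relative abundances) and renormalising; natural log. The query's city is
  the city of the nearest training sample ("nearest" mode; a per-city mean
  mode is available — the nearest-sample reading is the more literal one
  and is the default). Ranking cities by their minimum attained divergence
  gives a top-m candidate set, whose top-1 is by construction contained in
  any larger top-m.
- **Average-distance prediction**: given any sample × sample distance
  matrix (the package computes qualitative Kulczynski,
  1 − ½(a/(a+b) + a/(a+c)) over presence/absence counts, and Bray–Curtis;
  externally produced matrices load from TSV), a query is assigned the city
  with the smallest mean distance to its labelled samples. Leave-one-out
  mode excludes a labelled query from its own reference set, so its zero
  self-distance never votes. Ties break lexicographically with a warning.

## Taxonomy-free k-mer path

Reads that no reference database can classify still carry signal; the k-mer
path skips taxonomic assignment entirely. Per sample, all length-31 windows
over A/C/G/T are counted (windows containing any other symbol are skipped);
counting is canonical by default — each window folds onto the lexicographic
minimum of itself and its reverse complement, since shotgun reads come from
either strand — with a literal mode kept for cross-checking against the
enumeration oracle. K-mers below a per-sample count threshold (default 20,
overridable per sample for deeper libraries) are dropped; the assembled
matrix then drops k-mers present in fewer than 10% of samples (threshold
inclusive) and rows are normalised to sum to 1. The result feeds the same
ensemble as the taxonomic tables. This is a desk-scale implementation: it
holds count maps in memory and makes no attempt at the external-memory
scale of dedicated k-mer counters.

## Synthetic data

The generator defines the conditions under which every claim in the test
suite is checked. Its model: a shared baseline log-abundance vector (iid
N(0,1) over taxa); each city adds `signature_log_fold` (default 2.0) to its
`n_signature_taxa_per_city` (default 10) signature taxa; city profile
π_c = softmax(baseline + effects); each sample draws a composition from
Dirichlet(`dirichlet_concentration` · π_c) (default concentration 100,
giving heavy within-city overdispersion and overlapping city clouds) and
counts from Multinomial(library size), with library sizes uniform on
5,000–20,000. The reference scenario is four cities with 40/20/20/8
samples and 300 taxa — the 8-sample city plays the minority role, and
cities 1 and 2 form a confusable pair sharing 60% of their signatures,
emulating the geographically or microbially close city pairs that real
studies confuse. Lineage strings follow a fixed 7-rank template with
clade counts doubling per rank (powers of two keep the nesting exact) over
a seed-shuffled taxon order; species names are unique.

Read fixtures for the k-mer path embed one random 31-base marker per city
into each read with probability 0.3 (rate 1.0 available for forced
constructions); everything else in a read is uniform random sequence. At
200 reads × 100 bp per sample, marker k-mers occur ≈ 60 times per sample
while random 31-mers almost never repeat, so the count filter (≥ 20)
isolates the markers — a deliberate, interpretable caricature of a
fingerprint.

What the generator does **not** emulate: real taxon co-occurrence and
phylogenetic correlation, sequencing error, batch effects, library-size
confounding with class, or any quality-score structure in reads. Passing
tests therefore demonstrate the machinery's correctness and its claimed
relative behaviours (ensemble tracks best candidate; weighting helps the
minority; signal strength orders performance) under a known generative
model — not absolute performance on real metagenomes.

All randomness descends from one integer seed through
`numpy.random.SeedSequence` spawning; identical configurations are
bit-reproducible.

## Numerical choices and degenerate inputs

- Relative-mode rows must sum to 1 within 1e-9; renormalisation guarantees
  it exactly up to floating error.
- κ raises on P_E = 1; MAUC skips class pairs with an empty side and
  adjusts the divisor; G-mean excludes classes absent from the truth.
- Precision of a never-predicted class is null, not 0.
- Bootstrap draws are rejection-sampled (advance the seed, redraw) until
  the bag covers all classes and the OOB side holds ≥ 2 classes, with a
  bounded retry count.
- Footrule objective ties break by lexicographic candidate id, then
  declaration order; within-list measure ties keep declaration order.
- A candidate whose fit fails on one bootstrap is dropped from that
  bootstrap's lists only (logged); the run fails only if all candidates do.

## Problem sizes and measurement resolution

Test-suite and acceptance-script computations run the reference scenario
(88 samples × 300 taxa) with N = 5–20 bootstraps and the five-candidate
roster, 3–10 seeds per claim, and the k-mer path at 12 samples × 200 reads.
These sizes make every statistical claim checkable in minutes on one core
while leaving each effect (signal, imbalance, overdispersion) large enough
to measure; the construction itself is size-agnostic.

One measurement principle matters at this scale: held-out κ moves by
roughly 2/n_test per misclassification, so a comparison band of ±0.05
cannot be resolved on an 18-sample (20%) test split, where a single error
costs ~0.075. Comparisons between the ensemble and its candidates are
therefore evaluated on a large independent draw from the same city
profiles (50 samples per city, κ quantum ~0.013) while training stays at
the reference 40/20/20/8 sizes. The generator makes this free: the same
ground truth can emit as many evaluation samples as the measurement
requires.

## Known limitations

- Desk scale only: dense matrices inside the ensemble, in-memory k-mer
  maps.
- No hyperparameter tuning, no probability calibration of votes, no
  confidence intervals on reported measures.
- The HFE-style hierarchical feature engineering step is out of scope; any
  externally reduced table enters through the same reader.
- The KL predictor's nearest-sample reading and the unstated GaussNoise
  noise scale are package choices where the underlying procedure is
  ambiguous; both are flagged and configurable.
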