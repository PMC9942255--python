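# Methods

This note documents the models, defaults and numerical choices behind
`spscreen`, and what the synthetic tests do and do not demonstrate.

## Domain model

A signal peptide is represented as an amino-acid sequence with three region
boundaries (`n_end`, `h_end`, `c_end`), 0-based and half-open: N = [0,
n_end), H = [n_end, h_end), C = [h_end, c_end), and Ac = [c_end, c_end+3)
— the first three residues of the mature protein. The signal-peptidase
cleavage site lies between `c_end − 1` and `c_end`, so the biological −3/−1
positions are `aa_seq[c_end−3]` and `aa_seq[c_end−1]`. "SP" as a feature
scope means N+H+C, excluding Ac: the Ac residues belong to the mature
protein and carry their own features. Region boundaries are *inputs* (a TSV
sidecar); the package does not predict them from sequence — boundary
provenance (e.g. an external predictor plus curation) is upstream of this
toolkit.

## Scoring model

Bin counts are modelled as read draws out of B = 10 sorting gates. Three
operations, composable and individually testable:

* **Occupancy normalization** — counts in bin b are scaled by N̄/N_b, where
  N_b is the number of sorted compartments in bin b and N̄ their mean. The
  reference point (mean occupancy) is a convention; any uniform choice gives
  WA values identical up to the per-row renormalization, and the reference
  is configurable.
* **Informativeness filter** — a variant is kept iff its most populated bin
  holds ≥ 255 raw reads. The filter is applied to *raw* counts by default
  because the threshold is a sequencing-depth criterion; a flag switches it
  to post-normalization counts.
* **WA** — Σ_b b·f_b over relative frequencies; bins are equidistant with
  value = index. Non-integer bin values are supported via configuration.

WA is invariant under uniform rescaling of a row, strictly increasing when
reads move to higher bins, and bounded in [1, B].

## Feature encoding

All residue scales ship as two-column TSV data files and are overridable:
Kyte–Doolittle hydropathy (GRAVY), the Boman protein-interaction index,
Vihinen normalized flexibility, an Ez-style membrane-insertion potential,
and the EMBOSS pKa set for the isoelectric point. The Ez table is a coarse
well-depth parameterization of a depth-dependent potential (hydrophobics
negative, charged residues positive); it is a stand-in scale, clearly
swappable, and none of the package's guarantees depend on its exact values.
Net charge uses integer side-chain counting ((#R+#K) − (#D+#E), His
neutral); the pH-dependent alternative is available through `charge_at_ph`.
The pI is the bisection root of the Henderson–Hasselbalch net charge on
[0, 14] to 1e−3, verified in tests against a dense grid search.

Codon-level features: CAI is the geometric mean of RSCU-derived weights
(w = codon frequency / max frequency within its synonymous family), with
Met/Trp and stop codons excluded; the packaged codon-usage reference is a
genome-wide *B. subtilis*-style table and is configurable, and provenance
(which table produced a matrix) is the user's to track when overriding. The
folding proxy is a Nussinov-style base-pair maximization (WC + GU pairs,
minimum hairpin loop 3) returning the negated pair count so that "more
folding" is more negative, mirroring an energy; a thermodynamic backend
(e.g. an external RNAfold binary) can be plugged in as a callable. The
`amyQ_mfe_SP` feature folds the SP coding sequence plus a downstream window
(default 50 nt) of the fusion gene, truncated to the available sequence.

The 40 cleavage-site dummies one-hot encode the residues at −3 and −1
(ASCII names `-3_X`, `-1_X`); exactly two are 1 for any valid record.

## Feature selection

Zero-variance columns are dropped first. The remainder is partitioned at
|Pearson r| > 0.7 (Spearman available): features exceeding the threshold
with at least one other feature go to clustering. Affinity propagation is
implemented deterministically — responsibility/availability updates with
damping 0.5, preference = median similarity, similarity = negative squared
Euclidean distance between z-scored columns — with convergence declared
after 15 iterations of stable exemplars, and a final within-cluster
refinement of each exemplar. Unlike implementations that add random noise
to break ties, a fully degenerate block (all pairwise distances equal, e.g.
duplicated columns) is returned as a single cluster with the first column
as exemplar. "Centroid" and "exemplar" are treated as synonyms. Manual
exceptions (keep a whole cluster, keep extra members) are explicit
configuration overrides, never heuristics. The dummies bypass selection and
are appended unchanged.

## Model

Train/test splitting uses the Kennard–Stone maximin algorithm on z-scored
features (mixed units make raw Euclidean distances meaningless): seed with
the most distant pair, then repeatedly add the point whose minimal distance
to the selected set is largest, ties resolved to the lowest row index. The
training fraction is a configuration knob (examples here use 0.7).

The regressor is a random forest with defaults n_estimators = 75,
max_depth = 25, min_samples_leaf = 1e−4 and min_samples_split = 1e−3 as
fractions of the training set (resolved as ceil(fraction × n)), bootstrap
on. `max_features` defaults to `None` (all features): an explicit count
equal to the full feature-set size selects the same behaviour, and a
hard-coded integer would fail on smaller matrices. The fitted ensemble is
exported as backend-independent tree structures (children, split feature,
threshold, node value, training coverage) with nested-node JSON
serialization, so saved models predict and explain without the training
backend. Grid search is a seeded shuffled k-fold (default k = 5) minimizing
validation MSE with first-in-grid tie-breaking.

## Explanation

Attributions are path-dependent tree-Shapley values: the conditional
expectation of a tree given a feature coalition follows the input at splits
on known features and splits cover-proportionally otherwise, and the
algorithm aggregates all coalition weights in one traversal per tree
(polynomial time). Consequences: the base value equals the cover-weighted
mean training prediction, and local accuracy (base + Σφ = prediction) is
exact. Pairwise interaction values are computed by running the same kernel
with one feature conditioned present vs absent: Φ_ij = ½(φ_j | i present −
φ_j | i absent), symmetrized, with main effects on the diagonal so each row
sums to the feature's attribution. An exponential brute-force
implementation (explicit coalition enumeration over the same conditional
expectation) ships in the package, gated to ≤ 14 features, as the oracle;
randomized tests require agreement ≤ 1e−6. The sign convention is: positive
attributions push toward higher WA, i.e. *worse* secretion.

The kernel is numba-compiled with a pure-Python fallback; results are
identical either way.

## Generator

Seven dictionaries map residues to relative frequencies: N-region body
(initial Met excluded), H, C body (last three residues excluded), the −3,
−2 and −1 positions individually, and the pooled Ac positions. Region
lengths are uniform over N body 1–10 (+Met), H 9–16, C body 4–11 (+3 site
residues), Ac = 3; the length law is a modelling choice (the region
composition, not the length distribution, is the matching target). Regions
are sampled independently; batch size defaults to 10,000.

Batch acceptance compares per-sequence feature distributions (length, four
scale aggregates, net charge, pI, 20 residue frequencies — 27 features, all
composition-based and vectorized) between batch and reference with the
two-sample KS test: D is the ECDF supremum, and the p-value is asymptotic
(Kolmogorov distribution at √(n_a·n_b/(n_a+n_b))·D). A batch is accepted
when at least 21/16/18/17 features (N/H/C/Ac) have p > 0.1; the feature
list and thresholds are configuration, since thresholds are only meaningful
relative to an explicit list. Assembled SPs of total length ≥ 33 through
the Ac region are discarded. Retro-translation uses the most frequent codon
per residue (ties: lexicographically smallest), so translation exactly
inverts it.

## Synthetic screen

The simulator emulates the pipeline's inputs. Reference SPs draw from
region-specific residue pools (K/R-enriched N, hydrophobic H, polar C with
an Ala-X-Ala-biased site) with usage-weighted codons. The designed library
edits one feature at a time (N charge ±k, H hydrophobicity via residue
swaps, H length ±k, −1 substitution), skipping infeasible edits.

Bin probabilities per SP are a Gaussian evaluated at the bin indices,
centered on the truth-function value with dispersion σ (default 1 WA),
renormalized; read probabilities are additionally proportional to per-bin
occupancy, so occupancy normalization is genuinely needed to recover truth.
The *returned ground truth is the expected binned WA* (Σ b·p_b), not the
continuous center: a distribution snapped to integer bins cannot have its
WA converge to an arbitrary center as σ → 0, and edge bins truncate the
Gaussian. Under this definition the multinomial WA estimator is exactly
unbiased, and the truth map remains a monotone transform of the underlying
truth function, so rank-based recovery statements are unaffected.

The default truth function is a clipped affine-logistic combination,
WA = 1 + 9·σ(0.5 + 1.2·(GRAVY_SP − 1)² − 0.4·Charge_N − 1.5·[−1 is Ala]),
encoding a hydrophobicity optimum near GRAVY 1, a benefit of positive
N-region charge, and a benefit of Ala at −1. Truth functions are registered
by name so analyses can cite them unambiguously.

**What passing tests show — and don't.** Parameter recovery on this
simulator demonstrates that the pipeline's statistics (WA estimation,
selection, forest, Shapley ranking) are internally correct and can recover
known effects at realistic read depths. It does not validate the biology:
real screens have correlated noise, growth effects, occupancy statistics
and epistasis the simulator deliberately omits. One subtlety is inherent to
*any* collinearity-aware pipeline: when a truth feature lands in a
correlation cluster, the model can only credit the cluster's selected
representative, so recovery is asserted for the representative of each
truth feature (the report records the mapping).

## Problem sizes and determinism

Default analysis sizes used in the examples and the automated checks:
500-variant screens at 2000 reads/SP for recovery analyses, 10,000-sequence
generator batches, forests of 75 trees. These run in seconds to a few
minutes on a single core. Every stochastic component takes an explicit seed
or `numpy.random.Generator`; identical seeds give bit-identical outputs,
which the end-to-end manifest (input hashes, config snapshot, output
hashes) makes checkable.

## Known limitations

* Exact descriptor definitions for some named features in published screens
  (e.g. composite "flexibility and charge" measures) are not public; this
  package uses the standard published scales and flags them as defaults.
* The Ez scale is an approximate well-depth parameterization.
* The folding proxy counts base pairs; it correlates with, but is not, a
  free energy. Use the pluggable thermodynamic backend when energies in
  kcal/mol matter.
* Affinity propagation exemplars can differ between implementations on
  noisy, weakly separated data; agreement with the scikit-learn reference
  is asserted on separated toy cases only.
* The interventional (background-dataset) Shapley formulation is not
  implemented; attributions are path-dependent, weighted by training
  coverage.
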