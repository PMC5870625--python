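# Methods

This note documents the statistical machinery in `kinfer`, the design
choices behind it, and what the synthetic testbed does and does not show
about real mass-spectrometry data.

## Preprocessing (`kinfer.io`)

Peptide-level observations are collapsed to a site × condition log2
fold-change matrix in a fixed order: (i) non-canonical-transcript records
are dropped; (ii) multiply phosphorylated peptides are dropped, so that a
fold change is attributable to a single site; (iii) fold changes are
averaged across replicates of the same peptide and condition; (iv) then
across distinct peptide variants covering the same site; (v) conditions
quantifying fewer than `min_coverage` sites (default 1000) are removed.
Replicate averaging precedes peptide-variant averaging, which matters only
when replicate counts differ between variants (a mean of per-variant means
is not the flat mean); the peptide identity column is optional, and without
it both averaging steps coincide. The coverage filter counts post-collapse
quantified sites, reading "quantified phosphopeptides" as the number of
usable site-level quantifications.

**Quantile normalization with missing values.** MS matrices are ragged, so
classical complete-case quantile normalization does not apply directly.
Each condition's observed values are ranked (average ranks on ties) and
mapped at their rank quantiles (r − 0.5)/n onto a reference distribution —
the across-condition mean of each condition's sorted values interpolated to
a common grid whose length is the largest observed count. Missing entries
stay missing. Conditions with equal observed counts therefore acquire
identical sorted values (exactly the classical behaviour on complete
matrices); conditions with unequal counts are interpolated, which is the
standard compromise for ragged matrices.

## Inference methods (`kinfer.inference`)

All methods score one kinase in one condition from the vector of quantified
fold changes. Matching between network and matrix is by (protein, position)
only, because phosphoacceptor annotations frequently disagree between
resources; a residue mismatch is warned, not fatal.

- **Z-test**: z = (m_S − m_P)√n_S/δ against the mean and *sample* standard
  deviation of **all** fold changes in the condition (substrates included —
  the background is the full condition). At the ≥1000-site coverage this
  choice of ddof is numerically irrelevant but is documented for exactness.
- **KS and Wilcoxon**: substrates versus non-substrates. The Wilcoxon uses
  the normal approximation with average ranks, the tie-corrected variance
  and a 0.5 continuity correction (the convention of the standard R/scipy
  routines). The KS p uses Smirnov's finite-size form
  `kstwo.sf(D, round(n1·n2/(n1+n2)))` rather than the limiting Kolmogorov
  distribution: with 10–40 substrates against ~2000 background sites the
  limiting form is measurably miscalibrated (its null p-values fail a
  uniformity test), while the finite-size form—which is also what scipy's
  asymptotic mode computes—is calibrated.
- **KSEA/GSEA**: sites are ranked by fold change descending (stable sort;
  input order breaks ties). The running sum gains |fc|^w / N_R at substrate
  ranks (w = 1, N_R = Σ_substrates |fc|^w) and loses 1/(N − n_S) elsewhere;
  the ES is the signed maximum deviation, which occurs immediately before
  or after a substrate rank — the implementation evaluates only those 2·n_S
  candidate points, vectorized over permutations. Equal-magnitude ties
  between a positive and a negative extremum resolve to the one reached
  first along the list, matching a sequential scan. The two-sided empirical
  p is (1 + #{|ES_null| ≥ |ES|})/(1 + n_perm) over uniform random same-size
  site sets; the +1 pseudo-count keeps p positive. An exhaustive-enumeration
  null is available for small instances. Because the null distribution
  depends only on the condition's ranked fold changes and the substrate
  count, the driver caches one null sample per (condition, n_S) and shares
  it across kinases; the weighted variant re-ranks per kinase and therefore
  draws per-kinase nulls.
- **MLR**: ridge regression of the condition's fold changes on the binary
  site × kinase connectivity matrix, minimizing ‖Y − Xβ‖² + λ‖β‖² with
  λ = 0.1, no intercept (fold changes are already relative quantities) and
  no scaling of λ by sample count. Fitted with scikit-learn's Ridge; the
  closed form (XᵀX + λI)⁻¹XᵀY is kept as an independent oracle in the
  tests. All kinases are fitted jointly, so collinear regulons share
  credit — the L2 penalty is what keeps that assignment stable.

**Signed activity scores.** For the test-based methods the reported score
is sign(m_S)·(−log10 p); for the MLR it is β. Pairs with zero quantified
substrates produce *no* score — absence is distinct from a zero score, and
benchmark evaluation drops unscored pairs from both label sets with counts
recorded.

**Randomness contract.** Every stochastic operation takes an explicit seed
or Generator. The driver derives one substream per condition and per
(condition, regulon size) from the master seed, so results are invariant to
the order in which kinases are scored.

## Sequence specificity (`kinfer.specificity`)

Flanking windows are ±7 residues around the phosphoacceptor (length 15),
padded with `_` at protein termini. The PWM alphabet is the 20 amino acids
plus the padding symbol (K = 21, natural log); the central position is
included (it carries the S/T versus Y distinction). Frequencies use a
per-cell pseudocount of 0.01 — small enough not to distort informative
columns, large enough to keep the information vector and MSS defined for
10-sequence regulons. The information content is
I(i) = Σ_b f(i,b)·ln(K·f(i,b)), which is ln K for a single-letter column at
pseudocount 0 and ≈0 for a uniform column. The MSS of a window is the
information-weighted, min–max normalized match
(Current − Min)/(Max − Min) ∈ [0, 1]; a zero-information matrix scores 1 by
convention (no preference means no penalty). MSS is invariant to rescaling
I and monotone under single-letter improvements, and both properties are
tested. PWMs are built from **all** known substrate flanks of a kinase (not
only the sites quantified in a given condition), and only for kinases with
at least 10 usable flanks. The exact pseudocount and padding policy of
other MATCH-style reimplementations vary; ours is documented here rather
than asserted to be identical to any of them.

## Benchmarking (`kinfer.benchmark`)

The classifier score is |signed score|: the benchmark asks whether expected
regulations rank above random kinase–condition pairs in *magnitude*; the
expected direction feeds only the separate direction-accuracy report.
Negative pairs are sampled uniformly without replacement from the gold
standard's kinase × condition grid minus the positives, matched in number
to the positives, independently for each of the (default 60)
randomizations. ROC curves group tied scores into a single threshold step,
making the trapezoidal AUC equal the Mann–Whitney concordance probability
(tested to 1e-10). Precision at recall 0.5 is read at the smallest achieved
recall ≥ 0.5; if that recall is unreachable (possible only when positives
outnumber scored pairs) the result is flagged and the precision at maximum
recall reported. Summary statistics are medians over randomizations.
Stratified runs (≤5 versus >5 quantified substrates; evidence classes;
down-sampled regulons) reuse the same machinery; stratum negatives are
drawn from the stratum's own kinases and conditions.

## Synthetic studies (`kinfer.simulate`)

The generator emulates the statistical structure the inference methods
assume, with known ground truth. Background fold changes are i.i.d.
Normal(0, σ²); each condition designates `regulated_per_condition` kinases
whose regulon sites receive an additive shift ±δ (direction Bernoulli
`direction_mix`); entries are masked missing completely at random. Default
design: 2000 sites, 20 kinases with regulon sizes uniform in 10–40
(curated-database scale), 10 conditions × 2 regulated kinases, δ = 2,
σ = 1, 10% missingness. Each site lives on its own synthetic 15-residue
protein with the acceptor at position 8, so flank extraction runs without
inventing gene models; substrate windows follow their kinase's random
consensus letter-wise with probability `motif_strength` (default 0.9), and
a substrate's residue is always its kinase's consensus acceptor. With
`scale_signal_by_mss` the true shift of each substrate site is multiplied
by that site's MSS against its kinase's PWM, creating the regime in which
motif weighting genuinely helps.

What this testbed does **not** model: intensity-dependent missingness,
replicate-level variance structure, correlated background (shared pathways,
batch effects), heavy-tailed MS noise, and regulons whose annotation is
partly wrong. Passing tests therefore demonstrate correctness and
calibration of the statistics under the stated model, and qualitative
behaviours (power ordering, weighting benefit, randomization controls) —
not quantitative performance on real studies.

## Numerical and design choices

- Ranking ties: average ranks (Wilcoxon, quantile normalization); stable
  descending sort for KSEA.
- p-values are clipped into (0, 1] — the empirical null's pseudo-count and
  the clip guard the −log10 transform.
- Degenerate inputs raise typed errors rather than returning silent zeros:
  zero background SD, all-zero substrate fold changes, a regulon covering
  every quantified site, an empty connectivity matrix.
- Degree-preserving randomization samples each kinase independently and
  without replacement within a kinase; two kinases may share sites, as in
  the curated network.
- The network container enforces uniqueness on (kinase, protein, position,
  evidence); regulons deduplicate on (protein, position).
- The in_silico evidence class accepts an optional prediction-score cutoff
  (`filter_evidence(..., min_score=...)`), off by default.
- The shipped gold-standard fixture transcribes the published table of
  expected human kinase regulations (87 kinase–perturbation pairs across
  30 kinases); benchmarking real studies additionally requires their
  quantification tables, which are deliberately out of scope.

## Problem sizes in the validation suite

The test suite validates oracle equivalence on hundreds of random small
instances; null calibration on a 2000-site × 100-condition pure-noise study
(2000 p-value draws per method; KSEA at 250 permutations, whose p-value
granularity of 1/251 is far below the uniformity test's resolution); signal
recovery and weighting comparisons over 20 simulation seeds at the default
design with 250–500-permutation nulls; and the randomization control over
10 seeds pooling 60 negative-set randomizations each. These sizes were
chosen so the sampling error of each checked quantity is several times
smaller than the margin being asserted.
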