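# Methods

`coessnet` builds functional-interaction ("coessentiality") networks from
gene × cell-line CRISPR knockout fitness matrices and evaluates them
against pathway annotation. This note records the models, the defaults
and why they were chosen, the numerical conventions, and what the
synthetic benchmark does and does not demonstrate.

## The model

Genes operating in the same pathway tend to have similar knockout fitness
profiles across a diverse panel of cell lines. The pipeline therefore
treats the matrix X (genes × cell lines) of fitness scores — Bayes
Factors, Ceres/Chronos gene effects, or Z-scores; the pipeline is
agnostic — as a collection of gene profile vectors and scores all
unordered gene pairs by profile similarity. Three confounders are
addressed before similarity is measured:

1. **Screen-quality variance differences** between cell lines — handled by
   quantile normalization to the rank mean: within each cell line, genes
   are ranked, the mean score at each rank across cell lines replaces the
   value at that rank, and the original order is restored. Every column
   ends up with the identical value multiset.
2. **Artifactual components** visible in genes that should have no fitness
   effect — handled by removing the top right-singular vectors (sample
   space components, default 4) of the column-centered control-gene
   submatrix (classically olfactory receptors) from the whole matrix.
3. **Correlated cell lines** — tissue overrepresentation makes samples
   statistically dependent and inflates correlations between unrelated
   genes. Whitening ("sphering") removes it: with Σ the cell-line ×
   cell-line covariance estimated over genes, a transform W with
   W Σ Wᵀ = I is applied to every (centered) gene profile, so the
   transformed matrix has identity sample covariance. Two standard
   constructions are provided — W = Lᵀ from the Cholesky factorization
   Σ⁻¹ = LLᵀ, and W = D^(−1/2)Eᵀ from the eigendecomposition Σ = EDEᵀ.
   They differ by a rotation and whiten identically.

Similarity is the Pearson correlation ρ = cov(x, y)/(σₓσᵧ) of two gene
profiles, or equivalently per-pair ordinary least squares y = bx + c
scored by the slope's two-sided t-test with n − 2 degrees of freedom
(whitening + OLS is the generalized-least-squares construction). Because
the slope t statistic is t = ρ√((n−2)/(1−ρ²)), any P-value ranking is a
fixed monotone function of |ρ| at fixed n; `coessnet` ranks OLS pairs by
sign(slope)·(−log₁₀P), which is a strictly increasing function of ρ, so
the OLS and Pearson rankings coincide by construction. The practical
consequence is that the correlation matrix (one vectorized operation) is
the cheap and exact substitute for fitting every pair.

Ranking is by *signed* score descending: coessentiality is positive
co-dependency, and negative correlation is a different signal (it marks
mutually exclusive dependencies, used by the moonlighting scan), not a
weaker positive. `absolute=True` ranks by magnitude instead.

## Evaluation: log-likelihood scoring

A network's top pairs are compared to a pathway reference (GMT). A pair
is a true positive if both genes share a pathway, a false positive if
both are annotated but share none, and uncounted if either gene is
unannotated. The score

LLS = log₂[ (TP/FP) / (background_pos/background_neg) ]

compares the sample odds to the odds over all unordered annotated gene
pairs in the reference. Defaults follow common practice for this
benchmark: pathways filtered to 5–400 genes; the top 50,000 pairs scored
in bins of 1,000, cumulatively and locally; name-based exclusion of
mitochondrial-translation / oxidative-phosphorylation pathways is
supported because those few very large sets contribute a quadratic number
of "true positive" pairs and inflate apparent accuracy. Recall at a
threshold (e.g. the enrichment level of the hu.MAP 2.0 protein-complex
map) is the pooled pair/gene count at the last bin whose cumulative LLS
still meets the threshold — a deterministic, monotone-friendly reading of
"the bin where the score is approximately equal to the threshold".

Numerical conventions: a 0.5 pseudocount is added to TP and FP only when
one of them is zero, so non-degenerate scores are exactly the formula
above; a bin with no annotated pair has local LLS = NaN; P-values that
underflow are capped at the smallest positive double before logs; ranking
ties are broken lexicographically by gene pair for determinism.

## Moonlighting trios

A gene x whose partner differs by context (x tracks y in one subset of
lines and z in a disjoint subset, with y and z mutually exclusive) has
both marginal correlations diluted. The first-order partial correlation

ρ_{x,y|z} = (ρ_{xy} − ρ_{xz}ρ_{yz}) / √((1−ρ²_{xz})(1−ρ²_{yz}))

removes the co-parent's effect. A trio is called when ρ_{xy} and ρ_{xz}
exceed the gate (default 0.15), ρ_{yz} < 0, and both partial correlations
strictly exceed their marginals; the boost is reported as the squared
ratio ρ²_{x,y|z}/ρ²_{xy}.

Two properties of this criterion are worth recording. First, for the
required sign pattern (both marginals positive, parents negative) the
algebra makes both "boost" inequalities automatic, so the selectivity of
the scan rests entirely on the correlation gate and the sign pattern; the
`min_boost` option (default 1, i.e. any strict boost) exists to demand a
minimum effect size. Second, the gate is a statement about sampling
noise: at ~700 cell lines the null spread of ρ is ≈ 1/√n ≈ 0.037 and
0.15 is a ≈ 4σ event, while at 60 samples the null spread is ≈ 0.13 and
0.15 filters almost nothing. The default gate is therefore calibrated to
a DepMap-sized cohort, and the trio benchmarks in this package run the
generator at 730 samples; with small panels the gate should be raised.
The scan also assumes its input correlations come from covariance-
normalized data — on unwhitened data, tissue structure can manufacture
the sign pattern.

## The synthetic generator

`synthetic_data.generate` plants the three structures the pipeline is
built to exploit or remove:

* **modules** — groups of genes sharing a per-sample latent factor
  (loading `module_effect`), emulating pathway coessentiality;
* **sample blocks** — groups of cell lines sharing per-gene latent
  offsets (loading `sample_block_effect`), emulating tissue
  overrepresentation: the cell-line covariance acquires block structure
  and unrelated genes acquire spurious correlation, which whitening
  removes;
* **trios** — parent y is "essential" (score −μ with line-to-line
  variation of sd μ, μ = `trio_effect`) in the first half of samples and
  silent in the second, parent z the reverse, and moonlighter x copies
  whichever parent is active, plus its own noise.

Defaults are the desk-scale study condition used throughout the tests:
400 genes × 60 cell lines, 10 modules of 10 genes, blocks of 40/10/10
lines (deliberately imbalanced), 3 trios, all effect loadings 1.0 and
i.i.d. noise sd 0.5 (signal-to-noise 2). One seeded generator drives all
draws, so a spec + seed reproduces the matrix bitwise.

What the generator does *not* emulate: copy-number artifacts, gRNA-level
noise, missingness, heavy-tailed score distributions, overlapping
pathways, and modules coupled to specific tissues. Passing the synthetic
benchmarks therefore demonstrates the algebraic and statistical behavior
of the pipeline (whitening contracts, ranking identities, enrichment
gains under a known confounder, trio recovery under the planted
mechanism), not performance on any real screen compendium.

Two benchmark layouts deviate from the defaults for cause:

* the *whitening-benefit* experiment uses 39 modules of 10 genes so that
  (nearly) every gene is annotated. LLS only registers a confounder if
  the confounded edges are countable as false positives; with mostly
  unannotated genes both networks reach zero FP and the comparison
  degenerates to pseudocounts. A fully annotated universe mirrors a
  genome-scale reference, where most screened genes carry annotation.
* the *trio* experiments use 730 samples (cohort scale) for the gate
  calibration reasons above, with `sample_block_effect=0` because the
  scan operates downstream of covariance normalization.

## Numerical and design choices

* Covariance orientation: Σ is cell-line × cell-line with genes as
  observations (denominator n_genes − 1), columns centered by their mean
  across genes; the same centering is applied before whitening, which
  makes the identity-covariance contract exact. Per-gene centering is
  irrelevant to ρ and to the slope t-test, both of which center
  internally.
* A relative ridge (default 10⁻⁶ × mean diagonal) is added to Σ only
  when it is not positive definite; at typical shapes (genes ≫ samples)
  it never triggers.
* Quantile-normalization ties: stable sort; tied values receive the rank
  means of the positions they occupy in input order. Ties have measure
  zero in real scores.
* Control-gene components are right singular vectors of the
  column-centered control submatrix; requesting more components than the
  submatrix rank is an error rather than silently returning zeros.
* Degenerate |ρ| = 1 controllers are skipped inside scans (duplicate
  genes would otherwise zero the partial-correlation denominator) but are
  an error in the scalar `partial_correlation`.
* Missing values: gene rows containing any missing entry are dropped at
  load time (with a warning) rather than imputed.
* Gene labels in the `SYMBOL (EntrezID)` style are reduced to the symbol
  at load time, and matrices are intersected on symbols, because pathway
  references are keyed by symbol.

## Known limitations

* All-pairs similarity is O(G²) in memory for the edge list; at
  genome scale (~18k genes, ~160M pairs) the ranking DataFrame is the
  bottleneck, and `top_k` should be applied before writing edge tables.
* The trio scan enumerates parent pairs within each candidate's
  correlation neighborhood; with permissive gates on small panels it can
  be quadratic in neighborhood size (and, per the calibration note above,
  statistically meaningless).
* LLS treats pathways as flat sets; hierarchical references (GO) are
  handled only through the size filter.
* `best_controller` maximizes the partial correlation over single
  controllers; controlling for sets of genes is out of scope.
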