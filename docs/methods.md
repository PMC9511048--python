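# Methods

## Model and assumptions

The pipeline treats an interaction as an unordered pair of proteins and asks
which annotation terms' co-occurrence patterns separate interacting pairs
from random pairs.  Its assumptions are:

* Annotations are given as flat protein→term maps.  GO annotations are used
  as provided, without propagation to ancestor terms; if propagated
  annotations are wanted they must be materialized upstream.
* Orientation of a pair is meaningless, so the encoding must be symmetric.
  Per term the channels (g₁+g₂, |g₁−g₂|) are kept; the sum channel is
  genuinely ternary (0/1/2) and is stored as such, not binarized.  Per term
  the (sum, absdiff) pair can only be (0,0), (1,1) or (2,0).
* Any unordered non-self pair that is not a known positive is a negative.
  Negatives are sampled uniformly; no degree- or annotation-matching is
  attempted.
* Proteins with neither a GO term nor a KEGG pathway carry no usable
  information and are discarded, as are interaction pairs with an
  unannotated endpoint.

## Pipeline parameters

| parameter | default | meaning |
|---|---|---|
| `score_threshold` | 0 | keep pairs with experimental score strictly greater |
| `k` | `"auto"` | number of balanced datasets; auto = ⌊negatives/positives⌋ from the full complement; an integer K instead samples K·\|positives\| negatives |
| `boruta_max_iter` | 100 | shadow-feature iterations (early stop when all features decided) |
| `boruta_alpha` | 0.05 | two-sided binomial significance, Bonferroni-corrected over the feature count |
| `boruta_trees` | 100 | trees per random forest |
| `boruta_tentative_policy` | `reject` | undecided features at termination are dropped; `median` accepts those whose median importance beats the median shadow maximum |
| `lasso_alpha` | 0.01 | L1 penalty weight; features are standardized first so coefficient magnitudes are comparable |
| `gbdt_trees` | 100 | LightGBM estimators; importance is split count |
| `mrmr_top_k` | 500 | greedy mRMR picks before the id-ordered tail (mRMR is quadratic in ranked features) |
| `top_n` | 100 | consensus-list cut for the Venn intersection |
| `seed` | 0 | master seed; every stage derives a named stream `hash(seed, stage, dataset)` |

The L1 ranker is the regression-form lasso applied to 0/1 labels (not
logistic regression): coefficients on standardized columns are the
importance measure, zero-coefficient features fall to an id-ordered tail.
Mutual information for mRMR is the empirical plug-in estimate on the
discrete {0,1,2} alphabet in natural-log units; the difference criterion
I(f;y) − mean_{s∈S} I(f;s) is used (not the quotient form).  Criterion
values within 1e-9 are treated as ties and broken by ascending feature id —
as are ties everywhere else — so every ranked list is deterministic.

In the consensus score, ranks originate at 1 and a feature absent from every
list is excluded (its weight would be 0 and its score undefined); with a
non-divisible negative pool the K subset sizes differ by at most one, the
remainder going to the first subsets.

## The synthetic generator

`SyntheticConfig` defaults define the desk-scale study conditions used by
the test suite and the acceptance script: 500 proteins, 200 GO + 30 KEGG
terms, 10 signal terms spanning both channels, background prevalence 0.03,
signal prevalence 0.15, 2,000 positive pairs, 20× enrichment.  Prevalences
were chosen so profiles are sparse (a protein carries ~7 background terms)
while a uniformly random pair still shares ≥1 signal term ~20% of the time,
giving the enrichment mechanism room to act; with 20× odds roughly 80% of
positives share a signal term.  Positives are drawn by rejection sampling
(a sharing candidate is accepted with odds `enrichment` times those of a
non-sharing candidate), which scales without materializing all C(n,2) pairs;
`enrichment = 1` accepts every candidate and therefore plants nothing.

What the generator does **not** emulate: ontology DAG structure and term
co-occurrence correlations, protein degree heterogeneity, annotation
incompleteness bias, or sequence-level redundancy.  Passing recovery tests
therefore show the machinery extracts planted co-annotation signal under
class balance — not that real interactomes are this easy.

## Null controls and evaluation

`recovery_rate` counts planted terms with ≥1 derived feature (sum or
absdiff channel) in a list's top-N.  `rank_separation` assigns every feature
of the universe its 1-based consensus rank (absent features get worst+1) and
compares signal vs background mean ranks with a label-permutation test.

For the matched null the generator is run with `enrichment = 1` **and**
signal prevalence equal to background prevalence, so the designated signal
terms are fully exchangeable with background terms; otherwise the prevalence
difference alone is planted marginal structure (higher-entropy features
carry, e.g., larger plug-in MI bias and more tree-split opportunities) and
would confound a test whose null is exchangeability.  Under the null the
relevance filter correctly selects ~nothing, which leaves no ranked lists to
compare, so the null run bypasses the filter and ranks all features — the
separation statistic is then measurable and should be (and is tested to be)
consistent with chance.

## Numerical and design choices

* Desk-scale runs (tests, acceptance script) use 30 filter iterations and
  64-tree forests: with the binomial decision rule noise features are
  rejected around iteration 15 and the loop early-stops, so further
  iterations change nothing at these problem sizes.
* The filter's random forest consumes a dense float32 copy of the (small)
  per-dataset matrix; the encoded matrices themselves are CSR sparse.
* Shadow matrices are padded to at least 5 columns so the max-shadow null is
  not degenerate on tiny inputs.
* Output TSVs fix column order, sort order and float formatting (`%.10g`),
  so identical configuration and seed reproduce byte-identical files.
* Degenerate inputs: single-class labels and all-constant matrices are
  rejected/returned-empty with a warning; a gradient-boosting fit with no
  splits yields an all-tie list in feature-id order.

## Known limitations

* LightGBM split selection breaks gain ties by column order, so the gbdt
  ranking of near-tied (noise) features is not exactly
  permutation-equivariant; the lasso and mRMR rankings are.  Split-count
  importance also saturates for a near-perfect binary feature (one split per
  tree suffices), so it under-ranks such features relative to gain-based
  measures.
* mRMR cost grows quadratically in the number of ranked features;
  `mrmr_top_k` caps the greedy phase at large scale.
* The per-dataset filter/rank stages run sequentially; results are defined
  to be independent of execution order (per-dataset seeds are derived, not
  drawn from a shared stream), so parallel execution would be safe but is
  not implemented.
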