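"""Filter pair features with the shadow-feature loop, then rank them.

The filter appends a shuffled copy of every feature, fits a random forest,
and keeps features that repeatedly beat the best shuffled (shadow) feature.
The survivors are ranked three ways: L1 coefficients, boosted-tree split
counts, and greedy max-relevance min-redundancy.
"""

from ppiterms import (
    SyntheticConfig,
    boruta_filter,
    build_datasets,
    encode_dataset,
    gbdt_rank,
    generate,
    lasso_rank,
    mrmr_rank,
    num_subsets,
    partition,
    profiles_by_id,
    sample_negatives,
)

cfg = SyntheticConfig(n_proteins=150, n_go=60, n_kegg=12, n_signal=5,
                      n_pos=400, enrichment=20.0, seed=7)
catalog, profiles, positives, truth = generate(cfg)
pmap = profiles_by_id(profiles)

negatives = sample_negatives(sorted(pmap), positives, len(positives), seed=7)
datasets = build_datasets(positives, partition(negatives, 1, seed=7))
matrix = encode_dataset(datasets[0], pmap, catalog)
print(f"encoded {matrix.n_rows} pairs x {matrix.n_features} features "
      f"({matrix.X.nnz} nonzeros)")

result = boruta_filter(matrix, max_iter=20, seed=7, n_estimators=50)
print(f"filter kept {len(result.selected)} features "
      f"after {result.n_iterations} iterations")

selected = sorted(result.selected)
X, y = matrix.X[:, selected], matrix.labels
names = {d.feature_id: d.display_name for d in matrix.descriptors}
print(f"\nplanted signal terms: {sorted(truth.signal_terms)}\n")
for ranked in (
    lasso_rank(X, y, feature_ids=selected),
    gbdt_rank(X, y, seed=7, feature_ids=selected),
    mrmr_rank(X, y, feature_ids=selected),
):
    top3 = ", ".join(names[f] for f in ranked.feature_ids[:3])
    print(f"{ranked.algorithm:5s} top-3: {top3}")
# each ranker should put sum-channels of planted terms first
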