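"""Build balanced datasets from positives and sampled negative pairs.

Negative pairs (random protein pairs that are not known interactions) vastly
outnumber positives, so the negative pool is split into K disjoint subsets
and each subset is combined with all positives into one ~1:1 dataset.
"""

import numpy as np

from ppiterms import (
    InteractionTable,
    build_datasets,
    count_all_pairs,
    num_subsets,
    partition,
    sample_negatives,
)

# at the full human-interactome scale the arithmetic reads:
n_pairs = count_all_pairs(6623)
n_pos = 70_392
print(f"6623 proteins -> {n_pairs:,} unordered pairs")
print(f"{n_pairs:,} - {n_pos:,} positives = {n_pairs - n_pos:,} negatives")
print(f"negative/positive ratio -> K = {num_subsets(n_pairs - n_pos, n_pos)} subsets\n")

# desk scale: 30 proteins, 40 positive pairs, exact negative complement
rng = np.random.default_rng(0)
proteins = [f"P{i:02d}" for i in range(30)]
pos_pairs = set()
while len(pos_pairs) < 40:
    a, b = rng.choice(proteins, size=2, replace=False)
    pos_pairs.add((min(a, b), max(a, b)))
positives = InteractionTable(pairs=sorted(pos_pairs), scores=np.ones(40))

negatives = sample_negatives(proteins, positives, "all", seed=1)
k = num_subsets(len(negatives), len(positives))
subsets = partition(negatives, k, seed=1)
datasets = build_datasets(positives, subsets)

print(f"desk scale: {len(negatives)} negatives -> K={k} subsets "
      f"of sizes {[len(s) for s in subsets][:5]}...")
ds = datasets[0]
print(f"dataset 1: {len(ds.positive_pairs)} positives + "
      f"{len(ds.negative_pairs)} negatives (~balanced)")
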