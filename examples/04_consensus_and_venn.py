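"""Aggregate per-dataset rankings with the importance score and intersect.

A feature at rank R_i(f) in the N(f) of K lists that contain it scores
M(f)/W(f), where M(f) is its mean rank over those lists and W(f) = N(f)/K.
Smaller is better: good ranks and frequent selection both lower the score.
"""

from ppiterms import RankedList, integrate, top_n, venn

K = 4
lists = {
    "lasso": [RankedList(i, "lasso", fids, [0.0] * len(fids))
              for i, fids in enumerate([[7, 3, 5], [7, 5], [3, 7], [7, 3, 5]])],
    "gbdt": [RankedList(i, "gbdt", fids, [0.0] * len(fids))
             for i, fids in enumerate([[3, 7], [7, 3], [7, 5], [7, 3]])],
    "mrmr": [RankedList(i, "mrmr", fids, [0.0] * len(fids))
             for i, fids in enumerate([[5, 7], [5, 3], [5, 7], [5, 7]])],
}

tops = {}
for alg, lsts in lists.items():
    records = integrate(lsts, K)
    print(f"{alg}:")
    for rec in records:
        print(f"  feature {rec.feature_id}: N={rec.n_f} M={rec.m_f:.2f} "
              f"W={rec.w_f:.2f} score={rec.score:.2f}")
    tops[alg] = set(top_n(records, 2))

part = venn(tops)
print(f"\ntop-2 sets: {tops}")
print(f"in all three: {sorted(part.triple)}")
print(f"in exactly two: { {f: sorted(v) for f, v in part.double.items()} }")
print(f"in exactly one: {part.single}")
# conservation: 3|triple| + 2|double| + |single| = sum of top-N sizes
assert part.conservation() == sum(len(s) for s in tops.values())
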