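"""Summarise the distance distribution over every unordered concept pair.

The summary streams over all n(n-1)/2 pairs in blocks (no pair matrix is
ever materialised), reporting running mean/SD, the most extreme pairs and
a histogram.  At the published-norms scale this is ~788 million pairs; the
same code handles both.
"""

import smdist as sd

table = sd.generate_norms_fixture(sd.FixtureSpec(n_words=300, seed=2))
summary = sd.summarize_distances(table, sd.MetricSpec("cosine"), top_k=10)

print(f"concepts:        {summary.n_concepts}")
print(f"unordered pairs: {summary.n_pairs}")
print(f"mean distance:   {summary.mean:.3f} (SD = {summary.sd:.3f})")

print("\nclosest pairs (near-identical sensorimotor profiles):")
for p in sd.extreme_pairs(summary, "smallest", 3):
    print(f"  {p.word_a} - {p.word_b}: {p.value:.4f}")

print("\nfurthest pairs (most dissimilar profiles):")
for p in sd.extreme_pairs(summary, "largest", 3):
    print(f"  {p.word_a} - {p.word_b}: {p.value:.4f}")

mass = summary.bin_counts[:30].sum() / summary.n_pairs
print(f"\n{100 * mass:.1f}% of pairs have cosine distance below 0.30")
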