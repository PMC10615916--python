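"""Find a concept's nearest sensorimotor neighbours.

Neighbours are the concepts with the smallest distance to the query -
the words experienced most similarly through the 11 perceptual and
action dimensions.  The polar-profile export gives the per-dimension
ratings behind each neighbour, in the conventional clockwise plot order.
"""

import smdist as sd

table = sd.generate_norms_fixture(sd.FixtureSpec(n_words=200, seed=3))
query = table.words[10]

result = sd.nearest_neighbours(table, query, k=5)
print(f"5 nearest neighbours of {query!r} (cosine distance):")
for rank, (word, dist) in enumerate(result.neighbours, start=1):
    print(f"  {rank}. {word}  {dist:.4f}")

profile = sd.profile_export(table, query)
print(f"\nsensorimotor profile of {query!r} (clockwise from top):")
for dim, value in zip(profile.order, profile.values):
    print(f"  {dim:14s} {value:.2f}")
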