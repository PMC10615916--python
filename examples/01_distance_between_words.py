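"""Compute sensorimotor distance between pairs of concepts.

Builds a small synthetic norms table (11 sensorimotor ratings per word,
0-5 scale), then compares words under all five metrics.  Smaller values
mean the two concepts are experienced more similarly through perception
and action.
"""

import smdist as sd

table = sd.generate_norms_fixture(sd.FixtureSpec(n_words=50, seed=1))
ctx = sd.estimate_covariance(table)

w1, w2 = table.words[0], table.words[1]
print(f"distances between {w1!r} and {w2!r}:")
for kind in ("cosine", "correlation", "euclidean", "minkowski3", "mahalanobis"):
    spec = sd.MetricSpec(kind, context=ctx if kind == "mahalanobis" else None)
    d = sd.metric_distance(table.get_vector(w1), table.get_vector(w2), spec)
    print(f"  {kind:12s} {d:.4f}")

# cosine distance is the principal measure: 0 = same direction in rating
# space (same sensorimotor profile shape), 1 = orthogonal profiles.
d = sd.cosine_distance(table.get_vector(w1), table.get_vector(w2))
print(f"\ncosine distance {d:.4f}: "
      f"{'similar' if d < 0.1 else 'moderately distinct'} sensorimotor profiles")
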