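"""Project selected concepts into 2-D while preserving their distances.

The layout minimises Sammon stress: a weighted sum of squared
discrepancies between the input sensorimotor distances and the 2-D
Euclidean distances.  Low stress means the plane is a faithful picture
of the pairwise distances; coordinates are reproducible given the seed.
"""

import smdist as sd

table = sd.generate_norms_fixture(sd.FixtureSpec(n_words=100, seed=4))
words = list(table.words[:12])

layout = sd.sammon_layout(table, words, seed=0)
print(f"final Sammon stress: {layout.stress:.5f} "
      f"(after {layout.iterations} iterations)")
print("word, x, y:")
for word, (x, y) in zip(layout.words, layout.coords):
    print(f"  {word:8s} {x:+.3f} {y:+.3f}")

print("\nstress decreased monotonically:",
      all(b <= a for a, b in zip(layout.stress_history, layout.stress_history[1:])))
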