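"""Detect admixture with the three-population test.

A target population formed as a 50/50 mixture of two diverged sources has
allele frequencies intermediate between them, which makes the mean product
(x-a)(x-b) negative; an unadmixed target gives a positive value.  Z < -2
is the conventional evidence threshold.
"""

from admixkit import BlockSpec, allele_freqs, f3, simulate
from admixkit.validation import two_source_mixture_model

model = two_source_mixture_model(alpha=0.5)
ds, popmap = simulate(model, samples={"X": 40, "A": 40, "B": 40},
                      n_loci=200, locus_length=50_000, seed=11)
freqs = allele_freqs(ds, popmap)
result = f3("X", "A", "B", freqs, BlockSpec(1000))

print(result)
print(f"f3 = {result.estimate:.5f} with Z = {result.z_score:.1f}: "
      "a strongly negative Z (< -2) says X cannot sit on a simple tree "
      "with A and B - it is admixed between sources related to both.")
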