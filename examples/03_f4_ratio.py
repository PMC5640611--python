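"""Estimate an admixture proportion with the F4-ratio.

X is simulated as 75% IB-related and 25% BMX-related ancestry.  The ratio
f4(EUW, Sum; X, BMX) / f4(EUW, Sum; IB, BMX) isolates the fraction of
IB-like ancestry in X; 1 - alpha is the BMX-side (donor) fraction.
"""

from admixkit import BlockSpec, allele_freqs, f4_ratio, simulate
from admixkit.validation import f4_ratio_model

true_alpha = 0.75
model = f4_ratio_model(true_alpha)
ds, popmap = simulate(
    model, samples={p: 40 for p in ["EUW", "Sum", "X", "BMX", "IB"]},
    n_loci=300, locus_length=50_000, seed=5,
)
freqs = allele_freqs(ds, popmap)
r = f4_ratio("EUW", "Sum", "X", "BMX", "IB", freqs, BlockSpec(1000))

print(f"alpha_hat = {r.estimate:.3f} +/- {r.jackknife_se:.3f} "
      f"(simulated alpha = {true_alpha})")
print(f"donor-side ancestry fraction = {r.extra['alt_ancestry_fraction']:.3f}")
# The jackknife SE comes from deleting 1000-SNP blocks and recomputing the
# ratio, so it is robust to linkage within loci.
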