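"""Simulate one introgression scenario of the Eurasian pig demography.

Scenario II sends migrants from European wild boar groups (EUW) into five
European domestic breeds (EUD) at 4% per generation for 10 generations.
The simulator returns a diploid genotype panel plus a population map that
every other tool in the package consumes.
"""

from admixkit import ScenarioSpec, eurasian_pig_model, simulate

spec = ScenarioSpec("II", euw_eud_rate=0.04, seed=7, n_loci=100,
                    locus_length=50_000, chroms_per_pop=20)
model = eurasian_pig_model(spec)
ds, popmap = simulate(model, spec)

print(f"scenario II at 4%/generation: {ds.n_samples} diploids, "
      f"{ds.n_markers} biallelic SNPs across {spec.n_loci} loci")
print(f"populations: {', '.join(popmap.populations)}")
# Each population contributes chroms_per_pop/2 diploids; the SNP count is
# what the neutral mutation rate (1e-8/bp/gen) yields on these genealogies.
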