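# Methods

This note documents the models, estimators and numerical choices behind
admixkit, and what the simulation studies do and do not demonstrate.

## f-statistics and block-jackknife inference

All f-statistics are moments of population allele-frequency differences,
estimated as unweighted means of per-SNP terms over complete-case SNPs
(SNPs with a defined frequency in every population involved).  This is the
convention of the threepop/TreeMix family rather than the
heterozygosity-weighted ratio-of-sums used by some other implementations;
the sign and Z-threshold behaviour of the tests are unaffected by this
choice, and the unweighted mean keeps the delete-one-block algebra exact.

Per-SNP terms:

- `f2(A,B)`: `(a-b)^2 - a(1-a)/(n_A-1) - b(1-b)/(n_B-1)` — both sampling
  corrections, since both populations repeat inside the square;
- `f3(X;A,B)`: `(x-a)(x-b) - x(1-x)/(n_X-1)` — only the target repeats;
- `f4(A,B;C,D)`: `(a-b)(c-d)` — no correction needed when no population
  repeats, because the sampling errors of the two factors are independent.

Counts `n` are non-missing allele copies (2 x called diploids); SNPs where
the corrected population has fewer than two copies are dropped.  The
corrections are validated by a binomial Monte-Carlo oracle (100,000 draws
of 10 diploids): the mean corrected term matches the population-level
product within Monte-Carlo error.

Standard errors are weighted delete-one-block jackknives (Busing-style
weights equal to per-block SNP counts) over contiguous blocks of the
(chromosome, position)-ordered marker list.  The final short block is kept
and down-weighted; with equal blocks the formula reduces exactly to the
textbook delete-one jackknife (property-tested).  For the F4-ratio the
jackknife resamples the *ratio* — each delete-one-block replicate
recomputes both f4 sums — which is the correct treatment for the strongly
correlated numerator and denominator; the denominator is additionally
flagged unstable when its magnitude is below ten of its own SEs.
Calibration: over 200 replicates of independent-block simulations the mean
jackknife SE is within ~2% of the empirical SD of the estimate.

## QC and relatedness

LD pruning follows the sliding-window greedy rule (window 50 SNPs, step 5,
r² > 0.5 by default): within each window, whenever a retained pair exceeds
the threshold the lower-MAF member is dropped (ties drop the later
marker).  r² is the squared dosage correlation over pairwise-complete
samples — genotype, not haplotype, correlation, since chip data are
unphased.

IBD sharing is the method-of-moments decomposition of observed IBS 0/1/2
counts into P(IBD=0/1/2), with pi-hat = P(IBD=2) + P(IBD=1)/2.  The
expected IBS class probabilities given IBD state use *unbiased moment
estimators* of the frequency products (e.g. `a(a-1)(c-a)(c-a-1) /
[c(c-1)(c-2)(c-3)]` for `p^2q^2`, with `a` alt copies out of `c`); naive
plug-in products are biased when frequencies come from few samples and
inflate pi-hat for unrelated pairs.  Raw solutions are clipped to [0,1]
and renormalised.  Relative removal is greedy within each population
group: repeatedly delete the sample in the most pi-hat > threshold pairs
(ties: lower call rate, then lexicographically later id) until no pair
remains — a deterministic rule, chosen for reproducibility.

## Drift PCA

Markers are centred at twice the sample frequency and scaled by
`sqrt(p~(1-p~))` with the shrunken `p~ = (count+1)/(2n+2)`; missing
entries are mean-imputed (zero after centring), which keeps the estimator
deterministic.  Components come from an SVD of the normalised matrix;
variance fractions are eigenvalues over the trace; component signs are
fixed by making the largest-magnitude loading positive.  No Tracy-Widom
testing or outlier-removal iterations are performed.

## EM ancestry

The admixture likelihood treats genotype `g_ij` as Binomial(2, f_ij) with
`f = Q P`, Q the samples-x-K ancestry fractions and P the K-x-markers
ancestral frequencies.  The EM updates are the standard FRAPPE-style ones;
they are monotone in the log-likelihood (asserted on every fit).  P is
clipped to [1e-6, 1-1e-6]; Q rows are renormalised to the simplex each
step.  Initialisation (Dirichlet(1) rows for Q, Uniform(0.05, 0.95) for P)
and the cross-validation masks are keyed by *sample and marker ids*, so
results are invariant to storage order.  Five seeded restarts, keeping the
best likelihood, are the default guard against local optima.

Convergence matters more than usual here: EM approaches the simplex
boundary slowly, so loose tolerances understate the ancestry of pure
individuals.  The validation studies run with `tol = 1e-9`; with the
default `1e-6` pure individuals may plateau near 0.95 rather than 0.99+.

Cross-validation masks the non-missing entries in `folds` disjoint sets,
refits with the held-out entries missing, and scores the mean squared
error between held-out dosages and `2 Q P`.  On three well-separated
simulated populations the error is minimised at K=3 in 9-10 of 10
replicates.

## Drift tree

Pairwise f2 estimates (with both sampling corrections) are additive along
a pure drift tree, so neighbour joining recovers the split topology;
negative NJ branch lengths are floored at zero, the tree is rooted by
bisecting the outgroup's edge, and input order independence is obtained by
canonicalising the label order before NJ.  Branch lengths are then refit
by non-negative least squares against the observed distances, and the
variance-explained statistic is `1 - SS_res/SS_tot` about the mean
pairwise distance.  This NJ + least-squares stage deliberately replaces a
Gaussian maximum-likelihood tree search with migration edges: the
scientific claims checked here are topology-level (where the wild-boar
clade attaches), which NJ on drift distances reproduces; migration-edge
inference is out of scope.  The variance-explained figure is therefore an
analogue, monotone in fit quality but not numerically identical to the
covariance-parameterised statistic of migration-graph tools.

Group placement is classified on the rooted tree: two groups are
"separate" when the smallest clade spanning each contains no leaf of the
other, and group A is "within" group B when B's spanning clade covers
every A leaf (and not conversely).

## Coalescent simulator

Each genomic region is one independent non-recombining locus.  Its
genealogy is simulated backward in time in two phases: discrete
Wright-Fisher parent draws generation by generation while any migration
pulse window is open (a lineage in the recipient moves to the donor with
probability m in each pulse generation; lineages sharing a drawn parent
coalesce, polytomies allowed), then exponential waiting times between
coalescence events with per-population rate k(k-1)/(4Ne), interleaved with
population-split events.  Mutations are Poisson on branches at
`mu x locus length` per generation under infinite sites; every variant's
carrier set is a proper subset of sampled chromosomes, so no monomorphic
site is emitted.  Diploids pair consecutive chromosomes within a
population.  Calibration: single-population pairwise diversity matches
4 Ne mu within ~3%; segregating sites match Watterson's expectation; and a
two-population run agrees with an independent coalescent engine (msprime)
on S and pi within Monte-Carlo error.  Pulse bookkeeping is checked by
lineage tracking: after a pulse of rate m for d generations the
migrant-origin fraction matches `1-(1-m)^d` for m in {1, 2, 4, 6}% at
d = 10.

An optional `sub_loci` knob splits each region into k independently
simulated sub-loci, a coarse surrogate for intra-locus recombination
(default off: the analyses consume per-block statistics, where inter-locus
independence is what matters).  The simulator does not emulate chip
ascertainment bias, sequencing error or selection; simulated panels are
sequence-like (an excess of rare variants relative to a 60K chip), which
is why pipeline defaults apply a MAF filter before chip-style analyses.

### The Eurasian pig demography

The bundled demography has stems Sum (Ne 10,000), EU (175,000),
AS (170,000), EUD (20,000), EUW (8,000), ASD (26,000), ASW (36,000), one
generation per five years, mu = r = 1e-8/bp.  Eight European domestic
breeds, seven European wild groups, three Asian breeds and one Asian wild
group isolate from their stems at Ne 2,000, at times evenly spaced on
[40, 60] generations BP (deterministic, oldest first, so every pulse
recipient/donor exists throughout its window).  Wild/domestic splits sit
at 2,000 generations BP (domestication roughly 10,000 years ago).

The European-Asian split is modelled at 30,000 generations BP and the
outgroup at 45,000 — *effective* clean-split divergences, not literal
ages.  The real divergence is far older but was accompanied by extensive
gene flow, so its realized frequency differentiation is much smaller than
a clean split of the same age would produce; a no-migration emulation must
match the realized differentiation (here f2(EUD, ASD) ~ 0.27, in line
with observed European-Asian pig FST ~ 0.3).  With literal deep splits the
1-2%/generation Asian pulses would throw their recipient breeds basally
out of the European domestic cluster — behaviour the original analyses do
not show.

Scenario pulses: III/IV add ASD1 -> six EUD breeds (start 40 BP,
10 generations, per-breed rates alternating 1% and 2%); the EUD/EUW flow
runs between five partner pairs (start 30 BP, 10 generations) at 2, 4 or
6% per generation, direction I/III: EUD -> EUW, II/IV: EUW -> EUD.
Recipients default to the first six (respectively five) breeds by label
order; both are configurable.

## Study sizes

The replicate studies run at desk scale: mixtures use 20 diploids per
population and ~200 loci (~25,000-30,000 SNPs), F4-ratio recovery 10
diploids and 120 loci per replicate, scenario trees 200 loci x 20
chromosomes per population, jackknife calibration 200 replicates of 2,000
iid SNPs.  At these sizes the full validation sweep completes in about two
minutes on one CPU; all thresholds (detection in >= 38/40 replicates,
coverage >= 18/20, topology agreement 10/10) are met with margin, and the
same studies at larger sizes only tighten the Monte-Carlo error.

## Known limitations

- No intra-locus recombination (beyond the `sub_loci` surrogate) and no
  chip ascertainment model; absolute site-frequency spectra differ from
  real 60K panels even where the frequency-moment statistics behave
  identically.
- The EM implementation is plain EM, slower near convergence than
  quasi-Newton accelerations; fine at desk scale, slow for K of several
  dozen on full panels.
- TreeMix-style migration-edge fitting, D-statistics and qpAdm-style
  multi-source decompositions are out of scope.
- Strand-ambiguous (A/T, C/G) markers are kept in the first dataset's
  orientation on merge, without strand flipping; conflicting allele pairs
  are dropped and logged.  This is appropriate for single-platform chip
  merges, not for cross-platform meta-analysis.
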