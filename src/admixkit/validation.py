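"""Replicate validation studies for the admixture toolkit.

Each function runs a self-contained simulation study against a known truth:
f3 admixture-detection power and false-positive behaviour, F4-ratio
parameter recovery, coalescent calibration (nucleotide diversity and pulse
ancestry bookkeeping), the block-jackknife's agreement with empirical
sampling error, EM hybrid recovery and cross-validated choice of K, and the
drift-tree reproduction of the introgression-scenario topologies.  They are
the package's evidence that the statistics behave as advertised, and are
reused by the test suite and the reproduction script.
"""

from __future__ import annotations

import numpy as np

from .ancestry import cv_error, fit_ancestry
from .dataset import GenotypeDataset, PopulationMap
from .fstats import BlockSpec, FreqTable, allele_freqs, f3, f4_ratio, three_pop_scan
from .simulate import (
    EUD_BREEDS,
    EUW_GROUPS,
    DemographicModel,
    MigrationPulse,
    ScenarioSpec,
    SplitEvent,
    eurasian_pig_model,
    lineage_origin_fractions,
    simulate,
)
from .tree import build_tree, classify_group_placement, f2_matrix


# ---------------------------------------------------------------------------
# Fixture demographies
# ---------------------------------------------------------------------------

def two_source_mixture_model(
    alpha: float = 0.5,
    split_gens: float = 4000.0,
    ne: float = 10_000.0,
    mix_gen: int = 10,
) -> DemographicModel:
    """Target X formed ``mix_gen`` generations ago as an alpha/(1-alpha)
    mixture of two sources A and B that diverged ``split_gens`` ago."""
    pops = {"X": ne, "A": ne, "B": ne, "ANC": ne}
    splits = [
        SplitEvent(mix_gen, "X", "A"),
        SplitEvent(split_gens, "A", "ANC"),
        SplitEvent(split_gens, "B", "ANC"),
    ]
    pulses = [MigrationPulse("B", "X", mix_gen, 1, 1.0 - alpha)]
    m = DemographicModel(pops, splits, pulses)
    m.validate()
    return m


def unadmixed_target_model(ne: float = 10_000.0) -> DemographicModel:
    """Target X is a clean (unadmixed) recent sister of A, with its own
    drift; B..E are successively deeper outgroups giving ten source pairs."""
    pops = {"X": 2_000.0, "A": ne, "B": ne, "C": ne, "D": ne, "E": ne,
            "AB": ne, "ABC": ne, "ABCD": ne, "ANC": ne}
    splits = [
        SplitEvent(200, "X", "A"),
        SplitEvent(2000, "A", "AB"), SplitEvent(2000, "B", "AB"),
        SplitEvent(3000, "AB", "ABC"), SplitEvent(3000, "C", "ABC"),
        SplitEvent(4000, "ABC", "ABCD"), SplitEvent(4000, "D", "ABCD"),
        SplitEvent(5000, "ABCD", "ANC"), SplitEvent(5000, "E", "ANC"),
    ]
    m = DemographicModel(pops, splits)
    m.validate()
    return m


def f4_ratio_model(alpha: float, ne: float = 10_000.0) -> DemographicModel:
    """Admixed population X = alpha IB-related + (1-alpha) BMX-related, with
    EUW as the unadmixed reference and Sum as the outgroup:
    (((EUW, IB), BMX), Sum) with X grafted as a recent mixture."""
    pops = {"EUW": ne, "IB": ne, "BMX": ne, "Sum": ne, "X": ne,
            "EU": ne, "IN": ne, "ANC": ne}
    splits = [
        SplitEvent(10, "X", "IB"),
        SplitEvent(2000, "EUW", "EU"), SplitEvent(2000, "IB", "EU"),
        SplitEvent(6000, "EU", "IN"), SplitEvent(6000, "BMX", "IN"),
        SplitEvent(12_000, "IN", "ANC"), SplitEvent(12_000, "Sum", "ANC"),
    ]
    pulses = [MigrationPulse("BMX", "X", 10, 1, 1.0 - alpha)]
    m = DemographicModel(pops, splits, pulses)
    m.validate()
    return m


# ---------------------------------------------------------------------------
# f3 detection power and specificity
# ---------------------------------------------------------------------------

def f3_power_study(
    n_replicates: int = 40,
    n_diploids: int = 20,
    n_loci: int = 200,
    seed: int = 0,
    blocks: BlockSpec = BlockSpec(1000),
) -> dict:
    """Power of the three-population test on a 50/50 two-source mixture.

    Each replicate simulates the mixture demography, computes f3(X; A, B)
    with block-jackknife inference and records whether Z < -2.
    """
    chroms = 2 * n_diploids
    hits = 0
    zs, snps = [], []
    for rep in range(n_replicates):
        model = two_source_mixture_model(alpha=0.5)
        ds, pm = simulate(
            model, samples={"X": chroms, "A": chroms, "B": chroms},
            n_loci=n_loci, locus_length=50_000, seed=seed + 7919 * rep + 1,
        )
        ft = allele_freqs(ds, pm)
        r = f3("X", "A", "B", ft, blocks)
        zs.append(r.z_score)
        snps.append(r.n_snps_used)
        if r.z_score < -2.0:
            hits += 1
    return {
        "n_replicates": n_replicates,
        "detections": hits,
        "power": hits / n_replicates,
        "mean_z": float(np.mean(zs)),
        "mean_snps": float(np.mean(snps)),
    }


def f3_false_positive_study(
    n_replicates: int = 20,
    n_diploids: int = 20,
    n_loci: int = 120,
    seed: int = 0,
    blocks: BlockSpec = BlockSpec(1000),
) -> dict:
    """Specificity: scan an unadmixed target over the ten source pairs and
    count replicates where any pair is (wrongly) flagged at Z < -2."""
    chroms = 2 * n_diploids
    sources = ["A", "B", "C", "D", "E"]
    pairs = [(a, b) for i, a in enumerate(sources) for b in sources[i + 1:]]
    flagged = 0
    for rep in range(n_replicates):
        model = unadmixed_target_model()
        ds, pm = simulate(
            model, samples={p: chroms for p in ["X", *sources]},
            n_loci=n_loci, locus_length=50_000, seed=seed + 104729 * rep + 1,
        )
        ft = allele_freqs(ds, pm)
        table = three_pop_scan("X", pairs, ft, blocks)
        if table["significant"].any():
            flagged += 1
    return {
        "n_replicates": n_replicates,
        "false_positives": flagged,
        "false_positive_rate": flagged / n_replicates,
    }


# ---------------------------------------------------------------------------
# F4-ratio recovery
# ---------------------------------------------------------------------------

def f4_ratio_recovery_study(
    alpha: float,
    n_replicates: int = 20,
    n_diploids: int = 10,
    n_loci: int = 120,
    seed: int = 0,
    blocks: BlockSpec = BlockSpec(1000),
) -> dict:
    """Recover a known mixture proportion alpha from the F4-ratio.

    A replicate succeeds when the estimate falls within two jackknife
    standard errors of the simulated alpha.
    """
    chroms = 2 * n_diploids
    within = 0
    ests = []
    for rep in range(n_replicates):
        model = f4_ratio_model(alpha)
        ds, pm = simulate(
            model,
            samples={p: chroms for p in ["EUW", "Sum", "X", "BMX", "IB"]},
            n_loci=n_loci, locus_length=50_000, seed=seed + 15013 * rep + 1,
        )
        ft = allele_freqs(ds, pm)
        r = f4_ratio("EUW", "Sum", "X", "BMX", "IB", ft, blocks)
        ests.append(r.estimate)
        if abs(r.estimate - alpha) <= 2.0 * r.jackknife_se:
            within += 1
    return {
        "alpha": alpha,
        "n_replicates": n_replicates,
        "within_2se": within,
        "coverage": within / n_replicates,
        "mean_alpha_hat": float(np.mean(ests)),
    }


# ---------------------------------------------------------------------------
# Simulator calibration
# ---------------------------------------------------------------------------

def pi_calibration_study(
    ne: float = 10_000.0, mu: float = 1e-8, n_loci: int = 1000,
    locus_length: int = 50_000, seed: int = 0,
) -> dict:
    """Single-population nucleotide diversity against the neutral
    expectation E[pi] = 4 Ne mu per site (one pair of chromosomes)."""
    model = DemographicModel({"P": ne}, mutation_rate=mu)
    ds, _ = simulate(model, samples={"P": 2}, n_loci=n_loci,
                     locus_length=locus_length, seed=seed)
    # with one diploid, a heterozygous site is exactly one pairwise difference
    pi = float((ds.genotypes == 1).sum()) / (n_loci * locus_length)
    expected = 4.0 * ne * mu
    return {"pi": pi, "expected": expected, "ratio": pi / expected}


def pulse_ancestry_study(
    rates=(0.01, 0.02, 0.04, 0.06), duration: int = 10,
    n_loci: int = 600, n_chroms: int = 20, seed: int = 0,
) -> dict:
    """Lineage-tracked migrant ancestry versus 1 - (1 - m)^d for each pulse
    rate of the study design (1%, 2%, 4%, 6% over 10 generations)."""
    out = {}
    for i, m in enumerate(rates):
        model = DemographicModel(
            {"R": 10_000.0, "D": 10_000.0, "A": 10_000.0},
            splits=[SplitEvent(5000, "R", "A"), SplitEvent(5000, "D", "A")],
            pulses=[MigrationPulse("D", "R", 40, duration, m)],
        )
        fr = lineage_origin_fractions(
            model, {"R": n_chroms, "D": n_chroms}, "R", at_time=40,
            n_loci=n_loci, seed=seed + 31 * i,
        )
        expected = 1.0 - (1.0 - m) ** duration
        n_obs = n_loci * n_chroms
        out[m] = {
            "observed": fr.get("D", 0.0),
            "expected": expected,
            "binomial_se": float(np.sqrt(expected * (1 - expected) / n_obs)),
        }
    return out


# ---------------------------------------------------------------------------
# Block jackknife calibration
# ---------------------------------------------------------------------------

def jackknife_calibration_study(
    n_replicates: int = 200,
    n_snps: int = 2000,
    block_size: int = 100,
    n_diploids: int = 20,
    seed: int = 0,
) -> dict:
    """Does the block-jackknife SE track the empirical SD of f3?

    Replicates draw iid per-SNP population frequencies around a shared
    ancestral frequency and binomial genotypes, so blocks are independent by
    construction; the mean jackknife SE should match the across-replicate SD
    of the estimate.
    """
    rng = np.random.default_rng(seed)
    ests, ses = [], []
    for _ in range(n_replicates):
        anc = rng.uniform(0.1, 0.9, n_snps)
        sd = 0.12
        px, pa, pb = (
            np.clip(anc + rng.normal(0, sd, n_snps), 0.01, 0.99)
            for _ in range(3)
        )
        gx = rng.binomial(2, px, (n_diploids, n_snps)).astype(np.int8)
        ga = rng.binomial(2, pa, (n_diploids, n_snps)).astype(np.int8)
        gb = rng.binomial(2, pb, (n_diploids, n_snps)).astype(np.int8)
        freq = np.vstack([gx.mean(0), ga.mean(0), gb.mean(0)]) / 2.0
        count = np.full((3, n_snps), 2.0 * n_diploids)
        ft = FreqTable.from_frequencies(["X", "A", "B"], freq, count)
        r = f3("X", "A", "B", ft, BlockSpec(block_size))
        ests.append(r.estimate)
        ses.append(r.jackknife_se)
    emp_sd = float(np.std(ests, ddof=1))
    mean_se = float(np.mean(ses))
    return {
        "empirical_sd": emp_sd,
        "mean_jackknife_se": mean_se,
        "ratio": mean_se / emp_sd,
    }


# ---------------------------------------------------------------------------
# Ancestry EM studies
# ---------------------------------------------------------------------------

def _mendelian_child(rng, g_mother: np.ndarray, g_father: np.ndarray) -> np.ndarray:
    """Offspring dosage by transmitting one allele from each parent."""
    a = (rng.random(g_mother.size) < g_mother / 2.0).astype(np.int8)
    b = (rng.random(g_father.size) < g_father / 2.0).astype(np.int8)
    return a + b


def hybrid_panel(
    n_per_pop: int = 15, n_hybrids: int = 10, n_loci: int = 60,
    seed: int = 0, max_markers: int = 3000,
) -> tuple[GenotypeDataset, PopulationMap]:
    """Two long-diverged populations plus constructed 50/50 F1 hybrids.

    The split (8,000 generations at Ne 5,000, FST ~ 0.5) is deep enough
    that ancestral allele frequencies are well separated and pure
    individuals are unambiguous under the admixture model."""
    model = DemographicModel(
        {"P1": 5_000.0, "P2": 5_000.0, "ANC": 10_000.0},
        splits=[SplitEvent(8000, "P1", "ANC"), SplitEvent(8000, "P2", "ANC")],
    )
    ds, pm = simulate(
        model, samples={"P1": 2 * n_per_pop, "P2": 2 * n_per_pop},
        n_loci=n_loci, locus_length=50_000, seed=seed,
    )
    if ds.n_markers > max_markers:
        step = ds.n_markers // max_markers + 1
        ds = ds.take_markers(np.arange(0, ds.n_markers, step))
    rng = np.random.default_rng(seed + 1)
    i1 = [i for i, s in enumerate(ds.samples) if s.startswith("P1")]
    i2 = [i for i, s in enumerate(ds.samples) if s.startswith("P2")]
    hybrids = []
    for h in range(n_hybrids):
        g = _mendelian_child(
            rng,
            ds.genotypes[i1[h % len(i1)]].astype(float),
            ds.genotypes[i2[h % len(i2)]].astype(float),
        )
        hybrids.append(g)
    geno = np.vstack([ds.genotypes, np.array(hybrids, dtype=np.int8)])
    samples = list(ds.samples) + [f"H_{h + 1}" for h in range(n_hybrids)]
    assign = dict(pm.assignments)
    assign.update({f"H_{h + 1}": "F1" for h in range(n_hybrids)})
    return (
        GenotypeDataset(samples, ds.markers.copy(), geno),
        PopulationMap(assign, ["P1", "P2", "F1"]),
    )


def em_hybrid_study(n_runs: int = 20, seed: int = 0) -> dict:
    """K=2 recovery of pure populations and 50/50 hybrids over seeded runs.

    A run succeeds when every hybrid's major ancestry fraction lies in
    [0.4, 0.6] and every pure individual's exceeds 0.95.
    """
    ds, pm = hybrid_panel(seed=seed)
    pure = [i for i, s in enumerate(ds.samples) if not s.startswith("H_")]
    hyb = [i for i, s in enumerate(ds.samples) if s.startswith("H_")]
    p1 = [i for i, s in enumerate(ds.samples) if s.startswith("P1")]
    successes = 0
    for run in range(n_runs):
        # EM approaches the simplex boundary slowly; near-complete
        # ancestry for pure individuals needs a tight tolerance
        fit = fit_ancestry(ds, K=2, seed=seed + 97 * run, restarts=1,
                           max_iter=1500, tol=1e-9)
        # orient component 0 toward P1
        k1 = int(np.argmax(fit.Q[p1].mean(axis=0)))
        q1 = fit.Q[:, k1]
        ok_h = all(0.4 <= q1[i] <= 0.6 for i in hyb)
        ok_p = all(max(q1[i], 1 - q1[i]) >= 0.95 for i in pure)
        if ok_h and ok_p:
            successes += 1
    return {"n_runs": n_runs, "successes": successes}


def cv_choice_of_k_study(
    n_replicates: int = 10, k_range=(1, 2, 3, 4, 5), seed: int = 0,
    n_per_pop: int = 12, max_markers: int = 1200,
) -> dict:
    """Cross-validation error should be minimised at the true K = 3 for
    three well-separated simulated populations."""
    correct = 0
    chosen = []
    for rep in range(n_replicates):
        model = DemographicModel(
            {"P1": 5_000.0, "P2": 5_000.0, "P3": 5_000.0,
             "P12": 10_000.0, "ANC": 10_000.0},
            splits=[
                SplitEvent(4000, "P1", "P12"), SplitEvent(4000, "P2", "P12"),
                SplitEvent(8000, "P12", "ANC"), SplitEvent(8000, "P3", "ANC"),
            ],
        )
        ds, _ = simulate(
            model, samples={p: 2 * n_per_pop for p in ["P1", "P2", "P3"]},
            n_loci=40, locus_length=50_000, seed=seed + 2221 * rep,
        )
        if ds.n_markers > max_markers:
            step = ds.n_markers // max_markers + 1
            ds = ds.take_markers(np.arange(0, ds.n_markers, step))
        errs = {k: cv_error(ds, k, folds=5, seed=seed + rep, max_iter=150)
                for k in k_range}
        best = min(errs, key=errs.get)
        chosen.append(best)
        if best == 3:
            correct += 1
    return {"n_replicates": n_replicates, "correct": correct,
            "chosen": chosen}


# ---------------------------------------------------------------------------
# Scenario topology reproduction
# ---------------------------------------------------------------------------

def scenario_topology_study(
    seed: int = 0, n_loci: int = 200, chroms_per_pop: int = 20,
    blocks: BlockSpec = BlockSpec(5000),
) -> dict:
    """Drift-tree placement of EUW relative to EUD under each scenario.

    Expectation from the study design: gene flow EUD -> EUW (scenarios I
    and III) leaves EUW and EUD as two separate clades at every rate, while
    EUW -> EUD (scenarios II and IV) at 4% and 6% pulls the EUW clade
    inside the EUD group.
    """
    cases = (
        [("I", r, "separate") for r in (0.02, 0.04, 0.06)]
        + [("III", r, "separate") for r in (0.02, 0.04, 0.06)]
        + [("II", r, "a_within_b") for r in (0.04, 0.06)]
        + [("IV", r, "a_within_b") for r in (0.04, 0.06)]
    )
    results = {}
    for scen, rate, expected in cases:
        spec = ScenarioSpec(scen, rate, seed=seed, n_loci=n_loci,
                            locus_length=50_000, chroms_per_pop=chroms_per_pop)
        ds, pm = simulate(eurasian_pig_model(spec), spec)
        dm = f2_matrix(allele_freqs(ds, pm), blocks)
        pt = build_tree(dm, "Sum")
        got = classify_group_placement(pt, EUW_GROUPS, EUD_BREEDS)
        results[f"{scen}@{rate:g}"] = {
            "expected": expected, "observed": got, "match": got == expected,
        }
    return results
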