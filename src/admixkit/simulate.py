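"""Structured-coalescent simulator of multi-population SNP genotypes.

The generator emulates 60K-chip-like biallelic genotype panels from a
demography of population splits, per-population diploid effective sizes and
timed, directed per-generation migration pulses.  Each genomic region is an
independent non-recombining locus: its genealogy is simulated backward in
time — generation-by-generation (discrete Wright-Fisher parent draws) while
migration pulses are active, then by exponential waiting times between
coalescences — and infinite-sites mutations are dropped on branches at rate
mu per bp per generation.  Loci are concatenated into a
:class:`~admixkit.dataset.GenotypeDataset` of diploids formed by pairing
consecutive chromosomes within each population.

The bundled Eurasian pig demography reflects the split of European and
Asian Sus scrofa, wild/domestic divergences, breed/group isolations 40-60
generations ago at small Ne, and four introgression scenarios between
European wild (EUW), European domestic (EUD) and Asian domestic (ASD)
populations.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .dataset import GenotypeDataset, PopulationMap, make_marker_table


# ---------------------------------------------------------------------------
# Model types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class MigrationPulse:
    """Forward-time gene flow: ``dest`` receives a fraction ``rate_per_gen``
    of migrants from ``source`` each generation for ``duration_gens``
    generations, the window ending ``start_gen_bp`` generations before
    present.  Backward in time a lineage in ``dest`` moves to ``source``
    with probability ``rate_per_gen`` at generations
    ``start_gen_bp - duration_gens < t <= start_gen_bp``."""

    source: str
    dest: str
    start_gen_bp: int
    duration_gens: int
    rate_per_gen: float

    def __post_init__(self) -> None:
        if not 0 < self.rate_per_gen < 1:
            raise ValueError("rate_per_gen must be in (0, 1)")
        if self.duration_gens < 1:
            raise ValueError("duration_gens must be >= 1")

    def active(self, t: int) -> bool:
        return self.start_gen_bp - self.duration_gens < t <= self.start_gen_bp


@dataclass(frozen=True)
class SplitEvent:
    """Backward in time, at ``time_gen_bp`` all lineages of ``derived``
    merge into ``ancestral`` (forward: ``derived`` was founded then)."""

    time_gen_bp: float
    derived: str
    ancestral: str


@dataclass
class DemographicModel:
    populations: dict[str, float]        # name -> diploid Ne
    splits: list[SplitEvent] = field(default_factory=list)
    pulses: list[MigrationPulse] = field(default_factory=list)
    mutation_rate: float = 1e-8          # per bp per generation
    recombination_rate: float = 1e-8     # informational (no intra-locus rec.)
    generation_years: float = 5.0

    def validate(self) -> None:
        if any(ne <= 0 for ne in self.populations.values()):
            raise ValueError("all Ne must be > 0")
        if self.mutation_rate < 0 or self.recombination_rate < 0:
            raise ValueError("rates must be >= 0")
        seen_derived = set()
        for s in self.splits:
            if s.time_gen_bp <= 0:
                raise ValueError("split times must be strictly positive")
            for p in (s.derived, s.ancestral):
                if p not in self.populations:
                    raise ValueError(f"unknown population {p!r} in split")
            if s.derived in seen_derived:
                raise ValueError(f"{s.derived!r} is derived in two splits")
            seen_derived.add(s.derived)
        ends = self.split_times()
        for p in self.pulses:
            for pop in (p.source, p.dest):
                if pop not in self.populations:
                    raise ValueError(f"unknown population {pop!r} in pulse")
                if p.start_gen_bp > ends.get(pop, np.inf):
                    raise ValueError(
                        f"pulse window reaches {p.start_gen_bp} gens BP but "
                        f"{pop!r} merges at {ends[pop]}"
                    )

    def split_times(self) -> dict[str, float]:
        """Backward time at which each population merges away (inf = root)."""
        return {s.derived: s.time_gen_bp for s in self.splits}


@dataclass(frozen=True)
class ScenarioSpec:
    """One introgression scenario of the Eurasian pig demography.

    I: EUD -> EUW; II: EUW -> EUD; III: EUD -> EUW plus ASD -> EUD;
    IV: EUW -> EUD plus ASD -> EUD.  ``euw_eud_rate`` is the per-generation
    migration fraction between the five EUD/EUW partner pairs.
    """

    scenario: str
    euw_eud_rate: float = 0.04
    seed: int = 0
    n_loci: int = 1000
    locus_length: int = 50_000
    chroms_per_pop: int = 40

    def __post_init__(self) -> None:
        if self.scenario not in {"I", "II", "III", "IV"}:
            raise ValueError("scenario must be I, II, III or IV")
        if self.euw_eud_rate not in (0.02, 0.04, 0.06):
            raise ValueError("euw_eud_rate must be 0.02, 0.04 or 0.06")
        if self.chroms_per_pop % 2:
            raise ValueError("chroms_per_pop must be even (diploids)")


# ---------------------------------------------------------------------------
# Eurasian pig demography
# ---------------------------------------------------------------------------

STEM_NE = {
    "Sum": 10_000.0, "EU": 175_000.0, "AS": 170_000.0,
    "EUD": 20_000.0, "EUW": 8_000.0, "ASD": 26_000.0, "ASW": 36_000.0,
    "EUAS": 10_000.0, "ANC": 10_000.0,
}
BREED_NE = 2_000.0

EUD_BREEDS = [f"EUD{i}" for i in range(1, 9)]
EUW_GROUPS = [f"EUW{i}" for i in range(1, 8)]
ASD_BREEDS = [f"ASD{i}" for i in range(1, 4)]
ASW_GROUPS = ["ASW1"]
SAMPLED_POPULATIONS = EUD_BREEDS + EUW_GROUPS + ASD_BREEDS + ASW_GROUPS + ["Sum"]

# Deep split times (generations BP).  Wild/domestic divergence reflects
# domestication ~10,000 years ago at 5 years per generation.  The deeper
# splits are *effective* (clean-split) divergences chosen to match the
# realized differentiation between European and Asian Sus scrofa
# (f2 ~ 0.25-0.3): the literal split is far older but extensive
# post-divergence gene flow kept realized drift much smaller, and a
# no-migration stand-in must reproduce the realized f2, not the split age.
WILD_DOMESTIC_SPLIT = 2_000.0
EU_AS_SPLIT = 30_000.0
OUTGROUP_SPLIT = 45_000.0


def _isolation_times(n: int) -> list[int]:
    """Evenly spaced breed-isolation times on [40, 60] generations BP,
    oldest first (so breed 1 exists throughout every pulse window)."""
    return [int(round(t)) for t in np.linspace(60, 40, n)]


def eurasian_pig_model(spec: ScenarioSpec) -> DemographicModel:
    """The Eurasian pig demography under one introgression scenario.

    Stems: Sum (Ne 10,000), EU (175,000), AS (170,000), EUD (20,000),
    EUW (8,000), ASD (26,000), ASW (36,000); 8 EUD breeds, 7 EUW groups,
    3 ASD breeds and 1 ASW group isolate from their stems 40-60 generations
    BP at Ne 2,000.  Scenarios III/IV add ASD1 -> six EUD breeds pulses
    (start 40 BP, 10 generations, rates alternating 1%/2%); the EUD/EUW
    pulses run between five partner pairs (start 30 BP, 10 generations) at
    ``spec.euw_eud_rate`` in the scenario's direction.
    """
    pops = dict(STEM_NE)
    for b in EUD_BREEDS + EUW_GROUPS + ASD_BREEDS + ASW_GROUPS:
        pops[b] = BREED_NE

    splits: list[SplitEvent] = []
    for breeds, stem in [
        (EUD_BREEDS, "EUD"), (EUW_GROUPS, "EUW"),
        (ASD_BREEDS, "ASD"), (ASW_GROUPS, "ASW"),
    ]:
        for b, t in zip(breeds, _isolation_times(len(breeds))):
            splits.append(SplitEvent(t, b, stem))
    splits += [
        SplitEvent(WILD_DOMESTIC_SPLIT, "EUD", "EU"),
        SplitEvent(WILD_DOMESTIC_SPLIT, "EUW", "EU"),
        SplitEvent(WILD_DOMESTIC_SPLIT, "ASD", "AS"),
        SplitEvent(WILD_DOMESTIC_SPLIT, "ASW", "AS"),
        SplitEvent(EU_AS_SPLIT, "EU", "EUAS"),
        SplitEvent(EU_AS_SPLIT, "AS", "EUAS"),
        SplitEvent(OUTGROUP_SPLIT, "EUAS", "ANC"),
        SplitEvent(OUTGROUP_SPLIT, "Sum", "ANC"),
    ]

    pulses: list[MigrationPulse] = []
    if spec.scenario in {"III", "IV"}:
        for i, breed in enumerate(EUD_BREEDS[:6]):
            rate = 0.01 if i % 2 == 0 else 0.02
            pulses.append(MigrationPulse("ASD1", breed, 40, 10, rate))
    for eud, euw in zip(EUD_BREEDS[:5], EUW_GROUPS[:5]):
        if spec.scenario in {"I", "III"}:   # EUD -> EUW
            pulses.append(MigrationPulse(eud, euw, 30, 10, spec.euw_eud_rate))
        else:                                # II, IV: EUW -> EUD
            pulses.append(MigrationPulse(euw, eud, 30, 10, spec.euw_eud_rate))

    model = DemographicModel(pops, splits, pulses)
    model.validate()
    return model


# ---------------------------------------------------------------------------
# Coalescent engine
# ---------------------------------------------------------------------------

class _Genealogy:
    """One locus' genealogy: node times, children and leaf descendants."""

    __slots__ = ("times", "children")

    def __init__(self, n_leaves: int):
        self.times: list[float] = [0.0] * n_leaves
        self.children: list[list[int]] = [[] for _ in range(n_leaves)]

    def merge(self, nodes: list[int], time: float) -> int:
        nid = len(self.times)
        self.times.append(time)
        self.children.append(list(nodes))
        return nid

    def leaf_sets(self, n_leaves: int) -> list[np.ndarray]:
        out: list[np.ndarray | None] = [None] * len(self.times)
        for nid in range(len(self.times)):
            if nid < n_leaves:
                out[nid] = np.array([nid], dtype=np.int32)
            else:
                out[nid] = np.concatenate([out[c] for c in self.children[nid]])
        return out  # type: ignore[return-value]


def _simulate_locus_genealogy(
    model: DemographicModel,
    samples: dict[str, int],
    rng: np.random.Generator,
    stop_at: float | None = None,
):
    """Backward-in-time genealogy for one locus.

    Returns (genealogy, root id, lineage population snapshot or None).
    The snapshot (taken just after the migration phase of generation
    ``stop_at``) maps each sampled chromosome to the population label its
    ancestral lineage occupies at that time.
    """
    ne = model.populations
    split_by_time: dict[int, list[SplitEvent]] = {}
    cont_splits: list[SplitEvent] = []

    # discrete phase covers every pulse window (and any split inside it)
    t_discrete = max([p.start_gen_bp for p in model.pulses], default=0)
    if stop_at is not None:
        t_discrete = max(t_discrete, int(np.ceil(stop_at)))
    for s in model.splits:
        if s.time_gen_bp <= t_discrete:
            if s.time_gen_bp != int(s.time_gen_bp):
                raise ValueError(
                    "split times inside the pulse window must be integers"
                )
            split_by_time.setdefault(int(s.time_gen_bp), []).append(s)
        else:
            cont_splits.append(s)
    cont_splits.sort(key=lambda s: s.time_gen_bp)

    n_leaves = sum(samples.values())
    gen = _Genealogy(n_leaves)
    pools: dict[str, list[int]] = {}
    nid = 0
    for pop, k in samples.items():
        pools.setdefault(pop, []).extend(range(nid, nid + k))
        nid += k
    n_lineages = n_leaves
    track = stop_at is not None
    origin_of: dict[int, list[int]] = (
        {i: [i] for i in range(n_leaves)} if track else {}
    )

    # ---- discrete Wright-Fisher phase -------------------------------------
    for t in range(1, t_discrete + 1):
        # (a) pulse migration: backward, recipients\' lineages move to donor
        for p in model.pulses:
            if not p.active(t):
                continue
            dest = pools.get(p.dest)
            if not dest:
                continue
            move = rng.random(len(dest)) < p.rate_per_gen
            if move.any():
                stay = [l for l, m in zip(dest, move) if not m]
                moved = [l for l, m in zip(dest, move) if m]
                pools[p.dest] = stay
                pools.setdefault(p.source, []).extend(moved)
        if track and t == int(np.ceil(stop_at)):
            snapshot = {}
            for pop, lins in pools.items():
                for l in lins:
                    for leaf in origin_of[l]:
                        snapshot[leaf] = pop
            return gen, None, snapshot
        # (b) coalescence: draw Wright-Fisher parents within each population
        for pop, lins in pools.items():
            k = len(lins)
            if k < 2:
                continue
            parents = rng.integers(0, max(int(2 * ne[pop]), 1), size=k)
            by_parent: dict[int, list[int]] = {}
            for l, par in zip(lins, parents):
                by_parent.setdefault(int(par), []).append(l)
            if len(by_parent) == k:
                continue  # no collision, nothing coalesces
            new_pool: list[int] = []
            for group in by_parent.values():
                if len(group) == 1:
                    new_pool.append(group[0])
                else:
                    new = gen.merge(group, float(t))
                    new_pool.append(new)
                    n_lineages -= len(group) - 1
                    if track:
                        merged: list[int] = []
                        for l in group:
                            merged.extend(origin_of.pop(l))
                        origin_of[new] = merged
            pools[pop] = new_pool
        # (c) splits scheduled at this generation
        for s in split_by_time.get(t, []):
            if pools.get(s.derived):
                pools.setdefault(s.ancestral, []).extend(pools[s.derived])
                pools[s.derived] = []

    # ---- continuous phase -------------------------------------------------
    t_now = float(t_discrete)
    split_iter = iter(cont_splits)
    next_split = next(split_iter, None)
    while n_lineages > 1:
        rates = {
            pop: k * (k - 1) / (4.0 * ne[pop])
            for pop, lins in pools.items()
            if (k := len(lins)) >= 2
        }
        total = sum(rates.values())
        if total == 0.0:
            if next_split is None:
                raise RuntimeError("lineages cannot coalesce: model has no root")
            t_now = next_split.time_gen_bp
        else:
            wait = rng.exponential(1.0 / total)
            if next_split is not None and t_now + wait >= next_split.time_gen_bp:
                t_now = next_split.time_gen_bp
            else:
                t_now += wait
                u = rng.random() * total
                acc = 0.0
                pop = next(iter(rates))
                for pp, r in rates.items():
                    acc += r
                    if u <= acc:
                        pop = pp
                        break
                pool = pools[pop]
                i = int(rng.integers(len(pool)))
                j = int(rng.integers(len(pool) - 1))
                if j >= i:
                    j += 1
                a, b = pool[i], pool[j]
                new = gen.merge([a, b], t_now)
                # swap-remove the two, append the parent
                for victim in sorted((i, j), reverse=True):
                    pool[victim] = pool[-1]
                    pool.pop()
                pool.append(new)
                n_lineages -= 1
                continue
        # apply every split scheduled at t_now
        while next_split is not None and next_split.time_gen_bp <= t_now:
            s = next_split
            if pools.get(s.derived):
                pools.setdefault(s.ancestral, []).extend(pools[s.derived])
                pools[s.derived] = []
            next_split = next(split_iter, None)

    root = next(l for lins in pools.values() for l in lins)
    return gen, root, None


def _mutations_for_locus(
    gen: _Genealogy, root: int, n_leaves: int, mu_per_locus: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Drop infinite-sites mutations; returns haplotypes (n_leaves x S)."""
    times = np.asarray(gen.times)
    parent = np.full(len(times), -1, dtype=np.int64)
    for nid, kids in enumerate(gen.children):
        for c in kids:
            parent[c] = nid
    branch = np.where(parent >= 0, times[parent] - times, 0.0)
    n_mut = rng.poisson(branch * mu_per_locus)
    total = int(n_mut.sum())
    if total == 0:
        return np.zeros((n_leaves, 0), dtype=np.int8)
    leaf_sets = gen.leaf_sets(n_leaves)
    hap = np.zeros((n_leaves, total), dtype=np.int8)
    col = 0
    for nid in np.nonzero(n_mut)[0]:
        carriers = leaf_sets[nid]
        hap[carriers, col:col + n_mut[nid]] = 1
        col += n_mut[nid]
    return hap


def simulate(
    model: DemographicModel,
    spec: ScenarioSpec | None = None,
    *,
    samples: dict[str, int] | None = None,
    n_loci: int | None = None,
    locus_length: int | None = None,
    seed: int | None = None,
    sub_loci: int = 1,
) -> tuple[GenotypeDataset, PopulationMap]:
    """Simulate a diploid genotype dataset under ``model``.

    Either pass a :class:`ScenarioSpec` (samples default to
    ``chroms_per_pop`` chromosomes from every sampled pig population) or
    give ``samples`` (population -> even chromosome count), ``n_loci``,
    ``locus_length`` and ``seed`` explicitly.  ``sub_loci > 1`` splits each
    region into that many independently simulated sub-loci, a coarse stand-in
    for intra-locus recombination.
    """
    model.validate()
    if spec is not None:
        samples = samples or {p: spec.chroms_per_pop for p in SAMPLED_POPULATIONS
                              if p in model.populations}
        n_loci = n_loci or spec.n_loci
        locus_length = locus_length or spec.locus_length
        seed = spec.seed if seed is None else seed
    if samples is None or n_loci is None or locus_length is None:
        raise ValueError("need a ScenarioSpec or explicit samples/n_loci/locus_length")
    seed = 0 if seed is None else seed
    if any(k % 2 for k in samples.values()):
        raise ValueError("chromosome counts must be even to form diploids")

    n_chroms = sum(samples.values())
    hap_blocks: list[np.ndarray] = []
    chroms: list[str] = []
    positions: list[int] = []
    piece_len = locus_length // sub_loci
    for locus in range(n_loci):
        for piece in range(sub_loci):
            rng = np.random.default_rng([seed % (2**31), locus, piece])
            gen, root, _ = _simulate_locus_genealogy(model, samples, rng)
            hap = _mutations_for_locus(
                gen, root, n_chroms, model.mutation_rate * piece_len, rng
            )
            s = hap.shape[1]
            if s == 0:
                continue
            pos = np.sort(rng.choice(piece_len, size=min(s, piece_len),
                                     replace=False)) + 1 + piece * piece_len
            hap = hap[:, :len(pos)]
            hap_blocks.append(hap)
            chroms.extend([str(locus + 1)] * len(pos))
            positions.extend(int(x) for x in pos)

    if not hap_blocks:
        raise RuntimeError("simulation produced no polymorphic sites")
    hap = np.concatenate(hap_blocks, axis=1)
    dosage = hap[0::2] + hap[1::2]

    sample_ids: list[str] = []
    assignments: dict[str, str] = {}
    for pop, k in samples.items():
        for i in range(k // 2):
            sid = f"{pop}_{i + 1}"
            sample_ids.append(sid)
            assignments[sid] = pop
    markers = make_marker_table(
        [f"c{c}_p{p}" for c, p in zip(chroms, positions)],
        chroms, positions, ["A"] * len(chroms), ["G"] * len(chroms),
    )
    ds = GenotypeDataset(sample_ids, markers, dosage.astype(np.int8))
    return ds, PopulationMap(assignments, list(samples))


def lineage_origin_fractions(
    model: DemographicModel,
    samples: dict[str, int],
    population: str,
    at_time: int,
    n_loci: int = 1000,
    seed: int = 0,
) -> dict[str, float]:
    """Fraction of ``population``'s sampled chromosomes whose ancestral
    lineage sits in each population ``at_time`` generations BP, averaged
    over ``n_loci`` independent genealogies.  Tracks pulse-migration
    bookkeeping: after a pulse of rate m lasting d generations the donor
    fraction should be 1 - (1 - m)^d.
    """
    model.validate()
    offset = 0
    for pop, k in samples.items():
        if pop == population:
            target = list(range(offset, offset + k))
            break
        offset += k
    else:
        raise ValueError(f"{population!r} not among sampled populations")

    tallies: dict[str, int] = {}
    total = 0
    for locus in range(n_loci):
        rng = np.random.default_rng([seed % (2**31), locus, 0])
        _, _, snapshot = _simulate_locus_genealogy(
            model, samples, rng, stop_at=at_time
        )
        assert snapshot is not None
        for leaf in target:
            tallies[snapshot[leaf]] = tallies.get(snapshot[leaf], 0) + 1
            total += 1
    return {pop: c / total for pop, c in sorted(tallies.items())}


def export_fixture(
    ds: GenotypeDataset, popmap: PopulationMap, path: str,
    format: str = "plink-binary",
) -> None:
    """Write a simulated dataset plus its population map TSV."""
    import os

    from .genotype_io import write_dataset

    write_dataset(ds, path, format=format)
    prefix = os.path.splitext(str(path))[0] if format == "vcf" else str(path)
    popmap.to_tsv(prefix + ".populations.tsv")
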