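"""Marker/sample quality control, LD pruning and relatedness filtering.

The relatedness estimator is the classic method-of-moments decomposition of
identity-by-state (IBS) counts into identity-by-descent (IBD) sharing
probabilities, with pi-hat = P(IBD=2) + 0.5 P(IBD=1).  Pairs with
pi-hat above a threshold (0.3 by default downstream) are considered close
relatives and thinned greedily within each population group.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .dataset import MISSING, GenotypeDataset, PopulationMap


@dataclass(frozen=True)
class PruneSpec:
    """Sliding-window LD pruning parameters (PLINK --indep-pairwise style)."""

    window_snps: int = 50
    step_snps: int = 5
    r2_max: float = 0.5

    def __post_init__(self) -> None:
        if self.window_snps < 2:
            raise ValueError("window_snps must be >= 2")
        if not 1 <= self.step_snps <= self.window_snps:
            raise ValueError("step_snps must be in [1, window_snps]")
        if not 0 < self.r2_max <= 1:
            raise ValueError("r2_max must be in (0, 1]")


@dataclass
class IbdEstimate:
    pair: tuple[str, str]
    p_ibd0: float
    p_ibd1: float
    p_ibd2: float
    pi_hat: float
    n_markers: int
    low_confidence: bool = False


class EmptyDatasetError(ValueError):
    """A filter removed every marker (or sample)."""


# ---------------------------------------------------------------------------
# Marker / sample filters
# ---------------------------------------------------------------------------

def filter_samples(ds: GenotypeDataset, min_call_rate: float) -> GenotypeDataset:
    """Drop samples whose genotype call rate is below ``min_call_rate``."""
    keep = np.nonzero(ds.sample_call_rate() >= min_call_rate)[0]
    if keep.size == 0:
        raise EmptyDatasetError("call-rate filter removed every sample")
    return ds.take_samples(keep)


def filter_markers(
    ds: GenotypeDataset, min_call_rate: float = 0.0, min_maf: float = 0.0
) -> GenotypeDataset:
    """Sample call-rate filter followed by a marker MAF filter.

    MAF is computed over the non-missing dosages of the samples that survive
    the call-rate step.  Raises :class:`EmptyDatasetError` if nothing is left.
    """
    if not (0 <= min_call_rate <= 1 and 0 <= min_maf <= 1):
        raise ValueError("thresholds must lie in [0, 1]")
    if min_call_rate > 0:
        ds = filter_samples(ds, min_call_rate)
    maf = ds.maf()
    keep = np.nonzero(np.nan_to_num(maf, nan=-1.0) >= min_maf)[0]
    if keep.size == 0:
        raise EmptyDatasetError("MAF filter removed every marker")
    return ds.take_markers(keep)


# ---------------------------------------------------------------------------
# LD pruning
# ---------------------------------------------------------------------------

def _pairwise_r2(ds: GenotypeDataset, i: int, j: int) -> float:
    """Squared dosage correlation over pairwise-complete samples."""
    gi, gj = ds.genotypes[:, i], ds.genotypes[:, j]
    ok = (gi != MISSING) & (gj != MISSING)
    if ok.sum() < 2:
        return 0.0
    x = gi[ok].astype(float)
    y = gj[ok].astype(float)
    vx, vy = x.var(), y.var()
    if vx == 0.0 or vy == 0.0:
        return 0.0
    c = ((x - x.mean()) * (y - y.mean())).mean()
    return float(c * c / (vx * vy))


def ld_prune(ds: GenotypeDataset, spec: PruneSpec = PruneSpec()) -> list[str]:
    """Windowed greedy LD pruning; returns retained marker ids in input order.

    Within each window of ``window_snps`` markers (advanced by ``step_snps``,
    per chromosome), while some retained pair has r^2 > ``r2_max`` the member
    of the pair with the lower MAF is dropped (ties drop the later marker).
    """
    maf = np.nan_to_num(ds.maf(), nan=0.0)
    retained = np.ones(ds.n_markers, dtype=bool)
    chroms = ds.markers["chrom"].to_numpy()

    for chrom in dict.fromkeys(chroms):
        idx = np.nonzero(chroms == chrom)[0]
        start = 0
        while start < len(idx):
            window = idx[start:start + spec.window_snps]
            for a_pos, i in enumerate(window):
                if not retained[i]:
                    continue
                for j in window[a_pos + 1:]:
                    if not retained[j]:
                        continue
                    if _pairwise_r2(ds, int(i), int(j)) > spec.r2_max:
                        if maf[i] < maf[j]:
                            retained[i] = False
                        else:  # ties remove the later marker
                            retained[j] = False
                    if not retained[i]:
                        break
            if start + spec.window_snps >= len(idx):
                break
            start += spec.step_snps
    return [mid for mid, keep in zip(ds.markers["id"], retained) if keep]


# ---------------------------------------------------------------------------
# IBD / pi-hat
# ---------------------------------------------------------------------------

def estimate_ibd(
    ds: GenotypeDataset,
    pairs: list[tuple[str, str]],
    freqs: np.ndarray | None = None,
    counts: np.ndarray | None = None,
    min_markers: int = 50,
) -> list[IbdEstimate]:
    """Method-of-moments IBD sharing for the given sample pairs.

    ``freqs`` are per-marker alt-allele frequencies and ``counts`` the
    allele-copy counts they were estimated from (both default to the
    dataset's own).  Observed IBS0/1/2 counts over pairwise-complete markers
    are equated with their expectations given IBD state to solve for
    P(IBD=0/1/2); the expectations use unbiased moment estimators of the
    frequency products (a(a-1)(c-a)(c-a-1)/[c(c-1)(c-2)(c-3)] for p^2 q^2
    and so on), which removes the small-sample bias of naive plug-in
    products.  Raw estimates are bounded into [0,1] and renormalised.
    """
    if freqs is None:
        freqs = ds.alt_freq()
        counts = 2.0 * (ds.genotypes != MISSING).sum(axis=0)
    p = np.asarray(freqs, dtype=float)
    if counts is None:
        c = np.full_like(p, np.inf)
    else:
        c = np.asarray(counts, dtype=float)
    informative = ~np.isnan(p) & (p > 0.0) & (p < 1.0) & ((c >= 4) | np.isinf(c))
    q = 1.0 - p

    with np.errstate(invalid="ignore", divide="ignore"):
        a = p * c  # alt-copy counts
        fin = np.isfinite(c)
        # unbiased estimators of pq, p^2 q, p q^2, p^2 q^2, p^3 q, p q^3
        u_pq = np.where(fin, a * (c - a) / (c * (c - 1)), p * q)
        u_p2q = np.where(
            fin, a * (a - 1) * (c - a) / (c * (c - 1) * (c - 2)), p * p * q
        )
        u_pq2 = np.where(
            fin, a * (c - a) * (c - a - 1) / (c * (c - 1) * (c - 2)), p * q * q
        )
        denom4 = c * (c - 1) * (c - 2) * (c - 3)
        u_p2q2 = np.where(
            fin, a * (a - 1) * (c - a) * (c - a - 1) / denom4, p * p * q * q
        )
        u_p3q = np.where(
            fin, a * (a - 1) * (a - 2) * (c - a) / denom4, p**3 * q
        )
        u_pq3 = np.where(
            fin, a * (c - a) * (c - a - 1) * (c - a - 2) / denom4, p * q**3
        )

    # per-marker expected IBS class probabilities given IBD state
    e0_ibd0 = np.nan_to_num(2 * u_p2q2)
    e1_ibd0 = np.nan_to_num(4 * u_p3q + 4 * u_pq3)
    e1_ibd1 = np.nan_to_num(2 * (u_p2q + u_pq2))  # 2pq = 2(p^2 q + p q^2)

    lookup = {s: i for i, s in enumerate(ds.samples)}
    out = []
    for s1, s2 in pairs:
        g1 = ds.genotypes[lookup[s1]]
        g2 = ds.genotypes[lookup[s2]]
        ok = (g1 != MISSING) & (g2 != MISSING) & informative
        n = int(ok.sum())
        if n == 0:
            out.append(IbdEstimate((s1, s2), np.nan, np.nan, np.nan, np.nan, 0, True))
            continue
        diff = np.abs(g1[ok].astype(np.int16) - g2[ok])
        both_het = (g1[ok] == 1) & (g2[ok] == 1)
        ibs0 = int(((diff == 2)).sum())
        ibs1 = int((diff == 1).sum())
        ibs2 = n - ibs0 - ibs1
        # opposite homozygotes (IBS0) only; diff==0 includes both-het (IBS2)
        del both_het

        E0 = float(e0_ibd0[ok].sum())
        E1_0 = float(e1_ibd0[ok].sum())
        E1_1 = float(e1_ibd1[ok].sum())

        z0 = ibs0 / E0 if E0 > 0 else 0.0
        z1 = (ibs1 - z0 * E1_0) / E1_1 if E1_1 > 0 else 0.0
        e2_0 = n - E0 - E1_0
        e2_1 = n - E1_1
        z2 = (ibs2 - z0 * e2_0 - z1 * e2_1) / n
        z = np.clip([z0, z1, z2], 0.0, 1.0)
        total = z.sum()
        z = z / total if total > 0 else np.array([1.0, 0.0, 0.0])
        pi_hat = float(z[2] + 0.5 * z[1])
        out.append(
            IbdEstimate((s1, s2), float(z[0]), float(z[1]), float(z[2]),
                        pi_hat, n, n < min_markers)
        )
    return out


def drop_related(
    ds: GenotypeDataset,
    threshold: float,
    grouping: PopulationMap,
    prune: PruneSpec | None = PruneSpec(),
    min_maf: float = 0.05,
) -> tuple[GenotypeDataset, list[str]]:
    """Remove close relatives (pi-hat > ``threshold``) within each group.

    Mirrors the chip-data workflow: within every population group, markers
    are MAF-filtered and LD-pruned, pi-hat is estimated from the group's own
    allele frequencies, and samples are removed greedily — always the sample
    in the most offending pairs, ties broken by lower call rate then by
    lexicographically later id — until no pair exceeds the threshold.
    """
    removed: list[str] = []
    call_rate = dict(zip(ds.samples, ds.sample_call_rate()))
    for pop in grouping.populations:
        members = [s for s in grouping.samples_of(pop) if s in set(ds.samples)]
        if len(members) < 2:
            continue
        sub = ds.select_samples(members)
        try:
            sub = filter_markers(sub, min_maf=min_maf)
        except EmptyDatasetError:
            continue
        if prune is not None:
            kept_ids = set(ld_prune(sub, prune))
            keep_idx = [j for j, mid in enumerate(sub.markers["id"]) if mid in kept_ids]
            sub = sub.take_markers(keep_idx)
        pairs = [
            (members[a], members[b])
            for a in range(len(members))
            for b in range(a + 1, len(members))
        ]
        ests = estimate_ibd(sub, pairs)
        offending = {
            e.pair for e in ests if np.isfinite(e.pi_hat) and e.pi_hat > threshold
        }
        while offending:
            degree: dict[str, int] = {}
            for a, b in offending:
                degree[a] = degree.get(a, 0) + 1
                degree[b] = degree.get(b, 0) + 1
            # max degree; ties -> lower call rate; then lexicographically later
            victim = max(
                degree,
                key=lambda s: (degree[s], -call_rate[s], s),
            )
            removed.append(victim)
            offending = {p for p in offending if victim not in p}
    kept = [s for s in ds.samples if s not in set(removed)]
    return ds.select_samples(kept), removed
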