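"""Allele-frequency f-statistics with block-jackknife inference.

f2(A,B) is the average squared allele-frequency difference between two
populations, corrected for sampling noise in both; f3(X; A, B) is the
average product (x-a)(x-b) corrected for sampling noise in the target X —
significantly negative values (Z < -2) are evidence that X is admixed
between sources related to A and B; f4(A,B; C,D) is the average product
(a-b)(c-d) and measures drift shared between the two population pairs.

The F4-ratio f4(O', Out; X, Ref2) / f4(O', Out; Ref1, Ref2) estimates the
mixture proportion alpha of the Ref1-related ancestry in an admixed
population X.  Standard errors come from a weighted delete-one-block
jackknife over contiguous SNP blocks, which is robust to local linkage
disequilibrium; for ratios the jackknife is applied to the ratio itself so
correlation between numerator and denominator is handled correctly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .dataset import MISSING, GenotypeDataset, PopulationMap


@dataclass(frozen=True)
class BlockSpec:
    """Contiguous jackknife blocks of ``block_size_snps`` ordered markers."""

    block_size_snps: int = 200

    def __post_init__(self) -> None:
        if self.block_size_snps < 2:
            raise ValueError("block_size_snps must be >= 2")


@dataclass
class FStatResult:
    statistic_name: str
    populations: tuple[str, ...]
    estimate: float
    jackknife_se: float
    z_score: float
    n_snps_used: int
    n_blocks: int
    extra: dict = field(default_factory=dict)

    def __repr__(self) -> str:  # compact, table-friendly
        pops = ",".join(self.populations)
        return (
            f"{self.statistic_name}({pops}) = {self.estimate:.6g} "
            f"+/- {self.jackknife_se:.3g} (Z = {self.z_score:.2f}, "
            f"{self.n_snps_used} SNPs, {self.n_blocks} blocks)"
        )


@dataclass
class FreqTable:
    """Per-population per-marker alt-allele frequencies and copy counts.

    ``freq[p, m]`` is NaN and ``count[p, m]`` is 0 when a population has no
    called genotype at a marker (the marker is masked for that population).
    ``markers`` preserves the dataset's (chromosome, position) ordering on
    which jackknife blocks are defined.
    """

    populations: list[str]
    markers: pd.DataFrame
    freq: np.ndarray   # P x M float
    count: np.ndarray  # P x M float (allele copies; may be inf for
                       # population-level frequencies known without error)

    def __post_init__(self) -> None:
        self.freq = np.asarray(self.freq, dtype=float)
        self.count = np.asarray(self.count, dtype=float)
        P, M = len(self.populations), len(self.markers)
        if self.freq.shape != (P, M) or self.count.shape != (P, M):
            raise ValueError("freq/count shape must be populations x markers")

    @property
    def n_markers(self) -> int:
        return len(self.markers)

    def index_of(self, population: str) -> int:
        try:
            return self.populations.index(population)
        except ValueError:
            raise KeyError(f"population {population!r} not in table") from None

    @classmethod
    def from_frequencies(
        cls, populations: list[str], freq: np.ndarray, count: np.ndarray | None = None
    ) -> "FreqTable":
        """Build a table directly from frequencies (counts default to inf,
        i.e. population-level frequencies with no sampling noise)."""
        freq = np.atleast_2d(np.asarray(freq, dtype=float))
        if count is None:
            count = np.full_like(freq, np.inf)
        markers = pd.DataFrame(
            {
                "id": [f"snp{i}" for i in range(freq.shape[1])],
                "chrom": "1",
                "pos": np.arange(1, freq.shape[1] + 1),
            }
        )
        return cls(list(populations), markers, freq, np.atleast_2d(count))


def allele_freqs(ds: GenotypeDataset, popmap: PopulationMap) -> FreqTable:
    """Per-population alt-allele frequency = alt copies / non-missing copies."""
    pops = popmap.populations
    P, M = len(pops), ds.n_markers
    freq = np.full((P, M), np.nan)
    count = np.zeros((P, M))
    sample_idx = {s: i for i, s in enumerate(ds.samples)}
    for pi, pop in enumerate(pops):
        rows = [sample_idx[s] for s in popmap.samples_of(pop) if s in sample_idx]
        if not rows:
            raise ValueError(f"population {pop!r} has no samples in the dataset")
        g = ds.genotypes[rows, :]
        called = g != MISSING
        copies = 2.0 * called.sum(axis=0)
        alt = np.where(called, g, 0).sum(axis=0)
        count[pi] = copies
        with np.errstate(invalid="ignore", divide="ignore"):
            freq[pi] = np.where(copies > 0, alt / copies, np.nan)
    return FreqTable(list(pops), ds.markers[["id", "chrom", "pos"]].copy(), freq, count)


# ---------------------------------------------------------------------------
# Weighted block jackknife
# ---------------------------------------------------------------------------

def _block_ids(n_markers: int, blocks: BlockSpec) -> np.ndarray:
    return np.arange(n_markers) // blocks.block_size_snps


def _busing_se(theta_hat: float, theta_del: np.ndarray, m: np.ndarray) -> float:
    """Weighted delete-one-block jackknife SE (weights = block SNP counts)."""
    n = m.sum()
    g = len(m)
    h = n / m
    theta_j = g * theta_hat - np.sum((1.0 - m / n) * theta_del)
    tau = h * theta_hat - (h - 1.0) * theta_del
    var = np.sum((tau - theta_j) ** 2 / (h - 1.0)) / g
    return float(np.sqrt(var))


def _jackknife_mean(
    terms: np.ndarray, used: np.ndarray, blocks: BlockSpec
) -> tuple[float, float, int, int]:
    """Mean of per-SNP terms with block-jackknife SE.

    Returns (estimate, se, n_snps, n_blocks).
    """
    bid = _block_ids(terms.size, blocks)
    t = np.where(used, terms, 0.0)
    sums = np.bincount(bid, weights=t)
    counts = np.bincount(bid, weights=used.astype(float))
    keep = counts > 0
    sums, counts = sums[keep], counts[keep]
    g = len(sums)
    if g < 2:
        raise ValueError(f"need >= 2 usable jackknife blocks, got {g}")
    S, N = sums.sum(), counts.sum()
    est = S / N
    theta_del = (S - sums) / (N - counts)
    se = _busing_se(est, theta_del, counts)
    return float(est), se, int(N), g


def _jackknife_ratio(
    num: np.ndarray, den: np.ndarray, used: np.ndarray, blocks: BlockSpec
) -> tuple[float, float, int, int]:
    """Ratio of per-SNP sums with the jackknife applied to the ratio."""
    bid = _block_ids(num.size, blocks)
    a = np.bincount(bid, weights=np.where(used, num, 0.0))
    b = np.bincount(bid, weights=np.where(used, den, 0.0))
    counts = np.bincount(bid, weights=used.astype(float))
    keep = counts > 0
    a, b, counts = a[keep], b[keep], counts[keep]
    g = len(a)
    if g < 2:
        raise ValueError(f"need >= 2 usable jackknife blocks, got {g}")
    A, B = a.sum(), b.sum()
    est = A / B
    theta_del = (A - a) / (B - b)
    se = _busing_se(est, theta_del, counts)
    return float(est), se, int(counts.sum()), g


def _result(name, pops, est, se, n_snps, n_blocks, **extra) -> FStatResult:
    z = est / se if se > 0 else (0.0 if est == 0 else np.inf * np.sign(est))
    return FStatResult(name, tuple(pops), est, se, float(z), n_snps, n_blocks,
                       dict(extra))


# ---------------------------------------------------------------------------
# f-statistics
# ---------------------------------------------------------------------------

def _cols(freqs: FreqTable, pops) -> tuple[np.ndarray, np.ndarray]:
    idx = [freqs.index_of(p) for p in pops]
    return freqs.freq[idx], freqs.count[idx]


def f2(
    A: str, B: str, freqs: FreqTable, blocks: BlockSpec = BlockSpec(),
    corrected: bool = True,
) -> FStatResult:
    """f2(A,B): mean squared frequency difference, bias-corrected for the
    sampling noise of both populations."""
    (a, b), (na, nb) = _cols(freqs, [A, B])
    used = ~np.isnan(a) & ~np.isnan(b) & (na >= 2) & (nb >= 2)
    terms = (a - b) ** 2
    if corrected:
        with np.errstate(invalid="ignore", divide="ignore"):
            terms = terms - a * (1 - a) / (na - 1) - b * (1 - b) / (nb - 1)
    terms = np.nan_to_num(terms)  # inf counts give a zero correction
    est, se, n, g = _jackknife_mean(terms, used, blocks)
    return _result("f2", (A, B), est, se, n, g)


def f3(
    X: str, A: str, B: str, freqs: FreqTable, blocks: BlockSpec = BlockSpec(),
    corrected: bool = True,
) -> FStatResult:
    """Three-population statistic f3(X; A, B).

    Per-SNP term (x-a)(x-b) - x(1-x)/(n_X - 1) where n_X counts non-missing
    allele copies in the target; the subtraction removes the upward bias from
    sampling noise in X.  Z < -2 signals admixture in X.
    """
    (x, a, b), (nx, _, _) = _cols(freqs, [X, A, B])
    used = ~(np.isnan(x) | np.isnan(a) | np.isnan(b)) & (nx >= 2)
    terms = (x - a) * (x - b)
    if corrected:
        with np.errstate(invalid="ignore", divide="ignore"):
            correction = np.where(np.isinf(nx), 0.0, x * (1 - x) / (nx - 1))
        terms = terms - correction
    terms = np.nan_to_num(terms)
    est, se, n, g = _jackknife_mean(terms, used, blocks)
    return _result("f3", (X, A, B), est, se, n, g)


def f4(
    A: str, B: str, C: str, D: str, freqs: FreqTable,
    blocks: BlockSpec = BlockSpec(),
) -> FStatResult:
    """f4(A,B; C,D): mean of (a-b)(c-d) over complete-case SNPs.

    No bias correction is needed when no population repeats across the two
    pairs: sampling errors are independent and the product is unbiased.
    """
    (a, b, c, d), _ = _cols(freqs, [A, B, C, D])
    used = ~(np.isnan(a) | np.isnan(b) | np.isnan(c) | np.isnan(d))
    terms = np.nan_to_num((a - b) * (c - d))
    est, se, n, g = _jackknife_mean(terms, used, blocks)
    return _result("f4", (A, B, C, D), est, se, n, g)


def f4_ratio(
    euw: str, outgroup: str, eud: str, bmx: str, ib: str,
    freqs: FreqTable, blocks: BlockSpec = BlockSpec(),
) -> FStatResult:
    """Admixture proportion via the F4-ratio.

    alpha = f4(euw, outgroup; eud, bmx) / f4(euw, outgroup; ib, bmx)
    is the fraction of ib-related ancestry in the admixed population ``eud``;
    1 - alpha (reported in ``extra['alt_ancestry_fraction']``) is the
    bmx-related fraction.  Both f4 sums run over SNPs complete in all five
    populations and the jackknife resamples the ratio itself.
    """
    (w, o, x, m, r), _ = _cols(freqs, [euw, outgroup, eud, bmx, ib])
    used = ~(np.isnan(w) | np.isnan(o) | np.isnan(x) | np.isnan(m) | np.isnan(r))
    num = np.nan_to_num((w - o) * (x - m))
    den = np.nan_to_num((w - o) * (r - m))
    est, se, n, g = _jackknife_ratio(num, den, used, blocks)

    den_est, den_se, _, _ = _jackknife_mean(den, used, blocks)
    unstable = abs(den_est) < 10.0 * den_se
    res = _result(
        "f4-ratio", (euw, outgroup, eud, bmx, ib), est, se, n, g,
        alt_ancestry_fraction=1.0 - est,
        denominator_unstable=bool(unstable),
    )
    return res


def three_pop_scan(
    target: str,
    source_pairs: list[tuple[str, str]],
    freqs: FreqTable,
    blocks: BlockSpec = BlockSpec(),
    z_threshold: float = -2.0,
) -> pd.DataFrame:
    """f3(target; A, B) for every source pair, sorted by Z score.

    Rows with Z below ``z_threshold`` are flagged significant; the most
    significantly negative pair sorts first.
    """
    rows = []
    for A, B in source_pairs:
        r = f3(target, A, B, freqs, blocks)
        rows.append(
            {
                "target": target, "source_a": A, "source_b": B,
                "f3": r.estimate, "se": r.jackknife_se, "z": r.z_score,
                "n_snps": r.n_snps_used, "n_blocks": r.n_blocks,
                "significant": r.z_score < z_threshold,
            }
        )
    df = pd.DataFrame(
        rows,
        columns=["target", "source_a", "source_b", "f3", "se", "z",
                 "n_snps", "n_blocks", "significant"],
    )
    return df.sort_values("z", kind="stable").reset_index(drop=True)
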