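import numpy as np
import pytest

from admixkit.dataset import PopulationMap
from admixkit.fstats import (
    BlockSpec,
    FreqTable,
    allele_freqs,
    f2,
    f3,
    f4,
    f4_ratio,
    three_pop_scan,
)

from conftest import build_dataset


def _table(pops, freq, count=None):
    return FreqTable.from_frequencies(pops, np.asarray(freq, dtype=float), count)


def _rand_table(rng, pops, m=400):
    freq = rng.uniform(0.05, 0.95, (len(pops), m))
    return _table(pops, freq)


# ---------------------------------------------------------------------------
# allele_freqs
# ---------------------------------------------------------------------------

def test_allele_freqs_counts_and_masking():
    ds = build_dataset([[1, -1], [2, -1]])
    pm = PopulationMap({"s1": "A", "s2": "B"})
    ft = allele_freqs(ds, pm)
    assert ft.freq[0, 0] == pytest.approx(0.5)   # one heterozygote
    assert ft.count[0, 0] == 2
    assert np.isnan(ft.freq[0, 1])               # all missing -> masked
    assert ft.count[0, 1] == 0


def test_allele_freqs_unchanged_by_self_merge():
    from admixkit.genotype_io import merge_datasets

    rng = np.random.default_rng(0)
    g = rng.integers(0, 3, (6, 20)).astype(np.int8)
    ds = build_dataset(g, positions=list(range(1, 21)))
    merged = merge_datasets([ds, ds])
    pm1 = PopulationMap({s: "P" for s in ds.samples})
    pm2 = PopulationMap({s: "P" for s in merged.samples})
    f1 = allele_freqs(ds, pm1)
    f12 = allele_freqs(merged, pm2)
    keep = [list(merged.markers["id"]).index(m) for m in f1.markers["id"]
            if m in set(merged.markers["id"])]
    shared = [m for m in f1.markers["id"] if m in set(merged.markers["id"])]
    orig = [list(f1.markers["id"]).index(m) for m in shared]
    assert np.allclose(f12.freq[0, keep], f1.freq[0, orig])


# ---------------------------------------------------------------------------
# f3 / f4 point values
# ---------------------------------------------------------------------------

def test_f3_zero_when_target_equals_source():
    rng = np.random.default_rng(1)
    x = rng.uniform(0.1, 0.9, 400)
    b = rng.uniform(0.1, 0.9, 400)
    ft = _table(["X", "A", "B"], [x, x, b])
    r = f3("X", "A", "B", ft, BlockSpec(100))
    assert r.estimate == pytest.approx(0.0, abs=1e-15)


def test_f3_hand_computed_product():
    """x=0.5, a=0.1, b=0.9 with population-level counts: per-SNP term
    (0.5-0.1)(0.5-0.9) = -0.16."""
    ft = _table(["X", "A", "B"], [[0.5] * 4, [0.1] * 4, [0.9] * 4])
    r = f3("X", "A", "B", ft, BlockSpec(2))
    assert r.estimate == pytest.approx(-0.16)


def test_f3_correction_unbiased_binomial_oracle():
    """The x(1-x)/(n-1) correction: mean corrected term over binomial
    resamples of the target matches the population-level product."""
    rng = np.random.default_rng(2)
    n_draws, n_dip = 20_000, 10
    px, pa, pb = 0.4, 0.1, 0.8
    gx = rng.binomial(2, px, (n_dip, n_draws))
    xhat = gx.mean(axis=0) / 2.0
    n_c = 2 * n_dip
    terms = (xhat - pa) * (xhat - pb) - xhat * (1 - xhat) / (n_c - 1)
    target = (px - pa) * (px - pb)
    mc_se = terms.std(ddof=1) / np.sqrt(n_draws)
    assert abs(terms.mean() - target) < 3 * mc_se


def test_f4_zero_for_repeated_pair_and_fixed_difference():
    rng = np.random.default_rng(3)
    a = rng.uniform(0.1, 0.9, 200)
    c = rng.uniform(0.1, 0.9, 200)
    d = rng.uniform(0.1, 0.9, 200)
    ft = _table(["A", "B", "C", "D"], [a, a, c, d])
    assert f4("A", "B", "C", "D", ft, BlockSpec(50)).estimate == 0.0
    ft2 = _table(["A", "B", "C", "D"], [[1] * 4, [0] * 4, [1] * 4, [0] * 4])
    assert f4("A", "B", "C", "D", ft2, BlockSpec(2)).estimate == pytest.approx(1.0)


def test_f4_antisymmetry_exact():
    rng = np.random.default_rng(4)
    ft = _rand_table(rng, ["A", "B", "C", "D"])
    blocks = BlockSpec(64)
    r1 = f4("A", "B", "C", "D", ft, blocks)
    r2 = f4("B", "A", "C", "D", ft, blocks)
    assert r1.estimate == pytest.approx(-r2.estimate, abs=1e-15)
    assert r1.jackknife_se == pytest.approx(r2.jackknife_se, rel=1e-12)


def test_f2_identity_with_f4():
    """f4(A,B;A,B) = f2(A,B) on population-level frequencies."""
    rng = np.random.default_rng(5)
    ft = _rand_table(rng, ["A", "B"])
    blocks = BlockSpec(80)
    assert f4("A", "B", "A", "B", ft, blocks).estimate == pytest.approx(
        f2("A", "B", ft, blocks).estimate, abs=1e-15
    )


def test_f3_additivity_in_f2():
    """f3(X;A,B) = (f2(X,A)+f2(X,B)-f2(A,B))/2 without corrections."""
    rng = np.random.default_rng(6)
    ft = _rand_table(rng, ["X", "A", "B"])
    blocks = BlockSpec(80)
    lhs = f3("X", "A", "B", ft, blocks).estimate
    rhs = 0.5 * (
        f2("X", "A", ft, blocks).estimate
        + f2("X", "B", ft, blocks).estimate
        - f2("A", "B", ft, blocks).estimate
    )
    assert lhs == pytest.approx(rhs, abs=1e-14)


def test_f2_fixed_difference_and_self_distance():
    ft = _table(["A", "B"], [[1] * 4, [0] * 4])
    assert f2("A", "B", ft, BlockSpec(2)).estimate == pytest.approx(1.0)
    rng = np.random.default_rng(7)
    a = rng.uniform(0.1, 0.9, 100)
    ft2 = _table(["A", "B"], [a, a])
    assert f2("A", "B", ft2, BlockSpec(25)).estimate == pytest.approx(0.0, abs=1e-15)


# ---------------------------------------------------------------------------
# Block jackknife
# ---------------------------------------------------------------------------

def test_jackknife_se_zero_for_block_constant_statistic():
    """A statistic constant across blocks has SE exactly 0."""
    ft = _table(["X", "A", "B"], [[0.5] * 120, [0.1] * 120, [0.9] * 120])
    r = f3("X", "A", "B", ft, BlockSpec(30))
    assert r.jackknife_se == 0.0


def test_jackknife_requires_two_blocks():
    ft = _table(["X", "A", "B"], [[0.5, 0.4], [0.1, 0.2], [0.9, 0.8]])
    with pytest.raises(ValueError):
        f3("X", "A", "B", ft, BlockSpec(10))  # single block only


def test_short_final_block_kept_and_weighted():
    rng = np.random.default_rng(8)
    ft = _rand_table(rng, ["X", "A", "B"], m=250)  # blocks of 100: 100/100/50
    r = f3("X", "A", "B", ft, BlockSpec(100))
    assert r.n_blocks == 3
    assert r.n_snps_used == 250


def test_masked_snps_excluded():
    freq = np.array([[0.5, 0.5, 0.5], [0.1, np.nan, 0.1], [0.9, 0.9, 0.9]])
    count = np.array([[np.inf] * 3, [0.0, 0.0, np.inf], [np.inf] * 3])
    count[1, 0] = np.inf
    ft = _table(["X", "A", "B"], freq, count)
    r = f3("X", "A", "B", ft, BlockSpec(2))
    assert r.n_snps_used == 2


# ---------------------------------------------------------------------------
# F4-ratio
# ---------------------------------------------------------------------------

def test_f4_ratio_degenerate_endpoints():
    rng = np.random.default_rng(9)
    m = 300
    w, o, bmx, ib = (rng.uniform(0.05, 0.95, m) for _ in range(4))
    blocks = BlockSpec(50)
    ft_one = _table(["EUW", "Sum", "EUD", "BMX", "IB"], [w, o, ib, bmx, ib])
    r1 = f4_ratio("EUW", "Sum", "EUD", "BMX", "IB", ft_one, blocks)
    assert r1.estimate == pytest.approx(1.0, abs=1e-12)
    assert r1.extra["alt_ancestry_fraction"] == pytest.approx(0.0, abs=1e-12)
    ft_zero = _table(["EUW", "Sum", "EUD", "BMX", "IB"], [w, o, bmx, bmx, ib])
    r0 = f4_ratio("EUW", "Sum", "EUD", "BMX", "IB", ft_zero, blocks)
    assert r0.estimate == pytest.approx(0.0, abs=1e-12)


def test_f4_ratio_flags_unstable_denominator():
    rng = np.random.default_rng(10)
    m = 300
    w = rng.uniform(0.05, 0.95, m)
    o = w + rng.normal(0, 1e-4, m)  # nearly identical: denominator ~ 0
    bmx, ib, eud = (rng.uniform(0.05, 0.95, m) for _ in range(3))
    ft = _table(["EUW", "Sum", "EUD", "BMX", "IB"], [w, o, eud, bmx, ib])
    r = f4_ratio("EUW", "Sum", "EUD", "BMX", "IB", ft, BlockSpec(50))
    assert r.extra["denominator_unstable"]


# ---------------------------------------------------------------------------
# three_pop_scan
# ---------------------------------------------------------------------------

def test_scan_orders_by_z_and_flags():
    rng = np.random.default_rng(11)
    m = 600
    a, b = rng.uniform(0.05, 0.95, (2, m))
    x_adm = 0.5 * a + 0.5 * b + rng.normal(0, 0.01, m)
    x_adm = np.clip(x_adm, 0.01, 0.99)
    c = rng.uniform(0.05, 0.95, m)
    ft = _table(["X", "A", "B", "C"], [x_adm, a, b, c])
    table = three_pop_scan("X", [("A", "B"), ("A", "C"), ("B", "C")], ft,
                           BlockSpec(100))
    assert list(table["z"]) == sorted(table["z"])
    assert table.iloc[0][["source_a", "source_b"]].tolist() == ["A", "B"]
    assert bool(table.iloc[0]["significant"])


def test_scan_empty_source_list():
    rng = np.random.default_rng(12)
    ft = _rand_table(rng, ["X", "A", "B"])
    table = three_pop_scan("X", [], ft, BlockSpec(100))
    assert len(table) == 0
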