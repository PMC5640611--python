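import numpy as np
import pytest

from admixkit.dataset import PopulationMap
from admixkit.qc import (
    EmptyDatasetError,
    PruneSpec,
    drop_related,
    estimate_ibd,
    filter_markers,
    filter_samples,
    ld_prune,
)

from conftest import build_dataset


# ---------------------------------------------------------------------------
# MAF / call-rate filters
# ---------------------------------------------------------------------------

def test_maf_filter_direct_count():
    """Dosages (0,0,0,1) over 4 diploids: MAF 1/8 = 0.125 survives 0.05;
    a monomorphic marker is removed at any positive threshold."""
    ds = build_dataset([[0, 0], [0, 0], [0, 0], [1, 0]])
    kept = filter_markers(ds, min_maf=0.05)
    assert list(kept.markers["id"]) == ["snp1"]
    assert kept.maf()[0] == pytest.approx(0.125)


def test_maf_filter_retained_markers_all_pass():
    rng = np.random.default_rng(1)
    g = rng.binomial(2, rng.uniform(0.01, 0.5, 50), (30, 50)).astype(np.int8)
    kept = filter_markers(build_dataset(g), min_maf=0.1)
    assert (kept.maf() >= 0.1).all()


def test_call_rate_filter_removes_low_coverage_sample():
    """A sample with 94% call rate is removed at the 95% threshold."""
    g = np.ones((2, 100), dtype=np.int8)
    g[1, :6] = -1  # 94% call rate
    ds = build_dataset(g, positions=list(range(1, 101)))
    kept = filter_samples(ds, 0.95)
    assert kept.samples == ["s1"]
    with pytest.raises(EmptyDatasetError):
        filter_samples(ds, 1.01)


def test_all_markers_removed_errors():
    ds = build_dataset([[0, 0], [0, 0]])
    with pytest.raises(EmptyDatasetError):
        filter_markers(ds, min_maf=0.05)


# ---------------------------------------------------------------------------
# LD pruning
# ---------------------------------------------------------------------------

def _oracle_prune(ds, spec):
    """Independent re-statement of the windowed greedy rule."""
    from itertools import combinations

    maf = np.nan_to_num(ds.maf(), nan=0.0)
    retained = {i for i in range(ds.n_markers)}

    def r2(i, j):
        gi, gj = ds.genotypes[:, i].astype(float), ds.genotypes[:, j].astype(float)
        ok = (ds.genotypes[:, i] != -1) & (ds.genotypes[:, j] != -1)
        if ok.sum() < 2 or gi[ok].var() == 0 or gj[ok].var() == 0:
            return 0.0
        return np.corrcoef(gi[ok], gj[ok])[0, 1] ** 2

    chroms = list(ds.markers["chrom"])
    for chrom in dict.fromkeys(chroms):
        idx = [i for i, c in enumerate(chroms) if c == chrom]
        start = 0
        while start < len(idx):
            win = idx[start:start + spec.window_snps]
            for i, j in combinations(win, 2):
                if i in retained and j in retained and r2(i, j) > spec.r2_max:
                    if maf[i] < maf[j]:
                        retained.discard(i)
                    else:
                        retained.discard(j)
            if start + spec.window_snps >= len(idx):
                break
            start += spec.step_snps
    return [ds.markers["id"][i] for i in sorted(retained)]


def test_prune_uncorrelated_markers_all_kept():
    rng = np.random.default_rng(2)
    g = rng.binomial(2, 0.5, (200, 10)).astype(np.int8)
    ds = build_dataset(g, positions=list(range(1, 11)))
    assert ld_prune(ds, PruneSpec(5, 2, 0.5)) == list(ds.markers["id"])


def test_prune_duplicate_marker_keeps_one():
    rng = np.random.default_rng(3)
    col = rng.binomial(2, 0.5, 50).astype(np.int8)
    g = np.column_stack([col, col, rng.binomial(2, 0.5, 50)]).astype(np.int8)
    ds = build_dataset(g)
    kept = ld_prune(ds, PruneSpec(3, 1, 0.5))
    assert sum(m in kept for m in ("snp1", "snp2")) == 1


def test_prune_matches_greedy_oracle():
    """Constructed correlated fixture: retained set equals a brute-force
    oracle applying the same windowed greedy rule."""
    rng = np.random.default_rng(4)
    base = rng.binomial(2, 0.5, 40).astype(float)
    cols = []
    for k in range(8):
        noise = rng.binomial(2, 0.5, 40)
        lam = [1.0, 0.9, 0.1, 0.8, 0.5, 0.95, 0.0, 0.7][k]
        mixed = np.where(rng.random(40) < lam, base, noise)
        cols.append(mixed)
    g = np.column_stack(cols).astype(np.int8)
    ds = build_dataset(g, positions=list(range(1, 9)))
    spec = PruneSpec(5, 2, 0.5)
    assert ld_prune(ds, spec) == _oracle_prune(ds, spec)


def test_prune_leaves_no_window_pair_above_threshold():
    rng = np.random.default_rng(6)
    base = rng.binomial(2, 0.5, (60, 4)).astype(np.int8)
    g = np.repeat(base, 3, axis=1)  # triplicated columns, heavy LD
    ds = build_dataset(g, positions=list(range(1, 13)))
    spec = PruneSpec(6, 3, 0.5)
    kept = ld_prune(ds, spec)
    idx = [i for i, m in enumerate(ds.markers["id"]) if m in set(kept)]
    from admixkit.qc import _pairwise_r2

    for a in range(len(idx)):
        for b in range(a + 1, len(idx)):
            if abs(idx[a] - idx[b]) < spec.window_snps:
                assert _pairwise_r2(ds, idx[a], idx[b]) <= spec.r2_max + 1e-12


# ---------------------------------------------------------------------------
# IBD / pi-hat
# ---------------------------------------------------------------------------

def _freq_panel(rng, n, m):
    p = rng.uniform(0.1, 0.9, m)
    return rng.binomial(2, p, (n, m)).astype(np.int8)


def test_pi_hat_duplicate_is_one():
    rng = np.random.default_rng(7)
    g = _freq_panel(rng, 10, 500)
    g[1] = g[0]  # exact copy
    ds = build_dataset(g, positions=list(range(1, 501)))
    est = estimate_ibd(ds, [("s1", "s2")])[0]
    assert est.pi_hat == pytest.approx(1.0, abs=0.02)


def test_pi_hat_unrelated_near_zero():
    """Independent draws from one random-mating population: pi-hat ~ 0."""
    rng = np.random.default_rng(8)
    for _ in range(10):
        ds = build_dataset(_freq_panel(rng, 2, 5000),
                           positions=list(range(1, 5001)))
        est = estimate_ibd(ds, [("s1", "s2")])[0]
        assert abs(est.pi_hat) < 0.05


def test_pi_hat_parent_offspring_half():
    """Mendelian offspring of two panel parents: pi-hat ~ 0.5 with both."""
    rng = np.random.default_rng(9)
    g = _freq_panel(rng, 2, 5000)
    child = (
        (rng.random(5000) < g[0] / 2.0).astype(np.int8)
        + (rng.random(5000) < g[1] / 2.0).astype(np.int8)
    )
    ds = build_dataset(np.vstack([g, child]), positions=list(range(1, 5001)))
    est = estimate_ibd(ds, [("s1", "s3"), ("s2", "s3")])
    for e in est:
        assert e.pi_hat == pytest.approx(0.5, abs=0.05)
        assert e.p_ibd0 < 0.05


def test_pi_hat_symmetric_and_order_invariant():
    rng = np.random.default_rng(10)
    g = _freq_panel(rng, 3, 800)
    ds = build_dataset(g, positions=list(range(1, 801)))
    ab = estimate_ibd(ds, [("s1", "s2")])[0].pi_hat
    ba = estimate_ibd(ds, [("s2", "s1")])[0].pi_hat
    perm = rng.permutation(ds.n_markers)
    shuffled = ds.take_markers(perm)
    ab_shuffled = estimate_ibd(shuffled, [("s1", "s2")])[0].pi_hat
    assert ab == pytest.approx(ba, abs=1e-12)
    assert ab == pytest.approx(ab_shuffled, abs=1e-9)


def test_low_overlap_flagged():
    g = np.full((2, 60), -1, dtype=np.int8)
    g[:, :30] = 1
    ds = build_dataset(g, positions=list(range(1, 61)))
    est = estimate_ibd(ds, [("s1", "s2")])[0]
    assert est.low_confidence


# ---------------------------------------------------------------------------
# Relatedness removal
# ---------------------------------------------------------------------------

def test_drop_related_no_pairs_above_threshold():
    rng = np.random.default_rng(12)
    g = _freq_panel(rng, 6, 2000)
    ds = build_dataset(g, positions=list(range(1, 2001)))
    pm = PopulationMap({s: "P" for s in ds.samples})
    kept, removed = drop_related(ds, 0.3, pm, prune=None, min_maf=0.05)
    assert removed == []
    assert kept.n_samples == 6


def test_drop_related_removes_one_of_duplicate_pair():
    rng = np.random.default_rng(13)
    g = _freq_panel(rng, 5, 2000)
    g[1] = g[0]
    ds = build_dataset(g, positions=list(range(1, 2001)))
    pm = PopulationMap({s: "P" for s in ds.samples})
    kept, removed = drop_related(ds, 0.3, pm, prune=None, min_maf=0.05)
    assert len(removed) == 1 and removed[0] in {"s1", "s2"}


def test_drop_related_star_removes_hub():
    """pi-hat graph is a star: the hub (a parent of all others) goes."""
    rng = np.random.default_rng(14)
    m = 4000
    hub = _freq_panel(rng, 1, m)[0]
    others = []
    for _ in range(4):
        mate = _freq_panel(rng, 1, m)[0]
        child = (
            (rng.random(m) < hub / 2.0).astype(np.int8)
            + (rng.random(m) < mate / 2.0).astype(np.int8)
        )
        others.append(child)
    g = np.vstack([hub, *others])
    ds = build_dataset(g, positions=list(range(1, m + 1)),
                       samples=["hub", "c1", "c2", "c3", "c4"])
    pm = PopulationMap({s: "P" for s in ds.samples})
    kept, removed = drop_related(ds, 0.3, pm, prune=None, min_maf=0.05)
    assert removed == ["hub"]
    # greedy-vertex-cover oracle: removing the hub clears every edge
    ests = estimate_ibd(kept, [("c1", "c2"), ("c1", "c3"), ("c2", "c4")])
    assert all(e.pi_hat <= 0.3 for e in ests)
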