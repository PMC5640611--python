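"""Core in-memory containers for diploid SNP genotype data.

A :class:`GenotypeDataset` holds a samples x markers matrix of
alternate-allele dosages (0, 1, 2, or -1 for missing) together with marker
metadata (id, chromosome, 1-based position, ref/alt alleles) and the sample
ids.  A :class:`PopulationMap` assigns samples to named populations and is
the grouping handle used by every downstream analysis (allele frequencies,
f-statistics, relatedness scopes, tree leaves).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

MISSING = -1

MARKER_COLUMNS = ["id", "chrom", "pos", "ref", "alt"]


def _chrom_sort_key(chrom: pd.Series) -> pd.Series:
    """Numeric-aware chromosome ordering ('1' < '2' < '10' < 'X')."""
    num = pd.to_numeric(chrom, errors="coerce")
    # non-numeric labels sort after numeric ones, alphabetically
    return pd.Series(
        list(zip(num.isna(), num.fillna(0), chrom.astype(str))), index=chrom.index
    )


def make_marker_table(
    ids, chroms, positions, ref_alleles, alt_alleles
) -> pd.DataFrame:
    df = pd.DataFrame(
        {
            "id": np.asarray(ids, dtype=object),
            "chrom": np.asarray(chroms, dtype=object).astype(str),
            "pos": np.asarray(positions, dtype=np.int64),
            "ref": np.asarray(ref_alleles, dtype=object),
            "alt": np.asarray(alt_alleles, dtype=object),
        }
    )
    return df


@dataclass
class GenotypeDataset:
    """Samples x markers diploid genotype matrix with metadata.

    Attributes
    ----------
    samples:
        Ordered sample ids (unique).
    markers:
        DataFrame with columns ``id, chrom, pos, ref, alt``; one row per
        marker, in matrix column order.
    genotypes:
        ``int8`` array of shape ``(n_samples, n_markers)`` holding the count
        of the alt allele (0/1/2) or ``-1`` for missing.
    """

    samples: list[str]
    markers: pd.DataFrame
    genotypes: np.ndarray

    def __post_init__(self) -> None:
        self.genotypes = np.asarray(self.genotypes, dtype=np.int8)
        if self.genotypes.shape != (len(self.samples), len(self.markers)):
            raise ValueError(
                f"genotype matrix shape {self.genotypes.shape} does not match "
                f"{len(self.samples)} samples x {len(self.markers)} markers"
            )
        if self.genotypes.size and not (
            self.genotypes.min() >= MISSING and self.genotypes.max() <= 2
        ):  # int8 in [-1, 2] <=> {0,1,2,missing}
            raise ValueError("dosages must be 0, 1, 2 or -1 (missing)")
        if len(set(self.samples)) != len(self.samples):
            raise ValueError("duplicate sample ids")
        if self.markers["id"].duplicated().any():
            dups = self.markers.loc[self.markers["id"].duplicated(), "id"]
            raise ValueError(f"duplicate marker ids, e.g. {dups.iloc[0]!r}")
        self.markers = self.markers.reset_index(drop=True)

    # -- basic properties -------------------------------------------------
    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_markers(self) -> int:
        return len(self.markers)

    def missing_mask(self) -> np.ndarray:
        return self.genotypes == MISSING

    def sample_call_rate(self) -> np.ndarray:
        """Fraction of non-missing genotypes per sample."""
        if self.n_markers == 0:
            return np.ones(self.n_samples)
        return 1.0 - self.missing_mask().mean(axis=1)

    def marker_call_rate(self) -> np.ndarray:
        if self.n_samples == 0:
            return np.ones(self.n_markers)
        return 1.0 - self.missing_mask().mean(axis=0)

    def alt_freq(self) -> np.ndarray:
        """Per-marker alt-allele frequency over non-missing dosages (NaN if all missing)."""
        g = np.ma.masked_equal(self.genotypes, MISSING)
        with np.errstate(invalid="ignore"):
            return np.asarray(g.mean(axis=0).filled(np.nan)) / 2.0

    def maf(self) -> np.ndarray:
        p = self.alt_freq()
        return np.minimum(p, 1.0 - p)

    # -- subsetting -------------------------------------------------------
    def take_samples(self, index: np.ndarray | list[int]) -> "GenotypeDataset":
        index = np.asarray(index, dtype=np.intp)
        return GenotypeDataset(
            [self.samples[i] for i in index],
            self.markers.copy(),
            self.genotypes[index, :],
        )

    def take_markers(self, index: np.ndarray | list[int]) -> "GenotypeDataset":
        index = np.asarray(index, dtype=np.intp)
        return GenotypeDataset(
            list(self.samples),
            self.markers.iloc[index].reset_index(drop=True),
            self.genotypes[:, index],
        )

    def select_samples(self, ids: list[str]) -> "GenotypeDataset":
        lookup = {s: i for i, s in enumerate(self.samples)}
        return self.take_samples([lookup[s] for s in ids])

    def sort_markers(self) -> "GenotypeDataset":
        """Return a copy with markers sorted by (chromosome, position)."""
        key = pd.DataFrame(
            {"k": _chrom_sort_key(self.markers["chrom"]), "pos": self.markers["pos"]}
        )
        order = key.sort_values(["k", "pos"], kind="stable").index.to_numpy()
        return self.take_markers(order)

    def equals(self, other: "GenotypeDataset") -> bool:
        return (
            self.samples == other.samples
            and self.markers[MARKER_COLUMNS].equals(other.markers[MARKER_COLUMNS])
            and np.array_equal(self.genotypes, other.genotypes)
        )


@dataclass
class PopulationMap:
    """Assignment of sample ids to population labels."""

    assignments: dict[str, str]
    populations: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        seen = list(dict.fromkeys(self.assignments.values()))
        if not self.populations:
            self.populations = seen
        else:
            missing = set(seen) - set(self.populations)
            if missing:
                raise ValueError(f"labels missing from population order: {missing}")

    def samples_of(self, population: str) -> list[str]:
        return [s for s, p in self.assignments.items() if p == population]

    def restrict_to(self, samples: list[str]) -> "PopulationMap":
        kept = {s: p for s, p in self.assignments.items() if s in set(samples)}
        order = [p for p in self.populations if p in set(kept.values())]
        return PopulationMap(kept, order)

    @classmethod
    def from_tsv(cls, path) -> "PopulationMap":
        df = pd.read_csv(path, sep="\t", header=None, names=["sample", "population"],
                         dtype=str, comment="#")
        return cls(dict(zip(df["sample"], df["population"])))

    def to_tsv(self, path) -> None:
        with open(path, "w") as fh:
            for s, p in self.assignments.items():
                fh.write(f"{s}\t{p}\n")
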