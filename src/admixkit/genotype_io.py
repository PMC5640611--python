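"""Reading, writing, merging and annotating SNP genotype datasets.

Supported on-disk formats are the PLINK-1 binary triplet (``.bed`` in
SNP-major mode with its ``.bim``/``.fam`` companions) and VCF v4.2 with GT
genotypes.  Dosages always count the alt allele; in the PLINK triplet the
bim A1 column is the alt allele and A2 the ref allele.

Merging intersects marker sets by id, harmonises allele orientation to the
first dataset (flipping dosages ``d -> 2 - d`` where ref/alt are swapped),
drops markers with irreconcilable allele pairs, and removes markers fixed
across the merged dataset.
"""

from __future__ import annotations

import logging
import os

import numpy as np
import pandas as pd

from .dataset import MISSING, GenotypeDataset, PopulationMap, make_marker_table

logger = logging.getLogger(__name__)


class ParseError(ValueError):
    """A genotype file could not be parsed."""


class ConsistencyError(ValueError):
    """Companion files of a dataset disagree with each other."""


class MergeError(ValueError):
    """Datasets cannot be merged (e.g. empty marker intersection)."""


# ---------------------------------------------------------------------------
# PLINK-1 binary
# ---------------------------------------------------------------------------

_BED_MAGIC = bytes([0x6C, 0x1B, 0x01])  # SNP-major

# 2-bit code -> alt dosage: 00 hom A1 (=alt) -> 2, 01 missing, 10 het, 11 hom A2
_CODE_TO_DOSAGE = np.array([2, MISSING, 1, 0], dtype=np.int8)
_DOSAGE_TO_CODE = {2: 0, MISSING: 1, 1: 2, 0: 3}

# decode table: byte value -> 4 dosages (low bit-pair first)
_BYTE_DECODE = np.zeros((256, 4), dtype=np.int8)
for _b in range(256):
    for _j in range(4):
        _BYTE_DECODE[_b, _j] = _CODE_TO_DOSAGE[(_b >> (2 * _j)) & 3]


def _plink_prefix(path: str) -> str:
    base, ext = os.path.splitext(str(path))
    return base if ext in {".bed", ".bim", ".fam"} else str(path)


def _read_plink(path: str) -> GenotypeDataset:
    prefix = _plink_prefix(path)
    bed, bim, fam = (prefix + e for e in (".bed", ".bim", ".fam"))
    for f in (bed, bim, fam):
        if not os.path.exists(f):
            raise FileNotFoundError(f)

    fam_df = pd.read_csv(
        fam, sep=r"\s+", header=None,
        names=["fid", "iid", "father", "mother", "sex", "pheno"], dtype=str,
    )
    if fam_df.isna().any().any():
        raise ParseError(f"{fam}: expected 6 whitespace-separated columns")
    samples = list(fam_df["iid"])
    if len(set(samples)) != len(samples):
        samples = [f"{f}_{i}" for f, i in zip(fam_df["fid"], fam_df["iid"])]

    bim_df = pd.read_csv(
        bim, sep=r"\s+", header=None,
        names=["chrom", "id", "cm", "pos", "a1", "a2"], dtype=str,
    )
    if bim_df.isna().any().any():
        raise ParseError(f"{bim}: expected 6 whitespace-separated columns")
    markers = make_marker_table(
        bim_df["id"], bim_df["chrom"], bim_df["pos"].astype(int),
        bim_df["a2"], bim_df["a1"],
    )

    n, m = len(samples), len(markers)
    bytes_per_snp = (n + 3) // 4
    raw = np.fromfile(bed, dtype=np.uint8)
    if raw[:3].tobytes() != _BED_MAGIC:
        raise ParseError(f"{bed}: bad magic bytes (not SNP-major PLINK-1 bed)")
    body = raw[3:]
    if body.size != bytes_per_snp * m:
        raise ConsistencyError(
            f"{bed}: {body.size} data bytes, expected {bytes_per_snp * m} "
            f"for {n} samples x {m} markers"
        )
    decoded = _BYTE_DECODE[body.reshape(m, bytes_per_snp)]  # m x bytes x 4
    geno = decoded.reshape(m, bytes_per_snp * 4)[:, :n].T.copy()
    return GenotypeDataset(samples, markers, geno)


def _write_plink(ds: GenotypeDataset, path: str) -> None:
    prefix = _plink_prefix(path)
    os.makedirs(os.path.dirname(os.path.abspath(prefix)), exist_ok=True)
    with open(prefix + ".fam", "w") as fh:
        for s in ds.samples:
            fh.write(f"{s} {s} 0 0 0 -9\n")
    with open(prefix + ".bim", "w") as fh:
        for row in ds.markers.itertuples(index=False):
            fh.write(f"{row.chrom}\t{row.id}\t0\t{row.pos}\t{row.alt}\t{row.ref}\n")

    n, m = ds.n_samples, ds.n_markers
    bytes_per_snp = (n + 3) // 4
    codes = np.empty((m, bytes_per_snp * 4), dtype=np.uint8)
    codes[:] = 1  # pad positions encode as "missing" (conventional: PLINK pads with 0)
    g = ds.genotypes.T  # m x n
    code_lookup = np.array([_DOSAGE_TO_CODE[0], _DOSAGE_TO_CODE[1],
                            _DOSAGE_TO_CODE[2]], dtype=np.uint8)
    codes[:, :n] = np.where(g == MISSING, 1, code_lookup[np.clip(g, 0, 2)])
    codes[:, n:] = 0  # pad bits are zero
    packed = (
        codes.reshape(m, bytes_per_snp, 4)
        * np.array([1, 4, 16, 64], dtype=np.uint8)
    ).sum(axis=2, dtype=np.uint8)
    with open(prefix + ".bed", "wb") as fh:
        fh.write(_BED_MAGIC)
        packed.tofile(fh)


# ---------------------------------------------------------------------------
# VCF
# ---------------------------------------------------------------------------

_SNP_ALLELES = {"A", "C", "G", "T"}


def _read_vcf(path: str) -> GenotypeDataset:
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    ids, chroms, poss, refs, alts, rows = [], [], [], [], [], []
    n_dropped = 0
    for var in vcf:
        if (
            len(var.ALT) != 1
            or var.REF not in _SNP_ALLELES
            or var.ALT[0] not in _SNP_ALLELES
        ):
            n_dropped += 1
            continue
        ids.append(var.ID if var.ID else f"{var.CHROM}:{var.POS}")
        chroms.append(var.CHROM)
        poss.append(var.POS)
        refs.append(var.REF)
        alts.append(var.ALT[0])
        # cyvcf2 gt_types: 0 HOM_REF, 1 HET, 2 UNKNOWN, 3 HOM_ALT
        gt = var.gt_types
        rows.append(np.select([gt == 0, gt == 1, gt == 3], [0, 1, 2], MISSING))
    vcf.close()
    if n_dropped:
        logger.info("read_dataset: dropped %d multi-allelic/non-SNP records", n_dropped)
    if not ids:
        raise ParseError(f"{path}: no biallelic SNP records")
    geno = np.array(rows, dtype=np.int8).T
    return GenotypeDataset(samples, make_marker_table(ids, chroms, poss, refs, alts), geno)


_GT_STRINGS = {0: "0/0", 1: "0/1", 2: "1/1", MISSING: "./."}


def _write_vcf(ds: GenotypeDataset, path: str) -> None:
    os.makedirs(os.path.dirname(os.path.abspath(path)), exist_ok=True)
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        for chrom in dict.fromkeys(ds.markers["chrom"]):
            fh.write(f"##contig=<ID={chrom}>\n")
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(ds.samples) + "\n"
        )
        for j, row in enumerate(ds.markers.itertuples(index=False)):
            gts = "\t".join(_GT_STRINGS[int(d)] for d in ds.genotypes[:, j])
            fh.write(
                f"{row.chrom}\t{row.pos}\t{row.id}\t{row.ref}\t{row.alt}"
                f"\t.\t.\t.\tGT\t{gts}\n"
            )


# ---------------------------------------------------------------------------
# Public surface
# ---------------------------------------------------------------------------

def read_dataset(path, format: str = "plink-binary") -> GenotypeDataset:
    """Read a genotype dataset from disk.

    ``format`` is ``"plink-binary"`` (path may be the triplet prefix or any
    member file) or ``"vcf"``.
    """
    if format == "plink-binary":
        return _read_plink(str(path))
    if format == "vcf":
        return _read_vcf(str(path))
    raise ValueError(f"unknown format {format!r}")


def write_dataset(ds: GenotypeDataset, path, format: str = "plink-binary") -> None:
    """Write ``ds`` so that :func:`read_dataset` recovers it exactly."""
    if ds.n_markers == 0 or ds.n_samples == 0:
        raise ValueError("refusing to write an empty dataset")
    if format == "plink-binary":
        _write_plink(ds, str(path))
    elif format == "vcf":
        _write_vcf(ds, str(path))
    else:
        raise ValueError(f"unknown format {format!r}")


def merge_datasets(
    datasets: list[GenotypeDataset], source_tags: list[str] | None = None
) -> GenotypeDataset:
    """Merge >= 2 datasets on the intersection of their marker ids.

    Sample ids are namespaced ``<tag>:<id>``.  Alleles are harmonised to the
    first dataset's (ref, alt); swapped orientations flip dosages; markers
    whose allele pairs neither match nor swap are dropped, as are markers
    fixed across the merged dataset.
    """
    if len(datasets) < 2:
        raise MergeError("need at least two datasets to merge")
    if source_tags is None:
        source_tags = [f"ds{i + 1}" for i in range(len(datasets))]
    if len(source_tags) != len(datasets):
        raise MergeError("one source tag per dataset required")

    common = set(datasets[0].markers["id"])
    for ds in datasets[1:]:
        common &= set(ds.markers["id"])
    if not common:
        raise MergeError("no markers shared by all datasets")

    first = datasets[0]
    keep0 = first.markers["id"].isin(common).to_numpy().nonzero()[0]
    ref_markers = first.markers.iloc[keep0].reset_index(drop=True)
    orient = {
        r.id: (r.ref, r.alt) for r in ref_markers.itertuples(index=False)
    }

    # decide flip/drop per marker per dataset
    dropped_conflicts: set[str] = set()
    blocks = []
    for ds in datasets:
        lookup = {mid: j for j, mid in enumerate(ds.markers["id"])}
        flip = {}
        for mid in orient:
            j = lookup[mid]
            ref, alt = ds.markers["ref"].iat[j], ds.markers["alt"].iat[j]
            if (ref, alt) == orient[mid]:
                flip[mid] = False
            elif (alt, ref) == orient[mid]:
                flip[mid] = True
            else:
                dropped_conflicts.add(mid)
        blocks.append((ds, lookup, flip))
    if dropped_conflicts:
        logger.info("merge: dropped %d markers with irreconcilable alleles",
                    len(dropped_conflicts))

    kept_ids = [mid for mid in ref_markers["id"] if mid not in dropped_conflicts]
    if not kept_ids:
        raise MergeError("no markers left after allele harmonisation")

    samples: list[str] = []
    parts = []
    for tag, (ds, lookup, flip) in zip(source_tags, blocks):
        cols = np.array([lookup[mid] for mid in kept_ids], dtype=np.intp)
        g = ds.genotypes[:, cols].copy()
        flip_mask = np.array([flip[mid] for mid in kept_ids], dtype=bool)
        if flip_mask.any():
            sub = g[:, flip_mask]
            g[:, flip_mask] = np.where(sub == MISSING, MISSING, 2 - sub)
        parts.append(g)
        samples.extend(f"{tag}:{s}" for s in ds.samples)
    if len(set(samples)) != len(samples):
        raise MergeError("sample ids not unique after source prefixing")

    geno = np.vstack(parts)
    keep_rows = ref_markers["id"].isin(kept_ids).to_numpy()
    markers = ref_markers.loc[keep_rows].reset_index(drop=True)

    merged = GenotypeDataset(samples, markers, geno)
    # remove markers fixed in the whole merged dataset
    p = merged.alt_freq()
    poly = ~(np.isnan(p) | (p == 0.0) | (p == 1.0))
    n_fixed = int((~poly).sum())
    if n_fixed:
        logger.info("merge: removed %d markers fixed across the merged dataset",
                    n_fixed)
    merged = merged.take_markers(np.nonzero(poly)[0])
    return merged.sort_markers()


def apply_population_map(
    ds: GenotypeDataset, popmap: PopulationMap
) -> tuple[GenotypeDataset, PopulationMap]:
    """Restrict ``ds`` to mapped samples; returns (restricted dataset, map)."""
    kept = [s for s in ds.samples if s in popmap.assignments]
    if not kept:
        raise ValueError("population map covers no sample of the dataset")
    return ds.select_samples(kept), popmap.restrict_to(kept)
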