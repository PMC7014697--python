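"""Genotype, marker-map, and phenotype input for inbred-line panels.

All genotypes are coded 0/1: inbred lines are fully homozygous, so the two
homozygous genotypes at a biallelic SNP map to 0 (reference / lexicographically
smaller allele) and 1. Heterozygous or missing calls are rejected at the
boundary — imputation and phasing are upstream concerns, not this package's.
"""

from __future__ import annotations

import dataclasses
import logging
import os

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

MARKER_COLUMNS = ("id", "chrom", "pos")


class GenotypeError(ValueError):
    """Raised for malformed genotype input (heterozygous, missing, unsorted)."""


@dataclasses.dataclass
class GenotypeMatrix:
    """samples x markers 0/1 calls plus a marker map.

    Attributes
    ----------
    calls : ndarray of shape (n_samples, n_markers), entries in {0, 1}
    sample_ids : list of unique sample names, row order of ``calls``
    markers : DataFrame with columns ``id``, ``chrom``, ``pos`` (1-based bp),
        sorted by (chrom, pos) with strictly increasing positions per
        chromosome.
    """

    calls: np.ndarray
    sample_ids: list
    markers: pd.DataFrame

    def __post_init__(self):
        self.calls = np.asarray(self.calls, dtype=np.int8)
        self.sample_ids = list(self.sample_ids)
        self.validate()

    @property
    def n_samples(self) -> int:
        return self.calls.shape[0]

    @property
    def n_markers(self) -> int:
        return self.calls.shape[1]

    def validate(self) -> None:
        if self.calls.ndim != 2:
            raise GenotypeError("calls must be a 2-D samples x markers array")
        n, m = self.calls.shape
        if len(self.sample_ids) != n:
            raise GenotypeError(f"{len(self.sample_ids)} sample ids for {n} rows")
        if len(set(self.sample_ids)) != n:
            raise GenotypeError("sample ids are not unique")
        if not set(MARKER_COLUMNS).issubset(self.markers.columns):
            raise GenotypeError(f"marker map needs columns {MARKER_COLUMNS}")
        if len(self.markers) != m:
            raise GenotypeError(f"{len(self.markers)} map rows for {m} marker columns")
        bad = ~np.isin(self.calls, (0, 1))
        if bad.any():
            i, j = np.argwhere(bad)[0]
            raise GenotypeError(
                f"non-0/1 call {self.calls[i, j]} at sample {self.sample_ids[i]}, "
                f"marker {self.markers['id'].iloc[j]} (missing data must be imputed upstream)"
            )
        if m and (self.markers["pos"] < 1).any():
            raise GenotypeError("marker positions must be >= 1 (1-based bp)")
        _check_sorted(self.markers)

    def marker_positions(self) -> np.ndarray:
        return self.markers["pos"].to_numpy()

    def subset_markers(self, keep: np.ndarray) -> "GenotypeMatrix":
        keep = np.asarray(keep)
        if keep.dtype == bool:
            keep = np.flatnonzero(keep)
        return GenotypeMatrix(
            self.calls[:, keep],
            self.sample_ids,
            self.markers.iloc[keep].reset_index(drop=True),
        )

    def subset_samples(self, rows: np.ndarray) -> "GenotypeMatrix":
        rows = np.asarray(rows)
        return GenotypeMatrix(
            self.calls[rows], [self.sample_ids[i] for i in rows], self.markers
        )


@dataclasses.dataclass
class PhenotypeVector:
    """One quantitative trait, one value per sample."""

    trait_name: str
    values: np.ndarray
    sample_ids: list

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        self.sample_ids = list(self.sample_ids)
        if self.values.ndim != 1 or len(self.sample_ids) != self.values.size:
            raise ValueError("phenotype values and sample ids disagree in length")
        if not np.all(np.isfinite(self.values)):
            raise ValueError(f"non-finite phenotype values for trait {self.trait_name}")
        if self.values.size < 3:
            raise ValueError("need at least 3 phenotyped samples")

    @property
    def n(self) -> int:
        return self.values.size


def _check_sorted(markers: pd.DataFrame) -> None:
    """Markers must be grouped by chromosome with strictly increasing positions."""
    chroms = markers["chrom"].astype(str).to_numpy()
    pos = markers["pos"].to_numpy()
    seen = []
    for c in chroms:
        if not seen or seen[-1] != c:
            if c in seen:
                raise GenotypeError(f"chromosome {c} appears in two separate runs")
            seen.append(c)
    for c in seen:
        p = pos[chroms == c]
        if np.any(np.diff(p) <= 0):
            raise GenotypeError(f"positions on chromosome {c} not strictly increasing")


def read_genotypes(path, format: str = "auto", map_path=None) -> GenotypeMatrix:
    """Read a 0/1 genotype matrix from VCF or a plain tab-separated table.

    Parameters
    ----------
    path : file path; ``format='auto'`` infers vcf from a ``.vcf``/``.vcf.gz``
        suffix, table otherwise.
    map_path : 3-column tab-separated marker map (id, chrom, pos); required for
        table input, ignored for VCF (map is embedded).
    """
    if format == "auto":
        format = "vcf" if str(path).endswith((".vcf", ".vcf.gz")) else "table"
    if format == "vcf":
        return _read_vcf(path)
    if format == "table":
        return _read_table(path, map_path)
    raise ValueError(f"unknown genotype format {format!r}")


def _read_vcf(path) -> GenotypeMatrix:
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    cols, ids, chroms, poss = [], [], [], []
    for var in vcf:
        marker_id = var.ID or f"{var.CHROM}_{var.POS}"
        if len(var.ALT) != 1:
            raise GenotypeError(
                f"marker {marker_id}: expected exactly one ALT allele, got {var.ALT}"
            )
        col = np.empty(len(samples), dtype=np.int8)
        for i, gt in enumerate(var.genotypes):
            alleles = [a for a in gt[:-1]]  # last entry is the phased flag
            if any(a < 0 for a in alleles):
                raise GenotypeError(
                    f"missing genotype for sample {samples[i]} at marker {marker_id}; "
                    "impute missing calls before loading"
                )
            if len(set(alleles)) > 1:
                raise GenotypeError(
                    f"heterozygous call for sample {samples[i]} at marker {marker_id}; "
                    "this tool assumes fully inbred (homozygous) lines"
                )
            call = alleles[0]
            if call not in (0, 1):
                raise GenotypeError(
                    f"allele index {call} at marker {marker_id}: only biallelic 0/1 supported"
                )
            col[i] = call
        cols.append(col)
        ids.append(marker_id)
        chroms.append(str(var.CHROM))
        poss.append(int(var.POS))
    if not cols:
        raise GenotypeError(f"no variant records in {path}")
    markers = pd.DataFrame({"id": ids, "chrom": chroms, "pos": poss})
    return GenotypeMatrix(np.column_stack(cols), samples, markers)


def _read_table(path, map_path) -> GenotypeMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.isna().any().any():
        raise GenotypeError(
            f"missing cells in {path}; impute missing genotypes before loading"
        )
    if map_path is None:
        raise GenotypeError("table genotype input requires a marker map (map_path)")
    markers = read_marker_map(map_path)
    marker_ids = [str(c) for c in df.columns]
    mapped = markers.set_index("id")
    missing = [m for m in marker_ids if m not in mapped.index]
    if missing:
        raise GenotypeError(f"markers absent from map: {missing[:5]} ...")
    markers = mapped.loc[marker_ids].reset_index()
    calls = df.to_numpy()
    return GenotypeMatrix(calls, [str(s) for s in df.index], markers)


def read_marker_map(path) -> pd.DataFrame:
    markers = pd.read_csv(path, sep="\t", header=None, names=MARKER_COLUMNS,
                          dtype={"id": str, "chrom": str, "pos": int})
    return markers


def write_genotypes(G: GenotypeMatrix, path, map_path) -> None:
    """Write the table format: first row marker ids, first column sample ids."""
    df = pd.DataFrame(G.calls, index=G.sample_ids, columns=G.markers["id"])
    df.to_csv(path, sep="\t")
    G.markers[list(MARKER_COLUMNS)].to_csv(map_path, sep="\t", header=False, index=False)


def read_phenotypes(path, trait: str) -> PhenotypeVector:
    """Read one trait column from a delimited text table.

    First column holds sample ids; rows with a missing value for the requested
    trait are dropped (count logged).
    """
    df = pd.read_csv(path, sep=None, engine="python")
    id_col = df.columns[0]
    if trait not in df.columns[1:]:
        raise KeyError(
            f"trait {trait!r} not found; available traits: {list(df.columns[1:])}"
        )
    vals = pd.to_numeric(df[trait], errors="coerce")
    keep = vals.notna()
    n_drop = int((~keep).sum())
    if n_drop:
        logger.info("dropped %d samples with missing %s", n_drop, trait)
    return PhenotypeVector(
        trait, vals[keep].to_numpy(), [str(s) for s in df.loc[keep, id_col]]
    )


def align_samples(G: GenotypeMatrix, y: PhenotypeVector):
    """Restrict both objects to the shared samples, in genotype-file order."""
    pheno_index = {s: i for i, s in enumerate(y.sample_ids)}
    rows = [i for i, s in enumerate(G.sample_ids) if s in pheno_index]
    if not rows:
        raise ValueError("no samples shared between genotypes and phenotypes")
    if len(rows) == G.n_samples and len(rows) == y.n and all(
        G.sample_ids[i] == y.sample_ids[i] for i in rows
    ):
        return G, y
    G2 = G.subset_samples(np.array(rows))
    order = [pheno_index[G.sample_ids[i]] for i in rows]
    y2 = PhenotypeVector(y.trait_name, y.values[order], [y.sample_ids[i] for i in order])
    return G2, y2


def filter_maf(G: GenotypeMatrix, min_maf: float) -> GenotypeMatrix:
    """Drop markers with minor-allele frequency below ``min_maf`` (inclusive keep)."""
    if not 0.0 <= min_maf <= 0.5:
        raise ValueError("min_maf must lie in [0, 0.5]")
    p = G.calls.mean(axis=0)
    maf = np.minimum(p, 1.0 - p)
    keep = maf >= min_maf
    if keep.all():
        return G
    logger.info("MAF filter removed %d of %d markers", int((~keep).sum()), G.n_markers)
    return G.subset_markers(keep)
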