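"""Haplotype-block construction and design-matrix encoding of genetic units.

Blocks are built with the Four Gamete Test (FGT): a marker pair shows evidence
of historical recombination iff all four two-locus gamete classes (0,0),
(0,1), (1,0), (1,1) are observed at frequency >= ``cutoff``. In a fully
inbred panel each line IS an observed haplotype, so gamete classes are counted
directly over samples. A block is a maximal run of contiguous markers in which
*every* pair passes the test (no pair shows all four classes), grown greedily
left to right within each chromosome.

Within a block, each distinct multi-SNP pattern is a haplotype allele; alleles
rarer than ``rare_freq`` are pooled into a single "<block>_rare" class.
Genetic units are encoded as 0/1 regression columns: one column per SNP or per
haplotype-allele carrier indicator, and k-1 indicator columns per k-allele
block (the last allele in descending-frequency order is dropped so the design
plus intercept stays identifiable).
"""

from __future__ import annotations

import dataclasses
import logging
import re
from typing import Iterator, Optional

import numpy as np

from .genotype_io import GenotypeMatrix

logger = logging.getLogger(__name__)

RARE_PATTERN = "rare"


@dataclasses.dataclass
class HaplotypeAllele:
    allele_id: str
    pattern: str  # 0/1 string over the block's SNPs, or the sentinel "rare"
    frequency: float
    carriers: np.ndarray  # sample indices


@dataclasses.dataclass
class HaplotypeBlock:
    block_id: str
    chromosome: str
    start: int  # first marker index (into the GenotypeMatrix), inclusive
    end: int  # last marker index, inclusive
    span_bp: tuple
    n_snps: int
    alleles: list = dataclasses.field(default_factory=list)

    @property
    def marker_indices(self) -> range:
        return range(self.start, self.end + 1)

    @property
    def n_alleles(self) -> int:
        return len(self.alleles)


@dataclasses.dataclass
class BlockSet:
    blocks: list
    unblocked_marker_indices: list
    cutoff: float
    rare_freq: float

    @property
    def n_blocked_markers(self) -> int:
        return sum(b.n_snps for b in self.blocks)

    def coverage_pct(self, n_markers_total: Optional[int] = None) -> float:
        """Percentage of markers that fall inside some block."""
        if n_markers_total is None:
            n_markers_total = self.n_blocked_markers + len(self.unblocked_marker_indices)
        return 100.0 * self.n_blocked_markers / n_markers_total


@dataclasses.dataclass
class UnitDesign:
    """A tested genetic unit as a ready-made regression design (no intercept)."""

    unit_id: str
    unit_kind: str  # snp | hap_allele | hap_block
    columns: np.ndarray  # (n, df_beta)
    df_beta: int
    chromosome: str
    span_bp: tuple
    n_snps: Optional[int] = None
    n_alleles: Optional[int] = None


def four_gamete_pass(col_i: np.ndarray, col_j: np.ndarray, cutoff: float) -> bool:
    """True iff the pair shows NO recombination evidence.

    Fails (returns False) only when all four gamete classes reach frequency
    >= cutoff; classes rarer than the cutoff are treated as unobserved
    (genotyping error / recurrent mutation tolerance).
    """
    col_i = np.asarray(col_i)
    col_j = np.asarray(col_j)
    if col_i.shape != col_j.shape:
        raise ValueError("columns differ in length")
    n = col_i.size
    counts = np.bincount(2 * col_i.astype(np.int64) + col_j, minlength=4)
    return int(np.count_nonzero(counts / n >= cutoff)) <= 3


def _chrom_tag(chrom: str) -> str:
    return re.sub(r"^chr", "", str(chrom), flags=re.IGNORECASE)


def build_blocks(G: GenotypeMatrix, cutoff: float = 0.01) -> BlockSet:
    """Partition each chromosome into FGT blocks by greedy left-to-right growth.

    A candidate marker joins the open block only if it passes the four-gamete
    test against every marker already in the block (all-pairs criterion);
    single-marker "blocks" are recorded as unblocked.
    """
    if not 0.0 < cutoff < 0.5:
        raise ValueError("cutoff must lie in (0, 0.5)")
    calls = G.calls
    chroms = G.markers["chrom"].astype(str).to_numpy()
    pos = G.markers["pos"].to_numpy()
    blocks, unblocked = [], []
    for chrom in dict.fromkeys(chroms):  # preserves genome order
        idx = np.flatnonzero(chroms == chrom)
        lo, hi = idx[0], idx[-1]
        counter = 0
        i = lo
        while i <= hi:
            members = [i]
            j = i + 1
            while j <= hi and all(
                four_gamete_pass(calls[:, k], calls[:, j], cutoff) for k in members
            ):
                members.append(j)
                j += 1
            if len(members) >= 2:
                counter += 1
                blocks.append(
                    HaplotypeBlock(
                        block_id=f"Chr{_chrom_tag(chrom)}Block{counter}",
                        chromosome=chrom,
                        start=members[0],
                        end=members[-1],
                        span_bp=(int(pos[members[0]]), int(pos[members[-1]])),
                        n_snps=len(members),
                    )
                )
            else:
                unblocked.append(i)
            i = j
    return BlockSet(blocks=blocks, unblocked_marker_indices=unblocked,
                    cutoff=cutoff, rare_freq=np.nan)


def enumerate_alleles(
    G: GenotypeMatrix, block: HaplotypeBlock, rare_freq: float = 0.02
) -> HaplotypeBlock:
    """Enumerate distinct haplotype patterns in a block and pool rare ones.

    Patterns with frequency < rare_freq are merged into one "<block_id>_rare"
    allele when at least two of them exist; a lone sub-threshold pattern keeps
    its own identity (nothing to pool it with). If every pattern is rare, the
    most frequent one is kept named so the block retains >= 2 alleles. Alleles
    are sorted by descending frequency (ties: lexicographic pattern, pooled
    class last) and labelled "<block_id>_<rank>" / "<block_id>_rare".
    """
    if not 0.0 <= rare_freq < 0.5:
        raise ValueError("rare_freq must lie in [0, 0.5)")
    sub = G.calls[:, block.start : block.end + 1]
    n = sub.shape[0]
    patterns, inverse = np.unique(sub, axis=0, return_inverse=True)
    if len(patterns) < 2:
        raise ValueError(
            f"block {block.block_id} is monomorphic ({len(patterns)} pattern); "
            "FGT blocks of >= 2 polymorphic SNPs must carry >= 2 patterns"
        )
    entries = []  # (pattern_str, freq, carriers)
    for k, pat in enumerate(patterns):
        carriers = np.flatnonzero(inverse == k)
        entries.append(("".join(map(str, pat)), carriers.size / n, carriers))
    rare = [e for e in entries if e[1] < rare_freq]
    common = [e for e in entries if e[1] >= rare_freq]
    if not common and rare:
        # keep the top pattern named so the block stays polymorphic after pooling
        rare.sort(key=lambda e: (-e[1], e[0]))
        common, rare = [rare[0]], rare[1:]
    if len(rare) >= 2:
        pooled_carriers = np.sort(np.concatenate([e[2] for e in rare]))
        common.append((RARE_PATTERN, pooled_carriers.size / n, pooled_carriers))
    else:
        common.extend(rare)  # a lone rare pattern stays an ordinary allele
    common.sort(key=lambda e: (-e[1], e[0] == RARE_PATTERN, e[0]))
    alleles = []
    for rank, (pat, freq, carriers) in enumerate(common, start=1):
        suffix = RARE_PATTERN if pat == RARE_PATTERN else str(rank)
        alleles.append(
            HaplotypeAllele(
                allele_id=f"{block.block_id}_{suffix}",
                pattern=pat,
                frequency=freq,
                carriers=carriers,
            )
        )
    return dataclasses.replace(block, alleles=alleles)


def enumerate_all(G: GenotypeMatrix, blocks: BlockSet, rare_freq: float = 0.02) -> BlockSet:
    """enumerate_alleles over every block; returns a new BlockSet."""
    done = [enumerate_alleles(G, b, rare_freq) for b in blocks.blocks]
    return dataclasses.replace(blocks, blocks=done, rare_freq=rare_freq)


def _indicator(carriers: np.ndarray, n: int) -> np.ndarray:
    col = np.zeros(n)
    col[carriers] = 1.0
    return col


def encode_units(
    G: GenotypeMatrix, blocks: Optional[BlockSet], unit_kind: str
) -> Iterator[UnitDesign]:
    """Yield one regression design per tested unit, in genome order.

    snp: the raw 0/1 marker column (df 1). hap_allele: the carrier indicator of
    each haplotype allele (df 1). hap_block: k-1 allele indicators with the
    last (lowest-frequency) allele dropped for identifiability.
    """
    n = G.n_samples
    if unit_kind == "snp":
        chroms = G.markers["chrom"].astype(str).to_numpy()
        pos = G.markers["pos"].to_numpy()
        ids = G.markers["id"].to_numpy()
        for j in range(G.n_markers):
            yield UnitDesign(
                unit_id=str(ids[j]),
                unit_kind="snp",
                columns=G.calls[:, j : j + 1].astype(float),
                df_beta=1,
                chromosome=chroms[j],
                span_bp=(int(pos[j]), int(pos[j])),
            )
        return
    if blocks is None:
        raise ValueError(f"unit_kind {unit_kind!r} requires a BlockSet")
    if unit_kind == "hap_allele":
        for b in blocks.blocks:
            _require_alleles(b)
            for a in b.alleles:
                yield UnitDesign(
                    unit_id=a.allele_id,
                    unit_kind="hap_allele",
                    columns=_indicator(a.carriers, n)[:, None],
                    df_beta=1,
                    chromosome=b.chromosome,
                    span_bp=b.span_bp,
                    n_snps=b.n_snps,
                    n_alleles=b.n_alleles,
                )
        return
    if unit_kind == "hap_block":
        for b in blocks.blocks:
            _require_alleles(b)
            cols = np.column_stack([_indicator(a.carriers, n) for a in b.alleles[:-1]])
            yield UnitDesign(
                unit_id=b.block_id,
                unit_kind="hap_block",
                columns=cols,
                df_beta=cols.shape[1],
                chromosome=b.chromosome,
                span_bp=b.span_bp,
                n_snps=b.n_snps,
                n_alleles=b.n_alleles,
            )
        return
    raise ValueError(f"unknown unit_kind {unit_kind!r}")


def _require_alleles(b: HaplotypeBlock) -> None:
    if not b.alleles:
        raise ValueError(f"block {b.block_id}: alleles not enumerated yet")


def write_blocks(G: GenotypeMatrix, blocks: BlockSet, path) -> None:
    """Tab-separated block table: one row per block, inclusive 1-based bp span."""
    with open(path, "w") as fh:
        fh.write("block_id\tchrom\tstart_bp\tend_bp\tn_snps\tn_alleles\tallele_freqs\n")
        for b in blocks.blocks:
            freqs = ",".join(f"{a.frequency:.6g}" for a in b.alleles)
            fh.write(
                f"{b.block_id}\t{b.chromosome}\t{b.span_bp[0]}\t{b.span_bp[1]}\t"
                f"{b.n_snps}\t{b.n_alleles}\t{freqs}\n"
            )


def blocks_to_bed(blocks: BlockSet, path) -> None:
    # BED is 0-based half-open: start-1, end (inclusive 1-based end == open 0-based end)
    with open(path, "w") as fh:
        for b in blocks.blocks:
            fh.write(f"{b.chromosome}\t{b.span_bp[0] - 1}\t{b.span_bp[1]}\t{b.block_id}\n")
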