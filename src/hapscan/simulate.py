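"""Synthetic inbred-line genotypes with LD-block structure, and phenotypes
with polygenic + QTL + residual components.

Genotypes come from a founder-copying model: block boundaries are geometric,
each block carries a small pool of founder haplotypes (so blocks typically
show 3-6 common alleles), and each line copies one founder per block with
per-marker copying fidelity ``within_block_r`` (each copied bit is replaced by
a fresh allele-frequency draw with probability 1 - r). Across blocks, lines
draw founders independently, which is what makes the kinship informative.

Phenotypes follow the generative model the scan assumes:
y = mu + sum_q X_q beta_q + a + eps with a ~ N(0, K sigma_a^2) and
eps ~ N(0, I sigma_e^2); effect sizes are specified as fractions of a unit
total phenotypic variance.
"""

from __future__ import annotations

import dataclasses
from typing import Optional

import numpy as np
import pandas as pd

from .genotype_io import GenotypeMatrix, PhenotypeVector
from .haplotype_builder import BlockSet
from .kinship import KinshipMatrix, compute_rrm, spectral_decompose


@dataclasses.dataclass
class SimSpec:
    n_samples: int = 400
    n_snps: int = 1000
    block_length_mean: float = 8.0  # geometric mean block size, in SNPs
    maf_range: tuple = (0.1, 0.5)  # founder allele-frequency range per marker
    within_block_r: float = 0.98  # copying fidelity; 1-r is the per-bit redraw rate
    h2_poly: float = 0.4
    qtl: list = dataclasses.field(default_factory=list)  # (marker index, variance fraction)
    seed: int = 0
    n_founders: int = 4
    founder_alpha: float = 1.2  # Dirichlet concentration of founder frequencies
    n_chromosomes: int = 2
    bp_spacing: tuple = (500, 5000)

    def __post_init__(self):
        total = self.h2_poly + sum(f for _, f in self._qtl_pairs())
        if total >= 1.0:
            raise ValueError(f"h2_poly + QTL fractions = {total} must be < 1")
        if not 0.0 <= self.within_block_r < 1.0 + 1e-12:
            raise ValueError("within_block_r must lie in [0, 1]")

    def _qtl_pairs(self):
        out = []
        for entry in self.qtl:
            if isinstance(entry, dict):
                out.append((entry.get("index"), float(entry["fraction"])))
            else:
                out.append((entry[0], float(entry[1])))
        return out


def _rng(seed: int, stream: int) -> np.random.Generator:
    # one documented split point for all randomness: (seed, stream)
    return np.random.default_rng(np.random.SeedSequence([int(seed), int(stream)]))


def simulate_genotypes(spec: SimSpec) -> GenotypeMatrix:
    """Deterministic (per seed) founder-copying genotypes with LD blocks."""
    rng = _rng(spec.seed, 1)
    n, m = spec.n_samples, spec.n_snps
    lengths = []
    while sum(lengths) < m:
        lengths.append(int(rng.geometric(1.0 / spec.block_length_mean)))
    lengths[-1] -= sum(lengths) - m
    if lengths[-1] == 0:
        lengths.pop()
    calls = np.empty((n, m), dtype=np.int8)
    j = 0
    for L in lengths:
        p = rng.uniform(*spec.maf_range, size=L)
        founders = (rng.random((spec.n_founders, L)) < p).astype(np.int8)
        probs = rng.dirichlet(np.full(spec.n_founders, spec.founder_alpha))
        pick = rng.choice(spec.n_founders, size=n, p=probs)
        block = founders[pick]
        redraw = rng.random((n, L)) > spec.within_block_r
        if redraw.any():
            fresh = (rng.random((n, L)) < p).astype(np.int8)
            block = np.where(redraw, fresh, block)
        calls[:, j : j + L] = block
        j += L
    # marker map: contiguous chromosomes of near-equal marker counts
    per_chrom = np.array_split(np.arange(m), spec.n_chromosomes)
    chrom_col, pos_col, ids = [], [], []
    for c, idx in enumerate(per_chrom, start=1):
        gaps = rng.integers(spec.bp_spacing[0], spec.bp_spacing[1], size=len(idx))
        pos = np.cumsum(gaps)
        chrom_col.extend([str(c)] * len(idx))
        pos_col.extend(int(x) for x in pos)
        ids.extend(f"chr{c}.s{int(x)}" for x in pos)
    markers = pd.DataFrame({"id": ids, "chrom": chrom_col, "pos": pos_col})
    samples = [f"L{i:04d}" for i in range(n)]
    return GenotypeMatrix(calls, samples, markers)


def simulate_phenotype(
    G: GenotypeMatrix,
    spec: SimSpec,
    K: Optional[KinshipMatrix] = None,
    eig=None,
    blocks: Optional[BlockSet] = None,
    trait_name: str = "SIM",
):
    """Draw a phenotype from the mixed model; returns (PhenotypeVector, truth).

    Marker QTLs are spec.qtl entries (marker index, fraction); block QTLs can
    be passed as dicts {"kind": "block", "index": i, "fraction": f} together
    with an allele-enumerated BlockSet, and receive independent normal effects
    per haplotype allele. The truth dict records every drawn parameter.
    """
    rng = _rng(spec.seed, 2)
    n = G.n_samples
    if eig is None:
        if K is None:
            K = compute_rrm(G)
        eig = spectral_decompose(K)
    y = np.zeros(n)
    truth_qtl = []
    for entry in spec.qtl:
        kind = entry.get("kind", "snp") if isinstance(entry, dict) else "snp"
        if kind == "block":
            if blocks is None:
                raise ValueError("block QTL requires an allele-enumerated BlockSet")
            b = blocks.blocks[entry["index"]]
            frac = float(entry["fraction"])
            cat = np.zeros(n, dtype=int)
            for k, a in enumerate(b.alleles):
                cat[a.carriers] = k
            effects = rng.normal(size=len(b.alleles))
            g = effects[cat]
            g = g - g.mean()
            sd = g.std()
            if sd == 0:
                raise ValueError(f"block {b.block_id} QTL has no allelic variance")
            g *= np.sqrt(frac) / sd
            y += g
            truth_qtl.append(
                {"kind": "block", "block_id": b.block_id, "fraction": frac,
                 "allele_effects": effects.tolist()}
            )
        else:
            idx, frac = (entry["index"], float(entry["fraction"])) if isinstance(entry, dict) else (
                int(entry[0]), float(entry[1]))
            x = G.calls[:, idx].astype(float)
            sd = x.std()
            if sd == 0:
                raise ValueError(f"QTL marker {idx} is monomorphic")
            beta = np.sqrt(frac) / sd
            y += (x - x.mean()) * beta
            truth_qtl.append(
                {"kind": "snp", "marker_index": idx,
                 "marker_id": str(G.markers["id"].iloc[idx]),
                 "fraction": frac, "beta": float(beta)}
            )
    frac_qtl = sum(q["fraction"] for q in truth_qtl)
    sigma_e2 = 1.0 - spec.h2_poly - frac_qtl
    if sigma_e2 <= 0:
        raise ValueError("variance fractions leave no residual variance")
    if spec.h2_poly > 0:
        z = rng.normal(size=n)
        y += np.sqrt(spec.h2_poly) * (eig.vectors @ (np.sqrt(eig.values) * z))
    y += rng.normal(scale=np.sqrt(sigma_e2), size=n)
    truth = {
        "h2_poly": spec.h2_poly,
        "sigma_e2": sigma_e2,
        "qtl": truth_qtl,
        "seed": spec.seed,
        "trait_name": trait_name,
    }
    return PhenotypeVector(trait_name, y, G.sample_ids), truth


def write_phenotypes(phenos, path) -> None:
    """Write one or more PhenotypeVectors sharing sample ids as a TSV."""
    if isinstance(phenos, PhenotypeVector):
        phenos = [phenos]
    df = pd.DataFrame({"sample": phenos[0].sample_ids})
    for ph in phenos:
        df[ph.trait_name] = ph.values
    df.to_csv(path, sep="\t", index=False)
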