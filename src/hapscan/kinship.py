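"""Realized relationship matrix (RRM) and its one-off spectral decomposition.

K is the VanRaden-style cross-product of column-centred 0/1 genotypes,
K = M M^T / c with c = sum_j p_j (1 - p_j). For inbred (haploid-equivalent)
coding this puts diag(K) near 1. Any positive rescaling of K is absorbed by
the heritability parameter downstream, so the scaling convention changes the
interpretation of h2-hat but not a single test statistic.
"""

from __future__ import annotations

import dataclasses
import json

import numpy as np

from .genotype_io import GenotypeMatrix

SYM_TOL = 1e-8
EIG_FLOOR = -1e-10


@dataclasses.dataclass
class KinshipMatrix:
    K: np.ndarray
    n_markers_used: int
    scale: float = np.nan  # the denominator c

    def __post_init__(self):
        self.K = np.asarray(self.K, dtype=float)
        if self.K.ndim != 2 or self.K.shape[0] != self.K.shape[1]:
            raise ValueError("K must be square")
        if np.abs(self.K - self.K.T).max() > 1e-10:
            raise ValueError("K is not symmetric")


@dataclasses.dataclass
class EigenSystem:
    """Eigenvalues (descending, clipped at 0) and orthonormal eigenvectors of K."""

    values: np.ndarray
    vectors: np.ndarray  # columns are eigenvectors, ordered like values

    @property
    def n(self) -> int:
        return self.values.size


def compute_rrm(G: GenotypeMatrix, exclude_chroms=None) -> KinshipMatrix:
    """Marker-based kinship; monomorphic markers contribute nothing and are skipped.

    ``exclude_chroms`` drops whole chromosomes from the computation, which is
    how a leave-one-chromosome-out kinship is built to avoid proximal
    contamination of units tested on the excluded chromosome.
    """
    p = G.calls.mean(axis=0)
    poly = (p > 0) & (p < 1)
    if exclude_chroms is not None:
        exclude = {str(c) for c in exclude_chroms}
        poly &= ~G.markers["chrom"].astype(str).isin(exclude).to_numpy()
    if int(poly.sum()) < 2:
        raise ValueError("need at least 2 polymorphic markers to build a kinship matrix")
    M = G.calls[:, poly] - p[poly]
    c = float(np.sum(p[poly] * (1.0 - p[poly])))
    K = (M @ M.T) / c
    K = (K + K.T) / 2.0
    return KinshipMatrix(K=K, n_markers_used=int(poly.sum()), scale=c)


def spectral_decompose(km) -> EigenSystem:
    """Full symmetric eigendecomposition of K, eigenvalues sorted descending.

    Eigenvalues in (-1e-10, 0) are clipped to 0; anything more negative means
    the input was corrupted upstream and is rejected rather than repaired.
    """
    K = km.K if isinstance(km, KinshipMatrix) else np.asarray(km, dtype=float)
    if np.abs(K - K.T).max() > SYM_TOL:
        raise ValueError("kinship matrix is not symmetric within tolerance")
    vals, vecs = np.linalg.eigh((K + K.T) / 2.0)
    vals, vecs = vals[::-1], vecs[:, ::-1]
    if vals.min() < EIG_FLOOR:
        raise ValueError(
            f"kinship matrix has eigenvalue {vals.min():.3e} < {EIG_FLOOR}; "
            "not positive semi-definite"
        )
    return EigenSystem(values=np.clip(vals, 0.0, None), vectors=vecs)


def save_kinship(km: KinshipMatrix, path, sample_ids=None) -> None:
    """Dense .npy matrix plus a JSON sidecar with provenance fields."""
    path = str(path)
    np.save(path + ".npy", km.K)
    with open(path + ".json", "w") as fh:
        json.dump(
            {
                "n_markers_used": km.n_markers_used,
                "scale": km.scale,
                "sample_ids": list(sample_ids) if sample_ids is not None else None,
            },
            fh,
        )


def load_kinship(path) -> KinshipMatrix:
    path = str(path)
    K = np.load(path + ".npy")
    with open(path + ".json") as fh:
        meta = json.load(fh)
    return KinshipMatrix(K=K, n_markers_used=meta["n_markers_used"], scale=meta["scale"])


def export_kinship_text(km: KinshipMatrix, path) -> None:
    np.savetxt(path, km.K, delimiter="\t")
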