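"""Genomic relationship matrices, modified Rogers' distances, principal
coordinate analysis, and marker-based pedigree validation.

Reference allele frequencies are always an explicit argument: the frequency
set determines the location of GEBVs (training-set frequencies at selection
time, base-population frequencies for anchored reporting), so they are never
silently recomputed from the genotypes being related.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass

import numpy as np

__all__ = [
    "GRMatrix",
    "vanraden_grm",
    "cross_grm",
    "mrd",
    "mrd_matrix",
    "pcoa",
    "pedigree_check",
]


@dataclass(frozen=True)
class GRMatrix:
    """VanRaden method-1 realized relationship matrix with its frequencies."""

    matrix: np.ndarray
    ids: tuple[str, ...]
    ref_freqs: np.ndarray  # frequencies of the markers actually used
    denominator: float  # 2 * sum p (1 - p)
    marker_mask: np.ndarray  # which input markers were kept (polymorphic)

    def __post_init__(self) -> None:
        k = self.matrix
        if k.shape != (len(self.ids), len(self.ids)):
            raise ValueError("matrix dimension does not match ids")
        if not np.allclose(k, k.T, atol=1e-10):
            raise ValueError("GRM must be symmetric")
        if self.denominator <= 0:
            raise ValueError("denominator must be positive")


def _polymorphic_mask(ref_freqs: np.ndarray) -> np.ndarray:
    mask = (ref_freqs > 0.0) & (ref_freqs < 1.0)
    if not np.any(mask):
        raise ValueError("all markers monomorphic in the reference frequencies")
    if not np.all(mask):
        warnings.warn(
            f"dropping {int((~mask).sum())} markers monomorphic in the reference set",
            stacklevel=3,
        )
    return mask


def vanraden_grm(
    genotypes: np.ndarray,
    ref_freqs: np.ndarray,
    ids: list[str] | None = None,
) -> GRMatrix:
    """K = ZZ' / (2 sum p(1-p)) with Z = genotypes - 2p (method 1).

    Markers monomorphic in ``ref_freqs`` are dropped from numerator and
    denominator.  Missing genotypes are rejected; impute upstream.
    """
    genotypes = np.asarray(genotypes, dtype=float)
    ref_freqs = np.asarray(ref_freqs, dtype=float)
    if genotypes.ndim != 2 or genotypes.shape[1] != ref_freqs.shape[0]:
        raise ValueError("genotypes must be (n, m) matching ref_freqs length m")
    if np.any(~np.isfinite(genotypes)):
        raise ValueError("missing genotypes; impute before building the GRM")
    mask = _polymorphic_mask(ref_freqs)
    p = ref_freqs[mask]
    z = genotypes[:, mask] - 2.0 * p
    denom = float(2.0 * np.sum(p * (1.0 - p)))
    k = (z @ z.T) / denom
    if ids is None:
        ids = [f"ind{i + 1}" for i in range(genotypes.shape[0])]
    return GRMatrix(
        matrix=k, ids=tuple(ids), ref_freqs=p, denominator=denom, marker_mask=mask
    )


def cross_grm(
    train_genotypes: np.ndarray,
    new_genotypes: np.ndarray,
    ref_freqs: np.ndarray,
) -> np.ndarray:
    """Train x new relationship block with the same centering and denominator.

    Equivalent to slicing the VanRaden GRM of the stacked genotype set; the
    two inputs must share one marker set (column-for-column).
    """
    train_genotypes = np.asarray(train_genotypes, dtype=float)
    new_genotypes = np.asarray(new_genotypes, dtype=float)
    if train_genotypes.shape[1] != new_genotypes.shape[1]:
        raise ValueError("marker sets differ between training and new genotypes")
    ref_freqs = np.asarray(ref_freqs, dtype=float)
    if train_genotypes.shape[1] != ref_freqs.shape[0]:
        raise ValueError("ref_freqs length must match marker count")
    mask = _polymorphic_mask(ref_freqs)
    p = ref_freqs[mask]
    zt = train_genotypes[:, mask] - 2.0 * p
    zn = new_genotypes[:, mask] - 2.0 * p
    denom = 2.0 * np.sum(p * (1.0 - p))
    return (zt @ zn.T) / denom


def mrd(freqs_a: np.ndarray, freqs_b: np.ndarray) -> float:
    """Modified Rogers' distance between two allele-frequency vectors.

    For biallelic markers: sqrt(mean((p_a - p_b)^2)).  Individuals enter via
    genotype-derived frequencies {0, 0.5, 1}; populations via mean allele
    frequencies.
    """
    freqs_a = np.asarray(freqs_a, dtype=float)
    freqs_b = np.asarray(freqs_b, dtype=float)
    if freqs_a.shape != freqs_b.shape:
        raise ValueError("frequency vectors differ in length")
    return float(np.sqrt(np.mean((freqs_a - freqs_b) ** 2)))


def mrd_matrix(freqs: np.ndarray) -> np.ndarray:
    """All pairwise MRDs among rows of an (n, m) frequency matrix."""
    freqs = np.asarray(freqs, dtype=float)
    sq = np.sum(freqs**2, axis=1)
    d2 = sq[:, None] + sq[None, :] - 2.0 * freqs @ freqs.T
    d2 = np.clip(d2, 0.0, None) / freqs.shape[1]
    d = np.sqrt(d2)
    np.fill_diagonal(d, 0.0)
    return d


def pcoa(distances: np.ndarray, n_axes: int | None = None):
    """Classical scaling (Gower) of a distance matrix.

    Returns ``(coordinates, percent_explained)`` where percent explained is
    eigenvalue / sum of positive eigenvalues, axes ordered by eigenvalue.
    """
    d = np.asarray(distances, dtype=float)
    if d.ndim != 2 or d.shape[0] != d.shape[1]:
        raise ValueError("distance matrix must be square")
    if not np.allclose(d, d.T, atol=1e-10):
        raise ValueError("distance matrix must be symmetric")
    n = d.shape[0]
    j = np.eye(n) - np.ones((n, n)) / n
    b = -0.5 * j @ (d**2) @ j
    vals, vecs = np.linalg.eigh(b)
    order = np.argsort(vals)[::-1]
    vals, vecs = vals[order], vecs[:, order]
    pos = vals > 1e-10
    total = vals[pos].sum() if np.any(pos) else 1.0
    if n_axes is None:
        n_axes = int(pos.sum())
    n_axes = min(n_axes, n)
    coords = np.zeros((n, n_axes))
    percent = np.zeros(n_axes)
    for a in range(n_axes):
        if vals[a] > 1e-10:
            coords[:, a] = vecs[:, a] * np.sqrt(vals[a])
            percent[a] = 100.0 * vals[a] / total
    return coords, percent


def pedigree_check(
    offspring_geno: np.ndarray,
    mother_geno: np.ndarray,
    father_geno: np.ndarray,
    threshold: float = 0.98,
) -> tuple[float, bool]:
    """Fraction of markers Mendelian-consistent with the stated parent pair.

    A marker is consistent if the offspring genotype can be formed from one
    allele of each parent.  Returns (rate, flagged) with ``flagged`` true
    when the rate falls below ``threshold``.
    """
    o = np.asarray(offspring_geno)
    m = np.asarray(mother_geno)
    f = np.asarray(father_geno)
    if not (o.shape == m.shape == f.shape):
        raise ValueError("genotype vectors differ in length")
    # possible offspring dosages: {a + b : a in alleles(m), b in alleles(f)}
    ok = np.zeros(o.shape, dtype=bool)
    for a in (0, 1):
        for b in (0, 1):
            ok |= o == (_allele_option(m, a) + _allele_option(f, b))
    rate = float(np.mean(ok))
    return rate, rate < threshold


def _allele_option(geno: np.ndarray, which: int) -> np.ndarray:
    # dosage 0 -> alleles (0,0); 1 -> (0,1); 2 -> (1,1)
    if which == 0:
        return (geno == 2).astype(np.int8)
    return (geno >= 1).astype(np.int8)


def greedy_mrd_pairs(
    dist: np.ndarray, ids: list[str], n_pairs: int
) -> list[tuple[int, int]]:
    """Greedy max-weight matching on an MRD matrix; ties broken by id order."""
    n = dist.shape[0]
    if n < 2:
        raise ValueError("need at least 2 candidates to pair")
    if 2 * n_pairs > n:
        raise ValueError("not enough candidates for the requested pairs")
    order = sorted(
        itertools.combinations(range(n), 2),
        key=lambda ij: (-dist[ij], ids[ij[0]], ids[ij[1]]),
    )
    used: set[int] = set()
    pairs: list[tuple[int, int]] = []
    for i, j in order:
        if len(pairs) == n_pairs:
            break
        if i in used or j in used:
            continue
        pairs.append((i, j))
        used.update((i, j))
    return pairs


__all__.append("greedy_mrd_pairs")
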