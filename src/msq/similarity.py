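"""Haplotype-based similarity between parental Mendelian sampling terms.

Two parents can have large Mendelian sampling variances for entirely
different reasons: they may be heterozygous at the same high-impact
chromosome segments, or at disjoint ones.  The similarity

    s_ij = sum_c | m_i' R m_j |,        m_i = delta_i * (a' M)

(the absolute value of the per-chromosome covariance between the two
parents' gametic values, for the aggregate genotype with index weights
``a``) quantifies shared segregating segments: it is zero when the parents
share no heterozygous effect-bearing loci, and equals the parent's own MSV
on the diagonal.  The absolute value per chromosome makes ``s_ij``
invariant to how either parent's haplotypes happen to be labelled.

Standardizing by each parent's Mendelian standard deviation gives
``K = D^-1 S D^-1`` with unit diagonal and off-diagonals in [0, 1]
(Cauchy-Schwarz), usable directly as a diversity kernel by
optimal-contribution or mate-allocation optimizers.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .haplotype_io import Bundle, IndexWeights
from .mendelian_core import _individual_rows, _resolve_weights, phase_indicators

__all__ = [
    "SimilarityResult",
    "similarity_matrix",
    "zygotic_similarity",
    "standardize",
]


@dataclass(frozen=True)
class SimilarityResult:
    """Similarity matrix S, Mendelian SDs D, and standardized kernel K."""

    ids: tuple
    S: np.ndarray
    msv: np.ndarray
    K: np.ndarray | None = None

    @property
    def D(self) -> np.ndarray:
        return np.diag(np.sqrt(self.msv))


def _weighted_phase_effects(bundle: Bundle, a: np.ndarray, rows: np.ndarray, idx: np.ndarray) -> np.ndarray:
    """n x L_c matrix g_i = delta_i * (a' M) on one chromosome.

    a' M_i^c = delta_i * (a' M^c), so the aggregate-genotype bilinear form
    collapses to a single weighted effect vector per parent.
    """
    w = a @ bundle.effects.effects[:, idx]
    delta = phase_indicators(bundle.haps).delta[np.ix_(rows, idx)].astype(float)
    return delta * w


def similarity_matrix(
    bundle: Bundle,
    R_by_chrom: Mapping,
    weights: IndexWeights | Sequence | None = None,
    individuals: Sequence | None = None,
    chromosomes: Sequence | None = None,
    standardized: bool = True,
    chunk_size: int = 1024,
) -> SimilarityResult:
    """Build S (and optionally K) over a set of parents.

    S accumulates ``|G R G'|`` per chromosome, where row ``i`` of ``G`` is
    the parent's weighted phase-adjusted effect vector; loci homozygous in
    either parent drop out automatically (their phase indicator is zero).
    Rows are processed in chunks so peak memory is the output matrix plus one
    chunk of phase-adjusted effects; ``individuals`` and ``chromosomes``
    restrict the computation to a subset.
    """
    a = _resolve_weights(weights, bundle.effects.n_traits)
    rows = _individual_rows(bundle.haps, individuals)
    ids = tuple(bundle.haps.individual_id[rows])
    chroms = list(chromosomes) if chromosomes is not None else list(bundle.gmap.chromosomes)

    n = rows.size
    S = np.zeros((n, n))
    msv = np.zeros(n)
    for c in chroms:
        idx = bundle.gmap.chrom_indices(c)
        R = R_by_chrom[c].R
        G = _weighted_phase_effects(bundle, a, rows, idx)
        for start in range(0, n, chunk_size):
            block = slice(start, min(start + chunk_size, n))
            C = (G[block] @ R) @ G.T  # covariance of gametic values, this chromosome
            S[block] += np.abs(C)
        msv += np.einsum("nk,kl,nl->n", G, R, G, optimize=True)
    msv = np.maximum(msv, 0.0)
    K = standardize(S, msv) if standardized else None
    return SimilarityResult(ids=ids, S=S, msv=msv, K=K)


def zygotic_similarity(
    bundle: Bundle,
    R_by_chrom: Mapping,
    weights: IndexWeights | Sequence | None = None,
    pairs: Sequence[tuple] = (),
    chromosomes: Sequence | None = None,
    standardized: bool = True,
) -> SimilarityResult:
    """Similarity between zygotes of ordered parent pairs.

    For pairs (i, j) and (u, v) the similarity pairs first parent with first
    parent and second with second:

        s_ij,uv = sum_c [ |g_i' R g_u| + |g_j' R g_v| ],

    so callers must order pairs consistently (e.g. sire first, dam second).
    The diagonal equals each pair's zygotic MSV.
    """
    pairs = [tuple(p) for p in pairs]
    parents = sorted({p for pair in pairs for p in pair}, key=str)
    rows = _individual_rows(bundle.haps, parents)
    pos = {p: k for k, p in enumerate(parents)}
    for i, j in pairs:
        if i not in pos or j not in pos:
            raise KeyError(f"unknown individual id in pair ({i!r}, {j!r})")
    first = np.asarray([pos[i] for i, _ in pairs])
    second = np.asarray([pos[j] for _, j in pairs])
    a = _resolve_weights(weights, bundle.effects.n_traits)
    chroms = list(chromosomes) if chromosomes is not None else list(bundle.gmap.chromosomes)

    P = len(pairs)
    S = np.zeros((P, P))
    for c in chroms:
        idx = bundle.gmap.chrom_indices(c)
        R = R_by_chrom[c].R
        G = _weighted_phase_effects(bundle, a, rows, idx)
        C = np.abs((G @ R) @ G.T)
        S += C[np.ix_(first, first)] + C[np.ix_(second, second)]
    msv = np.diag(S).copy()
    K = standardize(S, msv) if standardized else None
    return SimilarityResult(ids=tuple(pairs), S=S, msv=msv, K=K)


def standardize(S: np.ndarray, msv: np.ndarray) -> np.ndarray:
    """Standardized kernel ``K = D^-1 S D^-1`` with ``D = diag(sqrt(msv))``.

    Ids with zero MSV have a degenerate Mendelian sampling term: their
    off-diagonal entries are set to 0 and their diagonal flagged as NaN
    (undefined), with a warning.
    """
    S = np.asarray(S, dtype=float)
    msv = np.asarray(msv, dtype=float).ravel()
    if S.ndim != 2 or S.shape[0] != S.shape[1] or msv.size != S.shape[0]:
        raise ValueError("S must be square and msv aligned to its ids")
    if np.any(msv < 0):
        raise ValueError("negative MSV passed to standardize")
    zero = msv == 0
    denom = np.sqrt(np.outer(np.where(zero, 1.0, msv), np.where(zero, 1.0, msv)))
    K = S / denom  # sqrt(msv_i * msv_j): keeps the diagonal exactly S_ii/msv_i
    if zero.any():
        warnings.warn(
            f"{int(zero.sum())} id(s) have zero MSV; their standardized "
            "similarities are set to 0 (diagonal undefined)",
            stacklevel=2,
        )
        K[zero, :] = 0.0
        K[:, zero] = 0.0
        K[np.diag_indices_from(K)] = np.where(zero, np.nan, np.diag(K))
    return K
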