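"""Mendelian sampling (co)variances, GEBVs and selection indices.

The gametic value a parent transmits is a random variable driven by
segregation at its heterozygous loci and by linkage phase.  With additive
marker effects ``m`` and the per-chromosome population covariance matrix
``R`` of transmitted-allele indicators, the Mendelian sampling variance (MSV)
of parent ``i`` is

    sigma2_i = sum_c  m_i' R m_i,          m_i = delta_i * m,

where ``delta_i`` is the phase indicator (+1 reference allele on the first
haplotype, -1 on the second, 0 homozygous).  In the multi-trait case the
T x T matrix ``V_i = sum_c M_i R M_i'`` holds MSVs on the diagonal and
Mendelian sampling covariances (MSC) off it; the aggregate-genotype variance
is ``a' V_i a`` for index weights ``a``.  Chromosomes segregate
independently, so all quantities accumulate over chromosomes.

For a parent pair the zygotic (offspring) covariance is the sum of the two
gametic covariances, ``V_ij = V_i + V_j``.

Selection uses the usefulness-criterion style index ``I = b + lambda * sigma``
combining the GEBV ``b`` with the Mendelian standard deviation.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .haplotype_io import Bundle, IndexWeights, PhasedHaplotypes

__all__ = [
    "PhaseIndicators",
    "GenotypeCodes",
    "MsqResult",
    "ZygoticResult",
    "phase_indicators",
    "genotype_codes",
    "parent_effects",
    "gametic_msq",
    "zygotic_msq",
    "selection_index",
    "lambda_from_proportion",
    "msq_table",
    "zygotic_table",
]


@dataclass(frozen=True)
class PhaseIndicators:
    """delta[i, k]: +1/-1 phase of the reference allele, 0 if homozygous."""

    delta: np.ndarray


@dataclass(frozen=True)
class GenotypeCodes:
    """codes[i, k]: 1 hom. reference, 0 heterozygous, -1 hom. alternative."""

    codes: np.ndarray


@dataclass
class MsqResult:
    """Per-parent Mendelian sampling summary.

    gebv/msv are per-trait; V is the T x T (co)variance matrix; aggregate
    quantities are on the index scale a' (.) a.
    """

    individual_id: object
    gebv: np.ndarray
    gebv_aggregate: float
    msv: np.ndarray
    V: np.ndarray
    msv_aggregate: float
    sd_aggregate: float
    index: float | None = None


@dataclass
class ZygoticResult:
    """Zygotic (parent-pair) Mendelian sampling summary: V_ij = V_i + V_j."""

    pair: tuple
    V: np.ndarray
    msv_aggregate: float
    sd_aggregate: float
    mean_gebv: float
    parent_gebv: tuple
    parent_sd: tuple
    index: float | None = None


def phase_indicators(haps: PhasedHaplotypes) -> PhaseIndicators:
    """Phase indicator per individual and marker: hap1 minus hap2 allele."""
    al = haps.alleles.astype(np.int8)
    return PhaseIndicators(al[:, 0, :] - al[:, 1, :])


def genotype_codes(haps: PhasedHaplotypes) -> GenotypeCodes:
    """Genotype coding 1 / 0 / -1 (reference-allele dosage minus one)."""
    al = haps.alleles.astype(np.int8)
    return GenotypeCodes(al[:, 0, :] + al[:, 1, :] - 1)


def parent_effects(delta_row: np.ndarray, effects: np.ndarray, chrom_idx: np.ndarray) -> np.ndarray:
    """Phase-adjusted marker effects M_i^c for one parent on one chromosome.

    Entry (t, k) is ``delta_ik * M[t, k]``; rows vanish at homozygous loci.
    """
    eff = np.atleast_2d(np.asarray(effects, dtype=float))
    return np.asarray(delta_row, dtype=float)[chrom_idx] * eff[:, chrom_idx]


def _resolve_weights(weights: IndexWeights | Sequence | None, n_traits: int) -> np.ndarray:
    if weights is None:
        return np.ones(n_traits)
    a = weights.a if isinstance(weights, IndexWeights) else np.asarray(weights, dtype=float).ravel()
    if a.size != n_traits:
        raise ValueError(f"index weights have length {a.size} but there are {n_traits} traits")
    return a


def _individual_rows(haps: PhasedHaplotypes, individuals) -> np.ndarray:
    if individuals is None:
        return np.arange(haps.n_individuals)
    return np.asarray([haps.index_of(i) for i in individuals])


def gametic_msq(
    bundle: Bundle,
    R_by_chrom: Mapping,
    weights: IndexWeights | Sequence | None = None,
    individuals: Sequence | None = None,
    chromosomes: Sequence | None = None,
) -> list[MsqResult]:
    """Gametic MSV/MSC, GEBVs and aggregate variance for each parent.

    Accumulates ``V_i = sum_c M_i^c R^c (M_i^c)'`` and
    ``b_i = sum_c (c_i^c)' m^c`` chromosome by chromosome; only one
    chromosome's R needs to be in memory at a time when ``R_by_chrom`` is a
    lazy mapping.
    """
    gmap, eff = bundle.gmap, bundle.effects
    T = eff.n_traits
    a = _resolve_weights(weights, T)
    rows = _individual_rows(bundle.haps, individuals)
    delta = phase_indicators(bundle.haps).delta[rows].astype(float)
    codes = genotype_codes(bundle.haps).codes[rows].astype(float)
    chroms = list(chromosomes) if chromosomes is not None else list(gmap.chromosomes)

    n = rows.size
    V = np.zeros((n, T, T))
    gebv = np.zeros((n, T))
    for c in chroms:
        idx = gmap.chrom_indices(c)
        cc = R_by_chrom[c]
        R, M = cc.R, eff.effects[:, idx]
        A = delta[:, idx, None] * M.T[None, :, :]          # n x L_c x T phase-adjusted
        B = np.einsum("nkt,kl->nlt", A, R, optimize=True)  # (M_i R)' per parent
        V += np.einsum("nlt,nlu->ntu", B, A, optimize=True)
        gebv += codes[:, idx] @ M.T

    out = []
    for r in range(n):
        # mirror the upper triangle: exactly symmetric, and commutes with
        # per-chromosome accumulation (selection is linear, bit for bit)
        Vi = np.triu(V[r]) + np.triu(V[r], 1).T
        msv_agg = float(a @ Vi @ a)
        if msv_agg < 0:  # PSD up to rounding; clip tiny negatives
            msv_agg = 0.0
        out.append(
            MsqResult(
                individual_id=bundle.haps.individual_id[rows[r]],
                gebv=gebv[r].copy(),
                gebv_aggregate=float(a @ gebv[r]),
                msv=np.diag(Vi).copy(),
                V=Vi,
                msv_aggregate=msv_agg,
                sd_aggregate=float(np.sqrt(msv_agg)),
            )
        )
    return out


def zygotic_msq(
    bundle: Bundle,
    R_by_chrom: Mapping,
    weights: IndexWeights | Sequence | None = None,
    pairs: Sequence[tuple] = (),
    parent_results: Sequence[MsqResult] | None = None,
) -> list[ZygoticResult]:
    """Zygotic (co)variance and mean GEBV for each parent pair.

    ``V_ij = V_i + V_j`` and ``b_ij = (b_i + b_j) / 2``; pass
    ``parent_results`` to reuse previously computed gametic results.
    """
    a = _resolve_weights(weights, bundle.effects.n_traits)
    if parent_results is None:
        needed = sorted({p for pair in pairs for p in pair}, key=str)
        parent_results = gametic_msq(bundle, R_by_chrom, weights, individuals=needed)
    by_id = {r.individual_id: r for r in parent_results}
    out = []
    for i, j in pairs:
        for p in (i, j):
            if p not in by_id:
                raise KeyError(f"unknown individual id in pair: {p!r}")
        ri, rj = by_id[i], by_id[j]
        Vij = ri.V + rj.V
        msv_agg = float(a @ Vij @ a)
        out.append(
            ZygoticResult(
                pair=(i, j),
                V=Vij,
                msv_aggregate=msv_agg,
                sd_aggregate=float(np.sqrt(max(msv_agg, 0.0))),
                mean_gebv=0.5 * (ri.gebv_aggregate + rj.gebv_aggregate),
                parent_gebv=(ri.gebv_aggregate, rj.gebv_aggregate),
                parent_sd=(ri.sd_aggregate, rj.sd_aggregate),
            )
        )
    return out


def selection_index(results: Sequence, lam: float, method: str = "zygotic_sd") -> list:
    """Fill the usefulness-style index ``I = b + lambda * sigma`` in place.

    For zygotic results the default uses the pair's own zygotic standard
    deviation, ``I_ij = mean_gebv + lambda * sigma_ij``;
    ``method="parent_average"`` instead averages the two parental indices,
    ``I_ij = mean_gebv + lambda * (sigma_i + sigma_j) / 2``.
    """
    if not np.isfinite(lam):
        raise ValueError("lambda must be finite")
    for r in results:
        if isinstance(r, ZygoticResult):
            if method == "parent_average":
                r.index = r.mean_gebv + lam * 0.5 * (r.parent_sd[0] + r.parent_sd[1])
            elif method == "zygotic_sd":
                r.index = r.mean_gebv + lam * r.sd_aggregate
            else:
                raise ValueError(f"unknown zygotic index method: {method!r}")
        else:
            r.index = r.gebv_aggregate + lam * r.sd_aggregate
    return list(results)


def lambda_from_proportion(p: float) -> float:
    """Index weight ``lambda = sqrt(2) * x`` from a selected proportion.

    ``x`` is the standard-normal upper-tail truncation point with
    ``P(Z > x) = p``; this choice maximizes the probability of producing
    offspring ranking in the top fraction ``p``.
    """
    if not 0.0 < p < 1.0:
        raise ValueError("selected proportion must be in (0, 1)")
    return float(np.sqrt(2.0) * stats.norm.isf(p))


def msq_table(results: Sequence[MsqResult], trait_names: Sequence[str]) -> pd.DataFrame:
    """Tabulate per-parent results (per-trait and aggregate columns)."""
    rows = []
    for r in results:
        row = {"id": r.individual_id}
        for t, name in enumerate(trait_names):
            row[f"gebv_{name}"] = r.gebv[t]
            row[f"msv_{name}"] = r.msv[t]
        row["gebv_aggregate"] = r.gebv_aggregate
        row["msv_aggregate"] = r.msv_aggregate
        row["sd_aggregate"] = r.sd_aggregate
        if r.index is not None:
            row["index"] = r.index
        rows.append(row)
    return pd.DataFrame(rows)


def zygotic_table(results: Sequence[ZygoticResult], trait_names: Sequence[str]) -> pd.DataFrame:
    rows = []
    for r in results:
        row = {"parent1": r.pair[0], "parent2": r.pair[1]}
        for t, name in enumerate(trait_names):
            row[f"msv_{name}"] = r.V[t, t]
        row["mean_gebv"] = r.mean_gebv
        row["msv_aggregate"] = r.msv_aggregate
        row["sd_aggregate"] = r.sd_aggregate
        if r.index is not None:
            row["index"] = r.index
        rows.append(row)
    return pd.DataFrame(rows)
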