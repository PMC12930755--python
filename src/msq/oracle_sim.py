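"""Ground truth for gametic (co)variances, plus a synthetic data generator.

The analytic machinery elsewhere in this package predicts moments of the
distribution of gametic values a parent can produce.  This module supplies
that distribution directly, by two independent routes:

* :func:`enumerate_gametes` lists all ``2^L`` inheritance vectors of a
  chromosome together with their exact probabilities under a no-interference
  (Haldane) Markov chain along the markers, and the gametic value of each.
  Exact means and (co)variances follow by summation — a brute-force oracle
  that shares no code with the matrix formulas it checks.
* :func:`simulate_gametes` draws gametes from the same crossover process by
  Monte Carlo, for chromosomes too long to enumerate.

A gamete contributes ``+m_k/2`` for a transmitted reference allele and
``-m_k/2`` for the alternative, so that the two gametes of a zygote add up
to the usual {1, 0, -1} genotype coding times ``m_k``; a single heterozygous
locus then has gametic variance ``m_k^2 / 4``, matching the 0.25 diagonal of
the population covariance matrix.

:func:`generate_synthetic` produces complete, validated datasets (map,
phased haplotypes, marker effects, optional paternal half-sib families)
modelled on the structure of dairy-cattle reference data: a few hundred
genotyped cows in a handful of half-sib families, tens of markers per
centiMorgan over ~30 chromosomes, and a small number of milk traits.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .genetic_map import GeneticMap, haldane_r
from .haplotype_io import Bundle, MarkerEffectSet, PhasedHaplotypes, validate_alignment

__all__ = [
    "GameteDistribution",
    "SyntheticParams",
    "SyntheticDataset",
    "enumerate_gametes",
    "simulate_gametes",
    "simulate_gamete_values",
    "generate_synthetic",
]

_MAX_ENUM_L = 20


@dataclass(frozen=True)
class GameteDistribution:
    """Exact distribution over the 2^L gamete origins of one chromosome.

    ``origins[g, k]`` is 0/1 for the parental haplotype transmitted at
    marker ``k``; ``probs[g]`` its probability under the Haldane chain;
    ``values[g]`` the T-dimensional gametic value.
    """

    origins: np.ndarray
    probs: np.ndarray
    values: np.ndarray

    def mean(self) -> np.ndarray:
        return self.probs @ self.values

    def cov(self) -> np.ndarray:
        mu = self.mean()
        centered = self.values - mu
        return (centered * self.probs[:, None]).T @ centered


def _interval_recomb(pos_morgan: np.ndarray) -> np.ndarray:
    d = np.diff(np.asarray(pos_morgan, dtype=float))
    return np.asarray(haldane_r(d))


def enumerate_gametes(parent_haps: np.ndarray, pos_morgan: np.ndarray, effects: np.ndarray) -> GameteDistribution:
    """Exact gamete distribution of one parent on one chromosome.

    The origin of the first marker is a fair coin; between adjacent markers
    the origin switches with the Haldane recombination fraction of the
    interval.  Raises for ``L > 20`` (use :func:`simulate_gametes` instead).
    """
    haps = np.asarray(parent_haps)
    if haps.ndim != 2 or haps.shape[0] != 2:
        raise ValueError("parent_haps must have shape (2, L)")
    L = haps.shape[1]
    if L > _MAX_ENUM_L:
        raise ValueError(
            f"enumeration over 2^{L} origins is infeasible; use simulate_gametes for L > {_MAX_ENUM_L}"
        )
    M = np.atleast_2d(np.asarray(effects, dtype=float))
    r = _interval_recomb(pos_morgan)

    # all inheritance vectors as bits of 0..2^L-1
    codes = np.arange(2**L, dtype=np.uint32)
    origins = ((codes[:, None] >> np.arange(L)[None, :]) & 1).astype(np.uint8)
    switch = origins[:, 1:] != origins[:, :-1]
    probs = 0.5 * np.prod(np.where(switch, r[None, :], 1.0 - r[None, :]), axis=1)
    alleles = haps[origins, np.arange(L)]
    values = (alleles - 0.5) @ M.T
    return GameteDistribution(origins=origins, probs=probs, values=values)


def simulate_gametes(
    parent_haps: np.ndarray,
    pos_morgan: np.ndarray,
    effects: np.ndarray,
    n: int,
    seed: int | np.random.Generator = 0,
    chunk: int = 50_000,
) -> np.ndarray:
    """Monte-Carlo sample of n gametic values (n x T) on one chromosome."""
    haps = np.asarray(parent_haps)
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    L = haps.shape[1]
    M = np.atleast_2d(np.asarray(effects, dtype=float))
    r = _interval_recomb(pos_morgan)
    out = np.empty((n, M.shape[0]))
    for start in range(0, n, chunk):
        m = min(chunk, n - start)
        origins = _sample_origins(rng, r, m, L)
        alleles = haps[origins, np.arange(L)]
        out[start:start + m] = (alleles - 0.5) @ M.T
    return out


def _sample_origins(rng: np.random.Generator, r: np.ndarray, n: int, L: int) -> np.ndarray:
    """Sample n origin chains: fair start, switch with prob r per interval."""
    start = rng.integers(0, 2, size=(n, 1), dtype=np.uint8)
    if L == 1:
        return start
    switches = (rng.random((n, L - 1)) < r[None, :]).astype(np.uint8)
    # origin_k = start XOR (number of switches up to k, mod 2)
    return np.concatenate([start, start ^ (np.cumsum(switches, axis=1) & 1).astype(np.uint8)], axis=1)


def simulate_gamete_values(
    haps_row: np.ndarray,
    gmap: GeneticMap,
    effects: MarkerEffectSet,
    n: int,
    seed: int | np.random.Generator = 0,
) -> np.ndarray:
    """Genome-wide gametic values: independent chromosomes summed (n x T)."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    total = np.zeros((n, effects.n_traits))
    for c in gmap.chromosomes:
        idx = gmap.chrom_indices(c)
        total += simulate_gametes(
            np.asarray(haps_row)[:, idx], gmap.pos_morgan[idx], effects.effects[:, idx], n, rng
        )
    return total


@dataclass(frozen=True)
class SyntheticParams:
    """Generation parameters; defaults emulate a dairy-cattle reference set:

    265 cows in 5 paternal half-sib families, 29 autosomes of 1 Morgan with
    355 evenly spaced markers each (~10,300 genome-wide), 3 traits, allele
    frequency 0.3 and unit-scale effects.
    """

    n_individuals: int = 265
    n_chromosomes: int = 29
    markers_per_chrom: int = 355
    morgans_per_chrom: float = 1.0
    allele_freq: float = 0.3
    effect_scale: float = 1.0
    n_traits: int = 3
    n_families: int = 5

    def __post_init__(self) -> None:
        if self.n_individuals < 1 or self.n_chromosomes < 1 or self.markers_per_chrom < 1:
            raise ValueError("n_individuals, n_chromosomes and markers_per_chrom must be >= 1")
        if not 0.0 < self.allele_freq < 1.0:
            raise ValueError("allele_freq must be in (0, 1)")
        if self.n_traits < 1:
            raise ValueError("n_traits must be >= 1")
        if self.n_families < 0:
            raise ValueError("n_families must be >= 0 (0 disables family structure)")
        if self.morgans_per_chrom < 0 or self.effect_scale <= 0:
            raise ValueError("morgans_per_chrom must be >= 0 and effect_scale > 0")


@dataclass(frozen=True)
class SyntheticDataset:
    """A validated synthetic (map, haplotypes, effects) triple."""

    gmap: GeneticMap
    haps: PhasedHaplotypes
    effects: MarkerEffectSet
    sire_of: dict = field(default_factory=dict)
    params: SyntheticParams = field(default_factory=SyntheticParams)
    seed: int = 0

    def bundle(self) -> Bundle:
        return validate_alignment(self.gmap, self.haps, self.effects)


def _random_haplotype(rng: np.random.Generator, L: int, freq: float) -> np.ndarray:
    return (rng.random(L) < freq).astype(np.uint8)


def generate_synthetic(params: SyntheticParams | None = None, seed: int = 0, **overrides) -> SyntheticDataset:
    """Generate a reproducible synthetic dataset.

    Markers are evenly spaced on each chromosome; population haplotypes draw
    alleles independently at ``allele_freq``; effects are centered normal
    with scale ``effect_scale``.  With ``n_families > 0``, individuals are
    split into paternal half-sib families: each family shares a sire whose
    gametes (drawn by the Haldane crossover process) form every member's
    first haplotype, while the second (dam) haplotype is drawn from the
    population.  Random streams are spawned per purpose, per individual and
    per chromosome from the master seed, so subsetting individuals does not
    perturb the draws of others.
    """
    if params is None:
        params = SyntheticParams()
    if overrides:
        params = replace(params, **overrides)
    ss = np.random.SeedSequence(seed)
    eff_ss, sire_ss, ind_ss = ss.spawn(3)

    L_c, C = params.markers_per_chrom, params.n_chromosomes
    marker_id, chrom, pos = [], [], []
    for c in range(1, C + 1):
        step = params.morgans_per_chrom / max(L_c - 1, 1)
        for k in range(L_c):
            marker_id.append(f"M{c}_{k + 1}")
            chrom.append(str(c))
            pos.append(k * step)
    gmap = GeneticMap(np.asarray(marker_id, dtype=object), np.asarray(chrom, dtype=object),
                      np.asarray(pos, dtype=float))
    L = gmap.n_markers

    eff_rng = np.random.default_rng(eff_ss)
    effects = MarkerEffectSet(
        tuple(f"trait{t + 1}" for t in range(params.n_traits)),
        eff_rng.normal(0.0, params.effect_scale, size=(params.n_traits, L)),
        gmap.marker_id,
    )

    N = params.n_individuals
    sire_of: dict = {}
    sire_haps = []
    if params.n_families > 0:
        n_fam = min(params.n_families, N)
        sire_rng = np.random.default_rng(sire_ss)
        for f in range(n_fam):
            sire_haps.append(
                np.stack([_random_haplotype(sire_rng, L, params.allele_freq) for _ in range(2)])
            )
        family = np.arange(N) % n_fam  # round-robin: families of near-equal size
    else:
        family = None

    alleles = np.empty((N, 2, L), dtype=np.uint8)
    ids = np.asarray([f"ind{i + 1}" for i in range(N)], dtype=object)
    ind_streams = ind_ss.spawn(N)
    for i in range(N):
        rng_i = np.random.default_rng(ind_streams[i])
        if family is not None:
            sire = sire_haps[family[i]]
            gamete = np.empty(L, dtype=np.uint8)
            for c in gmap.chromosomes:
                idx = gmap.chrom_indices(c)
                origins = _sample_origins(rng_i, _interval_recomb(gmap.pos_morgan[idx]), 1, idx.size)[0]
                gamete[idx] = sire[:, idx][origins, np.arange(idx.size)]
            alleles[i, 0] = gamete
            alleles[i, 1] = _random_haplotype(rng_i, L, params.allele_freq)
            sire_of[ids[i]] = f"sire{family[i] + 1}"
        else:
            alleles[i, 0] = _random_haplotype(rng_i, L, params.allele_freq)
            alleles[i, 1] = _random_haplotype(rng_i, L, params.allele_freq)

    haps = PhasedHaplotypes(ids, alleles, gmap.marker_id)
    return SyntheticDataset(gmap=gmap, haps=haps, effects=effects, sire_of=sire_of,
                            params=params, seed=seed)
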