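"""Genetic maps and per-chromosome population covariance matrices.

A genetic map assigns every marker to a chromosome and a genetic position in
Morgans.  From the pairwise map distances on a chromosome, a single
population-level covariance matrix ``R`` (shape ``L_c x L_c``) of
transmitted-allele indicators is built, shared by every parent.  Two mapping
functions are supported:

* ``haldane`` -- no-interference model, ``rho_kl = exp(-2 d_kl) / 4``;
* ``linear`` -- first-order approximation, ``rho_kl = 0.25 - d_kl / 2``,
  truncated to zero once the distance reaches 0.5 Morgans.

Both give ``rho_kk = 0.25`` on the diagonal, the segregation variance of a
single fully heterozygous locus.
"""

from __future__ import annotations

import math
import warnings
from collections.abc import Mapping
from dataclasses import dataclass, field
from typing import Iterator

import numpy as np
import pandas as pd

__all__ = [
    "GeneticMap",
    "ChromCovariance",
    "load_map",
    "pairwise_distance",
    "build_R",
    "build_all_R",
    "LazyChromCovariances",
    "haldane_r",
    "inverse_haldane",
]

KERNELS = ("haldane", "linear")


def haldane_r(d: np.ndarray | float) -> np.ndarray | float:
    """Recombination fraction for a map distance ``d`` in Morgans (Haldane)."""
    return 0.5 * (1.0 - np.exp(-2.0 * np.asarray(d, dtype=float)))


def inverse_haldane(r: np.ndarray | float) -> np.ndarray | float:
    """Map distance in Morgans for a recombination fraction ``r < 0.5``."""
    r = np.asarray(r, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        return -0.5 * np.log(1.0 - 2.0 * r)


@dataclass(frozen=True)
class GeneticMap:
    """Marker map: ids, chromosome labels and positions in Morgans.

    Markers are stored sorted by (chromosome, position); chromosome order is
    the order of first appearance in the input.
    """

    marker_id: np.ndarray
    chrom: np.ndarray
    pos_morgan: np.ndarray
    chromosomes: tuple = field(default=())

    def __post_init__(self) -> None:
        mid = np.asarray(self.marker_id, dtype=object)
        ch = np.asarray(self.chrom, dtype=object)
        pos = np.asarray(self.pos_morgan, dtype=float)
        if not (mid.shape == ch.shape == pos.shape) or mid.ndim != 1:
            raise ValueError("marker_id, chrom and pos_morgan must be 1-D and equal length")
        if len(set(mid)) != mid.size:
            dup = pd.Series(mid)[pd.Series(mid).duplicated()].iloc[0]
            raise ValueError(f"duplicate marker_id: {dup!r}")
        if np.any(pos < 0):
            raise ValueError("negative genetic positions are not allowed")
        chroms = self.chromosomes or tuple(pd.unique(ch))
        for c in chroms:
            p = pos[ch == c]
            if np.any(np.diff(p) < 0):
                raise ValueError(f"positions on chromosome {c!r} are not sorted")
        object.__setattr__(self, "marker_id", mid)
        object.__setattr__(self, "chrom", ch)
        object.__setattr__(self, "pos_morgan", pos)
        object.__setattr__(self, "chromosomes", chroms)

    @property
    def n_markers(self) -> int:
        return self.marker_id.size

    def chrom_mask(self, chrom) -> np.ndarray:
        if chrom not in self.chromosomes:
            raise KeyError(f"unknown chromosome label: {chrom!r}")
        return np.asarray(self.chrom == chrom)

    def chrom_indices(self, chrom) -> np.ndarray:
        return np.flatnonzero(self.chrom_mask(chrom))

    def positions(self, chrom) -> np.ndarray:
        return self.pos_morgan[self.chrom_mask(chrom)]

    def markers_per_chrom(self) -> dict:
        return {c: int(np.sum(self.chrom == c)) for c in self.chromosomes}


@dataclass(frozen=True)
class ChromCovariance:
    """Population covariance matrix ``R`` of one chromosome.

    Diagonal is exactly 0.25; off-diagonals lie in [0, 0.25] and decay with
    map distance according to the chosen mapping function.
    """

    chrom: object
    R: np.ndarray
    method: str

    def __post_init__(self) -> None:
        if self.method not in KERNELS:
            raise ValueError(f"method must be one of {KERNELS}, got {self.method!r}")
        R = np.asarray(self.R, dtype=float)
        if R.ndim != 2 or R.shape[0] != R.shape[1]:
            raise ValueError("R must be square")
        object.__setattr__(self, "R", R)

    @property
    def n_markers(self) -> int:
        return self.R.shape[0]


def _read_delimited(path) -> pd.DataFrame:
    # comma/tab autodetection on headered text
    return pd.read_csv(path, sep=None, engine="python")


def load_map(path, units: str = "morgan") -> GeneticMap:
    """Load a genetic map from headered delimited text.

    Expected columns: ``marker_id, chrom, pos``.  ``units`` is one of
    ``morgan``, ``centimorgan`` (``cM`` accepted) or ``adjacent_recomb``.
    With ``adjacent_recomb`` the pos column holds the recombination rate from
    each marker to the next one on the same chromosome (the value on the last
    marker of each chromosome is ignored); rates are converted to distances
    via the inverse Haldane map and accumulated into positions.
    """
    units = {"cm": "centimorgan", "adj-r": "adjacent_recomb"}.get(str(units).lower(), str(units).lower())
    if units not in ("morgan", "centimorgan", "adjacent_recomb"):
        raise ValueError(f"unknown map units: {units!r}")
    df = _read_delimited(path)
    required = ["marker_id", "chrom", "pos"]
    if list(df.columns[:3]) != required:
        raise ValueError(f"map file must have columns {required}, got {list(df.columns)}")
    if df[required].isna().any().any():
        raise ValueError("map file contains missing values")
    mid = df["marker_id"].astype(str).to_numpy(dtype=object)
    ch = df["chrom"].astype(str).to_numpy(dtype=object)
    val = df["pos"].to_numpy(dtype=float)

    if units == "centimorgan":
        pos = val / 100.0
    elif units == "morgan":
        pos = val.copy()
    else:  # adjacent_recomb: accumulate inverse-Haldane distances per chromosome
        pos = np.empty_like(val)
        for c in pd.unique(ch):
            idx = np.flatnonzero(ch == c)
            rates = val[idx[:-1]]  # L_c - 1 meaningful rates
            if np.any(rates < 0) or np.any(rates >= 0.5):
                bad = rates[(rates < 0) | (rates >= 0.5)][0]
                raise ValueError(
                    f"adjacent recombination rate {bad} on chromosome {c!r} is outside [0, 0.5)"
                )
            pos[idx] = np.concatenate(([0.0], np.cumsum(inverse_haldane(rates))))
    if np.any(pos < 0):
        raise ValueError("negative genetic positions are not allowed")

    chrom_order = {c: i for i, c in enumerate(pd.unique(ch))}
    order = np.lexsort((pos, np.array([chrom_order[c] for c in ch])))
    if not np.array_equal(order, np.arange(order.size)):
        warnings.warn("map markers were re-ordered by (chromosome, position)", stacklevel=2)
    return GeneticMap(mid[order], ch[order], pos[order], tuple(chrom_order))


def write_map(gmap: GeneticMap, path, units: str = "morgan") -> None:
    """Write a map as headered CSV (positions in Morgans or centiMorgans)."""
    scale = {"morgan": 1.0, "centimorgan": 100.0}[units]
    pd.DataFrame(
        {"marker_id": gmap.marker_id, "chrom": gmap.chrom, "pos": gmap.pos_morgan * scale}
    ).to_csv(path, index=False)


def pairwise_distance(gmap: GeneticMap, chrom) -> np.ndarray:
    """Matrix of absolute map distances (Morgans) between markers on a chromosome."""
    pos = gmap.positions(chrom)
    return np.abs(pos[:, None] - pos[None, :])


def build_R(gmap: GeneticMap, chrom, method: str = "haldane") -> ChromCovariance:
    """Build the population covariance matrix of one chromosome.

    ``haldane``: ``rho_kl = exp(-2 d_kl)/4``; ``linear``:
    ``rho_kl = max(0, 0.25 - d_kl/2)`` (zero for ``d_kl >= 0.5`` Morgans).
    The diagonal is 0.25 under either method.
    """
    if method not in KERNELS:
        raise ValueError(f"method must be one of {KERNELS}, got {method!r}")
    d = pairwise_distance(gmap, chrom)
    if method == "haldane":
        R = 0.25 * np.exp(-2.0 * d)
    else:
        R = np.maximum(0.0, 0.25 - 0.5 * d)
    np.fill_diagonal(R, 0.25)
    return ChromCovariance(chrom=chrom, R=R, method=method)


def build_all_R(gmap: GeneticMap, method: str = "haldane") -> dict:
    """Build and keep R for every chromosome (dict keyed by chromosome label)."""
    return {c: build_R(gmap, c, method) for c in gmap.chromosomes}


class LazyChromCovariances(Mapping):
    """Mapping view that builds each chromosome's R on access and keeps none.

    Bounds the working set to a single chromosome's ``L_c x L_c`` matrix,
    useful for dense maps processed one chromosome at a time.
    """

    def __init__(self, gmap: GeneticMap, method: str = "haldane") -> None:
        if method not in KERNELS:
            raise ValueError(f"method must be one of {KERNELS}, got {method!r}")
        self._gmap = gmap
        self.method = method

    def __getitem__(self, chrom) -> ChromCovariance:
        return build_R(self._gmap, chrom, self.method)

    def __iter__(self) -> Iterator:
        return iter(self._gmap.chromosomes)

    def __len__(self) -> int:
        return len(self._gmap.chromosomes)
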