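"""Reading, validation and writing of phased genotypes and marker effects.

The tool neither phases nor imputes: haplotypes must be fully phased and free
of missing calls, and the marker order of map, haplotypes and effects must
agree exactly before any computation starts.  Two haplotype dialects are
supported:

* ``two_row_csv`` -- two consecutive rows per individual (first haplotype,
  then second), first column the individual id, remaining columns alleles in
  {0, 1}.  An optional header row carries marker ids; headerless files are
  assumed to be in map order.
* ``phased_vcf`` -- standard VCF 4.x with biallelic records and phased
  ``GT`` fields (``|`` separator).  The VCF REF allele maps to allele code 1
  ("reference allele") and ALT to 0.

Allele semantics: code 1 is the "reference allele" whose presence on the
first haplotype of a heterozygote gives phase indicator +1.  A global swap of
allele labels flips the signs of phase indicators and genotype codes but
leaves every Mendelian sampling (co)variance and similarity unchanged; GEBVs
flip sign.
"""

from __future__ import annotations

import csv
import io
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genetic_map import GeneticMap

__all__ = [
    "PhasedHaplotypes",
    "MarkerEffectSet",
    "IndexWeights",
    "Bundle",
    "load_haplotypes",
    "write_haplotypes",
    "load_effects",
    "write_effects",
    "load_weights",
    "validate_alignment",
    "write_labeled_matrix",
]


@dataclass(frozen=True)
class PhasedHaplotypes:
    """N individuals x 2 haplotypes x L markers of alleles in {0, 1}."""

    individual_id: np.ndarray
    alleles: np.ndarray
    marker_id: np.ndarray | None = None

    def __post_init__(self) -> None:
        ids = np.asarray(self.individual_id, dtype=object)
        al = np.asarray(self.alleles)
        if al.ndim != 3 or al.shape[1] != 2:
            raise ValueError("alleles must have shape (N, 2, L)")
        if not np.isin(al, (0, 1)).all():
            raise ValueError("alleles must be 0 or 1 (no missing calls)")
        if ids.size != al.shape[0]:
            raise ValueError("individual_id length does not match alleles")
        if len(set(ids)) != ids.size:
            raise ValueError("individual ids must be unique")
        object.__setattr__(self, "individual_id", ids)
        object.__setattr__(self, "alleles", al.astype(np.uint8))
        if self.marker_id is not None:
            mid = np.asarray(self.marker_id, dtype=object)
            if mid.size != al.shape[2]:
                raise ValueError("marker_id length does not match allele count")
            object.__setattr__(self, "marker_id", mid)

    @property
    def n_individuals(self) -> int:
        return self.alleles.shape[0]

    @property
    def n_markers(self) -> int:
        return self.alleles.shape[2]

    def index_of(self, individual) -> int:
        hits = np.flatnonzero(self.individual_id == individual)
        if hits.size == 0:
            raise KeyError(f"unknown individual id: {individual!r}")
        return int(hits[0])


@dataclass(frozen=True)
class MarkerEffectSet:
    """Additive marker effects, T traits x L markers, aligned to the map."""

    trait_names: tuple
    effects: np.ndarray
    marker_id: np.ndarray | None = None

    def __post_init__(self) -> None:
        eff = np.asarray(self.effects, dtype=float)
        if eff.ndim == 1:
            eff = eff[None, :]
        if eff.ndim != 2:
            raise ValueError("effects must be a T x L matrix")
        if not np.isfinite(eff).all():
            raise ValueError("marker effects must be finite")
        names = tuple(self.trait_names)
        if len(names) != eff.shape[0] or len(names) < 1:
            raise ValueError("trait_names length must equal the number of effect rows")
        object.__setattr__(self, "trait_names", names)
        object.__setattr__(self, "effects", eff)
        if self.marker_id is not None:
            mid = np.asarray(self.marker_id, dtype=object)
            if mid.size != eff.shape[1]:
                raise ValueError("marker_id length does not match effect columns")
            object.__setattr__(self, "marker_id", mid)

    @property
    def n_traits(self) -> int:
        return self.effects.shape[0]

    @property
    def n_markers(self) -> int:
        return self.effects.shape[1]


@dataclass(frozen=True)
class IndexWeights:
    """Length-T index weight vector for the aggregate genotype."""

    a: np.ndarray

    def __post_init__(self) -> None:
        a = np.asarray(self.a, dtype=float).ravel()
        if a.size < 1 or not np.isfinite(a).all():
            raise ValueError("index weights must be a finite non-empty vector")
        if np.all(a == 0):
            raise ValueError("index weights must have at least one nonzero entry")
        object.__setattr__(self, "a", a)

    def __len__(self) -> int:
        return self.a.size


@dataclass(frozen=True)
class Bundle:
    """Validated, immutable (map, haplotypes, effects) triple.

    Produced by :func:`validate_alignment`; all downstream computations
    require a bundle so marker-order consistency is checked exactly once.
    """

    gmap: GeneticMap
    haps: PhasedHaplotypes
    effects: MarkerEffectSet
    _token: object = field(default=None, repr=False)

    @property
    def n_individuals(self) -> int:
        return self.haps.n_individuals

    @property
    def n_traits(self) -> int:
        return self.effects.n_traits


def _sniff_delimiter(sample: str) -> str:
    return "\t" if sample.count("\t") > sample.count(",") else ","


def _load_two_row_csv(path) -> PhasedHaplotypes:
    with open(path, "rt", newline="") as fh:
        text = fh.read()
    rows = list(csv.reader(io.StringIO(text), delimiter=_sniff_delimiter(text.splitlines()[0])))
    rows = [r for r in rows if r]
    if not rows:
        raise ValueError("empty haplotype file")
    marker_id = None
    if rows[0][0].lower() == "id":  # optional header row carrying marker ids
        marker_id = np.asarray(rows[0][1:], dtype=object)
        rows = rows[1:]
    if len(rows) % 2:
        raise ValueError("two_row_csv requires two rows per individual (odd row count)")
    ids, haps = [], []
    for r1, r2 in zip(rows[::2], rows[1::2]):
        if r1[0] != r2[0]:
            raise ValueError(f"haplotype row pair has mismatched ids: {r1[0]!r} vs {r2[0]!r}")
        ids.append(r1[0])
        for row in (r1, r2):
            bad = [c for c in row[1:] if c not in ("0", "1")]
            if bad:
                raise ValueError(f"allele outside {{0,1}} for individual {r1[0]!r}: {bad[0]!r}")
        haps.append([[int(c) for c in r1[1:]], [int(c) for c in r2[1:]]])
    return PhasedHaplotypes(np.asarray(ids, dtype=object), np.asarray(haps), marker_id)


def _load_phased_vcf(path) -> PhasedHaplotypes:
    import pysam

    with pysam.VariantFile(str(path)) as vf:
        samples = list(vf.header.samples)
        marker_id, columns = [], []
        for rec in vf:
            if rec.alts is None or len(rec.alts) != 1:
                raise ValueError(f"non-biallelic record at {rec.chrom}:{rec.pos} ({rec.id})")
            marker_id.append(rec.id if rec.id else f"{rec.chrom}:{rec.pos}")
            col = np.empty((len(samples), 2), dtype=np.uint8)
            for s, sample in enumerate(samples):
                call = rec.samples[sample]
                gt = call.get("GT")
                if gt is None or len(gt) != 2 or any(a is None for a in gt):
                    raise ValueError(
                        f"missing genotype for sample {sample!r} at {rec.chrom}:{rec.pos}"
                    )
                if not call.phased:
                    raise ValueError(
                        f"unphased genotype for sample {sample!r} at {rec.chrom}:{rec.pos}"
                    )
                # VCF allele index 0 (REF) -> code 1, index 1 (ALT) -> code 0
                col[s] = [1 - gt[0], 1 - gt[1]]
            columns.append(col)
    alleles = np.stack(columns, axis=2)  # N x 2 x L
    return PhasedHaplotypes(np.asarray(samples, dtype=object), alleles, np.asarray(marker_id, dtype=object))


def _reorder_to_map(haps: PhasedHaplotypes, gmap: GeneticMap) -> PhasedHaplotypes:
    if haps.n_markers != gmap.n_markers:
        raise ValueError(
            f"haplotypes have {haps.n_markers} markers but map has {gmap.n_markers}"
        )
    if haps.marker_id is None:
        return PhasedHaplotypes(haps.individual_id, haps.alleles, gmap.marker_id)
    pos = {m: i for i, m in enumerate(haps.marker_id)}
    missing = [m for m in gmap.marker_id if m not in pos]
    if missing:
        raise ValueError(f"haplotype file is missing map marker {missing[0]!r}")
    order = np.asarray([pos[m] for m in gmap.marker_id])
    return PhasedHaplotypes(haps.individual_id, haps.alleles[:, :, order], gmap.marker_id)


def load_haplotypes(path, dialect: str = "two_row_csv", gmap: GeneticMap | None = None) -> PhasedHaplotypes:
    """Load fully phased haplotypes; optionally reorder markers to a map."""
    if dialect == "two_row_csv":
        haps = _load_two_row_csv(path)
    elif dialect == "phased_vcf":
        haps = _load_phased_vcf(path)
    else:
        raise ValueError(f"unknown haplotype dialect: {dialect!r}")
    if gmap is not None:
        haps = _reorder_to_map(haps, gmap)
    return haps


def write_haplotypes(haps: PhasedHaplotypes, path, dialect: str = "two_row_csv",
                     gmap: GeneticMap | None = None) -> None:
    """Write haplotypes in either dialect (VCF output requires a map)."""
    if dialect == "two_row_csv":
        with open(path, "wt", newline="") as fh:
            w = csv.writer(fh)
            if haps.marker_id is not None:
                w.writerow(["id", *haps.marker_id])
            for i, ind in enumerate(haps.individual_id):
                w.writerow([ind, *haps.alleles[i, 0].tolist()])
                w.writerow([ind, *haps.alleles[i, 1].tolist()])
    elif dialect == "phased_vcf":
        if gmap is None:
            raise ValueError("writing VCF requires a genetic map for CHROM/POS fields")
        _write_phased_vcf(haps, gmap, path)
    else:
        raise ValueError(f"unknown haplotype dialect: {dialect!r}")


def _write_phased_vcf(haps: PhasedHaplotypes, gmap: GeneticMap, path) -> None:
    with open(path, "wt") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        for c in gmap.chromosomes:
            fh.write(f"##contig=<ID={c}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t")
        fh.write("\t".join(str(s) for s in haps.individual_id) + "\n")
        last_bp = {}
        for k in range(gmap.n_markers):
            c = gmap.chrom[k]
            bp = max(int(round(gmap.pos_morgan[k] * 1_000_000)) + 1, last_bp.get(c, 0) + 1)
            last_bp[c] = bp
            # allele code 1 = REF (VCF allele 0), code 0 = ALT (VCF allele 1)
            gts = "\t".join(f"{1 - haps.alleles[i, 0, k]}|{1 - haps.alleles[i, 1, k]}"
                            for i in range(haps.n_individuals))
            fh.write(f"{c}\t{bp}\t{gmap.marker_id[k]}\tA\tC\t.\tPASS\t.\tGT\t{gts}\n")


def load_effects(path, gmap: GeneticMap | None = None) -> MarkerEffectSet:
    """Load marker effects from headered text: ``marker_id,<trait1>,...``."""
    df = pd.read_csv(path, sep=None, engine="python")
    if df.columns[0] != "marker_id" or df.shape[1] < 2:
        raise ValueError("effects file must have columns marker_id,<trait1>,...")
    mid = df["marker_id"].astype(str).to_numpy(dtype=object)
    traits = tuple(df.columns[1:])
    try:
        eff = df[list(traits)].to_numpy(dtype=float).T
    except ValueError as exc:
        raise ValueError(f"non-numeric marker effect: {exc}") from exc
    if not np.isfinite(eff).all():
        raise ValueError("marker effects must be finite (no missing values)")
    if gmap is not None:
        pos = {m: i for i, m in enumerate(mid)}
        missing = [m for m in gmap.marker_id if m not in pos]
        if missing:
            raise ValueError(f"effects file is missing map marker {missing[0]!r}")
        extra = set(mid) - set(gmap.marker_id)
        if extra:
            raise ValueError(f"effects file has marker not on the map: {sorted(extra)[0]!r}")
        order = np.asarray([pos[m] for m in gmap.marker_id])
        mid, eff = mid[order], eff[:, order]
    return MarkerEffectSet(traits, eff, mid)


def write_effects(eff: MarkerEffectSet, path) -> None:
    df = pd.DataFrame(eff.effects.T, columns=list(eff.trait_names))
    df.insert(0, "marker_id", eff.marker_id)
    df.to_csv(path, index=False)


def load_weights(path, effects: MarkerEffectSet | None = None) -> IndexWeights:
    """Load index weights from headered text ``trait,weight``, aligned by trait name."""
    df = pd.read_csv(path, sep=None, engine="python")
    if list(df.columns[:2]) != ["trait", "weight"]:
        raise ValueError("weights file must have columns trait,weight")
    w = dict(zip(df["trait"].astype(str), df["weight"].astype(float)))
    if effects is not None:
        missing = [t for t in effects.trait_names if t not in w]
        if missing:
            raise ValueError(f"weights file is missing trait {missing[0]!r}")
        return IndexWeights(np.asarray([w[t] for t in effects.trait_names]))
    return IndexWeights(df["weight"].to_numpy(dtype=float))


def validate_alignment(gmap: GeneticMap, haps: PhasedHaplotypes, effects: MarkerEffectSet) -> Bundle:
    """Check exact marker alignment among map, haplotypes and effects.

    Marker-id sequences must be identical (same set, same order); any
    mismatch is a hard failure — no silent reordering happens here.
    """
    for name, mid in (("haplotypes", haps.marker_id), ("effects", effects.marker_id)):
        if mid is None:
            if (haps if name == "haplotypes" else effects).n_markers != gmap.n_markers:
                raise ValueError(f"{name} marker count does not match the map")
            continue
        if mid.size != gmap.n_markers:
            raise ValueError(f"{name} have {mid.size} markers but map has {gmap.n_markers}")
        neq = np.flatnonzero(mid != gmap.marker_id)
        if neq.size:
            k = int(neq[0])
            raise ValueError(
                f"{name} marker order differs from map at position {k}: "
                f"{mid[k]!r} vs {gmap.marker_id[k]!r}"
            )
    return Bundle(gmap=gmap, haps=haps, effects=effects)


def write_labeled_matrix(M: np.ndarray, row_ids, path, col_ids=None) -> None:
    """Write a matrix as headered CSV with id row/column labels."""
    col_ids = row_ids if col_ids is None else col_ids
    pd.DataFrame(np.asarray(M), index=list(row_ids), columns=list(col_ids)).to_csv(
        path, index_label="id"
    )
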