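# msq

Mendelian sampling (co)variance, selection indices and haplotype-based
similarity for genomic selection.

## The problem

Selecting purely on genomic estimated breeding values (GEBVs) ranks parents
by the *mean* merit of their gametes and ignores how *variable* those
gametes are. Two parents with identical GEBVs can differ enormously in the
spread of offspring they can produce, depending on which loci are
heterozygous and how alleles are arranged across their two haplotypes
(linkage phase). That within-family spread — the Mendelian sampling variance
(MSV) — drives both the chance of an outstanding offspring and the
long-term maintenance of haplotype diversity. `msq` computes these
quantities, for breeders and quantitative geneticists with access to phased
genotypes, a genetic map and marker-effect estimates from any genomic
prediction model.

## The model

For chromosome *c*, the population covariance matrix of transmitted-allele
indicators **R**ᶜ has diagonal 0.25 and off-diagonals, from the map
distance *d<sub>kl</sub>* in Morgans, either

- Haldane (no interference): ρ<sub>kl</sub> = exp(−2 d<sub>kl</sub>) / 4, or
- linear approximation: ρ<sub>kl</sub> = 0.25 − d<sub>kl</sub> / 2, set to 0
  for d<sub>kl</sub> ≥ 0.5.

Each parent *i* gets phase-adjusted marker effects
m<sub>ik</sub> = δ<sub>ik</sub> m<sub>k</sub>, with phase indicator
δ<sub>ik</sub> = +1 / −1 / 0 for the reference allele on the first
haplotype, on the second, or homozygous. Then

- gametic MSV (single trait): σ²<sub>bᵢ</sub> = Σ<sub>c</sub> mᵢᶜ′ Rᶜ mᵢᶜ,
- multi-trait: **V**ᵢ = Σ<sub>c</sub> Mᵢᶜ Rᶜ Mᵢᶜ′ (MSVs on the diagonal,
  Mendelian sampling covariances off it), aggregate variance a′**V**ᵢa for
  index weights a,
- zygotic (parent pair): **V**ᵢⱼ = **V**ᵢ + **V**ⱼ,
- usefulness-style index: I = b + λσ, with λ = √2·x for a selected
  proportion *p* and normal truncation point *x*,
- haplotype similarity: s<sub>ij</sub> = Σ<sub>c</sub> |a′ Mᵢᶜ Rᶜ Mⱼᶜ′ a|,
  with S's diagonal equal to each parent's MSV, and the standardized kernel
  **K** = **D**⁻¹**S****D**⁻¹ (unit diagonal, off-diagonals in [0, 1])
  ready for use as a diversity kernel in optimal-contribution or mating
  optimizers.

Everything is cross-checked against an independent oracle that enumerates
the exact 2ᴸ gamete distribution of a chromosome (and a Monte-Carlo gamete
simulator for long chromosomes); see `msq.oracle_sim`.

## Worked example

```bash
msq synth --n 6 --chroms 2 --markers 50 --traits 2 --families 2 --seed 42 --out-dir demo
```

```python
import msq

gmap = msq.load_map("demo/map.csv", units="morgan")
haps = msq.load_haplotypes("demo/haplotypes.csv", "two_row_csv", gmap=gmap)
eff = msq.load_effects("demo/effects.csv", gmap=gmap)
bundle = msq.validate_alignment(gmap, haps, eff)

R = msq.build_all_R(bundle.gmap, "haldane")
results = msq.gametic_msq(bundle, R)
msq.selection_index(results, msq.lambda_from_proportion(0.05))
print(msq.msq_table(results, bundle.effects.trait_names).round(3).to_string(index=False))
```

```
  id  gebv_trait1  msv_trait1  gebv_trait2  msv_trait2  gebv_aggregate  msv_aggregate  sd_aggregate  index
ind1       -6.030      13.056       -2.394       4.649          -8.424          9.408         3.067 -1.289
ind2       -9.370       6.408       -5.777      11.857         -15.147          9.002         3.000 -8.168
ind3        0.006      11.463       10.982      22.285          10.989         20.768         4.557 21.589
ind4       -0.950      11.066       -0.621       5.469          -1.571         23.584         4.856  9.725
ind5       -8.160       1.972        3.327       8.410          -4.833          9.263         3.044  2.247
ind6       -6.672       4.335        3.485      10.248          -3.187         11.949         3.457  4.854
```

Per-trait columns give each parent's GEBV and MSV; `msv_aggregate` is
a′**V**ᵢa for the (default, equal) index weights, and `index` combines
aggregate GEBV with the Mendelian standard deviation at λ(p = 0.05) ≈ 2.326.
ind3 and ind4 have similar mid-range GEBVs, but their large MSVs mean a far
better chance of top-ranking offspring than their means alone suggest —
exactly what the index rewards.

```python
sim = msq.similarity_matrix(bundle, R)
print(sim.K.round(3))   # standardized similarity, [0, 1]
```

```
[[1.    0.168 0.416 0.356 0.191 0.372]
 [0.168 1.    0.184 0.211 0.088 0.212]
 [0.416 0.184 1.    0.164 0.54  0.497]
 [0.356 0.211 0.164 1.    0.596 0.452]
 [0.191 0.088 0.54  0.596 1.    0.34 ]
 [0.372 0.212 0.497 0.452 0.34  1.   ]]
```

Off-diagonal entries near 1 flag parent pairs whose MSVs arise from the
*same* segregating segments — mating both heavily would erode haplotype
diversity; entries near 0 mark complementary parents.

The same computations are available from the shell:

```bash
msq estimate --map demo/map.csv --haps demo/haplotypes.csv \
    --effects demo/effects.csv --kernel haldane --prop 0.05 --out-prefix demo/
msq similarity --map demo/map.csv --haps demo/haplotypes.csv \
    --effects demo/effects.csv --out-prefix demo/
```

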