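# Methods

## Model

A gamete transmits, at each marker *k*, one of the parent's two alleles.
Code the transmitted reference allele as +m<sub>k</sub>/2 and the
alternative as −m<sub>k</sub>/2, where m<sub>k</sub> is the additive marker
effect; two gametes then sum to the familiar {1, 0, −1} genotype coding
times m<sub>k</sub>, and a single heterozygous locus contributes gametic
variance m<sub>k</sub>²/4. Under a no-interference (Haldane) crossover
process, the covariance between the transmitted-allele indicators of two
loci at map distance *d* Morgans is (1 − 2r)/4 = exp(−2d)/4, with
r = (1 − e<sup>−2d</sup>)/2 the recombination fraction. Collecting these
into a single per-chromosome matrix **R**ᶜ — diagonal 0.25, off-diagonals
exp(−2d<sub>kl</sub>)/4 — the gametic (Mendelian sampling) covariance of
parent *i* for traits is

V_i = Σ_c M_i^c R^c (M_i^c)',

where M_i^c carries the parent's phase-adjusted effects
(δ<sub>ik</sub> = ±1 by which haplotype holds the reference allele, 0 if
homozygous). Because phase enters through the effect vectors, one **R**ᶜ
serves the whole population; no parent-specific covariance matrix is ever
formed. Chromosomes assort independently, so every quantity accumulates
over chromosomes; zygotic (parent-pair) covariances are the sum of the two
parents' gametic covariances under additivity.

The identity cov = (1 − 2r)/4 is what makes the enumeration oracle in
`msq.oracle_sim` an *exact* check of the matrix formulas: the variance of
the full 2ᴸ gamete-origin distribution (fair coin at the first locus,
Markov switches with probability r per interval) must equal the quadratic
form under the Haldane kernel to floating-point accuracy, and the test
suite asserts relative error ≤ 1e−10 over random instances.

## Mapping functions and their domain

Two kernels are provided. `haldane` is consistent with the crossover model
at all distances. `linear` is the first-order expansion 0.25 − d/2,
truncated to 0 at d ≥ 0.5 Morgans; it is an approximation, cheaper and
historically common, and the tests document (rather than hide) its
deviation from the exact distribution at long range. Truncation is applied
on the distance scale when positions are the input; when the map supplies
adjacent recombination rates, those are converted at load time through the
inverse Haldane map d = −ln(1 − 2r)/2 (rates ≥ 0.5 are rejected as
non-invertible), so by the time a kernel sees the map everything is in
Morgans. Both kernels are valid one-dimensional covariance kernels
(exponential and triangular), so **R**ᶜ is positive semidefinite by
construction; a property test verifies symmetry, the 0.25 diagonal,
off-diagonals in [0, 0.25], PSD-ness and shift invariance on random maps.

Markers at identical positions are allowed (ρ = 0.25 off-diagonal): dense
chips produce ties and the formulas are well defined there. Interference
models (e.g. Kosambi) are out of scope.

## Units, coding and invariances

Positions are Morgans internally; centiMorgans are accepted only at the I/O
boundary. Allele code 1 is the "reference" allele (VCF REF maps to 1, ALT
to 0). A global swap of allele labels negates every δ and genotype code,
which leaves all MSVs, MSCs, V matrices and similarities unchanged and
flips the sign of every GEBV — asserted exactly (bitwise) in the tests, as
is chromosome additivity and the zygotic identity V_ij = V_i + V_j. The
accumulated V is made symmetric by mirroring its upper triangle, a choice
that commutes bit-for-bit with per-chromosome accumulation (averaging with
the transpose would not).

## Similarity kernel

s_ij = Σ_c |a' M_i^c R^c (M_j^c)' a| is the absolute per-chromosome
covariance between two parents' gametic values for the aggregate genotype.
The absolute value makes it invariant to either parent's arbitrary
haplotype labelling; the per-chromosome Cauchy–Schwarz inequality under a
PSD **R**ᶜ bounds s_ij by σ_i σ_j, so the standardized kernel
K = D⁻¹SD⁻¹ has unit diagonal and off-diagonals in [0, 1]. Parents with
zero MSV have a degenerate Mendelian sampling term; their standardized
off-diagonals are reported as 0 (no shared segregating segments) with the
diagonal flagged NaN and a warning, avoiding non-finite propagation. For
the zygotic pair similarity, first parents are matched with first parents
and second with second, so callers should order pairs consistently (sire
first, dam second). A per-trait-pair similarity (T×T blocks) would be a
different object and is not provided; the aggregate-genotype scalar is the
defined quantity.

S is assembled block-wise over individuals (default chunk 1024 rows), so
peak memory is the output matrix plus one chunk of weighted phase-adjusted
effect vectors; subsets of individuals and chromosomes restrict the
computation, which is the practical route for very large candidate sets
given the O(N²) output.

## Selection index

I = b + λσ combines the aggregate GEBV with the Mendelian standard
deviation. λ may be given directly or derived from a selected proportion
*p* as λ = √2·Φ⁻¹(1 − p), the choice that maximizes the probability of
producing offspring in the top fraction *p*. For a parent pair, the default
index uses the pair's own zygotic SD, I_ij = (b_i + b_j)/2 + λσ_ij; the
variant that averages the two parental indices is available
(`method="parent_average"`). The zygotic SD is the quantity the zygotic
variance formula exists to supply, hence the default.

## Synthetic data generator

`generate_synthetic` emulates the structure of dairy-cattle reference
panels: by default 265 individuals in 5 paternal half-sib families, 29
chromosomes of 1 Morgan with 355 evenly spaced markers each (~10,300
genome-wide), 3 traits, allele frequency 0.3 and unit-scale centered-normal
effects. Family structure is made by sampling each member's paternal
haplotype as a recombinant gamete of the family's sire (the same Haldane
crossover chain as the simulator) and its maternal haplotype from the
population. Random streams are spawned per purpose, per individual and per
chromosome from a master seed, so subsetting individuals never perturbs the
draws of others and a given seed is fully reproducible.

What the generator does *not* emulate: linkage disequilibrium beyond
family-induced haplotype sharing (population alleles are drawn
independently per marker), realistic allele-frequency spectra, genotyping
error, or effect-size distributions with major loci. Passing tests on this
data therefore validate the algebra and the code paths, not the behaviour
of the statistics on real LD structures; the enumeration oracle is the
stronger guarantee, since it is exact for any input haplotypes.

## Numerical choices and problem sizes

All accumulation is double precision with per-chromosome partial sums.
Tiny negative aggregate variances arising from rounding are clipped to 0.
Exact enumeration is limited to L ≤ 20 per chromosome (2ᴸ origins); beyond
that the Monte-Carlo simulator applies, drawing origin chains in chunks of
50,000 gametes to bound memory. The validation suite uses L ≤ 12 with ≥ 50
random instances for exact oracle agreement, and one 500-marker chromosome
with 200,000 simulated gametes for Monte-Carlo agreement (within 3
delta-method standard errors of the empirical variance) — sizes chosen so
the whole suite runs in well under a minute of compute while exercising
both regimes.

## Known limitations

Additive effects only: no dominance, epistasis, or polygenic residual
component; marker-effect estimation, phasing and imputation are upstream
of this package, and errors in any input propagate directly into the
outputs. The two_row_csv haplotype layout is this package's own on-disk
definition (the field has no standard); phased VCF is supported as the
interoperable alternative.
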