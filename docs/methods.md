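# Methods

This note documents the models and procedures implemented in `radancestry`,
the parameters that matter, the numerical choices, and what the synthetic
data generator does and does not emulate.

## Pairwise difference counting

All downstream inference consumes per-window counts *(k, n)* per sample
pair: *k* integer sequence differences and *n* compared allele-sites.
Coordinates are 0-based half-open internally; VCF positions are converted at
the parser boundary. Windows are nonoverlapping tiles of width *W* (default
100 kb, the resolution at which ancestry is assigned); a sliding `step` is
available for exploratory windowed summaries.

Phase is unavailable in RAD data, so each diploid is represented in a window
by two pseudo-haplotypes formed by sorting the alleles at every site (0
before 1). Comparing hap1–hap1 and hap2–hap2 and summing gives an integer
*k* per site pair: identical homozygotes contribute 0, hom–het 1, opposite
homozygotes 2. The denominator is *n* = 2 × (bp of the two samples' coverage
intersection in the window), so invariant callable sequence counts toward
*n* and *k/n* is a per-site rate comparable across windows with different
locus content. Three conventions complete the contract:

- a site where either sample lacks a genotype call but both are covered
  counts as equal (in *n*, not *k*) — assembled-locus counting, where
  invariant positions dominate;
- multi-allelic records and indels are dropped at VCF load (logged), as the
  binomial emission model assumes biallelic per-site rates;
- a window with *n* = 0 has an undefined rate and is flagged missing, never
  silently zero.

π(window, population) is the mean of *k/n* over within-population pairs,
d_XY the mean over between-population pairs; genome-wide values are
coverage-weighted (Σk/Σn per pair, then averaged over pairs), as is the
genome-wide distance matrix.

## The ancestry HMM

Three hidden states per window of a focal individual: SRC (both haplotypes
donor-derived), NAT (both native), HET (one of each). Emissions are
binomial: if the window is donor ancestry, the focal-vs-donor-panel
difference rate is about the donor's own diversity π; if native, about the
species divergence d_XY; if heterozygous, their midpoint m. Emission rates
are estimated as genome-wide **medians** of the windowed per-pair rates
(within-panel pairs for p_src; native-reference × panel pairs for p_nat),
clipped to [10⁻⁶, 1−10⁻⁶]; medians are robust to the minority of windows
that are themselves introgressed. p_nat ≤ p_src raises a diagnostic error —
the populations are not diverged enough for window-level assignment.

**Observation aggregation.** Per window the counts from the focal × panel
comparisons are combined. The default divides the summed (k, n) by the
number of pairs (rounding to integers) rather than using the raw sums:
almost all differences to the panel are fixed inter-species sites shared by
every panel member, so raw summation replicates the same observations P
times, inflating n P-fold without adding independent trials. The binomial
then becomes strongly overconfident, and ordinary window-to-window
fluctuation in the local density of fixed differences (Poisson in the
mutation process, CV ≈ 25–30 % at RAD site densities) is misread as ancestry
switching — in development measurements, ~10 % of native windows were called
HET. Panel-averaged counts keep n at the information content of one
diploid-pair comparison, for which the binomial is calibrated (the shared
fixed-site component is Poisson with variance ≈ mean), while still using the
whole panel; measured false-positive rates drop to ~5 × 10⁻⁴ with window
sensitivity ≈ 0.98. Raw summation (`aggregate="sum"`) and a panel-size cap
(`max_panel`) remain available.

**Transitions.** Symmetric: stay with probability 1−τ, switch τ/2 to each
other state, uniform initial distribution. Default τ = 10⁻³ per 100 kb
window, matching an expected block scale of tens of Mb; a distinct HET
switch rate is available. The matrix is fully overridable, as is the
emission parameterization.

**Decoding.** Log-space Viterbi per chromosome. Windows with
n < `min_sites` (default 100 allele-sites — a binomial with tiny n carries
no signal) contribute log 1 = 0 to every state, so the path stays continuous
through data gaps and is bridged by the transition prior; such windows are
labelled MISSING in the output. Exact log-likelihood ties break toward
NAT > HET > SRC, conservative against false introgression calls. A
forward–backward posterior decoder is included as an optional companion.
The HMM itself is deterministic; only simulations take seeds.

## Blocks, breakpoints, and ages

Blocks are maximal runs of SRC or HET windows; interior MISSING runs flanked
by the same state are bridged into the block (with a count of bridged
windows), while MISSING between different states belongs to no block.
Coordinates snap to window boundaries. The per-individual admixture
proportion weights HET windows by 0.5 (diploid dosage: one donor haplotype
of two) over all non-missing windows. Shared breakpoints group carriers
whose block start **and** end agree within a tolerance (default 1 window,
the HMM's resolution); because pairwise matching is not transitive, groups
are the connected components of the match graph.

Block age uses proportional tract erosion: if recombination removes a
fraction c of a donor tract per generation, a tract spanning fraction x of
its chromosome after t generations satisfies x = (1−c)^t, so
**t = ln x / ln(1−c)** — zero at x = 1 and strictly decreasing in x. This
survival-decay form is a deliberate modeling choice (c may be supplied
directly or derived as c = r_bp × L × κ); it yields ages of a few
generations for chromosome-scale surviving blocks (e.g. x = 0.792,
c = 0.054 → 4.20 generations) and should be read as an order-of-magnitude
dating, not a likelihood-based estimate from the tract-length distribution.

## Admixture mapping

Carrier status at a locus is dominance-coded: any SRC or HET block
overlapping the locus (half-open semantics) makes the individual a carrier,
since one donor haplotype suffices for a dominant phenotype; SRC maps to
hom-carrier and HET to het-carrier for reporting. Association is the χ²
test of independence on the 2×2 carrier × phenotype table with the **Yates
continuity correction on by default** — the sample sizes this design
produces are small, and the corrected statistic
N(|ad−bc|−N/2)²/((a+b)(c+d)(a+c)(b+d)) (floored at 0) is the appropriate
default; the uncorrected variant is a flag. The genome scan tests every
window with at least one carrier and one non-carrier among phenotyped,
non-missing individuals and reports raw p plus Benjamini–Hochberg q per
scan; candidate-locus windows are flagged so a candidate-gene lookup can
ignore the correction.

## Population-genetic summaries

`site_stats` computes S, θ_W = S/a₁, π, observed heterozygosity and
Tajima's D with the textbook variance constants on **complete-case sites**
(every sample in the set called), keeping the sample size of the constants
fixed; D is undefined (flagged, never 0) when S = 0. A windowed variant
reports mean ± s.d. of D across windows.

The folded SFS uses expected hypergeometric down-projection: a site with m
called chromosomes and j alternate alleles contributes
P(i | m, j, n′) to folded class min(i, n′−i) for each i ≤ n′, and is dropped
if m < n′ — deterministic, and mass-conserving (each retained site
contributes total weight 1). Masking (e.g. of inferred introgressed regions,
which otherwise masquerade as excess rare variants) excludes sites before
projection. The SFS bootstrap resamples sites across bins multinomially,
preserving the total. Spectra can be exported in the dadi frequency-spectrum
text format.

Patterson's D is frequency-weighted: ABBA = Σ(1−p₁)p₂p₃(1−p₄),
BABA = Σp₁(1−p₂)p₃(1−p₄) over biallelic sites, with the outgroup's major
allele as ancestral and polymorphic-outgroup sites dropped (counted).
Uncertainty comes from a block bootstrap over genomic blocks (default 1 Mb)
with a one-sided bootstrap p = (extreme+1)/(reps+1). Demographic rescaling
converts diffusion-fit outputs: N_ref = θ/(4μL); sizes multiply N_ref, times
multiply 2N_ref; a helper sums epoch times that are already in generations.

## The synthetic data generator

The generator emulates the *structure* of a two-species ddRAD panel: ~12
chromosomes (default 12 × 5 Mb), ~200 bp loci at a mean spacing of 3 kb
(≈20k loci per genome) with 20 % per-sample locus dropout (80 %
completeness), a donor panel and a native focal population, planted
Mb-scale donor tracts with explicit zygosity, and a dominance-coded binary
phenotype controlled by donor ancestry at a causal locus. Defaults follow
the study conditions it stands in for: π_donor = 4.5 × 10⁻⁴,
π_native = 2.3 × 10⁻⁴, d_XY = 2.3 × 10⁻³ per site.

The mutation model is star-like, not coalescent: a root sequence receives
species-ancestor mutations at rate (d − (π_s+π_n)/2)/2 per branch (fixed
within each species), and each haplotype adds private mutations at π_pop/2.
First moments are exact by construction — within-population pair rate
≈ π_pop, between-species ≈ d — which is all the HMM consumes. Mutations are
placed on integer positions inside the locus footprint without recurrence
(drawn without replacement). Tracts replace a focal haplotype segment with a
fresh donor haplotype (donor-branch alleles plus fresh donor-rate privates);
hom tracts replace both haplotypes. An optional `ancestral_poly_rate` plants
unlinked shared polymorphism (each ingroup haplotype carries the alternate
independently at a per-site random frequency) — off by default so the stated
moments hold, and needed only to give ABBA+BABA a nonzero denominator in
no-gene-flow D-statistic scenarios, since a pure star phylogeny has no
incomplete lineage sorting. Optional all-reference outgroup diploids
represent the root for polarization.

What this generator does **not** emulate — and what passing tests therefore
do not demonstrate about real data: linkage disequilibrium and realistic
haplotype structure, recombination during the simulated history (tracts are
planted, not recombined in), coalescent variance in genealogies, selection,
sequencing error, allele dropout correlated with divergence, or reference
bias. Its frequency spectrum is almost entirely singletons (every variant is
private to one haplotype or fixed between species), which is qualitatively
bottleneck-like but not calibrated to any demographic model.

The `mg114_scenario(seed)` preset builds the recovery benchmark used by the
acceptance checks: 15 focal diploids, a 10-diploid donor panel, six carriers
sharing a breakpoint-identical homozygous 1.6 Mb tract over the causal locus
on chr03 plus one private 0.6 Mb tract each (expected donor fraction
(1.6+0.6)/60 ≈ 3.7 % of the genome), non-carriers tract-free.
`evaluate_recovery` discretizes planted tracts to windows (a window is truth
introgressed when ≥ 50 % covered), counts the window-level confusion matrix
(MISSING predictions count as negative), and reports per-tract boundary
offsets in window units.

## Problem sizes and numerical choices

The test suite and the acceptance script run the full pipeline on 20
generator seeds of the preset scenario (25 diploids × 60 Mb × ~20k loci,
~35k SNPs per panel), 200 random Viterbi instances of ≤ 8 windows checked
against exhaustive 3^L enumeration, and 100 random small matrices (≤ 5
samples × ≤ 20 sites) checked against brute-force oracles for θ_W, π,
Tajima's D, the projected folded SFS, and D. Emission probabilities are
clipped to [10⁻⁶, 1−10⁻⁶]; binomial normalization is exact to 1e-9 for
n ≤ 200; χ² p-values agree with the erfc closed form to 1e-10. All
simulation entry points require an explicit seed and are reproducible
byte-for-byte.

## Known limitations

- Window-level resolution: sub-100 kb introgression signals are invisible;
  short heterozygous tracts (≲ 1 Mb) sit close to the decision boundary and
  may be missed.
- The block-age formula is a survival heuristic, not a tract-length
  likelihood; it ignores map heterogeneity unless folded into c.
- Emission estimation assumes the native reference is mostly unadmixed
  (medians tolerate a minority of introgressed windows).
- Published diversity tables, genome-wide Tajima's D, the real-data D
  statistic and demographic optima from the motivating study design require
  the original sequencing data and external optimizers; this package
  reproduces the *methods* and validates them on synthetic ground truth, and
  only rescales or totals such published outputs where they are pure
  arithmetic on printed inputs.
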