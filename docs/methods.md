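# Methods

## The problem

Meiotic recombination in humans concentrates in narrow (1–2 kb) hotspots
whose intensity can differ between chromosomes carrying different alleles
of nearby SNPs — *cis*-acting hotspot modifiers.  Direct measurement
(sperm typing) is laborious; this package maps such associations
computationally from phased population haplotype panels.  For a candidate
SNP near a hotspot, the panel is split into the two allele-defined
subpopulations, the historical (LD-inferred) recombination map is
re-estimated for each side with the identical estimator, and the hotspot
strengths are contrasted.  If an allele genuinely modulates the hotspot,
the subpopulation carrying the activating ("hot") allele should show the
larger historical activity, despite the opposing pull of biased gene
conversion (BGC), which under-transmits the hot allele among recombinant
gametes.

## Rate estimation

Per-segment population rates ρ = 4·Ne·r (one segment per adjacent SNP
pair, in units of ρ per kb) are estimated with a haplotype-copying
(Li–Stephens / PAC) composite likelihood: each haplotype is modelled as an
imperfect mosaic of the haplotypes preceding it in a random ordering; the
copying path switches templates by an exponential clock with intensity
ρ_j·d_j/k over segment j (d_j in kb, k templates), and mismatches are
emitted with the usual Watterson-scaled error.  The log composite
likelihood is averaged over `n_orderings` (default 2) seeded orderings.

Maximization is expectation–maximization: forward–backward yields the
expected number of copying switches and the clock exposure per segment;
the M-step refits the rates.  Because per-segment maximum-likelihood rates
are noisy, the M-step solves a penalized piecewise-constant fit — Poisson
likelihood on the expected switch counts with a fixed cost
(`block_penalty`, default 5.0) per change point — exactly, by optimal
partitioning dynamic programming.  Rates are clamped to
[`rho_floor` = 1e-3, `rho_ceil` = 500] per kb; a segment with no
recombination signal (only two of the four gametes observed) converges to
the floor.  Rows are put in canonical order before the seeded orderings
are applied, so profiles are bit-for-bit reproducible and invariant to
row order.

Two points matter for interpretation:

* **Scale.**  The PAC rate scale is biased upward relative to the true
  4·Ne·r (roughly 5-fold on the simulated benchmark).  All downstream
  statistics are *within-run contrasts* (Δρ is normalized by the sum, and
  permutation nulls use the same estimator), so the absolute scale
  cancels; only the hotspot-calling rate filter sees it (below).  Users
  who want LDhat- or pyrho-calibrated maps can import them through the
  rate-profile TSV interface.
* **Penalty as a detection device.**  The change-point penalty produces
  clean piecewise-flat maps for hotspot *calling*, but makes small-sample
  *strengths* nearly binary (the peak is either kept or flattened), which
  destroys the normality of random-split Δρ.  Strength quantification
  inside splits and permutations therefore uses the unpenalized
  per-segment fit (`ScanConfig.split_block_penalty = 0`).

## Hotspot calling

Peaks are runs of segments strictly above both neighbours (a plateau's
midpoint is its center — the derivative criterion is ill-defined on a
step function).  A normal density plus baseline is least-squares fitted
to the map in the 50-kb window around each peak; fits with σ ≤ 10 bp,
σ ≥ 25 kb, or vanishing amplitude are discarded.  Boundaries extend over
the contiguous run of segments, containing the peak, whose rate exceeds
the length-weighted mean rate of the 50-kb fit region, with the search
restricted to the span L = min(2σ, FWHM, 50 kb) centered at the fitted
peak (FWHM = 2√(2 ln 2)·σ, so effectively L = min(2σ, 50 kb); the
2×FWHM reading of the span is available via `width_rule="2fwhm"`).  Two
deliberate readings of this rule suit piecewise-flat maps: the reference
mean is taken over the 50-kb fit region, not over L (a plateau filling
its own span would otherwise always be compared against itself and
vanish), and a run touching the span edge keeps following the above-mean
plateau beyond it, so an over-wide plateau is measured at its true width
and rejected by the width filter rather than silently truncated.
Overlapping calls are separated at the midpoint of the minimum-rate
segment between their peaks.  Calls wider than 20 kb or with
width-averaged rate ≤ 1 cM/Mb (ρ converted with the configured Ne,
default 10,000) are dropped.  Because of the estimator's scale bias the
1 cM/Mb filter is nominal; the effective guards on simulated data are
the peak structure, the penalty, and the width filter (flat panels
produce no calls in ≥ 90% of benchmark replicates).

## The allele-split test

For each called hotspot the boundaries are frozen.  Candidate SNPs lie
inside the hotspot or within 200 SNPs of either boundary and have
MAF ≥ 0.3 (smaller minor classes give subpopulations too small for LD
rate estimation; a hard floor of 10 chromosomes is enforced).  Rate
estimation for a split runs in a sliding window of 500 segments centered
at the candidate SNP; when a window edge is interior to the panel, 50
edge segments are excluded from the trusted span (their rates depend on
SNPs outside the window).

The statistic is Δρ = (ρ0 − ρ1)/(ρ0 + ρ1), the normalized difference of
the two subpopulations' hotspot strengths (strength = Σ ρ·length over the
hotspot's segments, pro-rated at the ends).  Because allele age
correlates with allele frequency and with accumulated recombination, the
frequency-oriented Δρ (frequent minus rare allele) is standardized within
MAF bins: bins live at the sample's natural resolution (minor-allele
count), bins with fewer than two SNPs are merged with the nearest
populated bin, and z = (Δρ − E)/SD with the bin's empirical moments.

Significance comes from 200 random splits of the same chromosomes (each
side ≥ 30%).  By default the split sizes match the observed allele split
(the "ideal" test); a 50/50 mode with homologous chromosomes kept
together mirrors archival permutation schemes — the two give statistically
indistinguishable p-values.  The permutation Δρ are standardized by
**their own** empirical mean and SD.  This is deliberate: allele splits
partition the panel along genealogy (carriers of an allele share
ancestry), and their Δρ dispersion is measurably larger (about 2× on a
neutral benchmark panel) than that of random splits; standardizing both
sides by the observed-bin constants would leave the observed |z|
stochastically larger than the null |z| and pile p-values at zero even
without any causal SNP.  With self-standardized nulls both statistics
are pivotal, and on a causal-free panel the p-values are uniform across
distinct splits (Kolmogorov–Smirnov check in the test suite).  The
p-value is the fraction of permutation |z| exceeding the observed |z|
(an optional (k+1)/(n+1) correction is off by default, matching the
plain proportion definition); a raw-|Δρ| comparison mode is available.

Hotspots whose random-split Δρ fail Shapiro–Wilk normality (p < 0.05)
are gated out of the scan.  Such failures typically trace to a few
aberrant chromosomes: each chromosome's side score S = Σ ±|Δρ_i| over
permutations (positive when it sat on the hotter side) is screened by
iterative Grubbs' test (two-sided, t-based p, default threshold 0.1,
minimum 7 chromosomes), and the flagged chromosomes can be removed and
the pair re-tested (`retest_without_outliers`).

Multiple testing uses Storey q-values with π0 estimated at λ = 0.5,
computed once across all hotspot–SNP pairs of a run.  A null-model scan
(`null_scan`) repeats every test with a size-matched random pseudo-split
for FDR sanity checks.

## Forward simulator

The benchmark generator is a forward-time diploid Wright–Fisher model on
a 200-kb region: constant population (default 5,000; the desk-scale
benchmark uses 1,000), random mating between opposite-sex parents, at
most one crossover per meiosis.  A causal SNP controls the hotspot at
100 kb: crossover probability per meiosis is 0.001 (cold/cold), 0.01
(het), 0.02 (hot/hot); hotspot-active breakpoints are normal around the
center (σ = 1 kb, a free parameter), background breakpoints uniform.
BGC: with probability 0.5 conditional on a crossover, the conversion
tract (Gaussian length, mean 500 bp, σ = mean/5) centered at the
breakpoint is copied from the homolog of the hot-allele (DSB-initiating)
haplotype into the transmitted gamete, so a covered heterozygous causal
SNP is transmitted cold.  Among recombinant gametes of heterozygous
parents the cold-allele fraction is 0.5 + 0.5·p_BGC·P(tract covers SNP) —
75% under the default settings, verified to binomial precision in the
acceptance suite.

Neutral sites follow the infinite-site model: Poisson(μ) new sites per
haplotype per generation at fresh integer positions, fixed or lost sites
removed.  The founder population carries standing variation: `init_sites`
sites with frequencies drawn from the neutral 1/f spectrum, assigned
independently (linkage disequilibrium then accrues during the run).  The
defaults μ = 0.03 per haplotype per generation and `init_sites` = 300
were calibrated once so that a 90-individual sample of the desk-scale run
(1,000 diploids, 500 generations) carries ~150–300 sites with MAF ≥ 0.05.
The hot-allele frequency follows a linear trajectory between configured
endpoints ("cooling" from 1.0, "heating" from 0.0), enforced by
reject-sampling whole offspring generations into a band of ±0.02 around
the interpolant (budget 200 attempts per generation); the derived allele
is (re-)introduced by a mutation event whenever the trajectory requires
it.  Optional recurrent mutation flips the causal allele at 10× the
per-site background rate.  Exported panels keep sites with sample
MAF ≥ 0.05 (rare alleles carry no usable pairwise-LD signal) plus the
annotated causal SNP; samples whose causal MAF < 0.3 are flagged and
excluded from evaluation.

What the generator does *not* emulate: population growth or structure,
gene conversion outside crossovers, interference beyond the one-crossover
cap, mutation-rate heterogeneity, and genotyping/phasing error.  Passing
benchmarks therefore demonstrate internal consistency of the method under
its own model assumptions, not performance on real cohort data.

## Evaluation and enrichment

Direction accuracy: a simulated sample is scored correct when the
hot-allele subpopulation's estimated strength strictly exceeds the
cold-allele one (ties count as wrong), evaluated at hotspot calls matched
to the true center within 25 kb; unmatched or flagged samples are not
evaluated.  On the desk-scale benchmark (10 populations × 5 samples of
90 individuals, cooling to 0.5) the pipeline recovers the direction in
essentially all evaluated samples.  Confusion metrics de-duplicate linked
SNPs into greedy LD blocks (r² ≥ 0.8, ldSelect-style maximal bins; ties
to the smallest index): one tag per block (the causal SNP if a member,
else the min-p member), positive iff p < 0.05, true iff causal;
sensitivity TP/(TP+FN), specificity TN/(TN+FP), PPV TP/(TP+FP), with
zero-denominator ratios reported as absent rather than zero.

Enrichment analysis selects candidate tags (q ≤ 0.01) and distance-matched
control tags (q > 0.5, up to two control blocks per candidate block,
matched on block-center-to-hotspot-center distance), extends SNPs to
fixed-width windows (0-based half-open; an even-width window places the
SNP one base right of center, a documented convention), counts windows
sharing ≥ 1 bp with a feature track, and tests candidate enrichment with
a one-sided Fisher exact test.  A derived-allele tabulation
cross-classifies pairs by q-value and hotspot distance into derived-cold
versus derived-hot counts (derived allele's side strictly smaller →
cold), skipping and tallying SNPs with unknown ancestral state.

## Numerical and procedural choices

* EM runs 30 iterations (20 in the test suite) or to relative
  log-likelihood change < 1e-6; expected switch counts use the
  exponential-clock correction c/(1−e^(−c)).
* Peak fits sample the step-function map at 256 points; `curve_fit`
  with non-negative amplitude and σ ∈ (1 bp, 50 kb).
* Ties: frequent allele on an even split is allele 0; min-p tag ties
  break to the smallest SNP index; strength ties count against the
  method in direction accuracy.
* All randomness flows from explicit integer seeds (estimator orderings,
  splits, simulator); scans are reproducible bit-for-bit from
  (panel, configs, seed).
* Problem sizes in the shipped tests and acceptance script (populations
  of 300–1,000 diploids, 200–500 generations, panels of 25–90
  individuals, 10–200 permutations) are the package's desk-scale
  benchmark conditions; the code paths are the same at full scale.

## Known limitations

* The PAC scale bias makes the 1 cM/Mb filter nominal under the built-in
  estimator; calibrated external rate maps restore its literal meaning.
* Permutation nulls are cached per (hotspot, split size); with the
  size-matched default this costs 200 re-estimations per distinct
  candidate minor-allele count and hotspot — the dominant runtime.
* Single-pair retests cannot be MAF-standardized (a bin needs ≥ 2 SNPs)
  and fall back to the raw-|Δρ| comparison.
* Trio-phased or imputed panels violate the complete-phase assumption;
  loading rejects missing or unphased genotypes outright.
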