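# Methods

## Model and notation

A genome of total length L is partitioned into G_b windows of equal
length b (last window per chromosome truncated). N_ch(w) and N_in(w) are
the ChIP and Input read counts in window w; N_ch, N_in are the library
totals and N_tot = N_ch + N_in. A fraction π₀ of ChIP reads is
background; the normalization constant is r = π₀·N_ch/N_in, the ratio of
background reads in ChIP to reads in Input. Over any set W₀ of pure
background windows, r ≈ Σ_{W₀} N_ch(w) / Σ_{W₀} N_in(w) — every
estimator in this package is that ratio for a particular choice of Ŵ₀.

Read preprocessing follows common practice: at most a fixed number of
reads is retained per starting position (default 2; strand-aware by
default, switchable) to remove PCR amplification artefacts, and read
starts may optionally be shifted 3'-wards by half the mean fragment
length (default off — it helps sharp signals but is not required for
normalization). Coordinates are BED: 0-based, half-open; a read belongs
to window floor(start/b).

## The estimators

**Fixed threshold (CisGenome-style).** Ŵ₀ = {w : N_tot(w) ≤ t} at
b = 100 bp, t = 1. Simple, but t does not scale with sequencing depth.

**Adaptive (NCIS-style).** For each b in
{100, 200, 500, 1000, 2000, 5000, 10000, 20000} bp, candidate thresholds
are the distinct observed totals in ascending order; t* is the smallest
candidate whose r̂ is at least the r̂ at the previous candidate
("previous" means previous *candidate*, not t−1 arithmetically, since
the candidate set is the observed totals) and whose background set covers
at least f·G_b windows (f = 0.75 default; 0.5 supported). Across the
grid, b* is the smallest size whose r̂ is strictly below every smaller
size's and at most the next larger size's. Two boundary conventions make
the rule total: the smallest size vacuously passes the "below all
smaller" test and the largest size vacuously passes the "at most the
next" test (hence single-size grids work). If no size qualifies, the
global minimum over the grid is returned with a flag.

**Strand-symmetry iteration (CCAT-style).** r̂⁰ = N_ch/N_in; then
Ŵ₀ʲ = {w : N⁺_ch(w) < r̂^{j−1}·N⁺_in(w)} (strict inequality, at
b = 1000 bp) and r̂ʲ = Σ_{Ŵ₀ʲ} N⁻_ch / Σ_{Ŵ₀ʲ} N⁻_in. Using opposite
strands for selection and estimation avoids selection bias, assuming
background reads are strand-balanced. The stopping rule — relative change
below 1e-4, or an unchanged background set, or 100 iterations (flagged) —
is this package's choice; only "iterate until convergence" is inherent to
the scheme. The iteration is not globally convergent: on adversarial
fixtures the background set can empty out, which is reported as an
estimation failure carrying the last valid r̂.

π₀ = r̂·N_in/N_ch is reported unclipped; values above 1 carry a warning
(they indicate an over-estimated r̂, typical for pooled replicate
libraries whose mixture background breaks the single-r model). Pooled
π₀ across replicates is the ChIP-size-weighted mean.

## The diagnostic

Bins are formed per chromosome by closing at the first window where the
running N_tot reaches K (K in 100–1000; several K values should be
inspected); the terminal sub-K bin of each chromosome is dropped and
counted. Bins never span chromosomes. For a background bin the ChIP
count given the total is Binomial(Ñ_tot, r/(r+1)); the sample logit of
that proportion is exactly the log relative risk log(Ñ_ch/Ñ_in), with
approximate mean log r and sd (r+1)/√(Ñ_tot·r). Natural logarithms
throughout. Bins with a zero count are excluded from densities (an
optional +0.5 pseudocount exists for exploration but is off by default
because the normal approximation assumes positive counts).

Quartile sub-densities: bin lengths (windows per bin) are split at their
sample quartiles (linear interpolation between order statistics, the
common statistical-environment default); Q1 = shortest (signal-rich),
Q4 = longest (background-rich). Each sub-density is normalized within
its own subset — peak positions, not masses, are what the diagnostic
compares. All-equal lengths collapse every bin into Q1 under the ≤ rule
and are flagged as degenerate.

Densities use a Gaussian kernel with the classic Silverman rule-of-thumb
bandwidth 0.9·min(sd, IQR/1.34)·n^(−1/5) per curve, evaluated on one
shared 512-point grid spanning the data ± 3 bandwidths; near-degenerate
samples fall back to a small fixed bandwidth. Modes are located by grid
argmax. Identical inputs give bit-identical density tables.

Over-dispersion widens the background peak (sd grows like 1/√p for
variance inflation 1/p) and biases the mean slightly downward, but the
peak stays near log r, so the diagnostic applies to negative-binomial-like
data as well; the package's simulations verify both effects. The
diagnostic deliberately does *not* output an estimate of r from the peak:
the peak is broad and K-dependent, so such an estimate would be unstable.

## FDR by swapping

Each bin gets an original score g(Ñ_ch, Ñ_in, r) and a swapped score
g(Ñ_in, Ñ_ch, 1/r); S is the set where the swapped score wins (ties
included), S^c the rest. With G = max(orig, swap), bins are ranked by G
descending and k̂ is the largest cut where
(1 + #{S among top k}) / max(#{S^c among top k}, 1) ≤ q; the S^c bins
among the top k̂ are declared. Validity needs the null scores i.i.d. with
P(swap < orig | G) ≤ 1/2 — satisfied when null bins are exchangeable
under swapping, e.g. ChIP ~ Poisson(r·μ), Input ~ Poisson(μ).

Numerical choices: ties in G are sorted S^c-before-S by bin id, and a
run of tied G values is never split by the cut — this makes the rank
form and the score-threshold form (declare S^c bins with score ≥ T)
select identical sets even for discrete scores, which a naive "largest
k" reading does not guarantee. No qualifying cut means zero discoveries,
not an error. When only scores above a cut-off A are available, the
global ratio over the supplied bins is tried first (declaring all S^c
bins if it passes) before falling back to the ranked scan; the cut-off
can only cost power, not validity.

The default score is the Poisson upper tail −log P(X ≥ chip) with
X ~ Poisson(r·(input + 0.5)); the +0.5 keeps the rate positive at zero
Input. Any user score strictly decreasing in r may replace it — the
direction matters because an over-estimated r shrinks scores and the
discovery set (conservative), while an under-estimated r inflates both
and voids the guarantee. Whether scores exported from an external peak
caller satisfy the null-symmetry condition is the user's responsibility.

## Simulators

**NB bin pairs** (`simulate_nb_bins`): chip/input with means rK/(1+r)
and K/(1+r), variance mean/p via NB(size = μp/(1−p), prob = p); p = 1
short-circuits to exact Poisson draws. Defaults K = 500, r = 0.7 match
the bin-moment validation below.

**Background reads** (`synthetic_background`): per-window Poisson or
Gamma-mixed Poisson counts (variance/mean = overdispersion), uniform
positions within windows, random strands. This is a synthetic stand-in
for a deeply sequenced control library; it reproduces the count
statistics but not sequence-driven coverage structure (mappability, GC),
so estimator recovery here demonstrates correctness of the algorithms,
not robustness to those real-data biases.

**Read-add** (`read_add_simulate`): random read-wise half split,
independent 1/d Bernoulli subsampling of each half, then
Poisson(enrich_rate) extra reads per 100 bp window inside n_regions
non-overlapping regions (lengths uniform on 2–10 kb) added to the ChIP
half. "Average increase of 0.2 reads" is interpreted per 100 bp window
and exposed as a parameter. True r = 1 exactly.

**By-genes** (`by_genes_simulate`): Input ~ Multinomial(N, p_in) over
100 bp windows with p_in taken from an empirical control profile; ChIP ~
Multinomial(N, p_ch) with p_ch(w) = λ_w·p_in(w)/(f₀ + λ(1−f₀)), λ_w = λ
inside n_enriched non-overlapping gene bodies (chosen greedily in random
order from a possibly overlapping annotation) and 1 elsewhere. With
background mass f₀, true r = 1/(f₀ + λ(1−f₀)) = 1/(2−f₀) at λ = 2.
Synthetic gene annotations use log-normal lengths (median 1 kb, mean
5 kb); a real annotation can be supplied instead.

All generators take a seed and are bit-reproducible; the CLI derives
per-component substreams from one master seed.

## Validation quantities and problem sizes

`scripts/acceptance.py` recomputes, at sizes chosen to keep the whole run
under a minute while leaving Monte-Carlo error far below the quantities'
scale:

* closed forms log 0.7 = −0.3567 and (1+0.7)/√(500·0.7) = 0.0909;
* mean/sd of the bin log relative risk at K = 500, r = 0.7 from 10⁶
  simulated pairs for p ∈ {1, 0.5, 0.25} (MC standard error < 1e-4 on
  the mean);
* NCIS recovery of r = 1 on read-add data: five simulations of 10⁶
  background reads on a 12 Mb, 16-chromosome genome (yeast-scale),
  d = 2, 50 spiked regions;
* empirical FDR of the swap selection at q = 0.05: 2,000 replicates of
  5,000 bins, 95% null (r = 0.7, μ = 150) and 5% enriched at 2-fold.
  The observed FDR is well below nominal — the +1 in the numerator and
  the discreteness of Poisson scores both add slack.

## Known limitations

* Linear (global) normalization only; GC-content and other within-sample
  biases are out of scope.
* The NCIS coverage floor f·G_b is applied genome-wide, not per
  chromosome.
* The CCAT iteration can fail on data violating strand balance; failures
  are explicit errors, not silent results.
* Synthetic backgrounds lack mappability/GC structure (see above), and
  the simulators do not model duplicate reads, so the duplicate-capping
  path is exercised only by unit fixtures.
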