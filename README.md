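# chipdiag

Diagnostics for ChIP-seq ChIP-vs-Input normalization: estimators of the
linear scale factor *r*, a binning-based diagnostic plot for judging any
candidate estimate, and a swap-based procedure for selecting enriched
regions at a controlled false discovery rate.

## The problem

When a ChIP library is compared against its Input control, the two read
counts must be put on a common scale. The naive choice — the ratio of
library sizes N<sub>ch</sub>/N<sub>in</sub> — is correct only if *every*
ChIP read is background. In reality only a fraction π₀ of ChIP reads is
background, and the right scale factor is

> r = π₀ · N<sub>ch</sub> / N<sub>in</sub>,

the ratio of *background* reads in ChIP versus Input. Estimating r too
high costs power in peak calling; too low inflates false positives. π₀
itself measures antibody specificity. All estimators here work by finding
a set of background windows W₀ and taking
r̂ = Σ<sub>W₀</sub> N<sub>ch</sub>(w) / Σ<sub>W₀</sub> N<sub>in</sub>(w):

* **`cisgenome_estimate`** — W₀ = windows (100 bp) with total count ≤ t,
  t fixed at 1.
* **`ncis_estimate`** — data-adaptive: scans window sizes
  100 bp … 20 kb and all observed total-count thresholds, picking the
  smallest threshold where r̂ stops decreasing (subject to a coverage
  floor) and the smallest window size whose estimate is a local minimum
  over the grid.
* **`ccat_estimate`** — iterative, exploiting the strand symmetry of
  background reads: windows enter W₀ when their plus-strand ChIP count is
  below r̂ times the plus-strand Input count, and r̂ is re-estimated from
  minus-strand counts.

**The diagnostic.** None of the estimators is uniformly best, so the
package's centrepiece is a plot that judges an estimate against the data.
Consecutive windows are agglomerated into *bins* whose combined
ChIP + Input count reaches a target K. For a background bin, the ChIP
count given the bin total is binomial with success probability r/(r+1),
so the bin's log relative risk log(N<sub>ch</sub>/N<sub>in</sub>) is
approximately N(log r, (r+1)²/(K·r)). Background bins therefore pile up
in a peak near log r. Signal bins agglomerate *fewer* windows, so
splitting the density by quartile of bin length isolates the background:
a good estimate of log r sits near the peak of the longest-quartile (Q4)
sub-density.

**FDR by library swapping.** Given any enrichment score g(chip, input, r)
that decreases in r, the swapped score g(input, chip, 1/r) provides an
empirical null. Ranking bins by the larger of the two scores and walking
down until (1 + #swap-wins) / #original-wins exceeds q yields a discovery
set whose FDR is controlled at q — provided r is not under-estimated,
which is exactly what the diagnostic guards against.

## Worked example

Everything below is synthetic and seeded, so it reproduces exactly. The
read-add scheme splits one background library into two exchangeable
halves and spikes extra reads into 50 random regions of the "ChIP" half —
so the true r is exactly 1 by construction:

```python
import chipdiag as cd

genome = cd.compact_genome()                       # 12 Mb, 16 chromosomes
background = cd.synthetic_background(genome, mean_reads_per_window=8.3, seed=0)
chip, inp, truth = cd.read_add_simulate(background, genome, d=2,
                                        enrich_rate=1.0, seed=1)

est = cd.ncis_estimate(chip, inp, genome)
counts = cd.count_windows(chip, inp, 100, genome)
bins = cd.assign_quartiles(cd.make_bins(counts, K=500))
dens = cd.density_estimates(bins)
scored = cd.swap_partition(bins["chip"], bins["input"], est.r_hat)
sel = cd.fdr_select(scored, q=0.10)
```

prints (via the obvious `print` calls):

```
true r = 1.0, chip reads = 251895, input reads = 248888
NCIS:      r_hat = 1.0061  (b* = 100, t* = 5)
CisGenome: r_hat = 0.9895  pi0 = 0.9777
CCAT:      r_hat = 1.0055  (2 iterations)
bins: 990, mode of Q4 sub-density = -0.0241 (log true r = 0)
FDR 10%: 27 enriched bins, 20 overlap a spiked region
```

All three estimators land within about 1% of the truth; the peak of the
long-bin sub-density sits at log r̂ ≈ 0 as the theory predicts; and the
swap selection recovers mostly spiked regions. `diagnostic_plot(dens,
[("ncis", est.r_hat)], K=500, out="diag.png")` renders the five density
curves with a vertical line at log r̂, and writes the plotted numbers as
a TSV.

The same pipeline is available from the shell:

```sh
chipdiag simulate read-add --seed 1 --genome sizes.tsv --out sim
chipdiag estimate --chip sim.chip.bed --input sim.input.bed \
    --genome sizes.tsv --method all --out est
chipdiag count --chip sim.chip.bed --input sim.input.bed \
    --genome sizes.tsv --window-size 100 --out win
chipdiag plot --counts win.windows.tsv --k 200,500 --estimates ncis=1.006 --out diag
```

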