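"""Synthetic data generators with known normalization truth.

Three complementary schemes, each mirroring a validation experiment for
the normalization diagnostic:

* :func:`simulate_nb_bins` — paired bin counts from negative-binomial
  distributions with fixed rates ``rK/(1+r)`` and ``K/(1+r)`` and
  variances inflated by ``1/p`` (``p = 1`` is exactly Poisson). Used to
  study the distribution of the bin log relative risk with and without
  over-dispersion.
* :func:`read_add_simulate` — split a deeply sequenced background read set
  into two exchangeable halves ("ChIP" and "Input"), subsample each, and
  spike extra reads into the ChIP half at a small number of random
  regions. By construction the true normalization constant is 1.
* :func:`by_genes_simulate` — draw both libraries from multinomial
  distributions over 100 bp windows: the Input from an empirical
  background profile, the ChIP from the same profile with the read
  probability scaled by a fold ``lambda`` inside a set of enriched gene
  bodies. With background probability mass ``f0``, the true constant is
  ``1 / (f0 + lambda * (1 - f0))`` — i.e. ``1 / (2 - f0)`` at the default
  two-fold enrichment.

:func:`synthetic_background` generates the background read set itself (a
stand-in for a deeply sequenced control library, synthetic by design),
with optional Gamma-distributed window-rate heterogeneity to mimic the
non-uniformity of real Input coverage.

All generators are deterministic given their seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .reads_and_windows import GenomeLayout, WindowCounts


@dataclass
class SimTruth:
    """Ground truth attached to a simulated dataset."""

    true_r: float
    scheme: str
    seed: int
    enriched_regions: list[tuple[str, int, int]] = field(default_factory=list)
    f0: float | None = None
    params: dict = field(default_factory=dict)

    def to_json(self) -> dict:
        return {
            "scheme": self.scheme, "seed": self.seed, "true_r": self.true_r,
            "f0": self.f0,
            "enriched_regions": [list(reg) for reg in self.enriched_regions],
            "params": self.params,
        }


def compact_genome(total_length: int = 12_000_000,
                   n_chromosomes: int = 16) -> GenomeLayout:
    """A yeast-scale genome layout for simulation studies.

    Chromosome lengths taper from about twice to half the mean, mimicking
    the spread of a small eukaryotic karyotype; the total is exact.
    """
    raw = np.linspace(2.0, 0.5, n_chromosomes)
    lengths = np.round(raw / raw.sum() * total_length).astype(int)
    lengths[-1] += total_length - lengths.sum()
    return GenomeLayout([(f"chr{i+1}", int(l)) for i, l in enumerate(lengths)])


def swap_fdr_experiment(n_replicates: int = 2000, n_bins: int = 5000,
                        r: float = 0.7, mu: float = 150.0,
                        enriched_fraction: float = 0.05, fold: float = 2.0,
                        q: float = 0.05, seed: int = 0):
    """Measure the empirical FDR of the swap-based selection on null bins.

    Each replicate draws ``n_bins`` independent bins: Input counts
    ``Poisson(mu)`` throughout, ChIP counts ``Poisson(r * mu)`` for null
    bins and ``Poisson(fold * r * mu)`` for the enriched fraction. Bins
    are scored with the default Poisson-tail score at the true r and
    selected at level q; a false discovery is a declared null bin.

    Returns ``(mean_fdp, se, mean_discoveries)`` where ``se`` is the
    Monte-Carlo standard error of the mean false-discovery proportion.
    """
    from scipy import stats

    from .fdr_swap import fdr_select

    rng = np.random.default_rng(seed)
    n_enr = int(round(enriched_fraction * n_bins))
    null = np.ones((n_replicates, n_bins), dtype=bool)
    null[:, :n_enr] = False
    chip = rng.poisson(np.where(null, r * mu, fold * r * mu))
    inp = rng.poisson(mu, size=(n_replicates, n_bins))
    orig = -stats.poisson.logsf(chip - 1, r * (inp + 0.5))
    swap = -stats.poisson.logsf(inp - 1, (1.0 / r) * (chip + 0.5))
    in_s = swap >= orig
    G = np.maximum(orig, swap)
    bin_ids = np.arange(n_bins)
    fdps = np.empty(n_replicates)
    n_disc = np.empty(n_replicates)
    for i in range(n_replicates):
        scored = pd.DataFrame({"bin_id": bin_ids, "score_orig": orig[i],
                               "score_swap": swap[i], "in_S": in_s[i],
                               "G": G[i]})
        res = fdr_select(scored, q)
        n_disc[i] = res.n_discoveries
        fdps[i] = (null[i][res.discoveries].sum() / res.n_discoveries
                   if res.n_discoveries else 0.0)
    se = float(fdps.std(ddof=1) / np.sqrt(n_replicates))
    return float(fdps.mean()), se, float(n_disc.mean())


def simulate_nb_bins(K: float = 500, r: float = 0.7, p: float = 1.0,
                     n: int = 10000, seed: int = 0):
    """Paired (chip, input) bin counts with over-dispersion 1/p.

    Means are ``rK/(1+r)`` and ``K/(1+r)``; variances are mean divided by
    p. For ``p < 1`` the counts are negative binomial with size
    ``mu*p/(1-p)`` (success probability p); ``p = 1`` draws exact Poisson.

    Returns ``(chip, input, SimTruth)``.
    """
    if K <= 0 or r <= 0 or n <= 0 or not 0 < p <= 1:
        raise ValueError("require K, r, n > 0 and p in (0, 1]")
    rng = np.random.default_rng(seed)
    mu_ch = r * K / (1 + r)
    mu_in = K / (1 + r)
    if p == 1:
        chip = rng.poisson(mu_ch, size=n)
        inp = rng.poisson(mu_in, size=n)
    else:
        # NB with mean mu and variance mu/p: size = mu*p/(1-p), prob = p
        chip = rng.negative_binomial(mu_ch * p / (1 - p), p, size=n)
        inp = rng.negative_binomial(mu_in * p / (1 - p), p, size=n)
    truth = SimTruth(true_r=r, scheme="nb_bins", seed=seed,
                     params={"K": K, "p": p, "n": n})
    return chip.astype(np.int64), inp.astype(np.int64), truth


def logratio_summary(chip, input) -> tuple[float, float, int]:
    """Mean and sd of the natural-log count ratio, dropping zero pairs.

    Returns ``(mean, sd, n_dropped)``; sd uses the n-1 denominator.
    """
    chip = np.asarray(chip, dtype=float)
    inp = np.asarray(input, dtype=float)
    if chip.shape != inp.shape:
        raise ValueError("chip and input arrays must have equal length")
    ok = (chip > 0) & (inp > 0)
    if not ok.any():
        raise ValueError("all pairs contain a zero count")
    lr = np.log(chip[ok] / inp[ok])
    sd = float(np.std(lr, ddof=1)) if len(lr) > 1 else 0.0
    return float(lr.mean()), sd, int((~ok).sum())


def synthetic_background(genome: GenomeLayout, mean_reads_per_window: float,
                         window_size: int = 100, overdispersion: float = 1.0,
                         seed: int = 0) -> pd.DataFrame:
    """Generate a background read set over the genome (synthetic control).

    Window counts are Poisson with a common rate (``overdispersion = 1``)
    or Gamma-mixed Poisson with variance/mean equal to ``overdispersion``;
    read starts are uniform within their window, strands are assigned at
    random with equal probability.
    """
    if mean_reads_per_window <= 0 or overdispersion < 1:
        raise ValueError("mean must be positive and overdispersion >= 1")
    rng = np.random.default_rng(seed)
    frames = []
    for name, length in genome.chromosomes:
        nw = -(-length // window_size)
        if overdispersion == 1:
            counts = rng.poisson(mean_reads_per_window, size=nw)
        else:
            shape = mean_reads_per_window / (overdispersion - 1)
            rates = rng.gamma(shape, overdispersion - 1, size=nw)
            counts = rng.poisson(rates)
        win_starts = np.repeat(np.arange(nw, dtype=np.int64) * window_size, counts)
        win_len = np.repeat(
            np.minimum(window_size, length - np.arange(nw) * window_size), counts)
        starts = win_starts + rng.integers(0, win_len)
        frames.append(pd.DataFrame({
            "chrom": name, "start": starts,
            "strand": rng.choice(np.array(["+", "-"]), size=len(starts)),
        }))
    return pd.concat(frames, ignore_index=True)


def _place_regions(genome: GenomeLayout, n_regions: int, length_range, rng,
                   max_tries: int = 1000) -> list[tuple[str, int, int]]:
    """Place non-overlapping random regions; rejection sampling."""
    names = genome.names
    lengths = genome.lengths
    weights = np.array([lengths[n] for n in names], dtype=float)
    weights /= weights.sum()
    placed: dict[str, list[tuple[int, int]]] = {n: [] for n in names}
    regions = []
    for _ in range(n_regions):
        for _try in range(max_tries):
            chrom = names[rng.choice(len(names), p=weights)]
            span = int(rng.integers(length_range[0], length_range[1] + 1))
            if span >= lengths[chrom]:
                continue
            start = int(rng.integers(0, lengths[chrom] - span))
            end = start + span
            if all(end <= s or start >= e for s, e in placed[chrom]):
                placed[chrom].append((start, end))
                regions.append((chrom, start, end))
                break
        else:
            raise RuntimeError(
                f"could not place {n_regions} non-overlapping regions"
            )
    return regions


def read_add_simulate(background: pd.DataFrame, genome: GenomeLayout,
                      d: float = 2, n_regions: int = 50,
                      region_length_range: tuple[int, int] = (2000, 10000),
                      enrich_rate: float = 0.2, seed: int = 0):
    """Split-subsample-and-spike scheme; true normalization constant 1.

    The background reads are split read-wise at random into a "ChIP" and an
    "Input" half; each half is independently subsampled to ``1/d`` of its
    size. Extra reads are then added to the ChIP half: inside each of
    ``n_regions`` non-overlapping random regions (lengths uniform over
    ``region_length_range``), each 100 bp window receives
    ``Poisson(enrich_rate)`` additional reads at uniform positions. The
    two halves are exchangeable outside the spiked regions, so the true
    value of r is exactly 1.

    Returns ``(chip_reads, input_reads, SimTruth)``.
    """
    if len(background) == 0:
        raise ValueError("background read set is empty")
    if d < 1:
        raise ValueError("down-sampling factor d must be >= 1")
    rng = np.random.default_rng(seed)
    n = len(background)
    perm = rng.permutation(n)
    half = n // 2
    chip_idx, input_idx = perm[:half], perm[half:]
    keep_ch = chip_idx[rng.random(len(chip_idx)) < 1.0 / d]
    keep_in = input_idx[rng.random(len(input_idx)) < 1.0 / d]
    chip = background.iloc[np.sort(keep_ch)].reset_index(drop=True)
    inp = background.iloc[np.sort(keep_in)].reset_index(drop=True)

    regions = _place_regions(genome, n_regions, region_length_range, rng)
    added = []
    for chrom, start, end in regions:
        win_starts = np.arange(start, end, 100, dtype=np.int64)
        win_len = np.minimum(100, end - win_starts)
        counts = rng.poisson(enrich_rate, size=len(win_starts))
        pos = np.repeat(win_starts, counts) + rng.integers(
            0, np.repeat(win_len, counts))
        added.append(pd.DataFrame({
            "chrom": chrom, "start": pos,
            "strand": rng.choice(np.array(["+", "-"]), size=len(pos)),
        }))
    if added:
        chip = pd.concat([chip, *added], ignore_index=True)
    truth = SimTruth(true_r=1.0, scheme="read_add", seed=seed,
                     enriched_regions=regions,
                     params={"d": d, "n_regions": n_regions,
                             "enrich_rate": enrich_rate})
    return chip, inp, truth


def synthetic_gene_intervals(genome: GenomeLayout, n: int = 3000,
                             median_length: float = 1000.0,
                             mean_length: float = 5000.0,
                             seed: int = 0) -> list[tuple[str, int, int]]:
    """Random gene-body-like intervals with log-normal lengths.

    Lengths are log-normal with the given median and mean (defaults mimic
    a compact genome annotation: median 1 kb, mean 5 kb); positions are
    uniform and intervals may overlap, as real gene annotations do.
    """
    rng = np.random.default_rng(seed)
    mu = np.log(median_length)
    sigma = np.sqrt(2 * np.log(mean_length / median_length))
    lengths_map = genome.lengths
    names = genome.names
    weights = np.array([lengths_map[c] for c in names], dtype=float)
    weights /= weights.sum()
    out = []
    for _ in range(n):
        chrom = names[rng.choice(len(names), p=weights)]
        span = max(100, int(rng.lognormal(mu, sigma)))
        span = min(span, lengths_map[chrom] - 1)
        start = int(rng.integers(0, lengths_map[chrom] - span))
        out.append((chrom, start, start + span))
    return out


def control_profile(reads: pd.DataFrame, genome: GenomeLayout,
                    window_size: int = 100,
                    pseudocount: float = 0.5) -> np.ndarray:
    """Empirical per-window read probabilities from a control read set."""
    offsets = genome.window_offsets(window_size)
    n = genome.n_windows(window_size)
    chrom_offset = reads["chrom"].map(offsets).to_numpy(np.int64)
    idx = chrom_offset + reads["start"].to_numpy(np.int64) // window_size
    counts = np.bincount(idx, minlength=n).astype(float) + pseudocount
    return counts / counts.sum()


def by_genes_simulate(gene_intervals: list[tuple[str, int, int]],
                      profile: np.ndarray, genome: GenomeLayout,
                      n_enriched: int = 300, fold: float = 2.0,
                      n_reads: int = 500000, window_size: int = 100,
                      seed: int = 0):
    """Multinomial scheme with gene-body enrichment; r = 1/(f0 + fold(1-f0)).

    ``n_enriched`` non-overlapping gene bodies are chosen at random from
    ``gene_intervals`` and marked enriched. Input counts are multinomial
    over the window grid with probabilities ``profile``; ChIP counts are
    multinomial with the probability of every window inside an enriched
    gene multiplied by ``fold`` (then renormalized). Both libraries have
    exactly ``n_reads`` reads. The recorded truth is
    ``1 / (f0 + fold * (1 - f0))`` where ``f0`` is the background
    probability mass — ``1 / (2 - f0)`` at the default fold of 2.

    Returns ``(WindowCounts, SimTruth)``.
    """
    profile = np.asarray(profile, dtype=float)
    n_windows = genome.n_windows(window_size)
    if len(profile) != n_windows:
        raise ValueError("profile length must equal the number of windows")
    if not np.isclose(profile.sum(), 1.0):
        raise ValueError("profile must sum to 1")
    if fold <= 0:
        raise ValueError("fold must be positive")
    rng = np.random.default_rng(seed)

    order = rng.permutation(len(gene_intervals))
    chosen: list[tuple[str, int, int]] = []
    occupied: dict[str, list[tuple[int, int]]] = {}
    for i in order:
        if len(chosen) >= n_enriched:
            break
        chrom, start, end = gene_intervals[i]
        spans = occupied.setdefault(chrom, [])
        if all(end <= s or start >= e for s, e in spans):
            spans.append((start, end))
            chosen.append((chrom, start, end))
    if len(chosen) < n_enriched:
        raise RuntimeError(
            f"only {len(chosen)} non-overlapping gene bodies available, "
            f"{n_enriched} requested"
        )

    offsets = genome.window_offsets(window_size)
    enriched = np.zeros(n_windows, dtype=bool)
    for chrom, start, end in chosen:
        lo = offsets[chrom] + start // window_size
        hi = offsets[chrom] + (end - 1) // window_size
        enriched[lo:hi + 1] = True

    f0 = float(profile[~enriched].sum())
    lam = np.where(enriched, fold, 1.0)
    p_ch = lam * profile / (f0 + fold * (1 - f0))
    p_ch = p_ch / p_ch.sum()  # guard rounding of the analytic normalizer

    inp = rng.multinomial(n_reads, profile)
    chip = rng.multinomial(n_reads, p_ch)
    counts = WindowCounts(genome, window_size, chip.astype(np.int64),
                          inp.astype(np.int64))
    truth = SimTruth(true_r=1.0 / (f0 + fold * (1 - f0)), scheme="by_genes",
                     seed=seed, enriched_regions=chosen, f0=f0,
                     params={"fold": fold, "N": n_reads,
                             "n_enriched": n_enriched})
    return counts, truth
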