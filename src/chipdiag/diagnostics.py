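"""Equal-total-count bins, log relative risks, and the diagnostic plot.

The diagnostic works on *bins*: runs of consecutive windows agglomerated
until the combined ChIP + Input count reaches a target K. For a background
bin the conditional distribution of the ChIP count given the bin total is
binomial with success probability r/(r+1), so the bin's log relative risk
``log(N_ch / N_in)`` is approximately normal with mean ``log r`` and
standard deviation ``(r+1)/sqrt(N_tot * r)``. Because all bins share
(approximately) the same total K, background bins contribute a common peak
near ``log r`` to the density of log relative risks — which is what the
diagnostic plot displays, alongside the candidate estimates of ``log r``.

Bins containing signal agglomerate fewer windows (their windows are read
dense), so splitting the density by quartile of bin length separates
signal-dominated short bins (Q1) from background-dominated long bins (Q4):
an adequate estimate of log r should sit near the peak of the Q4 curve.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .reads_and_windows import WindowCounts

BIN_COLUMNS = ["chrom", "first_window", "last_window", "length",
               "chip", "input", "total", "log_rr"]
QUARTILE_ORDER = ["all", "q4", "q3", "q2", "q1"]


def make_bins(counts: WindowCounts, K: int = 200,
              pseudocount: float = 0.0) -> pd.DataFrame:
    """Agglomerate consecutive windows into bins of total count ~ K.

    Within each chromosome, windows are scanned in genomic order and a bin
    closes at the first window where the running ChIP + Input total reaches
    K. Bins never span chromosomes; the terminal partial bin of each
    chromosome (running total < K) is dropped and counted in
    ``result.attrs['n_dropped_terminal']``.

    ``log_rr`` is the natural log of the ChIP/Input ratio; with the default
    ``pseudocount=0`` it is NaN for bins with a zero count (such bins are
    excluded from the densities), otherwise ``(chip+pc)/(input+pc)`` is used.
    """
    if K < 1:
        raise ValueError("K must be >= 1")
    offsets = counts.genome.window_offsets(counts.window_size)
    total = counts.total
    rows = []
    n_dropped = 0
    for name, length in counts.genome.chromosomes:
        off = offsets[name]
        nw = -(-length // counts.window_size)
        cum = np.cumsum(total[off:off + nw])
        lo = 0  # first window of the open bin (chromosome-local)
        base = 0.0  # cumulative total before the open bin
        while lo < nw:
            hi = int(np.searchsorted(cum, base + K, side="left"))
            if hi >= nw:
                n_dropped += 1  # trailing windows with running total < K
                break
            rows.append((name, off + lo, off + hi))
            lo, base = hi + 1, float(cum[hi])
    if not rows:
        raise ValueError(
            f"no complete bin formed at K={K}; too few reads — try a smaller K"
        )
    first = np.array([r[1] for r in rows])
    last = np.array([r[2] for r in rows])
    # sum counts per bin via cumulative sums over the flat window grid
    cum_chip = np.concatenate([[0], np.cumsum(counts.chip)])
    cum_input = np.concatenate([[0], np.cumsum(counts.input)])
    chip = cum_chip[last + 1] - cum_chip[first]
    inp = cum_input[last + 1] - cum_input[first]
    bins = pd.DataFrame({
        "chrom": [r[0] for r in rows],
        "first_window": first,
        "last_window": last,
        "length": last - first + 1,
        "chip": chip,
        "input": inp,
        "total": chip + inp,
    })
    with np.errstate(divide="ignore", invalid="ignore"):
        if pseudocount > 0:
            bins["log_rr"] = np.log((chip + pseudocount) / (inp + pseudocount))
        else:
            lr = np.log(chip.astype(float)) - np.log(inp.astype(float))
            bins["log_rr"] = np.where((chip > 0) & (inp > 0), lr, np.nan)
    bins.attrs["K"] = int(K)
    bins.attrs["n_dropped_terminal"] = int(n_dropped)
    return bins


def assign_quartiles(bins: pd.DataFrame) -> pd.DataFrame:
    """Label each bin by the quartile of the bin-length distribution.

    Sample quartiles use linear interpolation between order statistics.
    Labels: Q1 for length <= first quartile, Q2 up to the median, Q3 up to
    the third quartile, Q4 above it. When the breaks collapse (many tied
    lengths) the result is flagged in ``attrs['degenerate_quartiles']``.
    """
    if len(bins) < 4:
        raise ValueError("need at least 4 bins to form length quartiles")
    lengths = bins["length"].to_numpy(float)
    q1, q2, q3 = np.quantile(lengths, [0.25, 0.5, 0.75])
    out = bins.copy()
    out["quartile"] = np.select(
        [lengths <= q1, lengths <= q2, lengths <= q3],
        ["Q1", "Q2", "Q3"], default="Q4",
    )
    out.attrs.update(bins.attrs)
    out.attrs["length_quartiles"] = (float(q1), float(q2), float(q3))
    out.attrs["degenerate_quartiles"] = bool(q1 == q3)
    return out


def logit_sd(r: float, n_tot: float) -> float:
    """Approximate sd of a background bin's log relative risk.

    Under the Poisson model the conditional ChIP count is binomial with
    success probability r/(r+1); the sample logit of that proportion equals
    the log relative risk, has approximate mean ``log r`` and standard
    deviation ``(r+1)/sqrt(n_tot * r)``.
    """
    if r <= 0 or n_tot <= 0:
        raise ValueError("r and n_tot must be positive")
    return (r + 1) / np.sqrt(n_tot * r)


@dataclass
class DensitySet:
    """Kernel density estimates of log relative risks on a shared grid.

    ``densities`` maps curve names (``all``, ``q1`` .. ``q4``) to arrays on
    ``grid``; each curve is normalized within its own subset of bins.
    Quartile curves with fewer than two finite values are absent.
    """

    grid: np.ndarray
    densities: dict[str, np.ndarray]
    bandwidths: dict[str, float]
    n_bins_used: int
    n_bins_excluded: int

    def mode(self, curve: str = "all") -> float:
        """Location of the curve's maximum (grid argmax)."""
        return float(self.grid[np.argmax(self.densities[curve])])

    def to_frame(self) -> pd.DataFrame:
        frame = pd.DataFrame({"log_rr": self.grid})
        for name in QUARTILE_ORDER:
            frame[name] = self.densities.get(name, np.full_like(self.grid, np.nan))
        return frame


def _silverman_bandwidth(x: np.ndarray) -> float:
    """0.9 * min(sd, IQR/1.34) * n^(-1/5); guarded for near-degenerate data."""
    sd = np.std(x, ddof=1)
    iqr = np.subtract(*np.percentile(x, [75, 25]))
    scale = min(sd, iqr / 1.34) if iqr > 0 else sd
    if scale <= 0:
        scale = max(abs(float(np.mean(x))), 1.0) * 1e-3
    return 0.9 * scale * len(x) ** (-0.2)


def _gaussian_kde(x: np.ndarray, grid: np.ndarray, h: float) -> np.ndarray:
    z = (grid[:, None] - x[None, :]) / h
    return np.exp(-0.5 * z * z).sum(axis=1) / (len(x) * h * np.sqrt(2 * np.pi))


def density_estimates(bins: pd.DataFrame, gridsize: int = 512) -> DensitySet:
    """Estimate the overall and per-quartile densities of log relative risk.

    Gaussian kernel with Silverman's rule-of-thumb bandwidth per curve, all
    curves evaluated on one shared grid spanning the data plus three
    bandwidths on each side. Bins with a zero ChIP or Input count (NaN
    ``log_rr``) are excluded and counted.
    """
    if "quartile" not in bins.columns:
        bins = assign_quartiles(bins)
    finite = bins[np.isfinite(bins["log_rr"])]
    n_excluded = len(bins) - len(finite)
    if len(finite) < 2:
        raise ValueError("fewer than two bins with finite log relative risk")
    groups = {"all": finite["log_rr"].to_numpy(float)}
    for q in ("Q1", "Q2", "Q3", "Q4"):
        vals = finite.loc[finite["quartile"] == q, "log_rr"].to_numpy(float)
        if len(vals) >= 2:
            groups[q.lower()] = vals
    bandwidths = {name: _silverman_bandwidth(v) for name, v in groups.items()}
    hmax = max(bandwidths.values())
    x_all = groups["all"]
    grid = np.linspace(x_all.min() - 3 * hmax, x_all.max() + 3 * hmax, gridsize)
    densities = {name: _gaussian_kde(v, grid, bandwidths[name])
                 for name, v in groups.items()}
    return DensitySet(grid=grid, densities=densities, bandwidths=bandwidths,
                      n_bins_used=len(finite), n_bins_excluded=n_excluded)


_CURVE_STYLES = {  # caption order: all, Q4 .. Q1
    "all": dict(color="black", linestyle="-", label="all bins"),
    "q4": dict(color="hotpink", linestyle=(0, (6, 2, 6, 2)), label="Q4 (longest)"),
    "q3": dict(color="royalblue", linestyle="--", label="Q3"),
    "q2": dict(color="forestgreen", linestyle="-.", label="Q2"),
    "q1": dict(color="crimson", linestyle=":", label="Q1 (shortest)"),
}
_ESTIMATE_COLORS = ("saddlebrown", "deeppink", "navy", "gray", "darkorange")


def diagnostic_plot(densities: DensitySet, estimates: list[tuple[str, float]],
                    K: int, out, ax=None) -> pd.DataFrame:
    """Render the diagnostic plot and write its density table.

    Draws the five density curves (all bins plus the four length-quartile
    sub-densities) and a vertical line at ``log r-hat`` for every supplied
    estimate. Alongside the figure (written to ``out``), the density table
    (grid plus five curve columns) is written to ``out`` with a ``.tsv``
    suffix and returned, so the plotted numbers are testable.
    """
    import matplotlib
    if matplotlib.get_backend().lower() not in ("agg", "module://matplotlib_inline.backend_inline"):
        matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    for label, r_hat in estimates:
        if r_hat <= 0:
            raise ValueError(f"estimate {label!r} must be positive, got {r_hat}")

    own_figure = ax is None
    if own_figure:
        fig, ax = plt.subplots(figsize=(7, 5))
    for name in QUARTILE_ORDER:
        if name in densities.densities:
            ax.plot(densities.grid, densities.densities[name], **_CURVE_STYLES[name])
    for (label, r_hat), color in zip(estimates, _ESTIMATE_COLORS * 10):
        ax.axvline(np.log(r_hat), color=color, linewidth=1.2,
                   label=f"{label}: log r = {np.log(r_hat):.3f}")
    ax.set_xlabel("log relative risk  log(N_ch / N_in)")
    ax.set_ylabel("density")
    ax.set_title(f"K = {K}")
    ax.legend(fontsize=8)

    table = densities.to_frame()
    if out is not None:
        if own_figure:
            fig.savefig(out, dpi=150)
            plt.close(fig)
        table.to_csv(f"{out}.tsv", sep="\t", index=False)
    return table


def diagnostic_panels(counts: WindowCounts, Ks: list[int],
                      estimates: list[tuple[str, float]], out) -> dict[int, pd.DataFrame]:
    """One diagnostic panel per K (the recommended multi-K view)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, axes = plt.subplots(1, len(Ks), figsize=(6 * len(Ks), 5), squeeze=False)
    tables = {}
    for ax, K in zip(axes.ravel(), Ks):
        bins = assign_quartiles(make_bins(counts, K=K))
        dens = density_estimates(bins)
        tables[K] = diagnostic_plot(dens, estimates, K, out=None, ax=ax)
    fig.tight_layout()
    fig.savefig(out, dpi=150)
    plt.close(fig)
    for K, table in tables.items():
        table.to_csv(f"{out}.K{K}.tsv", sep="\t", index=False)
    return tables
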