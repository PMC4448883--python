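"""Estimators of the ChIP-vs-Input normalization constant r.

The normalization constant ``r = pi0 * N_ch / N_in`` is the ratio of
background reads in the ChIP sample to reads in the Input sample. All
three estimators implemented here share the same strategy: identify a set
of background windows ``W0`` and estimate r as the ratio of ChIP to Input
reads over that set. They differ in how ``W0`` is chosen:

* ``cisgenome_estimate`` — fixed window size (100 bp) and fixed low-count
  threshold (total count <= 1).
* ``ncis_estimate`` — data-adaptive window size and threshold, scanning a
  grid of window sizes and the observed total-count values.
* ``ccat_estimate`` — iterative scheme using the strand symmetry of
  background reads: membership of ``W0`` is decided on plus-strand counts
  while r is re-estimated on minus-strand counts.

``pi0_from_r`` converts r into the background fraction pi0 of the ChIP
library, and ``pooled_pi0`` combines replicate estimates by a read-count
weighted average.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .reads_and_windows import GenomeLayout, WindowCounts, count_windows

NCIS_WINDOW_GRID = (100, 200, 500, 1000, 2000, 5000, 10000, 20000)


class EstimationError(RuntimeError):
    """The background window set is empty or degenerate; no estimate exists."""


@dataclass
class NormalizationEstimate:
    """An estimated normalization constant with its provenance.

    Attributes
    ----------
    r_hat
        Estimated scale factor r (dimensionless).
    pi0_hat
        Implied background fraction of the ChIP library, r * N_in / N_ch.
    method
        One of ``cisgenome``, ``ncis``, ``ccat``, ``user``.
    params
        Method settings actually used (window size, threshold, ...).
    background_windows
        Boolean mask over the window grid marking the estimated W0, when
        the method produces one.
    trace
        Per-iteration or per-(b, t) record of intermediate estimates.
    flags
        Human-readable warnings (non-convergence, fallbacks, pi0 > 1).
    """

    r_hat: float
    pi0_hat: float | None
    method: str
    params: dict = field(default_factory=dict)
    background_windows: np.ndarray | None = None
    trace: pd.DataFrame | None = None
    flags: list[str] = field(default_factory=list)


def _ratio_over(mask: np.ndarray, counts: WindowCounts) -> float:
    chip = int(counts.chip[mask].sum())
    inp = int(counts.input[mask].sum())
    if inp == 0:
        raise EstimationError(
            "Input read count over the background window set is zero"
        )
    return chip / inp


def cisgenome_estimate(counts: WindowCounts, t: int = 1) -> NormalizationEstimate:
    """Fixed-threshold background estimate (CisGenome-style).

    Windows with total count ``N_tot(w) <= t`` form the background set;
    r is the ratio of ChIP to Input reads over those windows. The default
    ``t=1`` targets 100 bp windows and does not scale with depth.
    """
    mask = counts.total <= int(t)
    if not mask.any():
        raise EstimationError(f"no window has total count <= t={t}")
    r_hat = _ratio_over(mask, counts)
    pi0 = pi0_from_r(r_hat, counts.n_chip, counts.n_input) if counts.n_chip else None
    return NormalizationEstimate(
        r_hat=r_hat, pi0_hat=pi0, method="cisgenome",
        params={"b": counts.window_size, "t": int(t)},
        background_windows=mask,
    )


def _ncis_scan_size(counts: WindowCounts, f: float):
    """Scan thresholds at one window size; return (t*, r*, mask, trace).

    Candidate thresholds are the distinct observed totals in ascending
    order. t* is the smallest candidate whose estimate is >= the estimate
    at the previous candidate (vacuous for the first) and whose background
    set covers at least ``f * G_b`` windows. Returns ``None`` in place of
    (t*, r*, mask) when no candidate qualifies.
    """
    total = counts.total
    order = np.argsort(total, kind="stable")
    sorted_total = total[order]
    cum_chip = np.cumsum(counts.chip[order])
    cum_input = np.cumsum(counts.input[order])

    candidates, last_pos = np.unique(sorted_total, return_index=True)
    # index of the last window with total <= candidate
    last_idx = np.append(last_pos[1:], len(sorted_total)) - 1
    coverage = last_idx + 1
    with np.errstate(divide="ignore", invalid="ignore"):
        r_vals = np.where(cum_input[last_idx] > 0,
                          cum_chip[last_idx] / cum_input[last_idx], np.nan)

    trace = pd.DataFrame({"t": candidates, "r": r_vals, "coverage": coverage})
    need = f * counts.n_windows
    prev_r = np.nan
    for i, (t, r, cov) in enumerate(zip(candidates, r_vals, coverage)):
        nondecreasing = i == 0 or np.isnan(prev_r) or (not np.isnan(r) and r >= prev_r)
        if nondecreasing and cov >= need and not np.isnan(r):
            mask = total <= t
            return int(t), float(r), mask, trace
        prev_r = r
    return None, None, None, trace


def ncis_estimate_from_counts(counts_by_size: Mapping[int, WindowCounts],
                              f: float = 0.75) -> NormalizationEstimate:
    """NCIS-style estimate from precomputed counts at each grid size."""
    if not 0 < f < 1:
        raise ValueError("coverage fraction f must lie in (0, 1)")
    sizes = sorted(counts_by_size)
    per_size: dict[int, dict] = {}
    trace_rows = []
    for b in sizes:
        t_star, r_b, mask, trace = _ncis_scan_size(counts_by_size[b], f)
        if t_star is not None:
            per_size[b] = {"t": t_star, "r": r_b, "mask": mask}
            trace_rows.append({"b": b, "t_star": t_star, "r": r_b})
    if not per_size:
        raise EstimationError("no window size admits a valid threshold t*")

    valid = [b for b in sizes if b in per_size]
    r_of = {b: per_size[b]["r"] for b in valid}
    flags = []
    # b*: smallest size strictly below every smaller size's estimate and at
    # most the next larger size's estimate; boundary conditions vacuous.
    b_star = None
    for i, b in enumerate(valid):
        below_smaller = all(r_of[b] < r_of[bp] for bp in valid[:i])
        at_most_next = i == len(valid) - 1 or r_of[b] <= r_of[valid[i + 1]]
        if below_smaller and at_most_next:
            b_star = b
            break
    if b_star is None:
        b_star = min(valid, key=lambda b: r_of[b])
        flags.append("no window size is a local minimum; "
                     "fell back to the global minimum of r over the grid")

    chosen = per_size[b_star]
    counts = counts_by_size[b_star]
    pi0 = pi0_from_r(chosen["r"], counts.n_chip, counts.n_input)
    est = NormalizationEstimate(
        r_hat=chosen["r"], pi0_hat=pi0, method="ncis",
        params={"b": b_star, "t": chosen["t"], "f": f, "grid": list(sizes)},
        background_windows=chosen["mask"],
        trace=pd.DataFrame(trace_rows),
        flags=flags,
    )
    if pi0 is not None and pi0 > 1:
        est.flags.append(_pi0_warning(pi0))
    return est


def ncis_estimate(chip_reads: pd.DataFrame, input_reads: pd.DataFrame,
                  genome: GenomeLayout,
                  window_grid: Sequence[int] = NCIS_WINDOW_GRID,
                  f: float = 0.75) -> NormalizationEstimate:
    """Data-adaptive estimate of r (NCIS-style).

    Counts both samples at every window size in ``window_grid``, picks a
    data-adaptive threshold t* at each size, and selects the smallest
    window size whose estimate is a local minimum over the grid.
    """
    counts_by_size = {int(b): count_windows(chip_reads, input_reads, int(b), genome)
                      for b in window_grid}
    return ncis_estimate_from_counts(counts_by_size, f=f)


def ccat_estimate(stranded_counts: WindowCounts, tol: float = 1e-4,
                  max_iter: int = 100) -> NormalizationEstimate:
    """Iterative strand-symmetry estimate of r (CCAT-style).

    Starts from the naive ratio ``N_ch / N_in`` and alternates: classify a
    window as background when its plus-strand ChIP count is below r-hat
    times its plus-strand Input count (strict inequality), then re-estimate
    r-hat from minus-strand counts over the background set. Stops when the
    relative change falls below ``tol``, the background set stabilises, or
    ``max_iter`` is reached (flagged).
    """
    c = stranded_counts
    if not c.stranded:
        raise ValueError("ccat_estimate requires strand-split window counts")
    if c.n_input == 0:
        raise EstimationError("Input sample has no reads")
    r = c.n_chip / c.n_input
    trace_rows = [{"iteration": 0, "r": r, "n_background": c.n_windows}]
    prev_mask = None
    flags: list[str] = []
    converged = False
    for j in range(1, max_iter + 1):
        mask = c.chip_plus < r * c.input_plus
        if not mask.any():
            raise EstimationError(
                f"background set empty at iteration {j} (last r = {r:.6g})"
            )
        minus_in = int(c.input_minus[mask].sum())
        if minus_in == 0:
            raise EstimationError(
                f"minus-strand Input count over the background set is zero "
                f"at iteration {j} (last r = {r:.6g})"
            )
        r_new = float(c.chip_minus[mask].sum()) / minus_in
        trace_rows.append({"iteration": j, "r": r_new,
                           "n_background": int(mask.sum())})
        stable_set = prev_mask is not None and np.array_equal(mask, prev_mask)
        small_step = r > 0 and abs(r_new - r) / r < tol
        r, prev_mask = r_new, mask
        if small_step or stable_set:
            converged = True
            break
    if not converged:
        flags.append(f"did not converge within {max_iter} iterations")
    pi0 = pi0_from_r(r, c.n_chip, c.n_input)
    if pi0 > 1:
        flags.append(_pi0_warning(pi0))
    return NormalizationEstimate(
        r_hat=r, pi0_hat=pi0, method="ccat",
        params={"b": c.window_size, "tol": tol, "max_iter": max_iter,
                "iterations": trace_rows[-1]["iteration"]},
        background_windows=prev_mask,
        trace=pd.DataFrame(trace_rows),
        flags=flags,
    )


def _pi0_warning(pi0: float) -> str:
    return (f"pi0 = {pi0:.4f} > 1: more apparent background in ChIP than the "
            "Input depth supports; the estimate of r is likely too large "
            "(common for pooled libraries)")


def pi0_from_r(r_hat: float, n_ch: int, n_in: int) -> float:
    """Background fraction of the ChIP library: pi0 = r * N_in / N_ch.

    Values above 1 are returned as-is with a warning: they indicate an
    over-estimated r rather than a meaningful fraction.
    """
    if n_ch <= 0:
        raise ValueError("ChIP read count must be positive")
    pi0 = r_hat * n_in / n_ch
    if pi0 > 1:
        warnings.warn(_pi0_warning(pi0), stacklevel=2)
    return pi0


def pooled_pi0(pi0_values: Sequence[float], chip_sizes: Sequence[int]) -> float:
    """Read-count weighted average of replicate pi0 estimates.

    The specificity of a pooled library is the mixture of the per-replicate
    specificities weighted by each replicate's share of the pool.
    """
    if len(pi0_values) != len(chip_sizes):
        raise ValueError("pi0_values and chip_sizes must have equal length")
    if not pi0_values:
        raise ValueError("need at least one replicate")
    w = np.asarray(chip_sizes, dtype=float)
    if (w <= 0).any():
        raise ValueError("chip_sizes must be positive")
    return float(np.dot(pi0_values, w) / w.sum())
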