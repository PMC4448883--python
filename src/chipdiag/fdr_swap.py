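"""Peak selection with FDR control by library swapping.

Given an enrichment score ``g(chip, input, r)`` for each bin, the swapped
score ``g(input, chip, 1/r)`` plays the role of an empirical null: for a
background bin, swapping ChIP and Input (and inverting r) leaves the score
distribution essentially unchanged. Bins whose swapped score is at least
their original score form the set S; the remaining bins form S^c and are
the candidates for discovery. Walking down the bins sorted by
``G = max(original, swapped)``, the ratio

    (1 + #S among the top k) / max(#S^c among the top k, 1)

over-estimates the fraction of false candidates, and the largest k keeping
it below the target level q yields the discovery set (the S^c bins among
the top k). Under a symmetry condition on null scores this controls the
FDR at q.

The score ``g`` is pluggable; the only contract is that it decreases in r
for fixed counts (a larger r means more of the ChIP signal is background).
The default is an upper-tail Poisson surprise score.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

SCORED_COLUMNS = ["bin_id", "score_orig", "score_swap", "in_S", "G"]


def default_score(chip, input, r) -> np.ndarray:
    """Upper-tail Poisson surprise: -log P(X >= chip), X ~ Poisson(r*(input+0.5)).

    The +0.5 stabiliser keeps the rate positive for zero Input counts.
    Strictly decreasing in r for fixed counts, as the swap construction
    requires. Vectorized over array inputs.
    """
    chip = np.asarray(chip)
    rate = np.asarray(r, dtype=float) * (np.asarray(input, dtype=float) + 0.5)
    if np.any(rate <= 0):
        raise ValueError("score rate must be positive (r > 0)")
    return -stats.poisson.logsf(chip - 1, rate)


def swap_partition(chip, input, r: float, score=default_score,
                   bin_ids=None) -> pd.DataFrame:
    """Score every bin under the original and swapped libraries.

    Returns a table with ``score_orig = g(chip, input, r)``,
    ``score_swap = g(input, chip, 1/r)``, the S-membership flag
    ``in_S = (score_swap >= score_orig)`` (ties go to S) and
    ``G = max(score_orig, score_swap)``.
    """
    if r <= 0:
        raise ValueError("r must be positive")
    chip = np.asarray(chip)
    input = np.asarray(input)
    orig = np.asarray(score(chip, input, r), dtype=float)
    swap = np.asarray(score(input, chip, 1.0 / r), dtype=float)
    if bin_ids is None:
        bin_ids = np.arange(len(chip))
    return pd.DataFrame({
        "bin_id": bin_ids,
        "score_orig": orig,
        "score_swap": swap,
        "in_S": swap >= orig,
        "G": np.maximum(orig, swap),
    })


@dataclass
class FdrResult:
    """Outcome of the swap-based selection at level q."""

    q: float
    k_hat: int
    threshold_T: float | None
    discoveries: np.ndarray  # bin_ids of declared S^c bins
    cutoff_A: float | None = None
    audit: pd.DataFrame | None = field(default=None, repr=False)

    @property
    def n_discoveries(self) -> int:
        return len(self.discoveries)


def fdr_select(scored: pd.DataFrame, q: float,
               keep_audit: bool = False) -> FdrResult:
    """Select enriched bins at FDR level q from a swap-scored table.

    Bins are sorted by G descending (ties broken S^c before S, then by
    bin_id, and a run of tied G values is never split, so the rank form
    and the score-threshold form select the same set). ``k_hat`` is the
    largest qualifying cut; the discoveries are the S^c bins among the top
    ``k_hat``; ``threshold_T`` is the G value at the cut (None when there
    are no discoveries). When no cut qualifies the result is empty, not an
    error.
    """
    if not 0 < q < 1:
        raise ValueError("q must lie in (0, 1)")
    if len(scored) == 0:
        raise ValueError("no scored bins supplied")
    g = scored["G"].to_numpy(float)
    in_s = scored["in_S"].to_numpy(bool)
    ids = scored["bin_id"].to_numpy()
    order = np.lexsort((ids, in_s, -g))  # G desc, S^c first, stable by id
    g, in_s, ids = g[order], in_s[order], ids[order]

    cum_s = np.cumsum(in_s)
    cum_c = np.arange(1, len(g) + 1) - cum_s
    ratio = (1 + cum_s) / np.maximum(cum_c, 1)
    # candidate cuts: boundaries of tied-G runs (so top-k == {G >= T})
    boundary = np.append(g[:-1] > g[1:], True)
    ok = (ratio <= q) & boundary
    if ok.any():
        k_hat = int(np.nonzero(ok)[0][-1]) + 1
    else:
        k_hat = 0
    discoveries = ids[:k_hat][~in_s[:k_hat]]
    threshold = float(g[k_hat - 1]) if k_hat else None
    audit = None
    if keep_audit:
        audit = pd.DataFrame({"bin_id": ids, "G": g, "in_S": in_s,
                              "rank": np.arange(1, len(g) + 1),
                              "ratio": ratio})
    return FdrResult(q=q, k_hat=k_hat, threshold_T=threshold,
                     discoveries=discoveries, audit=audit)


def fdr_select_with_cutoff(scored: pd.DataFrame, A: float, q: float,
                           keep_audit: bool = False) -> FdrResult:
    """Selection when only scores above a cut-off A are available.

    All supplied bins must have ``G >= A``. If the global ratio
    ``(1 + #S) / max(#S^c, 1)`` over the supplied bins is already <= q,
    every S^c bin is declared; otherwise the ranked selection is applied to
    the supplied list. The cut-off can cost power but never validity.
    """
    if len(scored) == 0:
        raise ValueError("no scored bins above the cut-off")
    if (scored["G"] < A).any():
        raise ValueError("all supplied bins must satisfy G >= A")
    n_s = int(scored["in_S"].sum())
    n_c = len(scored) - n_s
    if (1 + n_s) / max(n_c, 1) <= q:
        ids = scored.loc[~scored["in_S"], "bin_id"].to_numpy()
        g_min = float(scored["G"].min())
        return FdrResult(q=q, k_hat=len(scored), threshold_T=g_min,
                         discoveries=ids, cutoff_A=A)
    result = fdr_select(scored, q, keep_audit=keep_audit)
    result.cutoff_A = A
    return result
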