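"""Equal-count binning, log relative risks and density estimation."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import chipdiag as cd


def brute_force_bins(totals, K):
    """Oracle: linear scan accumulating totals, closing a bin at >= K."""
    bins, start, acc = [], 0, 0
    for i, t in enumerate(totals):
        acc += t
        if acc >= K:
            bins.append((start, i))
            start, acc = i + 1, 0
    return bins


class TestMakeBins:
    def test_boundary_rule_fixture(self):
        counts = cd.WindowCounts.from_arrays([3, 2, 1, 4, 6], [0] * 5)
        bins = cd.make_bins(counts, K=5)
        assert list(bins["length"]) == [2, 2, 1]
        assert list(bins["total"]) == [5, 5, 6]

    def test_exact_K_windows_become_single_window_bins(self):
        counts = cd.WindowCounts.from_arrays([5] * 4, [0] * 4)
        bins = cd.make_bins(counts, K=5)
        assert list(bins["length"]) == [1, 1, 1, 1]

    def test_insufficient_counts_error(self):
        counts = cd.WindowCounts.from_arrays([1, 1, 1], [0, 0, 0])
        with pytest.raises(ValueError, match="smaller K"):
            cd.make_bins(counts, K=5)

    def test_bins_never_span_chromosomes(self):
        genome = cd.GenomeLayout([("chrI", 300), ("chrII", 300)])
        chip = np.array([3, 3, 1, 3, 3, 3])
        counts = cd.WindowCounts(genome, 100, chip, np.zeros(6, dtype=int))
        bins = cd.make_bins(counts, K=5)
        assert all(b <= 2 or a >= 3 for a, b in
                   zip(bins["first_window"], bins["last_window"]))
        # each chromosome's trailing sub-K run is dropped and counted
        assert bins.attrs["n_dropped_terminal"] == 2

    @given(st.lists(st.integers(0, 8), min_size=1, max_size=80),
           st.integers(1, 12))
    @settings(max_examples=100, deadline=None, derandomize=True)
    def test_matches_brute_force_scan(self, totals, K):
        counts = cd.WindowCounts.from_arrays(totals, [0] * len(totals))
        expected = brute_force_bins(totals, K)
        if not expected:
            with pytest.raises(ValueError):
                cd.make_bins(counts, K=K)
            return
        bins = cd.make_bins(counts, K=K)
        got = list(zip(bins["first_window"], bins["last_window"]))
        assert got == expected
        # every emitted bin reaches K but overshoots by less than its max window
        maxw = np.array([max(totals[a:b + 1]) for a, b in got])
        assert ((bins["total"] >= K) & (bins["total"] <= K - 1 + maxw)).all()


class TestAssignQuartiles:
    def test_linear_interpolation_breaks(self):
        bins = pd.DataFrame({"length": np.arange(1, 9), "chrom": "c",
                             "first_window": 0, "last_window": 0,
                             "chip": 1, "input": 1, "total": 2, "log_rr": 0.0})
        out = cd.assign_quartiles(bins)
        assert out.attrs["length_quartiles"] == (2.75, 4.5, 6.25)
        assert list(out["quartile"]) == ["Q1"] * 2 + ["Q2"] * 2 + ["Q3"] * 2 + ["Q4"] * 2

    def test_tied_lengths_collapse_to_q1_flagged(self):
        bins = pd.DataFrame({"length": [7] * 6})
        out = cd.assign_quartiles(bins)
        assert set(out["quartile"]) == {"Q1"}
        assert out.attrs["degenerate_quartiles"]

    def test_single_long_bin_lands_in_q4(self):
        bins = pd.DataFrame({"length": [1, 1, 1, 100]})
        out = cd.assign_quartiles(bins)
        assert list(out["quartile"]) == ["Q1", "Q1", "Q1", "Q4"]

    def test_requires_four_bins(self):
        with pytest.raises(ValueError):
            cd.assign_quartiles(pd.DataFrame({"length": [1, 2, 3]}))


class TestLogitSd:
    def test_closed_form_values(self):
        assert cd.logit_sd(0.7, 500) == pytest.approx(0.0909, abs=5e-5)
        assert cd.logit_sd(1.0, 64) == pytest.approx(2 / 8)
        # quartering the bin total doubles the sd
        assert cd.logit_sd(0.7, 125) == pytest.approx(2 * cd.logit_sd(0.7, 500))

    def test_rejects_nonpositive_inputs(self):
        with pytest.raises(ValueError):
            cd.logit_sd(0, 100)
        with pytest.raises(ValueError):
            cd.logit_sd(0.7, 0)


def _poisson_bins(n, K=500, r=0.7, seed=0, lengths=None):
    chip, inp, _ = cd.simulate_nb_bins(K=K, r=r, p=1.0, n=n, seed=seed)
    rng = np.random.default_rng(seed + 1)
    if lengths is None:
        lengths = rng.integers(50, 150, size=n)
    with np.errstate(divide="ignore"):
        log_rr = np.where((chip > 0) & (inp > 0),
                          np.log(chip / np.maximum(inp, 1)), np.nan)
    return pd.DataFrame({"length": lengths, "chip": chip, "input": inp,
                         "total": chip + inp, "log_rr": log_rr})


class TestDensityEstimates:
    def test_each_curve_integrates_to_one(self):
        dens = cd.density_estimates(_poisson_bins(2000))
        for name, curve in dens.densities.items():
            assert np.trapezoid(curve, dens.grid) == pytest.approx(1.0,
                                                                   abs=0.01)

    def test_mode_near_log_r_for_background_bins(self):
        dens = cd.density_estimates(_poisson_bins(10000))
        assert dens.mode("all") == pytest.approx(np.log(0.7), abs=0.02)

    def test_signal_in_short_bins_separates_quartiles(self):
        """Enriched bins have short support: Q1 mode right of Q4 mode."""
        n, n_enr = 4000, 2600  # ~40% enriched so the Q1 break is at length 5
        background = _poisson_bins(n, r=0.7, seed=2)
        chip, inp, _ = cd.simulate_nb_bins(K=500, r=2.0, p=1.0, n=n_enr,
                                           seed=3)
        enriched = pd.DataFrame({
            "length": np.full(n_enr, 5), "chip": chip, "input": inp,
            "total": chip + inp, "log_rr": np.log(chip / inp)})
        bins = pd.concat([background, enriched], ignore_index=True)
        dens = cd.density_estimates(bins)
        assert dens.mode("q4") == pytest.approx(np.log(0.7), abs=0.05)
        assert dens.mode("q1") > dens.mode("q4") + 0.5

    def test_zero_count_bins_are_excluded_and_counted(self):
        bins = _poisson_bins(500, K=6, seed=4)  # small K: zeros occur
        assert bins["log_rr"].isna().any()
        dens = cd.density_estimates(bins)
        assert dens.n_bins_excluded == int(bins["log_rr"].isna().sum())
        assert dens.n_bins_used + dens.n_bins_excluded == len(bins)

    def test_sample_sd_matches_logit_approximation(self):
        """Poisson-model oracle: sd of log relative risk ~ (r+1)/sqrt(Kr)."""
        bins = _poisson_bins(20000, K=500, r=0.7, seed=5)
        sd = np.nanstd(bins["log_rr"], ddof=1)
        assert sd == pytest.approx(cd.logit_sd(0.7, 500), rel=0.10)

    def test_overdispersion_widens_but_keeps_the_peak(self):
        chip, inp, _ = cd.simulate_nb_bins(K=500, r=0.7, p=0.25, n=20000,
                                           seed=6)
        bins = pd.DataFrame({"length": np.full(20000, 100), "chip": chip,
                             "input": inp, "total": chip + inp,
                             "log_rr": np.log(chip / inp)})
        sd = np.nanstd(bins["log_rr"], ddof=1)
        assert sd > 1.5 * cd.logit_sd(0.7, 500)
        dens = cd.density_estimates(bins)
        assert dens.mode("all") == pytest.approx(np.log(0.7), abs=0.05)


class TestDiagnosticPlot:
    def test_writes_figure_and_density_table(self, tmp_path):
        dens = cd.density_estimates(_poisson_bins(1000))
        out = tmp_path / "diag.png"
        table = cd.diagnostic_plot(dens, [("ncis", 0.7)], K=500, out=out)
        assert out.exists()
        written = pd.read_csv(f"{out}.tsv", sep="\t")
        assert list(written.columns) == ["log_rr", "all", "q4", "q3", "q2", "q1"]
        pd.testing.assert_frame_equal(written, table, check_exact=False)

    def test_empty_estimate_list_is_fine(self, tmp_path):
        dens = cd.density_estimates(_poisson_bins(1000))
        cd.diagnostic_plot(dens, [], K=500, out=tmp_path / "d.png")
        assert (tmp_path / "d.png").exists()

    def test_nonpositive_estimate_rejected(self, tmp_path):
        dens = cd.density_estimates(_poisson_bins(1000))
        with pytest.raises(ValueError):
            cd.diagnostic_plot(dens, [("bad", 0.0)], K=500,
                               out=tmp_path / "d.png")

    def test_deterministic_density_tables(self):
        bins = _poisson_bins(1500, seed=9)
        a = cd.density_estimates(bins).to_frame()
        b = cd.density_estimates(bins.copy()).to_frame()
        pd.testing.assert_frame_equal(a, b)

    def test_multi_K_panels(self, tmp_path):
        rng = np.random.default_rng(12)
        counts = cd.WindowCounts.from_arrays(rng.poisson(4, 4000),
                                             rng.poisson(5, 4000))
        out = tmp_path / "panels.png"
        tables = cd.diagnostic_panels(counts, [100, 200], [("true", 0.8)], out)
        assert out.exists()
        assert set(tables) == {100, 200}
        assert (tmp_path / "panels.png.K100.tsv").exists()
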