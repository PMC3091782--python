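"""Evaluation layer: analytic detection power, sensitivity by frequency
bin, delta_p-stratified FSV means, and the correlation scan."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from fsvkit.evaluate import (
    detection_power,
    sensitivity,
    fsv_by_delta_bins,
    correlation_scan,
    best_windows,
)

from conftest import make_calls


def make_chip_summary(rows):
    """(chrom, pos, freq_high, freq_low) -> usable polymorphic summary."""
    frame = pd.DataFrame(rows, columns=["chrom", "pos", "freq_high", "freq_low"])
    frame["call_freq"] = 1.0
    frame["polymorphic"] = True
    frame["delta_p"] = (frame["freq_high"] - frame["freq_low"]).abs()
    frame["usable"] = True
    return frame


class TestDetectionPower:
    def test_zero_frequency_zero_error_has_no_power(self):
        assert detection_power(5.19, 0.0, error=0.0) == 0.0

    def test_closed_form_at_fixed_nonref(self):
        """lambda=5.19, q=1, k=3: 1 - e^-L(1 + L + L^2/2) = 0.8904."""
        lam = 5.19
        by_hand = 1 - np.exp(-lam) * (1 + lam + lam**2 / 2)
        assert detection_power(lam, 1.0) == pytest.approx(by_hand, abs=1e-12)
        assert detection_power(lam, 1.0) == pytest.approx(0.8904, abs=5e-4)

    def test_power_nondecreasing_in_frequency(self):
        grid = np.linspace(0, 1, 21)
        power = detection_power(5.19, grid)
        assert (np.diff(power) >= 0).all()

    def test_error_rate_lifts_power_at_low_frequency(self):
        assert detection_power(5.19, 0.0, error=0.05) > 0.0

    def test_invalid_arguments_rejected(self):
        with pytest.raises(ValueError):
            detection_power(5.19, 0.5, threshold=0)
        with pytest.raises(ValueError):
            detection_power(5.19, 1.5)
        with pytest.raises(ValueError):
            detection_power(-1.0, 0.5)


class TestSensitivity:
    def test_zero_frequency_snps_never_detected(self, study_run):
        """The bottom bin holds SNPs (near-)absent from the line's pool,
        so almost none can reach three non-reference reads."""
        sens = study_run.sensitivity
        pooled = sens[sens["line"] == "pooled"].set_index("bin")
        assert pooled.loc["0.0-0.1", "fraction_detected"] < 0.05

    def test_bins_partition_the_chip_snp_set(self, study_run):
        chip = study_run.chip_summary
        n_usable = int((chip["usable"] & chip["polymorphic"]).sum())
        sens = study_run.sensitivity
        for line in ("high", "low", "pooled"):
            total = sens.loc[sens["line"] == line, "n_chip_snps"].sum()
            assert total == (n_usable if line != "pooled" else 2 * n_usable)

    def test_detected_counts_bounded_by_totals(self, study_run):
        sens = study_run.sensitivity
        assert (sens["n_detected"] <= sens["n_chip_snps"]).all()
        frac = sens["fraction_detected"].dropna()
        assert frac.between(0, 1).all()

    def test_top_bin_fraction_near_analytic_power(self, study_run):
        """Empirical redetection in the 0.9-1.0 bin should sit within
        Monte-Carlo error of the analytic power averaged over the bin,
        allowing for finite-pool resampling of the pool frequency."""
        config = study_run.config
        sens = study_run.sensitivity
        row = sens[(sens["line"] == "high") & (sens["bin"] == "0.9-1.0")].iloc[0]
        # average analytic power over pool frequencies drawn around q ~ 0.95
        rng = np.random.default_rng(0)
        q = rng.binomial(22, rng.uniform(0.9, 1.0, 20_000)) / 22
        expected = detection_power(
            config.mean_depth_high, q, error=config.seq_error_rate
        ).mean()
        se = np.sqrt(expected * (1 - expected) / row["n_chip_snps"])
        assert abs(row["fraction_detected"] - expected) < 4 * se

    def test_disjoint_positions_error(self):
        chip = make_chip_summary([("c1", 10, 0.5, 0.5)])
        calls = make_calls([("c2", 999, True, True, 0.2, 0.8, False)])
        with pytest.raises(ValueError, match="overlap"):
            sensitivity(chip, calls)


class TestFsvDeltaBins:
    @staticmethod
    def _fsv_rows(values, window=62_000):
        return pd.DataFrame({
            "chrom": "c1",
            "pos": np.arange(1, len(values) + 1) * 1000,
            "window_total": window,
            "n_high": 70, "n_low": 70,
            "mean_absdiff_high": 1.0, "mean_absdiff_low": values,
            "fsv": values,
            "defined": True, "density_pass": True,
        })

    def test_constant_fsv_has_zero_se_everywhere(self):
        chip = make_chip_summary(
            [("c1", p * 1000, 0.9, 0.1) for p in range(1, 11)]
        )
        bins = fsv_by_delta_bins(chip, self._fsv_rows([0.5] * 10), 62_000)
        filled = bins[bins["n"] > 0]
        assert (filled["se_fsv"] == 0).all()
        assert (filled["mean_fsv"] == 0.5).all()

    def test_bin_counts_sum_to_joined_rows(self, study_run):
        window = next(iter(study_run.best_windows.values()))
        bins = fsv_by_delta_bins(study_run.chip_summary, study_run.fsv_table,
                                 window)
        joined = study_run.fsv_table
        joined = joined[(joined["window_total"] == window)
                        & joined["defined"] & joined["density_pass"]]
        chip = study_run.chip_summary
        chip = chip[chip["usable"] & chip["polymorphic"]]
        expected = len(joined.merge(chip[["chrom", "pos"]], on=["chrom", "pos"]))
        assert bins["n"].sum() == expected

    def test_high_divergence_snps_score_higher_fsv(self, study_run):
        """Mean FSV in the top delta_p bin exceeds the bottom bin on a
        divergent-selection simulation."""
        window = next(iter(study_run.best_windows.values()))
        bins = fsv_by_delta_bins(study_run.chip_summary, study_run.fsv_table,
                                 window).set_index("bin")
        assert bins.loc["0.9-1.0", "mean_fsv"] > bins.loc["0.0-0.1", "mean_fsv"]


class TestCorrelationScan:
    def test_fsv_equal_to_delta_gives_perfect_correlation(self):
        rng = np.random.default_rng(10)
        delta = rng.uniform(0.41, 1.0, 50)
        chip = make_chip_summary(
            [("c1", (i + 1) * 1000, d, 0.0) for i, d in enumerate(delta)]
        )
        fsv_rows = TestFsvDeltaBins._fsv_rows(delta)
        scan = correlation_scan(chip, fsv_rows, {"c1": "macro"})
        defined = scan[scan["defined"]]
        assert len(defined) > 0
        assert np.allclose(defined["pearson_r"], 1.0)

    def test_shuffled_pairing_shows_no_correlation(self):
        rng = np.random.default_rng(11)
        n = 400
        delta = rng.uniform(0.41, 1.0, n)
        fsv_vals = rng.uniform(0, 1, n)  # independent of delta
        chip = make_chip_summary(
            [("c1", (i + 1) * 1000, d, 0.0) for i, d in enumerate(delta)]
        )
        scan = correlation_scan(chip, TestFsvDeltaBins._fsv_rows(fsv_vals),
                                {"c1": "macro"})
        r = scan.loc[scan["stratum"] == "all", "pearson_r"].iloc[0]
        assert abs(r) < 3 / np.sqrt(n)

    def test_small_or_degenerate_strata_flagged_not_dropped(self):
        chip = make_chip_summary([("c1", 1000, 0.9, 0.1), ("c1", 2000, 0.8, 0.1)])
        fsv_rows = TestFsvDeltaBins._fsv_rows([0.5, 0.5])
        scan = correlation_scan(chip, fsv_rows, {"c1": "macro"})
        assert len(scan) > 0
        assert not scan["defined"].any()
        assert scan["pearson_r"].isna().all()

    def test_pearson_matches_reference_implementation(self, study_run):
        """Spot-check one stratum against scipy computed from the joined
        rows directly."""
        scan = study_run.correlation
        row = scan[scan["defined"]].iloc[0]
        chip = study_run.chip_summary
        chip = chip[chip["usable"] & chip["polymorphic"]]
        fsv_rows = study_run.fsv_table
        fsv_rows = fsv_rows[
            (fsv_rows["window_total"] == row["window_total"])
            & fsv_rows["defined"] & fsv_rows["density_pass"]
        ]
        merged = chip.merge(fsv_rows, on=["chrom", "pos"])
        if row["stratum"] != "all":
            cmap = study_run.config.chromosome_class_map
            merged = merged[merged["chrom"].map(cmap) == row["stratum"]]
        merged = merged[merged["delta_p"] > 0.4]
        r, p = stats.pearsonr(merged["fsv"], merged["delta_p"])
        assert row["pearson_r"] == pytest.approx(r)
        assert row["p_value"] == pytest.approx(p)
        assert row["n"] == len(merged)

    def test_best_windows_marks_the_argmax(self, study_run):
        scan = study_run.correlation
        best = best_windows(scan)
        for stratum, window in best.items():
            sub = scan[(scan["stratum"] == stratum) & scan["defined"]]
            assert window == int(sub.loc[sub["pearson_r"].idxmax(), "window_total"])
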