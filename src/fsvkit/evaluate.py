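"""Evaluation layer: detection sensitivity, FSV stratified means, and the
window-size correlation scan.

The three empirical summaries mirror the study design they evaluate:

- :func:`sensitivity` — fraction of chip SNPs redetected by the pooled
  low-coverage caller, stratified by the non-reference allele frequency
  in the line's population (decile bins; each line contributes one
  observation per SNP).
- :func:`fsv_by_delta_bins` — mean FSV (+/- SE) of chip SNPs stratified
  by the between-line frequency difference delta_p.
- :func:`correlation_scan` — Pearson product-moment correlation between
  FSV and delta_p per chromosome size class and total window size, with
  the window maximising r per class.

:func:`detection_power` is the analytic companion to the empirical
sensitivity: under Poisson read depth and binomial allele sampling, the
non-reference read count at a site with pool frequency q is marginally
Poisson with mean lambda * q' (Poisson thinning), so the probability of
reaching a k-read detection threshold has a closed form.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .chip import frequency_bin_index, frequency_bin_label, N_FREQ_BINS

LINES = ("high", "low")


def detection_power(mean_depth, q, threshold: int = 3, error: float = 0.0):
    """P(non-reference reads >= threshold) at a site with pool frequency q.

    Reads are Poisson(mean_depth)-many, each non-reference with
    probability q' = q(1-e) + (1-q)e; thinning makes the non-reference
    count Poisson(mean_depth * q'), so the power is the upper tail of
    that law at the calling threshold.  Vectorised over ``q`` and
    ``mean_depth``.
    """
    if threshold < 1:
        raise ValueError("threshold must be >= 1")
    mean_depth = np.asarray(mean_depth, dtype=float)
    q = np.asarray(q, dtype=float)
    if np.any(mean_depth <= 0):
        raise ValueError("mean depth must be positive")
    if np.any((q < 0) | (q > 1)) or not 0.0 <= error <= 1.0:
        raise ValueError("q and error must lie in [0, 1]")
    q_eff = q * (1.0 - error) + (1.0 - q) * error
    power = stats.poisson.sf(threshold - 1, mean_depth * q_eff)
    return float(power) if power.ndim == 0 else power


def sensitivity(
    chip_summary: pd.DataFrame, calls: pd.DataFrame
) -> pd.DataFrame:
    """Redetection fraction of chip SNPs per non-reference frequency decile.

    Uses usable, polymorphic chip SNPs; each line contributes one
    observation per SNP, binned by that line's frequency and counted as
    detected when the pool caller detected the SNP in that same line.
    Also reports both lines pooled.

    Returns a tidy frame ``line, bin, n_chip_snps, n_detected,
    fraction_detected``; bins with no SNPs keep n = 0 and NaN fraction.
    """
    chip = chip_summary[chip_summary["usable"] & chip_summary["polymorphic"]]
    merged = chip.merge(
        calls[["chrom", "pos", "detected_high", "detected_low"]],
        on=["chrom", "pos"], how="left",
    )
    if len(merged) == 0:
        raise ValueError("no chip SNPs available")
    if not merged["detected_high"].notna().any():
        raise ValueError("chip positions do not overlap the call table")

    rows = []
    pooled_n = np.zeros(N_FREQ_BINS, dtype=int)
    pooled_det = np.zeros(N_FREQ_BINS, dtype=int)
    for line in LINES:
        bins = frequency_bin_index(merged[f"freq_{line}"])
        detected = (
            merged[f"detected_{line}"].astype("boolean").fillna(False)
            .to_numpy(dtype=bool)
        )
        n = np.bincount(bins, minlength=N_FREQ_BINS)
        det = np.bincount(bins, weights=detected, minlength=N_FREQ_BINS).astype(int)
        pooled_n += n
        pooled_det += det
        rows.append((line, n, det))
    rows.append(("pooled", pooled_n, pooled_det))

    out = []
    for line, n, det in rows:
        with np.errstate(invalid="ignore"):
            frac = np.where(n > 0, det / np.maximum(n, 1), np.nan)
        out.append(
            pd.DataFrame(
                {
                    "line": line,
                    "bin": [frequency_bin_label(i) for i in range(N_FREQ_BINS)],
                    "n_chip_snps": n,
                    "n_detected": det,
                    "fraction_detected": frac,
                }
            )
        )
    return pd.concat(out, ignore_index=True)


def fsv_by_delta_bins(
    chip_summary: pd.DataFrame, fsv_table: pd.DataFrame, window_total: int
) -> pd.DataFrame:
    """Mean FSV +/- SE per delta_p decile bin, for one window size.

    Only defined, density-passing FSV rows at usable polymorphic chip
    SNPs enter; empty bins are reported with n = 0 and no mean.
    """
    merged = _join_fsv_chip(chip_summary, fsv_table)
    merged = merged[merged["window_total"] == window_total]
    bins = frequency_bin_index(merged["delta_p"])
    out = []
    for i in range(N_FREQ_BINS):
        vals = merged.loc[bins == i, "fsv"].to_numpy()
        n = len(vals)
        out.append(
            {
                "bin": frequency_bin_label(i),
                "n": n,
                "mean_fsv": vals.mean() if n else np.nan,
                "se_fsv": vals.std(ddof=1) / np.sqrt(n) if n > 1 else
                (0.0 if n == 1 else np.nan),
            }
        )
    return pd.DataFrame(out)


def _join_fsv_chip(chip_summary: pd.DataFrame, fsv_table: pd.DataFrame) -> pd.DataFrame:
    chip = chip_summary[chip_summary["usable"] & chip_summary["polymorphic"]]
    usable_fsv = fsv_table[fsv_table["defined"] & fsv_table["density_pass"]]
    return chip[["chrom", "pos", "delta_p"]].merge(
        usable_fsv, on=["chrom", "pos"], how="inner"
    )


def correlation_scan(
    chip_summary: pd.DataFrame,
    fsv_table: pd.DataFrame,
    class_map: dict[str, str],
    delta_min: float | None = 0.4,
    delta_max: float | None = None,
    min_n: int = 3,
) -> pd.DataFrame:
    """Pearson r between FSV and delta_p per (chromosome class, window).

    Rows must be defined, density-passing, at usable polymorphic chip
    SNPs, with delta_p strictly above ``delta_min`` and at most
    ``delta_max`` (either filter may be None to disable it).  Strata with
    fewer than ``min_n`` rows or zero variance are reported with
    ``defined = False`` rather than dropped.

    Returns a frame ``stratum, window_total, n, pearson_r, p_value,
    defined, best`` where ``best`` marks, per stratum, the window with
    maximal r among that stratum's defined rows.
    """
    merged = _join_fsv_chip(chip_summary, fsv_table)
    if delta_min is not None:
        merged = merged[merged["delta_p"] > delta_min]
    if delta_max is not None:
        merged = merged[merged["delta_p"] <= delta_max]
    merged = merged.assign(stratum=merged["chrom"].map(class_map))

    strata = ["all"] + sorted(merged["stratum"].dropna().unique())
    rows = []
    for stratum in strata:
        sub = merged if stratum == "all" else merged[merged["stratum"] == stratum]
        for w, grp in sub.groupby("window_total", sort=True):
            x = grp["fsv"].to_numpy()
            y = grp["delta_p"].to_numpy()
            ok = len(grp) >= min_n and x.std() > 0 and y.std() > 0
            if ok:
                r, p = stats.pearsonr(x, y)
            else:
                r, p = np.nan, np.nan
            rows.append(
                {
                    "stratum": stratum,
                    "window_total": int(w),
                    "n": len(grp),
                    "pearson_r": r,
                    "p_value": p,
                    "defined": ok,
                }
            )
    scan = pd.DataFrame(
        rows,
        columns=["stratum", "window_total", "n", "pearson_r", "p_value", "defined"],
    )
    scan["best"] = False
    for stratum in scan["stratum"].unique():
        mask = (scan["stratum"] == stratum) & scan["defined"]
        if mask.any():
            scan.loc[scan.loc[mask, "pearson_r"].idxmax(), "best"] = True
    return scan


def best_windows(scan: pd.DataFrame) -> dict[str, int]:
    """Per-stratum window size (bp) with the strongest correlation."""
    best = scan[scan["best"]]
    return dict(zip(best["stratum"], best["window_total"].astype(int)))
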