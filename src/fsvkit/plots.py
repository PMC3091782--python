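"""Optional matplotlib figures for the evaluation tables."""

from __future__ import annotations

import pandas as pd


def plot_sensitivity(sens: pd.DataFrame, ax=None):
    """Bar chart of redetection fraction per non-reference frequency decile."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(7, 4))
    pooled = sens[sens["line"] == "pooled"]
    ax.bar(range(len(pooled)), pooled["fraction_detected"], color="0.4")
    ax.set_xticks(range(len(pooled)), pooled["bin"], rotation=45)
    ax.set_xlabel("non-reference allele frequency in line")
    ax.set_ylabel("fraction of chip SNPs detected")
    ax.set_ylim(0, 1)
    return ax


def plot_correlation_scan(scan: pd.DataFrame, ax=None):
    """Pearson r vs total window size, one line per chromosome class."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(7, 4))
    for stratum, grp in scan.groupby("stratum"):
        grp = grp[grp["defined"]].sort_values("window_total")
        ax.plot(grp["window_total"] / 1000, grp["pearson_r"],
                marker="o", label=stratum)
    ax.set_xlabel("total flanking window (kb)")
    ax.set_ylabel("Pearson r (FSV vs delta_p)")
    ax.legend(title="chromosome class")
    return ax


def plot_fsv_delta_bins(bins: pd.DataFrame, ax=None):
    """Mean FSV (+/- SE) per delta_p decile."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(7, 4))
    filled = bins[bins["n"] > 0]
    ax.errorbar(range(len(filled)), filled["mean_fsv"], yerr=filled["se_fsv"],
                fmt="o-", color="0.2", capsize=3)
    ax.set_xticks(range(len(filled)), filled["bin"], rotation=45)
    ax.set_xlabel("allele frequency difference between lines (delta_p)")
    ax.set_ylabel("mean FSV")
    return ax
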