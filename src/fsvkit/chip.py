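"""Per-SNP summaries of individual chip genotypes.

Genotypes are non-reference allele dosages in {0, 1, 2} with missing calls.
For each SNP we compute the per-line non-reference allele frequency, the
joint call frequency across both lines, a polymorphism flag (variation
within or between lines), and the between-line frequency difference
delta_p = |freq_high - freq_low| that the flanking-window statistic is
meant to predict.

SNPs failing the call-frequency filter (default: call frequency must
exceed 0.95) or lacking any non-missing call in a line are flagged
unusable and dropped from downstream analyses, not raised as errors.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

SUMMARY_COLUMNS = [
    "chrom", "pos", "freq_high", "freq_low", "call_freq",
    "polymorphic", "delta_p", "usable",
]

N_FREQ_BINS = 10


def _line_stats(frame: pd.DataFrame) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """(non-missing count, dosage sum, frequency) per SNP for one line."""
    dosage = frame.drop(columns=["chrom", "pos"]).to_numpy(dtype=float, na_value=np.nan)
    n_called = np.sum(~np.isnan(dosage), axis=1)
    total = np.nansum(dosage, axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        freq = np.where(n_called > 0, total / (2 * n_called), np.nan)
    return n_called, dosage, freq


def summarize_chip(
    genotypes: dict[str, pd.DataFrame], min_call_freq: float = 0.95
) -> pd.DataFrame:
    """Summarise per-line genotype matrices into one row per chip SNP.

    Parameters
    ----------
    genotypes
        Mapping ``{"high": frame, "low": frame}``; each frame has columns
        ``chrom``, ``pos`` plus one dosage column per individual, aligned
        row-by-row between the two lines.
    min_call_freq
        SNPs must have a joint call frequency strictly above this to be
        usable downstream.
    """
    high, low = genotypes["high"], genotypes["low"]
    if len(high) != len(low) or not (
        high["pos"].to_numpy() == low["pos"].to_numpy()
    ).all():
        raise ValueError("high/low genotype frames must cover identical SNPs")
    if high.shape[1] <= 2 or low.shape[1] <= 2:
        raise ValueError("each line needs at least one genotyped individual")

    n_high, dos_high, freq_high = _line_stats(high)
    n_low, dos_low, freq_low = _line_stats(low)
    n_ind_total = (high.shape[1] - 2) + (low.shape[1] - 2)
    call_freq = (n_high + n_low) / n_ind_total

    # polymorphic: some variation within or between lines, i.e. NOT
    # (all non-missing dosages identical and homozygous)
    all_dos = np.concatenate([dos_high, dos_low], axis=1)
    with np.errstate(invalid="ignore"):
        mx = np.nanmax(np.where(np.isnan(all_dos), -np.inf, all_dos), axis=1)
        mn = np.nanmin(np.where(np.isnan(all_dos), np.inf, all_dos), axis=1)
    any_call = (n_high + n_low) > 0
    uniform = (mx == mn) & any_call
    homozygous_uniform = uniform & np.isin(mx, (0.0, 2.0))
    polymorphic = any_call & ~homozygous_uniform

    usable = (call_freq > min_call_freq) & (n_high > 0) & (n_low > 0)
    delta_p = np.abs(freq_high - freq_low)

    return pd.DataFrame(
        {
            "chrom": high["chrom"].to_numpy(),
            "pos": high["pos"].to_numpy(),
            "freq_high": freq_high,
            "freq_low": freq_low,
            "call_freq": call_freq,
            "polymorphic": polymorphic,
            "delta_p": delta_p,
            "usable": usable,
        }
    )


def frequency_bin_index(freq) -> np.ndarray:
    """Decile bin index 0..9 for frequencies in [0, 1]; top bin right-closed."""
    freq = np.asarray(freq, dtype=float)
    if np.any((freq < 0) | (freq > 1) | np.isnan(freq)):
        raise ValueError("frequencies must lie in [0, 1]")
    return np.minimum((freq * N_FREQ_BINS).astype(int), N_FREQ_BINS - 1)


def frequency_bin_label(index: int) -> str:
    lo = index / N_FREQ_BINS
    hi = (index + 1) / N_FREQ_BINS
    return f"{lo:.1f}-{hi:.1f}"


def nonref_frequency_bin(freq: float) -> str:
    """Label of the decile bin containing ``freq`` (e.g. 0.55 -> ``0.5-0.6``)."""
    return frequency_bin_label(int(frequency_bin_index(freq)))
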