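"""The Flanking SNPs Value (FSV).

FSV scores a focal genomic position by the between-line divergence of the
SNPs flanking it.  With S_H and S_L the per-line reference-agreement
scores of a flanking SNP (1 where a line shows no call, by the fixation
assumption applied at calling time), and with H / L the sets of flanking
SNPs detected in the high / low line within a total window of W bp
centred on the focal position (W/2 each side, closed interval, the focal
position itself removed):

    FSV = ( sum_{i in H} |S_H(i) - S_L(i)| / N_H )
        * ( sum_{j in L} |S_L(j) - S_H(j)| / N_L )

Each factor is a mean of values in [0, 1], so FSV lies in [0, 1]; a SNP
detected in both lines contributes one term to each sum.  SNPs flagged
``excluded`` (no reference read in either line) are omitted from both
sums.  FSV is undefined (not an error) if either N is zero, and a
separate density filter requires each line to contribute strictly more
than 1 flanking SNP per kb of total window for the value to be used in
correlation tests.

Two implementations are provided: :func:`compute_fsv`, a direct per-focal
evaluation of the definition, and :func:`fsv_scan`, a prefix-sum sweep
over many focal positions and window sizes whose output is contractually
identical to the direct evaluation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: Total flanking-window sizes (kb) scanned by default.
DEFAULT_WINDOWS_KB = (2, 8, 14, 20, 26, 32, 38, 44, 50, 56, 62, 68, 74, 128)

FSV_COLUMNS = [
    "chrom", "pos", "window_total", "n_high", "n_low",
    "mean_absdiff_high", "mean_absdiff_low", "fsv", "defined", "density_pass",
]


@dataclass(frozen=True)
class FsvResult:
    """FSV of one focal position for one total window size."""

    chrom: str
    pos: int
    window_total: int
    n_high: int
    n_low: int
    mean_absdiff_high: float
    mean_absdiff_low: float
    fsv: float
    defined: bool
    density_pass: bool


def density_filter(n_high: int, n_low: int, window_total: int) -> bool:
    """True iff both per-line flanking densities strictly exceed 1 SNP/kb."""
    kb = window_total / 1000.0
    return n_high / kb > 1.0 and n_low / kb > 1.0


def _check_window(window_total: int) -> int:
    window_total = int(window_total)
    if window_total <= 0 or window_total % 2:
        raise ValueError("window_total must be a positive even number of bp")
    return window_total


def compute_fsv(
    focal_pos: int, calls: pd.DataFrame, window_total: int,
    chrom_length: int | None = None,
) -> FsvResult:
    """Direct evaluation of the FSV definition for one focal position.

    Parameters
    ----------
    focal_pos
        1-based focal coordinate.
    calls
        Call table for a single chromosome, sorted by position.
    window_total
        Total window width W in bp (W/2 flanking each side).
    chrom_length
        If given and the window overhangs the chromosome, it is truncated
        at the ends (with a logged note); density still uses the nominal W.
    """
    window_total = _check_window(window_total)
    pos = calls["pos"].to_numpy()
    if len(pos) and (np.diff(pos) < 0).any():
        raise ValueError("calls must be sorted by position")
    if calls["chrom"].nunique() > 1:
        raise ValueError("compute_fsv operates on a single chromosome")

    half = window_total // 2
    lo, hi = focal_pos - half, focal_pos + half
    if chrom_length is not None and (lo < 1 or hi > chrom_length):
        logger.info(
            "window [%d, %d] truncated to chromosome bounds [1, %d]",
            lo, hi, chrom_length,
        )
        lo, hi = max(lo, 1), min(hi, chrom_length)

    in_window = (pos >= lo) & (pos <= hi) & (pos != focal_pos)
    flank = calls.loc[in_window & ~calls["excluded"].to_numpy()]

    absdiff = np.abs(flank["S_high"].to_numpy() - flank["S_low"].to_numpy())
    det_h = flank["detected_high"].to_numpy(dtype=bool)
    det_l = flank["detected_low"].to_numpy(dtype=bool)
    n_high, n_low = int(det_h.sum()), int(det_l.sum())
    defined = n_high >= 1 and n_low >= 1

    mean_h = float(absdiff[det_h].mean()) if n_high else np.nan
    mean_l = float(absdiff[det_l].mean()) if n_low else np.nan
    chrom = calls["chrom"].iloc[0] if len(calls) else ""
    return FsvResult(
        chrom=str(chrom),
        pos=int(focal_pos),
        window_total=window_total,
        n_high=n_high,
        n_low=n_low,
        mean_absdiff_high=mean_h,
        mean_absdiff_low=mean_l,
        fsv=mean_h * mean_l if defined else np.nan,
        defined=defined,
        density_pass=density_filter(n_high, n_low, window_total) if defined else False,
    )


def fsv_scan(
    focal: pd.DataFrame,
    calls: pd.DataFrame,
    windows_kb=DEFAULT_WINDOWS_KB,
    chrom_lengths=None,
) -> pd.DataFrame:
    """FSV for every (focal position, window) pair via a sorted sweep.

    Parameters
    ----------
    focal
        DataFrame with ``chrom`` and ``pos`` columns of focal positions.
    calls
        Full call table (all chromosomes), sorted by position within each.
    windows_kb
        Ascending total window sizes in kb.

    Returns
    -------
    One row per focal x window with columns ``FSV_COLUMNS``; identical to
    per-focal :func:`compute_fsv` output.
    """
    windows = [_check_window(w * 1000) for w in windows_kb]
    if windows != sorted(windows):
        raise ValueError("window list must be sorted ascending")

    out = []
    for chrom, chrom_focal in focal.groupby("chrom", sort=False):
        cc = calls[calls["chrom"] == chrom]
        pos = cc["pos"].to_numpy()
        if len(pos) and (np.diff(pos) < 0).any():
            raise ValueError(f"calls on {chrom} are not sorted by position")
        usable = ~cc["excluded"].to_numpy(dtype=bool)
        absdiff = np.abs(cc["S_high"].to_numpy() - cc["S_low"].to_numpy())
        det_h = cc["detected_high"].to_numpy(dtype=bool) & usable
        det_l = cc["detected_low"].to_numpy(dtype=bool) & usable

        # prefix sums over the sorted calls
        cnt_h = np.concatenate([[0], np.cumsum(det_h)])
        cnt_l = np.concatenate([[0], np.cumsum(det_l)])
        sum_h = np.concatenate([[0.0], np.cumsum(np.where(det_h, absdiff, 0.0))])
        sum_l = np.concatenate([[0.0], np.cumsum(np.where(det_l, absdiff, 0.0))])

        fpos = chrom_focal["pos"].to_numpy()
        length = None if chrom_lengths is None else int(chrom_lengths[chrom])
        # contribution of a call sitting exactly at the focal coordinate
        if len(pos):
            self_idx = np.searchsorted(pos, fpos, side="left")
            idx_safe = np.minimum(self_idx, len(pos) - 1)
            at_focal = (self_idx < len(pos)) & (pos[idx_safe] == fpos)
            self_h = np.where(at_focal, det_h[idx_safe], False)
            self_l = np.where(at_focal, det_l[idx_safe], False)
            self_ad = np.where(at_focal, absdiff[idx_safe], 0.0)
        else:
            self_h = self_l = np.zeros(len(fpos), dtype=bool)
            self_ad = np.zeros(len(fpos))

        for w in windows:
            half = w // 2
            lo, hi = fpos - half, fpos + half
            if length is not None:
                lo, hi = np.maximum(lo, 1), np.minimum(hi, length)
            i0 = np.searchsorted(pos, lo, side="left")
            i1 = np.searchsorted(pos, hi, side="right")
            n_h = cnt_h[i1] - cnt_h[i0] - np.where(self_h, 1, 0)
            n_l = cnt_l[i1] - cnt_l[i0] - np.where(self_l, 1, 0)
            s_h = sum_h[i1] - sum_h[i0] - np.where(self_h, self_ad, 0.0)
            s_l = sum_l[i1] - sum_l[i0] - np.where(self_l, self_ad, 0.0)
            defined = (n_h >= 1) & (n_l >= 1)
            with np.errstate(invalid="ignore", divide="ignore"):
                mean_h = np.where(n_h >= 1, s_h / np.maximum(n_h, 1), np.nan)
                mean_l = np.where(n_l >= 1, s_l / np.maximum(n_l, 1), np.nan)
            kb = w / 1000.0
            out.append(
                pd.DataFrame(
                    {
                        "chrom": chrom,
                        "pos": fpos,
                        "window_total": w,
                        "n_high": n_h,
                        "n_low": n_l,
                        "mean_absdiff_high": mean_h,
                        "mean_absdiff_low": mean_l,
                        "fsv": np.where(defined, mean_h * mean_l, np.nan),
                        "defined": defined,
                        "density_pass": defined & (n_h / kb > 1.0) & (n_l / kb > 1.0),
                    }
                )
            )
    if not out:
        return pd.DataFrame(columns=FSV_COLUMNS)
    return pd.concat(out, ignore_index=True)[FSV_COLUMNS]
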