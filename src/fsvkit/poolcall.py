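"""SNP calling from pooled pileups.

A site is called a SNP in a line when its pool shows at least ``threshold``
non-reference reads (default 3).  Each detected SNP carries a per-line
reference-agreement score

    S = ref_reads / (ref_reads + nonref_reads)

computed from that line's pool; where a detected SNP shows no call in the
other line, that line is assumed fixed for the reference allele and its
score is exactly 1.  That fixation assumption is applied here, once, and
nowhere downstream.

Sites where neither line has a single reference-supporting read are
flagged ``excluded``: their scores carry no between-line information and
downstream flanking-window sums skip them.  They are still emitted so that
variation-class tallies cover the full detected set.

Detected SNPs are classified by their within-line variation pattern
against the reference:

- ``both_all_nonref``  — no reference reads in either line;
- ``one_all_nonref``   — one line all non-reference, the other without
  non-reference evidence reaching the threshold;
- ``one_biallelic``    — exactly one line shows both alleles (reference
  reads plus >= threshold non-reference reads);
- ``both_biallelic``   — both lines show both alleles.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

VARIATION_CLASSES = (
    "both_all_nonref",
    "one_all_nonref",
    "one_biallelic",
    "both_biallelic",
)

CALL_COLUMNS = [
    "chrom", "pos", "detected_high", "detected_low", "S_high", "S_low",
    "depth_high", "depth_low", "variation_class", "excluded",
]


@dataclass(frozen=True)
class PoolPileupRecord:
    """Read evidence for one line at one site."""

    chrom: str
    pos: int
    line: str
    ref_reads: int
    nonref_reads: int

    def __post_init__(self):
        if self.ref_reads < 0 or self.nonref_reads < 0:
            raise ValueError("read counts must be non-negative")

    @property
    def depth(self) -> int:
        return self.ref_reads + self.nonref_reads


def classify_variation(
    ref_high: int, nonref_high: int, ref_low: int, nonref_low: int,
    threshold: int = 3,
) -> str:
    """Within-line variation class of a detected SNP (total, deterministic)."""
    det_high = nonref_high >= threshold
    det_low = nonref_low >= threshold
    if not (det_high or det_low):
        raise ValueError("variation class is defined only for detected SNPs")
    refzero_high = ref_high == 0
    refzero_low = ref_low == 0
    biallelic_high = det_high and not refzero_high
    biallelic_low = det_low and not refzero_low
    if refzero_high and refzero_low:
        return "both_all_nonref"
    if biallelic_high and biallelic_low:
        return "both_biallelic"
    if biallelic_high or biallelic_low:
        return "one_biallelic"
    return "one_all_nonref"


def call_site(
    rec_high: PoolPileupRecord | None,
    rec_low: PoolPileupRecord | None,
    threshold: int = 3,
) -> dict | None:
    """Call one site from the two line records; ``None`` if below threshold.

    A missing line record is treated as zero depth (no detection possible
    in that line).
    """
    if threshold < 1:
        raise ValueError("threshold must be >= 1")
    if rec_high is None and rec_low is None:
        raise ValueError("at least one line record is required")
    if rec_high is not None and rec_low is not None:
        if (rec_high.chrom, rec_high.pos) != (rec_low.chrom, rec_low.pos):
            raise ValueError(
                f"mismatched coordinates: {rec_high.chrom}:{rec_high.pos} vs "
                f"{rec_low.chrom}:{rec_low.pos}"
            )
    ref = rec_high if rec_high is not None else rec_low
    rh, nh = (rec_high.ref_reads, rec_high.nonref_reads) if rec_high else (0, 0)
    rl, nl = (rec_low.ref_reads, rec_low.nonref_reads) if rec_low else (0, 0)

    det_high = nh >= threshold
    det_low = nl >= threshold
    if not (det_high or det_low):
        return None
    return {
        "chrom": ref.chrom,
        "pos": ref.pos,
        "detected_high": det_high,
        "detected_low": det_low,
        "S_high": rh / (rh + nh) if det_high else 1.0,
        "S_low": rl / (rl + nl) if det_low else 1.0,
        "depth_high": rh + nh,
        "depth_low": rl + nl,
        "variation_class": classify_variation(rh, nh, rl, nl, threshold),
        "excluded": rh == 0 and rl == 0,
    }


def call_sites(pileup: pd.DataFrame, threshold: int = 3) -> pd.DataFrame:
    """Vectorised caller over a long pileup table.

    Parameters
    ----------
    pileup
        Columns ``chrom pos line ref_reads nonref_reads``; a (chrom, pos)
        absent for one line counts as zero depth there.

    Returns
    -------
    DataFrame with one row per detected SNP (columns ``CALL_COLUMNS``),
    sorted by chromosome then position.
    """
    if threshold < 1:
        raise ValueError("threshold must be >= 1")
    if (pileup[["ref_reads", "nonref_reads"]].to_numpy() < 0).any():
        raise ValueError("read counts must be non-negative")
    if pileup.duplicated(["chrom", "pos", "line"]).any():
        raise ValueError("duplicated (chrom, pos, line) in pileup")

    wide = pileup.pivot_table(
        index=["chrom", "pos"], columns="line",
        values=["ref_reads", "nonref_reads"], fill_value=0, aggfunc="sum",
    )
    rh = wide.get(("ref_reads", "high"), pd.Series(0, index=wide.index)).to_numpy()
    nh = wide.get(("nonref_reads", "high"), pd.Series(0, index=wide.index)).to_numpy()
    rl = wide.get(("ref_reads", "low"), pd.Series(0, index=wide.index)).to_numpy()
    nl = wide.get(("nonref_reads", "low"), pd.Series(0, index=wide.index)).to_numpy()

    det_high = nh >= threshold
    det_low = nl >= threshold
    keep = det_high | det_low

    with np.errstate(invalid="ignore", divide="ignore"):
        s_high = np.where(det_high, rh / np.maximum(rh + nh, 1), 1.0)
        s_low = np.where(det_low, rl / np.maximum(rl + nl, 1), 1.0)

    refzero_high = rh == 0
    refzero_low = rl == 0
    biallelic_high = det_high & ~refzero_high
    biallelic_low = det_low & ~refzero_low
    variation = np.select(
        [
            refzero_high & refzero_low,
            biallelic_high & biallelic_low,
            biallelic_high | biallelic_low,
        ],
        ["both_all_nonref", "both_biallelic", "one_biallelic"],
        default="one_all_nonref",
    )

    idx = wide.index[keep]
    calls = pd.DataFrame(
        {
            "chrom": idx.get_level_values("chrom"),
            "pos": idx.get_level_values("pos").astype(np.int64),
            "detected_high": det_high[keep],
            "detected_low": det_low[keep],
            "S_high": s_high[keep],
            "S_low": s_low[keep],
            "depth_high": (rh + nh)[keep].astype(np.int64),
            "depth_low": (rl + nl)[keep].astype(np.int64),
            "variation_class": variation[keep],
            "excluded": (refzero_high & refzero_low)[keep],
        }
    )
    return calls.sort_values(["chrom", "pos"], kind="mergesort").reset_index(drop=True)


def variation_class_counts(calls: pd.DataFrame) -> pd.Series:
    """Counts of the four variation classes (a partition of the call set)."""
    counts = calls["variation_class"].value_counts()
    return counts.reindex(VARIATION_CLASSES, fill_value=0)


def snp_density(
    calls: pd.DataFrame,
    chrom_lengths,
    class_map=None,
) -> pd.DataFrame:
    """Detected SNPs per kb, overall and per chromosome size class.

    Returns a DataFrame indexed by stratum (``overall`` plus each class in
    ``class_map``) with columns ``n_snps``, ``length_kb``, ``snps_per_kb``.
    Empty strata get density 0 with a warning.
    """
    if len(calls) == 0:
        raise ValueError("empty call set")
    total_bp = sum(int(v) for v in chrom_lengths.values())
    if total_bp <= 0:
        raise ValueError("zero-length genome")

    rows = {"overall": (len(calls), total_bp / 1000.0)}
    if class_map is not None:
        per_chrom = calls["chrom"].value_counts()
        classes = sorted(set(class_map.values()))
        for cls in classes:
            chroms = [c for c, k in class_map.items() if k == cls]
            kb = sum(int(chrom_lengths[c]) for c in chroms) / 1000.0
            n = int(per_chrom.reindex(chroms).fillna(0).sum())
            if n == 0:
                warnings.warn(f"no detected SNPs in chromosome class {cls!r}")
            rows[cls] = (n, kb)

    out = pd.DataFrame.from_dict(rows, orient="index", columns=["n_snps", "length_kb"])
    out["snps_per_kb"] = np.where(
        out["length_kb"] > 0, out["n_snps"] / out["length_kb"], 0.0
    )
    out.index.name = "stratum"
    return out
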