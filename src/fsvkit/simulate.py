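"""Synthetic two-line study generator.

Three stages, each consuming the previous one's output:

``simulate_truth``
    places true SNPs along each chromosome by a homogeneous point process,
    partitions the chromosome into divergence blocks with exponentially
    distributed lengths, and draws per-line non-reference allele
    frequencies from a Balding-Nichols law shared (up to a small per-SNP
    jitter) by every SNP in a block — so neighbouring SNPs have spatially
    correlated between-line divergence, the structure a flanking-window
    statistic exploits.

``simulate_chip``
    genotypes ``n_individuals_chip`` diploid individuals per line at the
    chip subset of SNPs (dosages Binomial(2, p_line), with no-calls).

``simulate_pools``
    resamples a finite sequencing pool per line (a fresh binomial draw of
    2 * pool_size chromosomes per site), then Poisson read depth and a
    binomial split of reads into reference / non-reference with a per-read
    error that flips alleles.

All randomness flows from ``numpy`` Generators; with no explicit generator
each stage derives a deterministic stream from ``config.rng_seed`` so that
identical seed + config reproduce every output bit-exactly.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .config import SimulationConfig

LINES = ("high", "low")

# stage tags used to derive independent, reproducible streams from the seed
_STAGE_KEY = {"truth": 1, "chip": 2, "pools": 3}


def _stage_rng(config: SimulationConfig, stage: str) -> np.random.Generator:
    return np.random.default_rng(
        np.random.SeedSequence([int(config.rng_seed), _STAGE_KEY[stage]])
    )


@dataclass(frozen=True)
class SimulationTruth:
    """Ground truth of one simulated study (the oracle for recovery tests).

    Attributes
    ----------
    snps
        One row per true SNP: ``chrom``, ``pos`` (1-based), ``p_high``,
        ``p_low`` (true non-reference allele frequencies), ``block_id``,
        ``on_chip``.  Positions strictly increase within a chromosome.
    blocks
        One row per divergence block: ``chrom``, ``block_id``, ``start``,
        ``end`` (closed interval in bp).
    """

    snps: pd.DataFrame
    blocks: pd.DataFrame
    config: SimulationConfig

    def line_freqs(self, line: str) -> np.ndarray:
        if line not in LINES:
            raise ValueError(f"unknown line {line!r}")
        return self.snps[f"p_{line}"].to_numpy()

    @property
    def chip_snps(self) -> pd.DataFrame:
        return self.snps[self.snps["on_chip"]].reset_index(drop=True)


def _balding_nichols(rng, p0: np.ndarray, fst: float) -> np.ndarray:
    """Draw descendant-population frequencies around ancestral ``p0``."""
    p0 = np.asarray(p0, dtype=float)
    if fst == 0.0:
        return p0.copy()
    out = p0.copy()  # ancestrally fixed sites stay fixed
    inner = (p0 > 0.0) & (p0 < 1.0)
    if inner.any():
        ratio = (1.0 - fst) / fst
        out[inner] = rng.beta(p0[inner] * ratio, (1.0 - p0[inner]) * ratio)
    return out


def _jitter(rng, p: np.ndarray, concentration: float) -> np.ndarray:
    """Small per-SNP Beta jitter around block-level frequencies."""
    out = p.copy()
    inner = (p > 0.0) & (p < 1.0)
    if inner.any():
        pi = p[inner]
        out[inner] = rng.beta(pi * concentration, (1.0 - pi) * concentration)
    return out


def simulate_truth(
    config: SimulationConfig, rng: np.random.Generator | None = None
) -> SimulationTruth:
    """Generate the true SNP landscape for both lines.

    Raises
    ------
    ValueError
        If a chromosome is shorter than one average divergence block.
    """
    if rng is None:
        rng = _stage_rng(config, "truth")

    fst = config.fst_within_block
    a, b = config.ancestral_freq_law
    rate = config.snp_density / 1000.0  # SNPs per bp

    snp_frames = []
    block_frames = []
    for chrom, length in config.chromosome_lengths.items():
        length = int(length)
        if length < config.block_length_mean:
            raise ValueError(
                f"chromosome {chrom!r} (length {length} bp) is shorter than "
                f"one average divergence block ({config.block_length_mean:g} bp)"
            )
        # homogeneous point process for SNP positions
        n_snps = rng.poisson(rate * length)
        positions = np.unique(rng.integers(1, length + 1, size=n_snps))

        # exponential block lengths, truncated at the chromosome end
        bounds = [0]
        while bounds[-1] < length:
            step = max(1, int(round(rng.exponential(config.block_length_mean))))
            bounds.append(min(length, bounds[-1] + step))
        starts = np.asarray(bounds[:-1]) + 1
        ends = np.asarray(bounds[1:])
        n_blocks = len(starts)

        block_id = np.searchsorted(ends, positions, side="left")
        p0 = rng.beta(a, b, size=n_blocks)
        ph_block = _balding_nichols(rng, p0, fst)
        pl_block = _balding_nichols(rng, p0, fst)

        if fst == 0.0:
            # zero-divergence limit: lines identical, no jitter
            p_high = p0[block_id]
            p_low = p_high.copy()
        else:
            p_high = _jitter(rng, ph_block[block_id], config.snp_jitter_concentration)
            p_low = _jitter(rng, pl_block[block_id], config.snp_jitter_concentration)

        snp_frames.append(
            pd.DataFrame(
                {
                    "chrom": chrom,
                    "pos": positions,
                    "p_high": p_high,
                    "p_low": p_low,
                    "block_id": block_id,
                }
            )
        )
        block_frames.append(
            pd.DataFrame(
                {"chrom": chrom, "block_id": np.arange(n_blocks),
                 "start": starts, "end": ends}
            )
        )

    snps = pd.concat(snp_frames, ignore_index=True)
    snps["on_chip"] = rng.random(len(snps)) < config.chip_fraction
    blocks = pd.concat(block_frames, ignore_index=True)
    return SimulationTruth(snps=snps, blocks=blocks, config=config)


def simulate_chip(
    truth: SimulationTruth,
    config: SimulationConfig | None = None,
    rng: np.random.Generator | None = None,
) -> dict[str, pd.DataFrame]:
    """Genotype the chip panel in both lines.

    Returns a mapping line -> DataFrame with columns ``chrom``, ``pos`` and
    one nullable-integer dosage column per individual (``ind01`` ...);
    missing genotypes are ``pd.NA``.
    """
    config = config or truth.config
    if rng is None:
        rng = _stage_rng(config, "chip")
    chip = truth.chip_snps
    if len(chip) == 0:
        raise ValueError("chip panel is empty (chip_mask selected no SNPs)")

    n_ind = config.n_individuals_chip
    ind_cols = [f"ind{i + 1:02d}" for i in range(n_ind)]
    out = {}
    for line in LINES:
        p = chip[f"p_{line}"].to_numpy()
        dosages = rng.binomial(2, p[:, None], size=(len(chip), n_ind))
        frame = pd.DataFrame(dosages, columns=ind_cols).astype("Int8")
        if config.missing_rate > 0:
            missing = rng.random((len(chip), n_ind)) < config.missing_rate
            frame = frame.mask(pd.DataFrame(missing, columns=ind_cols))
        frame.insert(0, "pos", chip["pos"].to_numpy())
        frame.insert(0, "chrom", chip["chrom"].to_numpy())
        out[line] = frame
    return out


def simulate_pools(
    truth: SimulationTruth,
    config: SimulationConfig | None = None,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Generate pooled pileup records for both lines at every true SNP site.

    Per line and site: the pool's allele frequency q is a fresh binomial
    draw over 2 * pool_size chromosomes; read depth is Poisson with the
    line's mean; non-reference reads are Binomial(depth, q') with
    q' = q(1-e) + (1-q)e for per-read error e.

    Returns a long DataFrame ``chrom pos line ref_reads nonref_reads``.
    """
    config = config or truth.config
    if rng is None:
        rng = _stage_rng(config, "pools")
    if config.pool_size < 1:
        raise ValueError("pool must contain at least one individual")

    n_chrom_copies = 2 * config.pool_size
    e = config.seq_error_rate
    frames = []
    for line in LINES:
        p = truth.line_freqs(line)
        pool_count = rng.binomial(n_chrom_copies, p)
        q = pool_count / n_chrom_copies
        depth = rng.poisson(config.mean_depth(line), size=len(p))
        q_eff = q * (1.0 - e) + (1.0 - q) * e
        nonref = rng.binomial(depth, q_eff)
        frames.append(
            pd.DataFrame(
                {
                    "chrom": truth.snps["chrom"].to_numpy(),
                    "pos": truth.snps["pos"].to_numpy(),
                    "line": line,
                    "ref_reads": depth - nonref,
                    "nonref_reads": nonref,
                }
            )
        )
    return pd.concat(frames, ignore_index=True)
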