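"""Simulation configuration.

A :class:`SimulationConfig` fixes every knob of the synthetic study design:
the genome (chromosome names, lengths and size classes), the true SNP
landscape (density, divergence-block structure, ancestral frequency law,
between-line differentiation), the chip panel (fraction of SNPs assayed,
individuals genotyped per line, no-call rate) and the pooled resequencing
design (pool composition, mean depth per line, per-read error rate).

Defaults emulate two lines divergently selected for body weight: DNA pools
of 7 males + 4 females per line sequenced at 5.19X / 5.53X mean depth,
20 chip-genotyped individuals per line, and ~5 true SNPs per kb.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Mapping

import yaml

CHROMOSOME_CLASSES = ("macro", "intermediate", "micro")

#: 20 Mb toy genome spanning the three avian chromosome size classes.
DEFAULT_CHROMOSOME_LENGTHS: dict[str, int] = {
    "chr1": 5_000_000,
    "chr2": 5_000_000,
    "chr6": 3_000_000,
    "chr7": 3_000_000,
    "chr11": 2_000_000,
    "chr12": 2_000_000,
}

DEFAULT_CLASS_MAP: dict[str, str] = {
    "chr1": "macro",
    "chr2": "macro",
    "chr6": "intermediate",
    "chr7": "intermediate",
    "chr11": "micro",
    "chr12": "micro",
}


def default_class_map(chromosomes) -> dict[str, str]:
    """Assign size classes by rank: first 5 macro, next 5 intermediate, rest micro."""
    out = {}
    for i, chrom in enumerate(chromosomes):
        out[chrom] = "macro" if i < 5 else ("intermediate" if i < 10 else "micro")
    return out


@dataclass(frozen=True)
class SimulationConfig:
    """Full parameterisation of the synthetic two-line study.

    Parameters
    ----------
    chromosome_lengths
        Chromosome name -> length in bp (1-based, closed coordinates).
    chromosome_class_map
        Chromosome name -> one of ``macro``/``intermediate``/``micro``.
    snp_density
        True SNPs per kb (homogeneous point process).
    chip_fraction
        Fraction of true SNPs placed on the chip panel.
    n_individuals_chip
        Individuals genotyped per line on the chip.
    pool_males, pool_females
        Composition of each line's sequencing pool.
    mean_depth_high, mean_depth_low
        Mean Poisson read depth per site for the high / low line pool.
    fst_within_block
        Balding-Nichols differentiation parameter shared within a block.
    block_length_mean
        Mean divergence-block length in bp (exponential lengths).
    ancestral_freq_law
        ``(alpha, beta)`` of the Beta law for the ancestral frequency p0.
    snp_jitter_concentration
        Beta concentration of the small per-SNP jitter around the block-level
        line frequency; larger means tighter coupling within a block.
    seq_error_rate
        Per-read miscall probability (flips ref <-> non-ref).
    missing_rate
        Chip no-call probability per genotype.
    rng_seed
        Master seed; every stage derives its stream from it.
    """

    chromosome_lengths: Mapping[str, int] = field(
        default_factory=lambda: dict(DEFAULT_CHROMOSOME_LENGTHS)
    )
    chromosome_class_map: Mapping[str, str] = field(
        default_factory=lambda: dict(DEFAULT_CLASS_MAP)
    )
    snp_density: float = 5.0
    chip_fraction: float = 0.012
    n_individuals_chip: int = 20
    pool_males: int = 7
    pool_females: int = 4
    mean_depth_high: float = 5.19
    mean_depth_low: float = 5.53
    fst_within_block: float = 0.4
    block_length_mean: float = 30_000.0
    ancestral_freq_law: tuple[float, float] = (1.0, 1.0)
    snp_jitter_concentration: float = 200.0
    seq_error_rate: float = 0.002
    missing_rate: float = 0.01
    rng_seed: int = 0

    def __post_init__(self):
        if not self.chromosome_lengths:
            raise ValueError("at least one chromosome is required")
        for chrom, length in self.chromosome_lengths.items():
            if int(length) <= 0:
                raise ValueError(f"chromosome {chrom!r} has non-positive length")
        for chrom in self.chromosome_lengths:
            cls = self.chromosome_class_map.get(chrom)
            if cls not in CHROMOSOME_CLASSES:
                raise ValueError(
                    f"chromosome {chrom!r} has invalid class {cls!r}; "
                    f"expected one of {CHROMOSOME_CLASSES}"
                )
        for name in ("snp_density", "block_length_mean", "snp_jitter_concentration",
                     "mean_depth_high", "mean_depth_low"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        for name in ("n_individuals_chip", "pool_males", "pool_females"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        for name in ("chip_fraction", "seq_error_rate", "missing_rate"):
            value = getattr(self, name)
            if not 0.0 <= value <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")
        if not 0.0 <= self.fst_within_block < 1.0:
            raise ValueError("fst_within_block must lie in [0, 1)")
        a, b = self.ancestral_freq_law
        if a <= 0 or b <= 0:
            raise ValueError("ancestral_freq_law parameters must be positive")

    @property
    def n_chromosomes(self) -> int:
        return len(self.chromosome_lengths)

    @property
    def pool_size(self) -> int:
        """Diploid individuals per sequencing pool."""
        return self.pool_males + self.pool_females

    def mean_depth(self, line: str) -> float:
        if line == "high":
            return self.mean_depth_high
        if line == "low":
            return self.mean_depth_low
        raise ValueError(f"unknown line {line!r}")

    # -- serialisation ----------------------------------------------------

    def to_dict(self) -> dict:
        d = asdict(self)
        d["chromosome_lengths"] = dict(self.chromosome_lengths)
        d["chromosome_class_map"] = dict(self.chromosome_class_map)
        d["ancestral_freq_law"] = list(self.ancestral_freq_law)
        return d

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def from_dict(cls, d: Mapping) -> "SimulationConfig":
        d = dict(d)
        d.pop("n_chromosomes", None)
        if "ancestral_freq_law" in d:
            d["ancestral_freq_law"] = tuple(d["ancestral_freq_law"])
        if "chromosome_lengths" in d and "chromosome_class_map" not in d:
            d["chromosome_class_map"] = default_class_map(d["chromosome_lengths"])
        return cls(**d)

    @classmethod
    def from_yaml(cls, path) -> "SimulationConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))
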