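import numpy as np
import pandas as pd
import pytest
from hypothesis import settings, HealthCheck

from fsvkit import SimulationConfig, run_pipeline

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

#: Seed for the shared study-scale simulation.
STUDY_SEED = 1234


@pytest.fixture(scope="session")
def study_config() -> SimulationConfig:
    """Default study-scale configuration: 20 Mb genome across the three
    chromosome size classes, 5 true SNPs/kb, pools of 7+4 at 5.19X/5.53X,
    20 chip individuals per line, 30 kb divergence blocks."""
    return SimulationConfig(rng_seed=STUDY_SEED)


@pytest.fixture(scope="session")
def study_run(study_config):
    """One full pipeline run shared by the evaluation-layer tests."""
    return run_pipeline(study_config)


@pytest.fixture()
def toy_config() -> SimulationConfig:
    """Small 2-chromosome genome for fast end-to-end tests."""
    return SimulationConfig(
        chromosome_lengths={"c1": 600_000, "c2": 400_000},
        chromosome_class_map={"c1": "macro", "c2": "micro"},
        chip_fraction=0.05,
        rng_seed=7,
    )


_CALL_COLS = ["chrom", "pos", "detected_high", "detected_low", "S_high",
              "S_low", "depth_high", "depth_low", "variation_class", "excluded"]


def make_calls(records) -> pd.DataFrame:
    """Build a call table from (chrom, pos, det_h, det_l, S_h, S_l, excluded)."""
    if not records:
        return pd.DataFrame(columns=_CALL_COLS)
    rows = []
    for chrom, pos, det_h, det_l, s_h, s_l, excluded in records:
        rows.append(
            {
                "chrom": chrom,
                "pos": pos,
                "detected_high": det_h,
                "detected_low": det_l,
                "S_high": s_h,
                "S_low": s_l,
                "depth_high": 6,
                "depth_low": 6,
                "variation_class": "one_biallelic",
                "excluded": excluded,
            }
        )
    return pd.DataFrame(rows).sort_values(["chrom", "pos"]).reset_index(drop=True)


def random_calls(rng: np.random.Generator, n: int, length: int = 100_000,
                 chrom: str = "c1") -> pd.DataFrame:
    """Randomised call table for fuzzing the flanking-window statistic."""
    pos = np.sort(rng.choice(np.arange(1, length + 1), size=n, replace=False))
    det_h = rng.random(n) < 0.6
    det_l = rng.random(n) < 0.6
    keep = det_h | det_l
    pos, det_h, det_l = pos[keep], det_h[keep], det_l[keep]
    n = keep.sum()
    s_h = np.where(det_h, rng.random(n), 1.0)
    s_l = np.where(det_l, rng.random(n), 1.0)
    return pd.DataFrame(
        {
            "chrom": chrom,
            "pos": pos,
            "detected_high": det_h,
            "detected_low": det_l,
            "S_high": s_h,
            "S_low": s_l,
            "depth_high": 6,
            "depth_low": 6,
            "variation_class": "one_biallelic",
            "excluded": rng.random(n) < 0.1,
        }
    )
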