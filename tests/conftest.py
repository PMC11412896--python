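"""Shared fixtures: small synthetic cohorts and region fixtures.

Everything is generated programmatically at test time from fixed seeds; no
data files ship with the package.
"""
import numpy as np
import pandas as pd
import pytest

from stratewas.config import CohortConfig
from stratewas.synth import simulate_cohort


@pytest.fixture(scope="session")
def null_cohort():
    """400-sample cohort with no causal probes (2,000 probes)."""
    cfg = CohortConfig(n_cases=200, n_controls=200, n_probes=2000, n_causal=0, seed=11)
    return simulate_cohort(cfg, cohort="NULL")


@pytest.fixture(scope="session")
def null_cohort_large():
    """400-sample null cohort at 10,000 probes for inflation calibration."""
    cfg = CohortConfig(n_cases=200, n_controls=200, n_probes=10_000, n_causal=0, seed=12)
    return simulate_cohort(cfg, cohort="NULL10K")


def make_isolated_cluster_meta(cluster_size: int, seed: int = 5, cluster_p: float = 1e-8,
                               n_flank: int = 1000, flank_bp: int = 800,
                               cluster_bp: int = 100) -> tuple[pd.DataFrame, np.ndarray]:
    """Meta-style table with one planted significant cluster.

    Background probes are spaced ``flank_bp`` apart (beyond the default
    750 bp region gap) so the planted cluster's smoothed p-values cannot
    recruit flanking probes; the cluster itself is densely spaced.
    """
    rng = np.random.default_rng(seed)
    pos_bg1 = 1 + np.arange(n_flank) * flank_bp
    cstart = pos_bg1[-1] + flank_bp
    pos_cl = cstart + np.arange(cluster_size) * cluster_bp
    pos_bg2 = pos_cl[-1] + flank_bp + np.arange(n_flank) * flank_bp
    pos = np.concatenate([pos_bg1, pos_cl, pos_bg2])
    n = len(pos)
    p = rng.uniform(size=n)
    eff = rng.standard_normal(n)
    idx = np.arange(n_flank, n_flank + cluster_size)
    p[idx] = cluster_p
    eff[idx] = 1.0
    table = pd.DataFrame(
        {"probe": [f"cg{i:06d}" for i in range(n)], "chrom": "chr1", "pos": pos,
         "p": p, "effect": eff}
    )
    return table, idx
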