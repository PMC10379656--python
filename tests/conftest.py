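import numpy as np
import pytest

from epiqt import (
    ScanConfig,
    SimulationConfig,
    build_design,
    simulate_dataset,
)


@pytest.fixture(scope="session")
def small_panel():
    """Seeded 200-subject x 60-SNP cohort with one planted interaction pair.

    Returns (genotypes, cohort, truth, y, covariate_block).  Session-scoped:
    everything drawn from it is deterministic.
    """
    cfg = SimulationConfig(
        n_subjects=200,
        n_snps=60,
        planted_pairs=[(0, 1, 0.056)],
        planted_mains=[(2, 0.02)],
        covariate_r2=0.093,
        maf_range=(0.1, 0.5),
        seed=20240601,
    )
    gm, cohort, truth = simulate_dataset(cfg)
    y = np.log(cohort.data["ptau"].to_numpy())
    C, _ = build_design(cohort)
    return gm, cohort, truth, y, C


@pytest.fixture
def full_scan_config():
    return ScanConfig(p_threshold=1.0)
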