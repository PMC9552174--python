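import numpy as np
import pytest

from panelsieve.cohort import CohortDataset
from panelsieve.simulate import SimulationConfig, simulate_cohort


@pytest.fixture(scope="session")
def small_cohort() -> CohortDataset:
    """Deterministic 200-patient cohort with a moderate planted effect."""
    cfg = SimulationConfig(
        n_patients=200,
        n_genes=30,
        n_benefit_genes=5,
        mutation_freq_range=(0.1, 0.4),
        seed=42,
    )
    return simulate_cohort(cfg)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(7)


def make_step_cohort(
    n: int = 1500,
    threshold: int = 3,
    hr_step: float = 0.5,
    max_score: int = 8,
    baseline_hazard: float = 1.0 / 6.0,
    censor_max: float = 36.0,
    seed: int = 0,
) -> tuple[CohortDataset, np.ndarray]:
    """Treated-arm cohort whose hazard is multiplied by ``hr_step`` exactly
    when the benefit score reaches ``threshold``; used as a planted-breakpoint
    fixture for the cutpoint tests."""
    rng = np.random.default_rng(seed)
    genes = [f"G{i:03d}" for i in range(max_score)]
    # score ~ Binomial(max_score, 0.35): wide spread over the cutoff grid
    mutations = (rng.random((n, max_score)) < 0.35).astype(np.int8)
    score = mutations.sum(axis=1)
    hazard = baseline_hazard * np.where(score >= threshold, hr_step, 1.0)
    t = rng.exponential(1.0 / hazard)
    c = rng.uniform(0, censor_max, size=n)
    time = np.maximum(np.minimum(t, c), 1e-9)
    event = (t <= c).astype(int)
    ds = CohortDataset(
        patient_ids=[f"P{i:05d}" for i in range(n)],
        genes=genes,
        mutations=mutations,
        arm=np.array(["treated"] * n, dtype=object),
        pfs_time=time,
        pfs_event=event,
        os_time=time,
        os_event=event,
    )
    return ds, score
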