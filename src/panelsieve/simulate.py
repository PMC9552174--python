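"""Synthetic two-arm randomized cohort generator with a planted benefit-gene panel.

The simulator draws exponential PFS/OS times whose hazard is modulated by the
count of mutated planted genes (the "score"), with opposite effects in the two
arms, plus a logistic response model with a treatment x score interaction.
Constant baseline hazards keep proportional hazards exact, so Cox regression
is an exact recovery oracle for the planted log hazard ratios.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np

from .cohort import CONTROL, TREATED, CohortDataset

DEFAULT_TMB_REGION_MB = 1.1


@dataclass
class SimulationConfig:
    """Parameters of the synthetic randomized-trial generator.

    Effects are on the log-hazard scale per mutated planted gene; positive
    values worsen (increase) the hazard. ``censor_time_max`` applies uniform
    administrative censoring on (0, max]; ``inf`` disables censoring.
    """

    n_patients: int = 850
    n_genes: int = 400
    n_benefit_genes: int = 20
    mutation_freq_range: tuple[float, float] = (0.01, 0.25)
    arm_ratio: float = 0.5
    log_hr_treated_per_mutation: float = np.log(0.8)
    log_hr_control_per_mutation: float = 0.0
    log_hr_treatment_main: float = 0.0
    baseline_hazard_pfs: float = 1.0 / 6.0
    baseline_hazard_os: float = 1.0 / 15.0
    censor_time_max: float = 36.0
    response_intercept: float = -2.0
    response_score_by_arm_slope: float = 0.5
    sld_mean: float = 70.0
    sld_sd: float = 25.0
    seed: int = 0

    def __post_init__(self) -> None:
        lo, hi = self.mutation_freq_range
        if not (0.0 <= lo <= hi <= 1.0):
            raise ValueError("mutation_freq_range must be within [0, 1] with lo <= hi")
        if not 0.0 <= self.arm_ratio <= 1.0:
            raise ValueError("arm_ratio must be a probability")
        if self.n_benefit_genes > self.n_genes:
            raise ValueError("n_benefit_genes must not exceed n_genes")
        if self.n_patients < 1 or self.n_genes < 1:
            raise ValueError("n_patients and n_genes must be positive")
        if self.baseline_hazard_pfs <= 0 or self.baseline_hazard_os <= 0:
            raise ValueError("baseline hazards must be strictly positive")
        if self.censor_time_max <= 0:
            raise ValueError("censor_time_max must be positive (inf disables censoring)")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["mutation_freq_range"] = list(self.mutation_freq_range)
        return d


def simulate_cohort(config: SimulationConfig) -> CohortDataset:
    """Generate a cohort under ``config``; bit-identical for identical seeds.

    Survival times are exponential with hazard
    ``h0 * exp(arm*b_main + arm*score*b_trt + (1-arm)*score*b_ctl)`` where
    ``score`` counts mutated planted genes; censoring is uniform
    administrative; the responder indicator follows
    ``logit p = intercept + arm * slope * score`` and is emitted as PR/PD.
    """
    rng = np.random.default_rng(config.seed)
    n, g = config.n_patients, config.n_genes

    genes = [f"G{i:04d}" for i in range(g)]
    benefit_idx = rng.choice(g, size=config.n_benefit_genes, replace=False)
    truth = sorted(genes[i] for i in benefit_idx)

    lo, hi = config.mutation_freq_range
    freqs = rng.uniform(lo, hi, size=g)
    mutations = (rng.random((n, g)) < freqs).astype(np.int8)

    treated = rng.random(n) < config.arm_ratio
    arm = np.where(treated, TREATED, CONTROL).astype(object)

    score = mutations[:, benefit_idx].sum(axis=1) if len(benefit_idx) else np.zeros(n)
    a = treated.astype(float)
    lp = (
        a * config.log_hr_treatment_main
        + a * score * config.log_hr_treated_per_mutation
        + (1.0 - a) * score * config.log_hr_control_per_mutation
    )

    def _draw_survival(h0: float) -> tuple[np.ndarray, np.ndarray]:
        t = rng.exponential(1.0 / (h0 * np.exp(lp)))
        if np.isinf(config.censor_time_max):
            return np.maximum(t, 1e-9), np.ones(n, dtype=int)
        c = rng.uniform(0.0, config.censor_time_max, size=n)
        time = np.minimum(t, c)
        event = (t <= c).astype(int)
        return np.maximum(time, 1e-9), event

    pfs_time, pfs_event = _draw_survival(config.baseline_hazard_pfs)
    os_time, os_event = _draw_survival(config.baseline_hazard_os)

    logit = config.response_intercept + a * config.response_score_by_arm_slope * score
    p_resp = 1.0 / (1.0 + np.exp(-logit))
    responder = rng.random(n) < p_resp
    response = np.where(responder, "PR", "PD").astype(object)

    sld = np.maximum(rng.normal(config.sld_mean, config.sld_sd, size=n), 1.0)
    tmb = mutations.sum(axis=1) / DEFAULT_TMB_REGION_MB

    return CohortDataset(
        patient_ids=[f"P{i:05d}" for i in range(n)],
        genes=genes,
        mutations=mutations,
        arm=arm,
        pfs_time=pfs_time,
        pfs_event=pfs_event,
        os_time=os_time,
        os_event=os_event,
        response=response,
        sld=sld,
        tmb=tmb,
        truth=truth,
    )


def true_panel(dataset: CohortDataset) -> list[str]:
    """Return the planted benefit genes of a simulated cohort.

    Raises ``ValueError`` for cohorts without ground truth (real data).
    """
    if dataset.truth is None:
        raise ValueError("dataset has no planted truth panel (not a simulated cohort)")
    return list(dataset.truth)
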