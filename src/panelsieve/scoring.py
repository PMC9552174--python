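"""Benefit score, TMB, and dichotomization."""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .cohort import CohortDataset
from .selection import GenePanel

logger = logging.getLogger(__name__)


@dataclass
class ScoringConfig:
    """Scoring thresholds and the TMB normalization basis.

    ``tmb_region_mb`` defaults to the 1.1 Mb coding footprint of the targeted
    assay; ``tmb_high_cutoff`` defaults to the conventional 10 mutations/Mb.
    """

    panel: GenePanel | list[str]
    score_cutoff: int = 2
    tmb_region_mb: float = 1.1
    tmb_high_cutoff: float = 10.0

    def __post_init__(self) -> None:
        if self.tmb_region_mb <= 0:
            raise ValueError("tmb_region_mb must be positive")
        if self.score_cutoff < 0:
            raise ValueError("score_cutoff must be >= 0")

    @property
    def panel_genes(self) -> list[str]:
        return self.panel.genes if isinstance(self.panel, GenePanel) else list(self.panel)


def ici_benefit_score(
    dataset: CohortDataset,
    panel: GenePanel | list[str],
    count_variants: bool = False,
) -> np.ndarray:
    """Per-patient benefit score: number of mutated panel genes.

    Panel genes absent from the dataset contribute 0 (their count is logged).
    ``count_variants`` has no effect on a collapsed binary matrix and is kept
    for score definitions built upstream of collapsing.
    """
    genes = panel.genes if isinstance(panel, GenePanel) else list(panel)
    idx = dataset.gene_index(genes)
    absent = len(genes) - len(idx)
    if absent:
        logger.info("%d panel genes absent from dataset contribute 0", absent)
    if len(idx) == 0:
        return np.zeros(dataset.n_patients, dtype=int)
    return dataset.mutations[:, idx].sum(axis=1).astype(int)


def tmb_per_mb(mutation_count: np.ndarray | float, config: ScoringConfig) -> np.ndarray | float:
    """Mutation counts normalized per sequenced megabase."""
    counts = np.asarray(mutation_count, dtype=float)
    if (counts < 0).any():
        raise ValueError("mutation counts must be non-negative")
    out = counts / config.tmb_region_mb
    return float(out) if out.ndim == 0 else out


def cohort_tmb(dataset: CohortDataset, config: ScoringConfig) -> np.ndarray:
    """Per-patient TMB: the clinical column verbatim when present, otherwise
    total mutated genes / region size (a documented approximation)."""
    if dataset.tmb is not None:
        return np.asarray(dataset.tmb, dtype=float)
    return tmb_per_mb(dataset.mutations.sum(axis=1), config)


def stratify(values: np.ndarray, cutoff: float, direction: str = "ge") -> np.ndarray:
    """Binary group labels: 1 where value >= cutoff ('ge') or > cutoff ('gt')."""
    values = np.asarray(values, dtype=float)
    if direction == "ge":
        groups = (values >= cutoff).astype(int)
    elif direction == "gt":
        groups = (values > cutoff).astype(int)
    else:
        raise ValueError("direction must be 'ge' or 'gt'")
    if len(groups) and len(np.unique(groups)) == 1:
        logger.warning("degenerate stratification: all patients in one stratum")
    return groups
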