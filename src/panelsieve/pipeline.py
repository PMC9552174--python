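"""End-to-end orchestration: simulate/load -> select -> score -> cutpoint -> evaluate.

A single global seed deterministically derives one sub-seed per stage
(SeedSequence spawn keys 0..3 for simulation, selection, bootstrap, and any
auxiliary draws), so each stage can also be re-run standalone with its
logged seed and reproduce the pipeline output bit-identically.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io as psio
from .cohort import CohortDataset
from .cutpoint import hr_curve, select_cutoff
from .evaluation import build_report
from .scoring import ScoringConfig, cohort_tmb, ici_benefit_score, stratify
from .selection import SelectionConfig, select_panel
from .simulate import SimulationConfig, simulate_cohort

logger = logging.getLogger(__name__)

STAGES = ("simulate", "select", "score", "cutpoint", "evaluate")


@dataclass
class RunConfig:
    """Resolved configuration of one pipeline run."""

    output_dir: str
    seed: int = 0
    simulation: dict | None = None
    mutations_path: str | None = None
    clinical_path: str | None = None
    gene_universe_path: str | None = None
    selection: dict = field(default_factory=dict)
    scoring: dict = field(default_factory=dict)
    cutpoint: dict = field(default_factory=dict)
    evaluation: dict = field(default_factory=dict)
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        has_sim = self.simulation is not None
        has_files = self.mutations_path is not None or self.clinical_path is not None
        if has_sim == has_files:
            raise ValueError(
                "exactly one of {simulation, input files} must be supplied"
            )
        if has_files and (self.mutations_path is None or self.clinical_path is None):
            raise ValueError("both mutations_path and clinical_path are required")

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        with open(path, encoding="utf-8") as fh:
            raw = yaml.safe_load(fh)
        return cls(**raw)

    def to_dict(self) -> dict:
        return {
            "output_dir": self.output_dir,
            "seed": self.seed,
            "simulation": self.simulation,
            "mutations_path": self.mutations_path,
            "clinical_path": self.clinical_path,
            "gene_universe_path": self.gene_universe_path,
            "selection": self.selection,
            "scoring": self.scoring,
            "cutpoint": self.cutpoint,
            "evaluation": self.evaluation,
            "log_level": self.log_level,
        }


def derive_stage_seeds(seed: int) -> dict[str, int]:
    """Deterministic per-stage seeds from the global seed."""
    state = np.random.SeedSequence(seed).generate_state(4, dtype=np.uint64)
    return {
        "simulate": int(state[0] % (2**31)),
        "select": int(state[1] % (2**31)),
        "bootstrap": int(state[2] % (2**31)),
        "aux": int(state[3] % (2**31)),
    }


def run_pipeline(config: RunConfig) -> Path:
    """Execute every stage, persisting inputs/outputs and a config snapshot.

    Any stage failure aborts with the stage name; outputs of completed stages
    are left in place.
    """
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    logging.basicConfig(level=config.log_level)
    seeds = derive_stage_seeds(config.seed)

    with open(out / "resolved_config.json", "w", encoding="utf-8") as fh:
        json.dump({"config": config.to_dict(), "stage_seeds": seeds}, fh, indent=2, sort_keys=True)

    stage = "simulate"
    try:
        if config.simulation is not None:
            sim_kwargs = dict(config.simulation)
            sim_kwargs.setdefault("seed", seeds["simulate"])
            if "mutation_freq_range" in sim_kwargs:
                sim_kwargs["mutation_freq_range"] = tuple(sim_kwargs["mutation_freq_range"])
            sim_config = SimulationConfig(**sim_kwargs)
            dataset = simulate_cohort(sim_config)
            psio.write_cohort(dataset, out / "mutations.tsv", out / "clinical.tsv")
            if dataset.truth is not None:
                psio.write_gene_list(dataset.truth, out / "truth_panel.txt")
        else:
            universe = (
                psio.read_gene_list(config.gene_universe_path)
                if config.gene_universe_path
                else None
            )
            dataset = psio.read_cohort(
                config.mutations_path, config.clinical_path, gene_universe=universe
            )

        stage = "select"
        sel_kwargs = dict(config.selection)
        sel_kwargs.setdefault("seed", seeds["select"])
        sel_config = SelectionConfig(**sel_kwargs)
        panel, trace = select_panel(dataset, sel_config)
        psio.write_gene_list(panel.genes, out / "panel.txt")
        pd.DataFrame(
            {"repetition": range(1, len(trace.sizes) + 1), "intersection_size": trace.sizes}
        ).to_csv(out / "stability_trace.tsv", sep="\t", index=False)
        pd.DataFrame(
            [
                {"gene": g, "mean_importance": panel.mean_importance[g],
                 "inclusion_frequency": panel.inclusion_frequency[g]}
                for g in panel.genes
            ]
        ).to_csv(out / "panel_evidence.tsv", sep="\t", index=False)

        stage = "score"
        score = ici_benefit_score(dataset, panel)

        stage = "cutpoint"
        cut_kwargs = dict(config.cutpoint)
        span = cut_kwargs.pop("span", 0.80)
        smooth = cut_kwargs.pop("smooth", True)
        curve = hr_curve(dataset, score, endpoint=cut_kwargs.pop("endpoint", "pfs"),
                         span=span, **cut_kwargs)
        cut = select_cutoff(curve, smooth=smooth)
        curve.frame().to_csv(out / "hr_curve.tsv", sep="\t", index=False)
        with open(out / "cutpoint.json", "w", encoding="utf-8") as fh:
            json.dump(cut.to_dict(), fh, indent=2, sort_keys=True)

        stage = "score"
        scoring_config = ScoringConfig(
            panel=panel, score_cutoff=cut.selected_cutoff, **config.scoring
        )
        tmb = cohort_tmb(dataset, scoring_config)
        scored = dataset.clinical_frame()
        scored["score"] = score
        scored["benefit_group"] = stratify(score, scoring_config.score_cutoff, "ge")
        scored["tmb"] = tmb
        scored["tmb_group"] = stratify(tmb, scoring_config.tmb_high_cutoff, "ge")
        scored.to_csv(out / "scored_cohort.tsv", sep="\t", index=False, float_format="%.12g")

        stage = "evaluate"
        eval_kwargs = dict(config.evaluation)
        report = build_report(
            dataset,
            panel,
            scoring_config,
            n_bootstrap=eval_kwargs.get("n_bootstrap", 2000),
            seed=seeds["bootstrap"],
        )
        report.to_json(out / "report.json")
        pd.DataFrame(
            [dict(contrast=k, **{kk: vv for kk, vv in v.items()
                                 if not isinstance(vv, dict)})
             for k, v in report.contrasts.items()]
        ).to_csv(out / "hr_table.tsv", sep="\t", index=False)
        if report.orr:
            pd.concat(
                [pd.DataFrame(v["table"]).assign(marker=k)
                 for k, v in report.orr.items()]
            ).to_csv(out / "orr_table.tsv", sep="\t", index=False)
        km_rows = [
            {"curve": name, "group": g, "time": t, "survival": s}
            for name, km in report.km.items()
            for g, coords in km["groups"].items()
            for t, s in zip(coords["time"], coords["survival"])
        ]
        if km_rows:
            pd.DataFrame(km_rows).to_csv(out / "km_coordinates.tsv", sep="\t", index=False)
    except Exception as exc:
        raise RuntimeError(f"pipeline failed at stage {stage!r}: {exc}") from exc

    return out
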