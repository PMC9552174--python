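"""Stability-based gene panel selection.

Repeatedly fits a gradient-boosted tree classifier on random stratified
train/validation splits of the treated arm, ranks genes by importance
(held-out permutation importance by default, native split gain optionally),
and returns the intersection of the per-repetition top-k gene sets together
with a stability trace of the running intersection.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, asdict

import numpy as np
from scipy.stats import rankdata
from sklearn.ensemble import HistGradientBoostingClassifier
from sklearn.model_selection import train_test_split

from .cohort import RESPONDER_CATEGORIES, CohortDataset

logger = logging.getLogger(__name__)

MIN_CLASS_TRAIN = 20

DEFAULT_LEARNER_PARAMS = {
    "max_depth": 3,
    "max_iter": 200,
    "learning_rate": 0.1,
    "min_samples_leaf": 10,
    "early_stopping": False,
}


@dataclass
class SelectionConfig:
    """Knobs of the repeated-modeling selection procedure."""

    n_repetitions: int = 350
    train_fraction: float = 0.8
    top_k: int = 150
    label_spec: str = "responder"  # or "pfs_ge_<m>"
    importance: str = "permutation_auc"  # or "native_gain"
    n_permutation_shuffles: int = 5
    stability_window: int = 25
    min_inclusion_fraction: float | None = None  # alternative to strict intersection
    base_learner_params: dict = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.train_fraction < 1.0:
            raise ValueError("train_fraction must be in (0, 1)")
        if self.n_repetitions < 1:
            raise ValueError("n_repetitions must be >= 1")
        if self.top_k < 1:
            raise ValueError("top_k must be >= 1")
        if self.importance not in ("permutation_auc", "native_gain"):
            raise ValueError(f"unknown importance mode: {self.importance!r}")

    def learner_params(self) -> dict:
        params = dict(DEFAULT_LEARNER_PARAMS)
        params.update(self.base_learner_params)
        return params

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class ImportanceRanking:
    """Gene importances and 1-based ranks from one repetition."""

    repetition: int
    importance: dict[str, float]
    rank: dict[str, int]
    validation_metric: float

    def top_genes(self, k: int) -> list[str]:
        order = sorted(self.rank, key=self.rank.get)
        return order[:k]


@dataclass
class StabilityTrace:
    """Running top-k intersection size across repetitions."""

    sizes: list[int]
    plateau: bool
    plateau_start: int | None

    def __post_init__(self) -> None:
        diffs = np.diff(self.sizes)
        if (diffs > 0).any():
            raise ValueError("running intersection size must be non-increasing")


@dataclass
class GenePanel:
    """Selected panel ordered by descending mean importance."""

    genes: list[str]
    mean_importance: dict[str, float]
    inclusion_frequency: dict[str, float]
    config: SelectionConfig | None = None

    def __len__(self) -> int:
        return len(self.genes)


# -- labels -------------------------------------------------------------------


def make_label(dataset: CohortDataset, label_spec: str) -> tuple[np.ndarray, np.ndarray]:
    """Binary training label plus usable-patient mask, on the full cohort index.

    ``responder``: 1 for CR/PR, 0 for SD/PD, NE masked out.
    ``pfs_ge_<m>``: 1 if pfs_time >= m; 0 if progression/death before m;
    patients censored before m are masked out (label unknowable).
    """
    n = dataset.n_patients
    labels = np.zeros(n, dtype=int)
    mask = np.zeros(n, dtype=bool)
    if label_spec == "responder":
        if dataset.response is None:
            raise ValueError("label_spec='responder' requires a response column")
        for i, r in enumerate(dataset.response):
            if r == "NE":
                continue
            mask[i] = True
            labels[i] = int(r in RESPONDER_CATEGORIES)
    elif label_spec.startswith("pfs_ge_"):
        try:
            m = float(label_spec.removeprefix("pfs_ge_"))
        except ValueError as exc:
            raise ValueError(f"cannot parse months from label spec {label_spec!r}") from exc
        at_least = dataset.pfs_time >= m
        event_before = (dataset.pfs_time < m) & (dataset.pfs_event == 1)
        mask = at_least | event_before
        labels = at_least.astype(int)
    else:
        raise ValueError(f"unknown label spec: {label_spec!r}")
    return labels, mask


# -- single repetition --------------------------------------------------------


def _fast_auc(y: np.ndarray, score: np.ndarray) -> float:
    """Mann-Whitney AUC with midrank tie handling (no input validation)."""
    n1 = int(y.sum())
    n0 = len(y) - n1
    ranks = rankdata(score)
    return float((ranks[y == 1].sum() - n1 * (n1 + 1) / 2.0) / (n1 * n0))


def _fit_learner(X_train, y_train, params: dict, seed: int) -> HistGradientBoostingClassifier:
    model = HistGradientBoostingClassifier(random_state=seed, **params)
    model.fit(X_train, y_train)
    return model


def _native_gain(model: HistGradientBoostingClassifier, n_features: int) -> np.ndarray:
    """Total split gain per feature, summed over all trees."""
    gain = np.zeros(n_features)
    for stage in model._predictors:
        for predictor in stage:
            nodes = predictor.nodes
            internal = nodes["is_leaf"] == 0
            np.add.at(gain, nodes["feature_idx"][internal], nodes["gain"][internal])
    return gain


def _permutation_auc_importance(
    model,
    X_val: np.ndarray,
    y_val: np.ndarray,
    n_shuffles: int,
    rng: np.random.Generator,
    candidates: np.ndarray | None = None,
) -> np.ndarray:
    """Mean decrease in validation AUC when one gene column is shuffled.

    Exploits the binary feature encoding: predictions under any shuffle of a
    0/1 column are a row-wise mix of the two forced-value predictions
    (column set to all-0 and all-1), so each gene costs two batched model
    evaluations regardless of ``n_shuffles``. ``candidates`` restricts the
    scan to genes that can have nonzero importance (e.g. genes the model
    actually split on); all other genes get importance 0.
    """
    n_val, n_genes = X_val.shape
    X_val = X_val.astype(np.float32)
    base_auc = _fast_auc(y_val, model.predict_proba(X_val)[:, 1])
    drops = np.zeros(n_genes)
    if candidates is None:
        candidates = np.arange(n_genes)
    candidates = np.asarray(candidates, dtype=int)
    if len(candidates) == 0:
        return drops
    if not np.isin(X_val, (0.0, 1.0)).all():
        raise ValueError("permutation importance expects a binary matrix")

    base_proba = model.predict_proba(X_val)[:, 1]

    # Forcing column j to v only changes predictions on rows where the column
    # differs from v, so exactly n_val rows per gene need re-prediction;
    # batch them (~100k rows per predict_proba call).
    chunk = max(1, 100_000 // max(n_val, 1))
    for start in range(0, len(candidates), chunk):
        cols = candidates[start : start + chunk]
        stacked, spans = [], []
        for j in cols:
            ones = np.flatnonzero(X_val[:, j] == 1.0)
            zeros = np.flatnonzero(X_val[:, j] == 0.0)
            X0 = X_val[ones].copy()
            X0[:, j] = 0.0
            X1 = X_val[zeros].copy()
            X1[:, j] = 1.0
            stacked.extend((X0, X1))
            spans.append((j, ones, zeros))
        proba = model.predict_proba(np.vstack(stacked))[:, 1]
        pos = 0
        for j, ones, zeros in spans:
            p0 = base_proba.copy()
            p0[ones] = proba[pos : pos + len(ones)]
            pos += len(ones)
            p1 = base_proba.copy()
            p1[zeros] = proba[pos : pos + len(zeros)]
            pos += len(zeros)
            col = X_val[:, j]
            acc = 0.0
            for _ in range(n_shuffles):
                shuffled = col[rng.permutation(n_val)]
                pred = np.where(shuffled == 1.0, p1, p0)
                acc += base_auc - _fast_auc(y_val, pred)
            drops[j] = acc / n_shuffles
    return drops


def _rank_genes(genes: list[str], importance: np.ndarray, used: np.ndarray) -> dict[str, int]:
    """Ranks 1..n: importance desc, symbol asc; never-used zero-importance
    genes are placed after every gene with signal, alphabetically."""
    dead = (~used) & (importance == 0)
    order = sorted(
        range(len(genes)),
        key=lambda j: (dead[j], -importance[j], genes[j]),
    )
    return {genes[j]: r + 1 for r, j in enumerate(order)}


def run_repetition(
    dataset: CohortDataset,
    labels: np.ndarray,
    config: SelectionConfig,
    repetition_seed: int,
    repetition: int = 0,
) -> ImportanceRanking:
    """One stratified split + fit + importance ranking over all genes."""
    X = dataset.mutations.astype(np.float64)
    y = np.asarray(labels, dtype=int)
    if len(np.unique(y)) < 2:
        raise ValueError("degenerate label: only one class present")
    if dataset.n_genes < config.top_k:
        raise ValueError(
            f"fewer genes ({dataset.n_genes}) than top_k ({config.top_k})"
        )

    X_train, X_val, y_train, y_val = train_test_split(
        X,
        y,
        train_size=config.train_fraction,
        stratify=y,
        random_state=repetition_seed % (2**32),
    )
    counts = np.bincount(y_train, minlength=2)
    if counts.min() < MIN_CLASS_TRAIN:
        raise ValueError(
            f"need >= {MIN_CLASS_TRAIN} training patients per class, got {counts.tolist()}"
        )

    model = _fit_learner(X_train, y_train, config.learner_params(), repetition_seed % (2**32))
    val_auc = _fast_auc(y_val, model.predict_proba(X_val)[:, 1])

    used = np.zeros(dataset.n_genes, dtype=bool)
    for stage in model._predictors:
        for predictor in stage:
            nodes = predictor.nodes
            used[np.unique(nodes["feature_idx"][nodes["is_leaf"] == 0])] = True
    # constant (e.g. all-zero) columns can never be split on
    used &= X.min(axis=0) != X.max(axis=0)

    if config.importance == "native_gain":
        imp = _native_gain(model, dataset.n_genes)
    else:
        rng = np.random.default_rng(repetition_seed)
        # unused features cannot change predictions: importance exactly 0
        imp = _permutation_auc_importance(
            model, X_val, y_val, config.n_permutation_shuffles, rng,
            candidates=np.flatnonzero(used),
        )

    rank = _rank_genes(dataset.genes, imp, used)
    return ImportanceRanking(
        repetition=repetition,
        importance=dict(zip(dataset.genes, imp.tolist())),
        rank=rank,
        validation_metric=float(val_auc),
    )


# -- full selection -----------------------------------------------------------


def select_panel(
    dataset: CohortDataset,
    config: SelectionConfig,
    labels: np.ndarray | None = None,
    mask: np.ndarray | None = None,
) -> tuple[GenePanel, StabilityTrace]:
    """Run the full repeated-modeling selection on the treated, labeled subset.

    Panel = strict intersection of the per-repetition top-k gene sets (or, if
    ``min_inclusion_fraction`` is set, genes in the top-k of at least that
    fraction of repetitions), ordered by mean importance across repetitions.
    """
    if labels is None or mask is None:
        labels, mask = make_label(dataset, config.label_spec)
    usable = mask & dataset.treated_mask
    sub = dataset.subset(usable)
    y = labels[usable]
    if len(np.unique(y)) < 2:
        raise ValueError("degenerate label: only one class present in treated labeled subset")

    seeds = np.random.SeedSequence(config.seed).generate_state(config.n_repetitions, dtype=np.uint64)
    rankings: list[ImportanceRanking] = []
    running: set[str] | None = None
    sizes: list[int] = []
    inclusion = dict.fromkeys(dataset.genes, 0)
    imp_sum = dict.fromkeys(dataset.genes, 0.0)

    for r in range(config.n_repetitions):
        ranking = run_repetition(sub, y, config, int(seeds[r]), repetition=r)
        rankings.append(ranking)
        top = set(ranking.top_genes(config.top_k))
        for g in top:
            inclusion[g] += 1
        for g, v in ranking.importance.items():
            imp_sum[g] += v
        running = top if running is None else (running & top)
        sizes.append(len(running))

    plateau_start = None
    w = config.stability_window
    if w >= 1 and len(sizes) >= w:
        for i in range(len(sizes) - w + 1):
            if len(set(sizes[i : i + w])) == 1:
                plateau_start = i
                break
    trace = StabilityTrace(sizes=sizes, plateau=plateau_start is not None, plateau_start=plateau_start)

    n_reps = config.n_repetitions
    if config.min_inclusion_fraction is not None:
        selected = {g for g, c in inclusion.items() if c / n_reps >= config.min_inclusion_fraction}
    else:
        selected = running or set()
    if not selected:
        logger.warning("final top-%d intersection is empty", config.top_k)

    mean_imp = {g: imp_sum[g] / n_reps for g in dataset.genes}
    ordered = sorted(selected, key=lambda g: (-mean_imp[g], g))
    panel = GenePanel(
        genes=ordered,
        mean_importance={g: mean_imp[g] for g in ordered},
        inclusion_frequency={g: inclusion[g] / n_reps for g in ordered},
        config=config,
    )
    panel.rankings = rankings  # full per-repetition evidence, kept for export
    panel.all_inclusion_frequency = {g: c / n_reps for g, c in inclusion.items()}
    return panel, trace


def restrict_panel(panel: GenePanel, assay_genes: list[str]) -> GenePanel:
    """Intersect a panel with another assay's gene universe, keeping order."""
    assay = set(assay_genes)
    kept = [g for g in panel.genes if g in assay]
    dropped = len(panel.genes) - len(kept)
    if dropped:
        logger.info("restrict_panel: dropped %d genes not in assay", dropped)
    if not kept:
        logger.warning("restrict_panel: no panel genes detectable on assay")
    return GenePanel(
        genes=kept,
        mean_importance={g: panel.mean_importance[g] for g in kept},
        inclusion_frequency={g: panel.inclusion_frequency[g] for g in kept},
        config=panel.config,
    )
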