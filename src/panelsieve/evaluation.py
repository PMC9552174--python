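"""Survival contrasts, response tables, discrimination, and the full
score-vs-TMB evaluation report."""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.statistics import multivariate_logrank_test
from scipy import stats

from .cohort import RESPONDER_CATEGORIES, CONTROL, TREATED, CohortDataset
from .scoring import ScoringConfig, cohort_tmb, ici_benefit_score, stratify

logger = logging.getLogger(__name__)


@dataclass
class SurvivalContrast:
    """One univariate Cox comparison, optionally with group medians."""

    label: str
    hr: float
    ci_low: float
    ci_high: float
    coef: float
    se: float
    wald: float
    p: float
    logrank_p: float | None = None
    medians: dict[str, float | None] | None = None
    group_n: dict[str, int] | None = None
    group_events: dict[str, int] | None = None


class UnidentifiableError(ValueError):
    """Cox model cannot be fit (constant covariate or no events)."""


def fit_cox(
    time: np.ndarray,
    event: np.ndarray,
    covariate: np.ndarray,
    covariate_kind: str = "continuous",
    label: str = "cox",
) -> SurvivalContrast:
    """Univariate Cox proportional-hazards fit (Efron ties, Wald CI).

    For a binary covariate the contrast also carries per-group sizes, event
    counts, KM medians, and the two-sided log-rank p.
    """
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=int)
    covariate = np.asarray(covariate, dtype=float)
    if covariate_kind not in ("continuous", "binary"):
        raise ValueError("covariate_kind must be 'continuous' or 'binary'")
    if len(np.unique(covariate)) < 2:
        raise UnidentifiableError("unidentifiable: covariate is constant")
    if event.sum() == 0:
        raise UnidentifiableError("unidentifiable: no events observed")

    df = pd.DataFrame({"time": time, "event": event, "x": covariate})
    cph = CoxPHFitter()
    cph.fit(df, duration_col="time", event_col="event")
    coef = float(cph.params_["x"])
    se = float(cph.standard_errors_["x"])
    z = coef / se
    contrast = SurvivalContrast(
        label=label,
        hr=float(np.exp(coef)),
        ci_low=float(np.exp(coef - 1.959963984540054 * se)),
        ci_high=float(np.exp(coef + 1.959963984540054 * se)),
        coef=coef,
        se=se,
        wald=float(z * z),
        p=float(2.0 * stats.norm.sf(abs(z))),
    )
    if covariate_kind == "binary":
        groups = covariate.astype(int)
        km = km_curve(time, event, groups)
        contrast.logrank_p = km["logrank_p"]
        contrast.medians = {k: v["median"] for k, v in km["groups"].items()}
        contrast.group_n = {k: v["n"] for k, v in km["groups"].items()}
        contrast.group_events = {k: v["events"] for k, v in km["groups"].items()}
    return contrast


def km_curve(time: np.ndarray, event: np.ndarray, groups: np.ndarray) -> dict:
    """Kaplan-Meier product-limit curves per group plus a log-rank test.

    Returns ``{"groups": {label: {"time": [...], "survival": [...],
    "median": float | None, "n": int, "events": int}}, "logrank_p": float}``.
    Medians that are never reached are reported as ``None``.
    """
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=int)
    groups = np.asarray(groups)
    out: dict = {"groups": {}, "logrank_p": None}
    for gval in np.unique(groups):
        sel = groups == gval
        if sel.sum() == 0:
            raise ValueError(f"empty group {gval!r}")
        kmf = KaplanMeierFitter()
        kmf.fit(time[sel], event[sel])
        sf = kmf.survival_function_
        surv = sf.iloc[:, 0].to_numpy()
        ts = sf.index.to_numpy(dtype=float)
        median = kmf.median_survival_time_
        out["groups"][str(gval)] = {
            "time": ts.tolist(),
            "survival": surv.tolist(),
            "median": None if np.isinf(median) else float(median),
            "n": int(sel.sum()),
            "events": int(event[sel].sum()),
        }
    if len(np.unique(groups)) >= 2:
        lr = multivariate_logrank_test(time, groups, event)
        out["logrank_p"] = float(lr.p_value)
    return out


@dataclass
class ORRTable:
    """Objective response rates per stratum x arm, NE excluded."""

    table: pd.DataFrame
    differences: dict[str, float] = field(default_factory=dict)
    flags: list[str] = field(default_factory=list)


def orr_compare(dataset: CohortDataset, strata: np.ndarray, stratum_names: tuple[str, str] = ("non-benefit", "benefit")) -> ORRTable:
    """ORR (CR+PR over evaluable) per stratum and arm with absolute differences."""
    if dataset.response is None:
        raise ValueError("ORR requires a response column")
    strata = np.asarray(strata, dtype=int)
    evaluable = dataset.response != "NE"
    responder = np.isin(dataset.response, RESPONDER_CATEGORIES)

    rows, flags = [], []
    orr = {}
    for s, sname in zip((0, 1), stratum_names):
        for arm in (TREATED, CONTROL):
            sel = evaluable & (strata == s) & (dataset.arm == arm)
            n = int(sel.sum())
            r = int(responder[sel].sum())
            if n == 0:
                flags.append(f"empty stratum: {sname}/{arm}")
                orr[(sname, arm)] = np.nan
            else:
                orr[(sname, arm)] = r / n
            rows.append({"stratum": sname, "arm": arm, "n": n, "responders": r,
                         "orr": orr[(sname, arm)]})
    diffs = {
        f"{TREATED}_vs_{CONTROL}_in_{stratum_names[1]}": orr[(stratum_names[1], TREATED)] - orr[(stratum_names[1], CONTROL)],
        f"{TREATED}_vs_{CONTROL}_in_{stratum_names[0]}": orr[(stratum_names[0], TREATED)] - orr[(stratum_names[0], CONTROL)],
        f"{stratum_names[1]}_vs_{stratum_names[0]}_in_{TREATED}": orr[(stratum_names[1], TREATED)] - orr[(stratum_names[0], TREATED)],
        f"{stratum_names[1]}_vs_{stratum_names[0]}_in_{CONTROL}": orr[(stratum_names[1], CONTROL)] - orr[(stratum_names[0], CONTROL)],
    }
    return ORRTable(table=pd.DataFrame(rows), differences=diffs, flags=flags)


def responder_auc(
    marker: np.ndarray,
    labels: np.ndarray,
    n_bootstrap: int = 2000,
    seed: int = 0,
) -> tuple[float, tuple[float, float]]:
    """Mann-Whitney AUC (ties get 0.5 credit) with a percentile bootstrap CI."""
    marker = np.asarray(marker, dtype=float)
    labels = np.asarray(labels, dtype=int)
    if set(np.unique(labels)) != {0, 1}:
        raise ValueError("both responder classes must be present")

    def _auc(m, y):
        n1 = int(y.sum())
        n0 = len(y) - n1
        ranks = stats.rankdata(m)
        return (ranks[y == 1].sum() - n1 * (n1 + 1) / 2.0) / (n1 * n0)

    point = float(_auc(marker, labels))
    rng = np.random.default_rng(seed)
    boots = []
    n = len(labels)
    for _ in range(n_bootstrap):
        idx = rng.integers(0, n, size=n)
        y = labels[idx]
        if y.sum() == 0 or y.sum() == n:
            continue
        boots.append(_auc(marker[idx], y))
    if boots:
        lo, hi = np.percentile(boots, [2.5, 97.5])
    else:
        lo = hi = np.nan
    return point, (float(lo), float(hi))


def spearman_rho(a: np.ndarray, b: np.ndarray) -> tuple[float, float]:
    """Spearman rank correlation with pairwise-complete missing handling."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) != len(b):
        raise ValueError("inputs must have equal length")
    ok = ~(np.isnan(a) | np.isnan(b))
    if ok.sum() < 3:
        raise ValueError("need at least 3 complete pairs")
    rho, p = stats.spearmanr(a[ok], b[ok])
    return float(rho), float(p)


# -- full report ---------------------------------------------------------------


@dataclass
class EvaluationReport:
    """All score-vs-TMB contrasts on one cohort; JSON-serializable."""

    contrasts: dict[str, dict]
    orr: dict
    auc: dict[str, dict]
    spearman: dict[str, dict]
    km: dict[str, dict]
    flags: list[str]
    config: dict

    def to_dict(self) -> dict:
        return asdict(self)

    def to_json(self, path: str | Path | None = None) -> str:
        text = json.dumps(self.to_dict(), indent=2, sort_keys=True, allow_nan=True)
        if path is not None:
            Path(path).write_text(text, encoding="utf-8")
        return text

    @classmethod
    def from_json(cls, text: str) -> "EvaluationReport":
        return cls(**json.loads(text))


def _try_cox(contrasts, flags, key, *args, **kwargs):
    try:
        contrasts[key] = asdict(fit_cox(*args, label=key, **kwargs))
    except (UnidentifiableError, ValueError) as exc:
        flags.append(f"{key}: {exc}")


def build_report(
    dataset: CohortDataset,
    panel,
    scoring_config: ScoringConfig,
    n_bootstrap: int = 2000,
    seed: int = 0,
) -> EvaluationReport:
    """Head-to-head evaluation of the panel score against TMB.

    For each marker (score, TMB) and endpoint (PFS, OS): the continuous Cox
    HR per arm, the dichotomized benefit-vs-non-benefit HR per arm, and the
    treated-vs-control HR within each stratum; plus ORR tables, responder
    AUCs in the treated arm, Spearman correlations, and KM coordinates.
    """
    score = ici_benefit_score(dataset, panel)
    tmb = cohort_tmb(dataset, scoring_config)
    benefit = stratify(score, scoring_config.score_cutoff, "ge")
    tmb_high = stratify(tmb, scoring_config.tmb_high_cutoff, "ge")

    contrasts: dict[str, dict] = {}
    flags: list[str] = []
    endpoints = {
        "pfs": (dataset.pfs_time, dataset.pfs_event),
        "os": (dataset.os_time, dataset.os_event),
    }
    arms = {TREATED: dataset.arm == TREATED, CONTROL: dataset.arm == CONTROL}
    for arm, arm_mask in arms.items():
        if arm_mask.sum() == 0:
            flags.append(f"missing arm: {arm}")
            continue
        for ep, (t, e) in endpoints.items():
            for marker_name, cont, strat in (
                ("score", score, benefit),
                ("tmb", tmb, tmb_high),
            ):
                _try_cox(contrasts, flags, f"{marker_name}_continuous_{ep}_{arm}",
                         t[arm_mask], e[arm_mask], cont[arm_mask], "continuous")
                _try_cox(contrasts, flags, f"{marker_name}_group_{ep}_{arm}",
                         t[arm_mask], e[arm_mask], strat[arm_mask], "binary")

    # treated vs control inside each stratum
    arm_binary = (dataset.arm == TREATED).astype(int)
    for ep, (t, e) in endpoints.items():
        for marker_name, strat in (("score", benefit), ("tmb", tmb_high)):
            for s, sname in ((1, "benefit"), (0, "non_benefit")):
                sel = strat == s
                if sel.sum() == 0:
                    flags.append(f"empty stratum {marker_name}/{sname}")
                    continue
                _try_cox(contrasts, flags, f"arm_within_{marker_name}_{sname}_{ep}",
                         t[sel], e[sel], arm_binary[sel], "binary")

    orr_out: dict = {}
    if dataset.response is not None:
        score_orr = orr_compare(dataset, benefit)
        tmb_orr = orr_compare(dataset, tmb_high, stratum_names=("tmb-low", "tmb-high"))
        orr_out = {
            "score": {"table": score_orr.table.to_dict(orient="records"),
                      "differences": score_orr.differences, "flags": score_orr.flags},
            "tmb": {"table": tmb_orr.table.to_dict(orient="records"),
                    "differences": tmb_orr.differences, "flags": tmb_orr.flags},
        }
    else:
        flags.append("no response column: ORR and AUC skipped")

    auc_out: dict = {}
    if dataset.response is not None:
        treated = dataset.arm == TREATED
        evaluable = treated & (dataset.response != "NE")
        y = np.isin(dataset.response, RESPONDER_CATEGORIES).astype(int)[evaluable]
        if 0 < y.sum() < len(y):
            for name, marker in (("score", score), ("tmb", tmb)):
                a, (lo, hi) = responder_auc(marker[evaluable], y, n_bootstrap, seed)
                auc_out[name] = {"auc": a, "ci_low": lo, "ci_high": hi}
        else:
            flags.append("degenerate responder labels in treated arm: AUC skipped")

    spearman_out: dict = {}
    try:
        rho, p = spearman_rho(score, tmb)
        spearman_out["score_vs_tmb"] = {"rho": rho, "p": p}
    except ValueError as exc:
        flags.append(f"spearman score~tmb: {exc}")
    if dataset.sld is not None:
        try:
            rho, p = spearman_rho(score.astype(float), dataset.sld)
            spearman_out["score_vs_sld"] = {"rho": rho, "p": p}
        except ValueError as exc:
            flags.append(f"spearman score~sld: {exc}")

    km_out: dict = {}
    for ep, (t, e) in endpoints.items():
        for arm, arm_mask in arms.items():
            if arm_mask.sum() and len(np.unique(benefit[arm_mask])) == 2:
                km_out[f"score_group_{ep}_{arm}"] = km_curve(
                    t[arm_mask], e[arm_mask], benefit[arm_mask]
                )

    return EvaluationReport(
        contrasts=contrasts,
        orr=orr_out,
        auc=auc_out,
        spearman=spearman_out,
        km=km_out,
        flags=flags,
        config={
            "score_cutoff": scoring_config.score_cutoff,
            "tmb_region_mb": scoring_config.tmb_region_mb,
            "tmb_high_cutoff": scoring_config.tmb_high_cutoff,
            "n_bootstrap": n_bootstrap,
            "seed": seed,
            "panel_size": len(panel.genes if hasattr(panel, "genes") else panel),
        },
    )
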