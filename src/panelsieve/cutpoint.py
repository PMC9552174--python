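"""Score-threshold selection from the hazard-ratio curve.

Scans Cox PFS hazard ratios of (score >= c) vs (score < c) over all candidate
cutoffs in the treated arm, smooths the Wald-statistic curve with LOESS
(span 0.80), and locates the structural breakpoint by maximizing the Chow
F statistic over all admissible breaks.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .cohort import CohortDataset, TREATED
from .evaluation import UnidentifiableError, fit_cox

logger = logging.getLogger(__name__)

MIN_SEGMENT = 3  # points per side of a Chow break (2-parameter linear model)


@dataclass
class HRCurve:
    """Per-cutoff Cox points plus LOESS-smoothed counterparts."""

    cutoffs: list[int]
    n_at_or_above: list[int]
    hr: list[float]
    ci_low: list[float]
    ci_high: list[float]
    wald: list[float]
    smoothed_wald: list[float] | None = None
    smoothed_hr: list[float] | None = None
    skipped: list[dict] = field(default_factory=list)

    def __post_init__(self) -> None:
        c = np.asarray(self.cutoffs)
        if len(c) and not (np.diff(c) > 0).all():
            raise ValueError("cutoffs must be strictly increasing")
        if any(h <= 0 for h in self.hr):
            raise ValueError("hazard ratios must be positive")
        if any(w < 0 for w in self.wald):
            raise ValueError("Wald statistics must be non-negative")

    def frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "cutoff": self.cutoffs,
                "n_at_or_above": self.n_at_or_above,
                "hr": self.hr,
                "ci_low": self.ci_low,
                "ci_high": self.ci_high,
                "wald": self.wald,
                "smoothed_wald": self.smoothed_wald,
                "smoothed_hr": self.smoothed_hr,
            }
        )


@dataclass
class CutpointResult:
    """Chosen threshold and the Chow-test evidence behind it."""

    selected_cutoff: int
    chow: list[dict]  # {"cutoff", "f", "p"} per candidate break
    elbow_range: tuple[int, int] | None
    significant_break: bool
    flags: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        return asdict(self)


def hr_curve(
    dataset: CohortDataset,
    scores: np.ndarray,
    arm: str = TREATED,
    endpoint: str = "pfs",
    min_group_size: int = 20,
    min_events: int = 5,
    span: float = 0.80,
) -> HRCurve:
    """Cox HR of (score >= c) vs (score < c) at every retained cutoff.

    The grid is 1..max(score); cutoffs where either stratum has fewer than
    ``min_group_size`` patients or ``min_events`` events are skipped and
    flagged. Raises when fewer than 3 cutoffs survive.
    """
    if endpoint not in ("pfs", "os"):
        raise ValueError("endpoint must be 'pfs' or 'os'")
    scores = np.asarray(scores, dtype=int)
    sel = dataset.arm == arm
    if sel.sum() == 0:
        raise ValueError(f"no patients in arm {arm!r}")
    s = scores[sel]
    time = (dataset.pfs_time if endpoint == "pfs" else dataset.os_time)[sel]
    event = (dataset.pfs_event if endpoint == "pfs" else dataset.os_event)[sel]

    cutoffs, n_above, hrs, lo, hi, wald, skipped = [], [], [], [], [], [], []
    for c in range(1, int(s.max()) + 1):
        grp = (s >= c).astype(int)
        n1, n0 = int(grp.sum()), int((1 - grp).sum())
        e1, e0 = int(event[grp == 1].sum()), int(event[grp == 0].sum())
        if min(n1, n0) < min_group_size or min(e1, e0) < min_events:
            skipped.append({"cutoff": c, "reason": "degenerate stratum",
                            "n": [n0, n1], "events": [e0, e1]})
            continue
        try:
            fit = fit_cox(time, event, grp, "binary", label=f"score>={c}")
        except (UnidentifiableError, Exception) as exc:  # lifelines convergence
            skipped.append({"cutoff": c, "reason": str(exc)})
            continue
        cutoffs.append(c)
        n_above.append(n1)
        hrs.append(fit.hr)
        lo.append(fit.ci_low)
        hi.append(fit.ci_high)
        wald.append(fit.wald)

    if len(cutoffs) < 3:
        raise ValueError("curve too short for breakpoint analysis "
                         f"({len(cutoffs)} retained cutoffs)")

    x = np.asarray(cutoffs, dtype=float)
    curve = HRCurve(
        cutoffs=cutoffs, n_at_or_above=n_above, hr=hrs,
        ci_low=lo, ci_high=hi, wald=wald, skipped=skipped,
    )
    if len(cutoffs) >= 4:
        curve.smoothed_wald = loess_smooth(x, np.asarray(wald), span=span).tolist()
        curve.smoothed_hr = loess_smooth(x, np.log(hrs), span=span)
        curve.smoothed_hr = np.exp(curve.smoothed_hr).tolist()
    return curve


def loess_smooth(x: np.ndarray, y: np.ndarray, span: float = 0.80) -> np.ndarray:
    """LOESS: local linear regression with tricube weights, evaluated at x.

    Values are returned in input order. Requires at least 4 points and a
    span in (0, 1].
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y):
        raise ValueError("x and y must have equal length")
    if len(x) < 4:
        raise ValueError("LOESS needs at least 4 points")
    if not 0.0 < span <= 1.0:
        raise ValueError("span must be in (0, 1]")
    fitted = sm.nonparametric.lowess(
        y, x, frac=span, it=0, return_sorted=False
    )
    return np.asarray(fitted, dtype=float)


def chow_statistic(x: np.ndarray, y: np.ndarray, break_index: int) -> tuple[float, float]:
    """Chow F test for a structural break of the linear model y ~ x.

    The break splits the data into ``x[:break_index+1]`` and
    ``x[break_index+1:]``; each segment needs at least 3 points. F is
    ``[(RSS_pooled - RSS1 - RSS2)/2] / [(RSS1 + RSS2)/(n - 4)]`` with the
    p-value from F(2, n-4). When all three regressions have zero residual
    variance, F is 0 by the no-break convention.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(x)
    if len(y) != n:
        raise ValueError("x and y must have equal length")
    n1 = break_index + 1
    n2 = n - n1
    if n1 < MIN_SEGMENT or n2 < MIN_SEGMENT:
        raise ValueError(
            f"segment too short for break at index {break_index}: sizes {n1}, {n2}"
        )

    def _rss(xs, ys):
        X = np.column_stack([np.ones_like(xs), xs])
        beta, *_ = np.linalg.lstsq(X, ys, rcond=None)
        r = ys - X @ beta
        return float(r @ r)

    rss_p = _rss(x, y)
    rss_1 = _rss(x[:n1], y[:n1])
    rss_2 = _rss(x[n1:], y[n1:])
    # exactly (or numerically) linear data: no-break convention
    tol = 1e-12 * max(1.0, float(y @ y))
    if rss_p <= tol:
        return 0.0, 1.0
    denom = (rss_1 + rss_2) / (n - 4)
    num = (rss_p - rss_1 - rss_2) / 2.0
    if denom <= tol:
        return float("inf"), 0.0
    f = num / denom
    f = max(f, 0.0)
    p = float(stats.f.sf(f, 2, n - 4))
    return float(f), p


def select_cutoff(curve: HRCurve, smooth: bool = True, alpha: float = 0.05) -> CutpointResult:
    """Pick the breakpoint cutoff from the (smoothed) Wald-vs-cutoff curve.

    Chow F is computed at every admissible break; the selected cutoff is the
    maximal-F break with p < ``alpha``. Without a significant break the
    cutoff maximizing the raw Wald statistic is returned with a
    "no significant structural break" flag. The elbow range is the contiguous
    cutoff interval around the best break whose F >= max(F)/2.
    """
    x = np.asarray(curve.cutoffs, dtype=float)
    if smooth and curve.smoothed_wald is not None:
        y = np.asarray(curve.smoothed_wald, dtype=float)
    else:
        y = np.asarray(curve.wald, dtype=float)
        if smooth:
            logger.info("smoothed curve unavailable; using raw Wald values")

    n = len(x)
    flags: list[str] = []
    chow_rows: list[dict] = []
    for i in range(MIN_SEGMENT - 1, n - MIN_SEGMENT):
        f, p = chow_statistic(x, y, i)
        chow_rows.append({"cutoff": int(curve.cutoffs[i]), "f": f, "p": p})

    if not chow_rows:
        # curve shorter than 2*MIN_SEGMENT points: no admissible break
        flags.append("curve too short for Chow test; raw Wald maximum used")
        selected = int(curve.cutoffs[int(np.argmax(curve.wald))])
        return CutpointResult(
            selected_cutoff=selected, chow=[], elbow_range=None,
            significant_break=False, flags=flags,
        )

    fs = np.array([r["f"] for r in chow_rows])
    ps = np.array([r["p"] for r in chow_rows])
    best = int(np.argmax(fs))
    significant = bool(ps[best] < alpha)
    if significant:
        selected = chow_rows[best]["cutoff"]
    else:
        flags.append("no significant structural break")
        selected = int(curve.cutoffs[int(np.argmax(curve.wald))])

    # contiguous run of breaks with F >= max/2, bracketing the best break
    half = fs.max() / 2.0 if fs.max() > 0 else 0.0
    lo = hi = best
    while lo > 0 and fs[lo - 1] >= half:
        lo -= 1
    while hi < len(fs) - 1 and fs[hi + 1] >= half:
        hi += 1
    elbow = (chow_rows[lo]["cutoff"], chow_rows[hi]["cutoff"]) if fs.max() > 0 else None

    if curve.skipped:
        flags.append(f"{len(curve.skipped)} degenerate cutoffs excluded from grid")
    return CutpointResult(
        selected_cutoff=int(selected),
        chow=chow_rows,
        elbow_range=elbow,
        significant_break=significant,
        flags=flags,
    )
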