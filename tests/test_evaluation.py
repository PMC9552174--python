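import json

import numpy as np
import pytest

from panelsieve.cohort import CohortDataset
from panelsieve.evaluation import (
    EvaluationReport,
    UnidentifiableError,
    build_report,
    fit_cox,
    km_curve,
    orr_compare,
    responder_auc,
    spearman_rho,
)
from panelsieve.scoring import ScoringConfig
from panelsieve.simulate import SimulationConfig, simulate_cohort


def auc_oracle(marker, labels):
    """Exhaustive average over all (positive, negative) pairs."""
    pos = marker[labels == 1]
    neg = marker[labels == 0]
    wins = 0.0
    for p in pos:
        for q in neg:
            wins += 1.0 if p > q else (0.5 if p == q else 0.0)
    return wins / (len(pos) * len(neg))


class TestFitCox:
    def test_recovers_true_hr_two(self):
        rng = np.random.default_rng(2)
        n = 2000
        group = rng.integers(0, 2, size=n)
        t = rng.exponential(1.0 / (0.1 * np.exp(np.log(2.0) * group)))
        c = rng.exponential(1.0 / 0.042, size=n)  # ~30% censoring
        time = np.minimum(t, c)
        event = (t <= c).astype(int)
        fit = fit_cox(time, event, group, "binary")
        assert 1.85 <= fit.hr <= 2.16

    def test_exponential_oracle_agreement(self, rng):
        # uncensored exponential two-sample: HR oracle = event/exposure ratio
        n = 4000
        group = rng.integers(0, 2, size=n)
        lam = np.where(group == 1, 0.3, 0.1)
        time = rng.exponential(1.0 / lam)
        event = np.ones(n, dtype=int)
        oracle = (event[group == 1].sum() / time[group == 1].sum()) / (
            event[group == 0].sum() / time[group == 0].sum()
        )
        fit = fit_cox(time, event, group, "binary")
        assert fit.hr == pytest.approx(oracle, rel=0.05)

    def test_constant_covariate_unidentifiable(self):
        with pytest.raises(UnidentifiableError, match="constant"):
            fit_cox([1.0, 2.0, 3.0], [1, 1, 0], [1.0, 1.0, 1.0])

    def test_zero_events_unidentifiable(self):
        with pytest.raises(UnidentifiableError, match="events"):
            fit_cox([1.0, 2.0, 3.0], [0, 0, 0], [0.0, 1.0, 2.0])

    def test_binary_carries_group_metadata(self, rng):
        t = rng.exponential(5.0, size=200)
        e = np.ones(200, dtype=int)
        g = rng.integers(0, 2, size=200)
        fit = fit_cox(t, e, g, "binary")
        assert fit.group_n == {"0": int((g == 0).sum()), "1": int((g == 1).sum())}
        assert fit.logrank_p is not None


class TestKMCurve:
    def test_hand_computed_steps(self):
        out = km_curve(np.array([1.0, 2, 3, 4]), np.ones(4, int), np.zeros(4, int))
        g = out["groups"]["0"]
        steps = dict(zip(g["time"], g["survival"]))
        assert steps[1.0] == pytest.approx(0.75)
        assert steps[2.0] == pytest.approx(0.5)
        assert steps[3.0] == pytest.approx(0.25)
        assert steps[4.0] == pytest.approx(0.0)
        assert g["median"] == pytest.approx(2.0)

    def test_identical_groups_logrank_near_one(self, rng):
        t = rng.exponential(5.0, size=400)
        e = np.ones(400, int)
        groups = np.concatenate([np.zeros(200, int), np.ones(200, int)])
        out = km_curve(np.concatenate([t[:200], t[:200]]), np.concatenate([e[:200], e[:200]]), groups)
        assert out["logrank_p"] > 0.9

    def test_exponential_median(self, rng):
        lam = 0.2
        t = rng.exponential(1.0 / lam, size=5000)
        out = km_curve(t, np.ones(5000, int), np.zeros(5000, int))
        assert out["groups"]["0"]["median"] == pytest.approx(np.log(2) / lam, rel=0.05)

    def test_survival_monotone_in_unit_interval(self, rng):
        t = rng.exponential(3.0, size=300)
        e = rng.integers(0, 2, size=300)
        e[0] = 1
        out = km_curve(t, e, np.zeros(300, int))
        s = np.array(out["groups"]["0"]["survival"])
        assert (np.diff(s) <= 1e-12).all()
        assert (s >= 0).all() and (s <= 1).all()

    def test_median_not_reached_is_none(self):
        out = km_curve(np.array([1.0, 2, 3, 4]), np.array([1, 0, 0, 0]),
                       np.zeros(4, int))
        assert out["groups"]["0"]["median"] is None

    def test_no_censoring_matches_empirical_survival(self, rng):
        t = rng.exponential(2.0, size=100)
        out = km_curve(t, np.ones(100, int), np.zeros(100, int))
        g = out["groups"]["0"]
        for ts, sv in zip(g["time"], g["survival"]):
            assert sv == pytest.approx((t > ts).mean(), abs=1e-12)


def _orr_cohort():
    resp = ["PR"] * 3 + ["CR"] + ["PD"] * 6
    n = len(resp)
    return CohortDataset(
        patient_ids=[f"P{i}" for i in range(n)],
        genes=["A"],
        mutations=np.zeros((n, 1), dtype=np.int8),
        arm=np.array(["treated"] * n, dtype=object),
        pfs_time=np.ones(n),
        pfs_event=np.ones(n, int),
        os_time=np.ones(n),
        os_event=np.ones(n, int),
        response=np.array(resp, dtype=object),
    )


class TestORR:
    def test_simple_rate(self):
        ds = _orr_cohort()
        out = orr_compare(ds, np.ones(ds.n_patients, int))
        row = out.table.query("stratum == 'benefit' and arm == 'treated'").iloc[0]
        assert row["orr"] == pytest.approx(0.4)
        assert row["n"] == 10 and row["responders"] == 4

    def test_empty_stratum_flagged(self):
        ds = _orr_cohort()
        out = orr_compare(ds, np.ones(ds.n_patients, int))
        assert any("empty stratum" in f for f in out.flags)
        assert np.isnan(
            out.table.query("stratum == 'non-benefit' and arm == 'treated'")["orr"].iloc[0]
        )

    def test_ne_excluded(self):
        ds = _orr_cohort()
        ds.response[0] = "NE"
        out = orr_compare(ds, np.ones(ds.n_patients, int))
        row = out.table.query("stratum == 'benefit' and arm == 'treated'").iloc[0]
        assert row["n"] == 9 and row["responders"] == 3

    def test_absolute_difference_arithmetic(self):
        assert 0.306 - 0.114 == pytest.approx(0.192)


class TestResponderAUC:
    def test_perfect_separation(self):
        m = np.array([1.0, 2, 3, 10, 11, 12])
        y = np.array([0, 0, 0, 1, 1, 1])
        auc, _ = responder_auc(m, y, n_bootstrap=50, seed=0)
        assert auc == 1.0

    def test_constant_marker(self):
        auc, _ = responder_auc(np.ones(10), np.array([0, 1] * 5), n_bootstrap=50, seed=0)
        assert auc == 0.5

    def test_matches_exhaustive_oracle(self, rng):
        for _ in range(20):
            n = int(rng.integers(10, 60))
            m = rng.integers(0, 6, size=n).astype(float)  # ties likely
            y = rng.integers(0, 2, size=n)
            if y.sum() in (0, n):
                continue
            auc, _ = responder_auc(m, y, n_bootstrap=10, seed=1)
            assert auc == pytest.approx(auc_oracle(m, y), abs=1e-12)

    def test_negation_identity(self, rng):
        m = rng.normal(size=50)
        y = rng.integers(0, 2, size=50)
        y[:2] = [0, 1]
        a1, _ = responder_auc(m, y, n_bootstrap=10, seed=0)
        a2, _ = responder_auc(-m, y, n_bootstrap=10, seed=0)
        assert a1 + a2 == pytest.approx(1.0, abs=1e-15)

    def test_one_class_errors(self):
        with pytest.raises(ValueError):
            responder_auc(np.arange(5.0), np.ones(5, int))

    def test_bootstrap_deterministic(self, rng):
        m = rng.normal(size=80)
        y = rng.integers(0, 2, size=80)
        y[:2] = [0, 1]
        assert responder_auc(m, y, seed=3) == responder_auc(m, y, seed=3)


class TestSpearman:
    def test_identity(self):
        rho, _ = spearman_rho(np.arange(10.0), np.arange(10.0))
        assert rho == pytest.approx(1.0)

    def test_negation(self):
        rho, _ = spearman_rho(np.arange(10.0), -np.arange(10.0))
        assert rho == pytest.approx(-1.0)

    def test_rank_formula_oracle(self):
        a = np.array([1.0, 2, 3, 4, 5])
        b = np.array([2.0, 1, 4, 3, 5])
        # no ties: rho = 1 - 6*sum(d^2)/(n(n^2-1))
        d = np.argsort(np.argsort(a)) - np.argsort(np.argsort(b))
        expected = 1 - 6 * np.sum(d.astype(float) ** 2) / (5 * 24)
        rho, _ = spearman_rho(a, b)
        assert rho == pytest.approx(expected, abs=1e-12)

    def test_pairwise_complete(self):
        a = np.array([1.0, 2, np.nan, 4, 5, 6])
        b = np.array([1.0, 2, 3, 4, np.nan, 6])
        rho, _ = spearman_rho(a, b)
        assert rho == pytest.approx(1.0)

    def test_too_few_pairs(self):
        with pytest.raises(ValueError):
            spearman_rho(np.array([1.0, np.nan, 3]), np.array([1.0, 2, np.nan]))


@pytest.fixture(scope="module")
def planted_report():
    cfg = SimulationConfig(
        n_patients=1200, n_genes=60, n_benefit_genes=10,
        mutation_freq_range=(0.15, 0.35),
        log_hr_treated_per_mutation=np.log(0.7),
        log_hr_control_per_mutation=np.log(1.1),
        response_intercept=-2.5, response_score_by_arm_slope=0.8,
        seed=17,
    )
    ds = simulate_cohort(cfg)
    scoring = ScoringConfig(panel=ds.truth, score_cutoff=2, tmb_high_cutoff=16)
    return build_report(ds, ds.truth, scoring, n_bootstrap=200, seed=5)


class TestBuildReport:
    def test_qualitative_benefit_pattern(self, planted_report):
        r = planted_report
        assert r.contrasts["score_group_pfs_treated"]["hr"] < 1.0
        assert r.contrasts["score_group_pfs_control"]["hr"] >= 1.0

    def test_null_cohort_ci_coverage(self):
        covered = total = 0
        for s in range(8):
            cfg = SimulationConfig(
                n_patients=400, n_genes=30, n_benefit_genes=5,
                mutation_freq_range=(0.2, 0.4),
                log_hr_treated_per_mutation=0.0,
                log_hr_control_per_mutation=0.0,
                response_score_by_arm_slope=0.0,
                seed=500 + s,
            )
            ds = simulate_cohort(cfg)
            scoring = ScoringConfig(panel=ds.truth, score_cutoff=1, tmb_high_cutoff=10)
            rep = build_report(ds, ds.truth, scoring, n_bootstrap=10, seed=s)
            for key in ("score_group_pfs_treated", "score_group_os_control",
                        "score_continuous_pfs_treated"):
                c = rep.contrasts[key]
                covered += c["ci_low"] <= 1.0 <= c["ci_high"]
                total += 1
        assert covered / total >= 0.80

    def test_serialization_round_trip(self, planted_report, tmp_path):
        text = planted_report.to_json(tmp_path / "r.json")
        back = EvaluationReport.from_json((tmp_path / "r.json").read_text())
        assert back.to_dict() == planted_report.to_dict()
        assert json.loads(text) == planted_report.to_dict()

    def test_deterministic_given_seed(self):
        cfg = SimulationConfig(n_patients=300, n_genes=20, n_benefit_genes=4, seed=9)
        ds = simulate_cohort(cfg)
        scoring = ScoringConfig(panel=ds.truth, score_cutoff=1)
        a = build_report(ds, ds.truth, scoring, n_bootstrap=100, seed=2)
        b = build_report(ds, ds.truth, scoring, n_bootstrap=100, seed=2)
        assert a.to_json() == b.to_json()

    def test_missing_arm_partial_report(self):
        cfg = SimulationConfig(n_patients=300, n_genes=20, n_benefit_genes=4,
                               arm_ratio=1.0, seed=10)
        ds = simulate_cohort(cfg)
        scoring = ScoringConfig(panel=ds.truth, score_cutoff=1)
        rep = build_report(ds, ds.truth, scoring, n_bootstrap=10, seed=0)
        assert any("missing arm" in f for f in rep.flags)
        assert "score_group_pfs_treated" in rep.contrasts
        assert "score_group_pfs_control" not in rep.contrasts

    def test_cox_and_logrank_agree_in_direction(self, planted_report):
        c = planted_report.contrasts["score_group_pfs_treated"]
        km = planted_report.km["score_group_pfs_treated"]
        m1, m0 = km["groups"]["1"]["median"], km["groups"]["0"]["median"]
        if m1 is not None and m0 is not None:
            assert (c["hr"] < 1) == (m1 >= m0)
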