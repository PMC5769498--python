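import itertools

import numpy as np
import pytest
from scipy.stats import chi2

from emtdx.reclassification import (
    CENSORED,
    EVENT,
    NONEVENT,
    BootstrapError,
    RiskCategories,
    assign_risk_category,
    bootstrap_intervals,
    classify_status,
    event_nri,
    idi,
    nonevent_nri,
    reclassification_calibration,
    stratification_table,
)


class TestCategories:
    def test_low(self):
        assert assign_risk_category(0.10, RiskCategories()) == 0

    def test_top(self):
        assert assign_risk_category(0.45, RiskCategories()) == 3

    def test_boundary_goes_up(self):
        assert assign_risk_category(0.20, RiskCategories()) == 1
        assert assign_risk_category(0.40, RiskCategories()) == 3

    def test_out_of_range(self):
        with pytest.raises(ValueError):
            assign_risk_category(1.2, RiskCategories())

    def test_invalid_cuts(self):
        with pytest.raises(ValueError):
            RiskCategories((0.3, 0.2))
        with pytest.raises(ValueError):
            RiskCategories((0.0, 0.5))

    def test_labels(self):
        assert RiskCategories().labels == ["0–20%", "20–30%", "30–40%", ">40%"]


class TestClassifyStatus:
    def test_partition(self):
        times = np.array([2.0, 5.0, 3.0, 6.0])
        events = np.array([1, 0, 0, 0])
        status = classify_status(times, events, horizon=5.0)
        assert list(status) == [EVENT, NONEVENT, CENSORED, NONEVENT]


class TestStratification:
    def test_identity(self):
        risks = np.array([0.1, 0.25, 0.35, 0.5])
        status = np.array([EVENT, NONEVENT, NONEVENT, EVENT])
        table = stratification_table(risks, risks, status)
        assert table.moved_up == table.moved_down == 0
        assert np.all(table.overall == np.diag(np.diag(table.overall)))
        assert table.total_reclassified == 0

    def test_hand_count(self):
        base = np.array([0.1] * 10)
        new = base.copy()
        new[:3] = 0.25          # three move up
        new[3] = 0.05           # stays in lowest category (no boundary crossed)
        base2 = base.copy()
        base2[4] = 0.25
        new[4] = 0.1            # one moves down
        status = np.full(10, NONEVENT)
        table = stratification_table(base2, new, status)
        assert table.moved_up == 3
        assert table.moved_down == 1
        assert table.total_reclassified == 4
        pct = table.percentages()
        assert pct["moved_up_pct"] == pytest.approx(30.0)
        assert pct["moved_down_pct"] == pytest.approx(10.0)
        assert pct["total_reclassified_pct"] == pytest.approx(40.0)

    def test_order_invariance(self, rng):
        n = 30
        base = rng.random(n)
        new = rng.random(n)
        status = rng.choice([EVENT, NONEVENT, CENSORED], n)
        t1 = stratification_table(base, new, status)
        perm = rng.permutation(n)
        t2 = stratification_table(base[perm], new[perm], status[perm])
        assert np.array_equal(t1.overall, t2.overall)
        assert np.array_equal(t1.events, t2.events)

    def test_cell_sum(self, rng):
        n = 50
        table = stratification_table(
            rng.random(n), rng.random(n), np.full(n, NONEVENT)
        )
        assert table.overall.sum() == n


class TestNRI:
    def test_no_changes_zero(self):
        cats = np.array([0, 1, 2, 3])
        status = np.array([EVENT] * 4)
        assert event_nri(cats, cats, status) == 0.0

    def test_event_hand_computed(self):
        # 10 events: 3 up, 1 down -> +20%
        base = np.zeros(10, dtype=int)
        new = np.zeros(10, dtype=int)
        new[:3] = 1
        base[3] = 1
        status = np.full(10, EVENT)
        assert event_nri(base, new, status) == pytest.approx(20.0)

    def test_event_maximum(self):
        base = np.zeros(5, dtype=int)
        new = np.ones(5, dtype=int)
        assert event_nri(base, new, np.full(5, EVENT)) == 100.0

    def test_nonevent_hand_computed(self):
        # 100 non-events: 50 down, 10 up -> +40%
        base = np.ones(100, dtype=int)
        new = np.ones(100, dtype=int)
        new[:50] = 0
        new[50:60] = 2
        status = np.full(100, NONEVENT)
        assert nonevent_nri(base, new, status) == pytest.approx(40.0)

    def test_nonevent_maximum(self):
        base = np.ones(7, dtype=int)
        new = np.zeros(7, dtype=int)
        assert nonevent_nri(base, new, np.full(7, NONEVENT)) == 100.0

    def test_zero_events_rejected(self):
        cats = np.zeros(3, dtype=int)
        with pytest.raises(ValueError):
            event_nri(cats, cats, np.full(3, NONEVENT))

    def test_censored_excluded(self):
        base = np.array([0, 0, 0])
        new = np.array([1, 1, 1])
        status = np.array([EVENT, CENSORED, CENSORED])
        assert event_nri(base, new, status) == 100.0

    def test_exhaustive_enumeration_oracle(self, rng):
        """Category-based NRI on fully observed toys vs direct enumeration."""
        cats = RiskCategories()
        for _ in range(25):
            n = int(rng.integers(4, 13))
            base = rng.random(n)
            new = rng.random(n)
            status = rng.choice([EVENT, NONEVENT], n)
            if not (status == EVENT).any() or not (status == NONEVENT).any():
                continue
            bc, nc = cats.assign(base), cats.assign(new)
            up_e = down_e = up_n = down_n = 0
            for i in range(n):
                move = np.sign(nc[i] - bc[i])
                if status[i] == EVENT:
                    up_e += move > 0
                    down_e += move < 0
                else:
                    up_n += move > 0
                    down_n += move < 0
            n_e = int((status == EVENT).sum())
            n_n = n - n_e
            assert event_nri(bc, nc, status) == pytest.approx(
                100 * (up_e - down_e) / n_e
            )
            assert nonevent_nri(bc, nc, status) == pytest.approx(
                100 * (down_n - up_n) / n_n
            )


class TestIDI:
    def test_identity_zero(self):
        risks = np.array([0.2, 0.4, 0.6])
        status = np.array([EVENT, NONEVENT, EVENT])
        assert idi(risks, risks, status) == 0.0

    def test_hand_computed(self):
        base = np.array([0.5, 0.5, 0.5, 0.5])
        new = np.array([0.7, 0.9, 0.3, 0.1])
        status = np.array([EVENT, EVENT, NONEVENT, NONEVENT])
        assert idi(base, new, status) == pytest.approx(60.0)

    def test_antisymmetry(self, rng):
        n = 20
        base = rng.random(n)
        new = rng.random(n)
        status = rng.choice([EVENT, NONEVENT], n)
        if not (status == EVENT).any():
            status[0] = EVENT
        if not (status == NONEVENT).any():
            status[1] = NONEVENT
        assert idi(base, new, status) == pytest.approx(-idi(new, base, status))

    def test_slope_difference_oracle(self, rng):
        n = 40
        base = rng.random(n)
        new = rng.random(n)
        status = rng.choice([EVENT, NONEVENT], n)
        status[:2] = [EVENT, NONEVENT]
        ev, ne = status == EVENT, status == NONEVENT
        slope = lambda r: r[ev].mean() - r[ne].mean()
        assert idi(base, new, status) == pytest.approx(
            100 * (slope(new) - slope(base)), abs=1e-12
        )

    def test_empty_stratum_rejected(self):
        risks = np.array([0.2, 0.3])
        with pytest.raises(ValueError):
            idi(risks, risks, np.array([EVENT, EVENT]))


class TestCalibration:
    def test_exact_agreement_zero(self):
        # 3 cells, observed proportions equal mean predicted risks
        risks = np.concatenate(
            [np.full(50, 0.20), np.full(50, 0.30), np.full(50, 0.40)]
        )
        cells = np.repeat([0, 1, 2], 50)
        events = np.concatenate(
            [
                np.r_[np.ones(10), np.zeros(40)],
                np.r_[np.ones(15), np.zeros(35)],
                np.r_[np.ones(20), np.zeros(30)],
            ]
        ).astype(int)
        times = np.where(events == 1, 3.0, 6.0)
        out = reclassification_calibration(
            risks, times, events, cell_labels=cells
        )
        assert out["statistic"] == pytest.approx(0.0, abs=1e-12)
        assert out["p_value"] == pytest.approx(1.0)

    def test_hand_computed_chi_square(self):
        risks = np.concatenate(
            [np.full(50, 0.20), np.full(50, 0.30), np.full(50, 0.40)]
        )
        cells = np.repeat([0, 1, 2], 50)
        observed = [12, 15, 18]  # perturbed in cells 0 and 2
        events = np.concatenate(
            [
                np.r_[np.ones(o), np.zeros(50 - o)] for o in observed
            ]
        ).astype(int)
        times = np.where(events == 1, 3.0, 6.0)
        out = reclassification_calibration(risks, times, events, cell_labels=cells)
        expected = (
            (12 - 10) ** 2 / (50 * 0.2 * 0.8)
            + 0.0
            + (18 - 20) ** 2 / (50 * 0.4 * 0.6)
        )
        assert out["statistic"] == pytest.approx(expected, abs=1e-10)
        assert out["df"] == 1
        assert out["p_value"] == pytest.approx(chi2.sf(expected, 1))

    def test_small_cells_merged(self):
        risks = np.concatenate(
            [np.full(30, 0.1), np.full(2, 0.22), np.full(30, 0.35), np.full(30, 0.5)]
        )
        events = np.zeros(92, dtype=int)
        events[:5] = 1
        times = np.where(events == 1, 2.0, 6.0)
        out = reclassification_calibration(risks, times, events)
        assert out["n_cells"] == 3  # tiny 0.22 cell merged into a neighbor

    def test_too_few_cells_rejected(self):
        risks = np.concatenate([np.full(30, 0.1), np.full(30, 0.5)])
        events = np.zeros(60, dtype=int)
        times = np.full(60, 6.0)
        with pytest.raises(ValueError):
            reclassification_calibration(risks, times, events)

    def test_km_used_with_censoring(self):
        # without censoring observed proportion = raw fraction; censoring
        # before the horizon must increase the KM-estimated event probability
        risks = np.concatenate(
            [np.full(40, 0.2), np.full(40, 0.3), np.full(40, 0.4)]
        )
        cells = np.repeat([0, 1, 2], 40)
        events = np.zeros(120, dtype=int)
        events[:8] = 1
        times = np.full(120, 6.0)
        times[:8] = 2.0
        base = reclassification_calibration(
            risks, times, events, cell_labels=cells
        )
        times_censored = times.copy()
        times_censored[8:20] = 1.0  # censor some cell-0 subjects early
        censored = reclassification_calibration(
            risks, times_censored, events, cell_labels=cells
        )
        assert censored["statistic"] != pytest.approx(base["statistic"])


class TestBootstrap:
    def test_constant_metric_zero_width(self):
        out = bootstrap_intervals(lambda idx: 7.0, n=20, B=50, seed=1)
        assert out["lo95"] == out["hi95"] == 7.0

    def test_determinism(self, rng):
        data = rng.random(30)

        def metric(idx):
            return float(data[idx].mean() - 0.5)

        a = bootstrap_intervals(metric, n=30, B=200, seed=9)
        b = bootstrap_intervals(metric, n=30, B=200, seed=9)
        assert a == b

    def test_undefined_abort(self):
        def metric(idx):
            return float("nan")

        with pytest.raises(BootstrapError):
            bootstrap_intervals(metric, n=10, B=50, seed=0)

    def test_b_validation(self):
        with pytest.raises(ValueError):
            bootstrap_intervals(lambda idx: 0.0, n=5, B=1)

    def test_coverage_of_known_mean(self, rng):
        """95% interval covers the population mean in >= 90/100 cohorts."""
        covered = 0
        for s in range(100):
            data = np.random.default_rng(s).normal(0.3, 1.0, 120)

            def metric(idx):
                return float(data[idx].mean())

            out = bootstrap_intervals(metric, n=120, B=200, seed=s)
            if out["lo95"] <= 0.3 <= out["hi95"]:
                covered += 1
        assert covered >= 90
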