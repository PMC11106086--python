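import numpy as np
import pytest
from scipy import stats

from ringanchor.calendar_units import CalendarYear
from ringanchor.miyake import (
    SampleSeries,
    anchor_chronology,
    chi_squared_at,
    chi_squared_scan,
    consensus_anchor,
    detect_excursions,
)
from ringanchor.refcurve import ReferenceCurve
from ringanchor.simulate import SimulationConfig, simulate_reference, simulate_sample_series


def brute_force_chi2(sample, rc, x):
    """Independent plain-Python evaluation of the placement statistic."""
    total = 0.0
    for r, R, dR in zip(sample.offsets, sample.values, sample.sigmas):
        y = x - int(r)
        C, dC = rc.at(y)
        total += (R - C) ** 2 / (dR**2 + dC**2)
    return total


class TestChiSquaredAt:
    def test_perfect_match_is_zero(self, toy_reference):
        rc = toy_reference
        offsets = np.arange(5)
        values = np.array([rc.at(-5250 - int(r))[0] for r in offsets])
        s = SampleSeries("S", offsets, values, np.ones(5))
        assert chi_squared_at(s, rc, -5250) == pytest.approx(0.0, abs=1e-12)

    def test_single_point_half(self):
        rc = ReferenceCurve(-5000, np.array([0.0, 0.0, 0.0]), np.ones(3))
        s = SampleSeries("S", [0], [1.0], [1.0])
        # (1-0)^2 / (1+1) = 0.5
        assert chi_squared_at(s, rc, -4999) == pytest.approx(0.5)

    def test_hand_evaluated_spike_placement(self):
        rc = ReferenceCurve(1, np.array([0.0, 0.0, 10.0, 0.0, 0.0]),
                            np.zeros(5))
        s = SampleSeries("S", [2, 1, 0], [0.0, 10.0, 0.0], [1.0, 1.0, 1.0])
        assert chi_squared_at(s, rc, 4) == pytest.approx(0.0)
        assert chi_squared_at(s, rc, 5) == pytest.approx(200.0)

    def test_out_of_coverage_signalled(self, toy_reference):
        s = SampleSeries("S", [0, 10], [0.0, 0.0], [1.0, 1.0])
        with pytest.raises(KeyError, match="coverage"):
            chi_squared_at(s, toy_reference, toy_reference.first_year + 5)

    def test_invariances(self, toy_reference):
        rc = toy_reference
        offsets = np.arange(8)
        rng = np.random.default_rng(0)
        values = np.array([rc.at(-5250 - int(r))[0] for r in offsets]) + rng.normal(0, 3, 8)
        s = SampleSeries("S", offsets, values, np.full(8, 1.5))
        base = chi_squared_at(s, rc, -5250)
        # adding a constant to both R and C leaves chi2 unchanged
        rc_shift = ReferenceCurve(rc.first_year, rc.c + 7.0, rc.dc)
        s_shift = SampleSeries("S", offsets, values + 7.0, s.sigmas)
        assert chi_squared_at(s_shift, rc_shift, -5250) == pytest.approx(base)
        # scaling all errors by s scales chi2 by 1/s^2
        rc2 = ReferenceCurve(rc.first_year, rc.c, rc.dc * 2)
        s2 = SampleSeries("S", offsets, values, s.sigmas * 2)
        assert chi_squared_at(s2, rc2, -5250) == pytest.approx(base / 4)


class TestScan:
    def test_scan_equals_brute_force_everywhere(self, toy_reference):
        """Vectorised scan must agree with the independent per-year
        evaluation at every admissible candidate year."""
        rng = np.random.default_rng(17)
        offsets = np.array([0, 1, 2, 4, 7, 11])
        values = rng.normal(95, 5, len(offsets))
        s = SampleSeries("S", offsets, values, np.full(len(offsets), 1.5))
        scan = chi_squared_scan(s, toy_reference)
        for x, chi2 in zip(scan.x, scan.chi2):
            assert chi2 == pytest.approx(brute_force_chi2(s, toy_reference, int(x)),
                                         rel=1e-12)
        # admissible range is exactly the coverage-compatible one
        assert scan.x[0] == toy_reference.first_year + offsets.max()
        assert scan.x[-1] == toy_reference.last_year

    def test_noiseless_cut_recovers_truth_with_zero_min(self, toy_reference):
        rc = toy_reference
        offsets = np.arange(10)
        values = np.array([rc.at(-5245 - int(r))[0] for r in offsets])
        s = SampleSeries("S", offsets, values, np.ones(10))
        scan = chi_squared_scan(s, rc)
        assert scan.best_x == -5245
        assert scan.chi2_min == pytest.approx(0.0, abs=1e-12)
        assert (scan.chi2[scan.x != -5245] > 0).all()

    @pytest.mark.parametrize("n,crit", [(5, 9.49), (9, 15.51)])
    def test_critical_values(self, n, crit):
        """alpha = 0.05 screening thresholds at df = n - 1."""
        s = SampleSeries("S", np.arange(n), np.zeros(n), np.ones(n))
        rc = ReferenceCurve(0, np.zeros(n + 5), np.ones(n + 5))
        scan = chi_squared_scan(s, rc)
        assert scan.critical_value == pytest.approx(crit, abs=5e-3)

    def test_spike_recovery_rate(self, config):
        """10 annual points spanning a 15.8 permil spike, 1.5 permil noise:
        the true end year is recovered in >= 95% of seeds."""
        hits = 0
        trials = 200
        truth, _ = simulate_reference(config)
        rc = ReferenceCurve(truth.first_year, truth.c, np.full(len(truth), 1.5))
        true_end = config.spike_year + 4
        for seed in range(trials):
            rng = np.random.default_rng(seed)
            s = simulate_sample_series(
                config, truth, true_end, np.arange(10), rng=rng
            )
            scan = chi_squared_scan(s, rc)
            if len(scan.minimizers) == 1 and scan.best_x == true_end:
                hits += 1
        assert hits / trials >= 0.95

    def test_expected_minimum_under_correct_noise(self, config):
        """Under correctly specified Gaussian noise the scan minimum at the
        true placement is a chi-square sum over the n measurements: its
        mean is n (the placement is a discrete grid point, no continuous
        parameter is fitted away), checked to within 3 standard errors."""
        truth, _ = simulate_reference(config)
        rc = ReferenceCurve(truth.first_year, truth.c, np.full(len(truth), 1e-9))
        true_end = config.spike_year + 4
        n = 10
        mins = []
        for seed in range(500):
            rng = np.random.default_rng(10_000 + seed)
            s = simulate_sample_series(config, truth, true_end, np.arange(n), rng=rng)
            mins.append(chi_squared_scan(s, rc).chi2_min)
        mean = np.mean(mins)
        se = np.std(mins, ddof=1) / np.sqrt(len(mins))
        assert abs(mean - n) <= 3 * se


class TestDetectExcursions:
    def years(self, c, first=-5300):
        return ReferenceCurve(first, np.asarray(c, dtype=float), np.ones(len(c)))

    def test_flat_curve_no_events(self):
        assert detect_excursions(self.years(np.full(40, 90.0))) == []

    def test_single_jump_flagged_at_jump_year(self):
        c = np.concatenate([np.full(20, 90.0), np.full(20, 105.8)])
        assert detect_excursions(self.years(c)) == [-5300 + 20]

    def test_two_step_rule(self):
        base = np.full(30, 90.0)
        c = base.copy()
        c[15:] += 6.0
        c[16:] += 5.0  # total 11 permil in 2 years -> flagged at the
        # year the cumulative two-year rise crosses the threshold
        assert detect_excursions(self.years(c)) == [-5300 + 16]
        c2 = base.copy()
        c2[15:] += 6.0
        c2[16:] += 3.0  # total 9 permil -> below the 1% criterion
        assert detect_excursions(self.years(c2)) == []

    def test_simulated_spike_found(self, config):
        truth, _ = simulate_reference(config)
        assert detect_excursions(truth) == [config.spike_year]


class TestAnchoring:
    @pytest.mark.parametrize(
        "rel,length,event_bc,expected_bc",
        [(184, 303, 5259, 5140), (303, 303, 5259, 5259), (1, 10, 5259, 5250)],
    )
    def test_end_year(self, rel, length, event_bc, expected_bc):
        event = CalendarYear.from_bc_ad(event_bc, "BC")
        end = anchor_chronology(rel, length, event)
        assert end.to_bc_ad() == (expected_bc, "BC")

    def test_event_outside_chronology_rejected(self):
        with pytest.raises(ValueError, match="outside"):
            anchor_chronology(304, 303, CalendarYear(-5258))


class TestConsensus:
    def _sample_and_scan(self, rc, end_year, rel_end, sid, shift=0):
        offsets = np.arange(8)
        values = np.array([rc.at(end_year + shift - int(r))[0] for r in offsets])
        s = SampleSeries(sid, offsets, values, np.ones(8), end_relative_year=rel_end)
        return s, chi_squared_scan(s, rc)

    def test_consistent_samples_reach_consensus(self, toy_reference):
        event_rel, length, event_year = 23, 60, -5258
        samples, scans = [], []
        for k, rel_end in enumerate([30, 40, 45, 50]):
            end = event_year + (rel_end - event_rel)
            s, sc = self._sample_and_scan(toy_reference, end, rel_end, f"S{k}")
            samples.append(s)
            scans.append(sc)
        rep = consensus_anchor(scans, samples, event_rel, length, event_year)
        assert rep.consensus
        assert all(r == 0 for r in rep.residuals.values())
        assert rep.chronology_end_year.astronomical == event_year + (length - event_rel)

    def test_one_shifted_sample_flagged(self, toy_reference):
        event_rel, length, event_year = 23, 60, -5258
        samples, scans = [], []
        for k, (rel_end, shift) in enumerate([(30, 0), (40, 0), (45, 1)]):
            end = event_year + (rel_end - event_rel)
            s, sc = self._sample_and_scan(toy_reference, end, rel_end, f"S{k}", shift)
            samples.append(s)
            scans.append(sc)
        rep = consensus_anchor(scans, samples, event_rel, length, event_year)
        assert not rep.consensus
        assert rep.residuals["S2"] == 1
        assert rep.residuals["S0"] == 0 and rep.residuals["S1"] == 0

    def test_unplaced_sample_excluded(self, toy_reference):
        s, sc = self._sample_and_scan(toy_reference, -5250, None, "FLOAT")
        rep = consensus_anchor([sc], [s], 23, 60, -5258)
        assert rep.excluded == ["FLOAT"]
        assert not rep.consensus
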