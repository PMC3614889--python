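"""State classification, bimodality/precision, FPT summaries, population
averages and lineage reconstruction."""

import math

import numpy as np
import pytest

from luxswitch import analysis
from luxswitch.analysis import (FptSample, ResponseDistribution,
                                bimodality_range, classify_state,
                                mfpt_and_quantiles, population_average)
from luxswitch.ssa import Event, EventLog, Trajectory


class TestClassify:
    @pytest.mark.parametrize("x, expected", [
        (0.0, "low"), (1.0, "high"), (0.5, "high"), (0.499, "low")])
    def test_threshold_and_tie_break(self, x, expected):
        assert classify_state(x) == expected

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            classify_state(-0.1)

    def test_vectorized(self):
        out = classify_state(np.array([0.1, 0.9]))
        assert list(out) == ["low", "high"]


def dist(ca, frac_high, n=20):
    k = int(round(frac_high * n))
    return ResponseDistribution(ca, np.array([1.0] * k + [0.0] * (n - k)))


class TestBimodality:
    def test_all_unimodal_low_gives_infinite_precision(self):
        r = bimodality_range([dist(c, 0.0) for c in (0.0, 10.0, 20.0)])
        assert math.isinf(r.precision)

    def test_even_split_is_inside_the_range(self):
        r = bimodality_range([dist(0.0, 0.0), dist(10.0, 0.5),
                              dist(20.0, 1.0)])
        assert r.cA_b1 < 10.0 < r.cA_b2
        assert r.precision == pytest.approx(1.0 / r.width)

    def test_exact_ninety_percent_counts_as_unimodal(self):
        # criterion is "below 90%": a snapshot exactly at 90% is unimodal
        assert not dist(5.0, 0.9, n=20).bimodal
        assert dist(5.0, 0.85, n=20).bimodal

    def test_linear_interpolation_of_boundaries(self):
        # frac_high: 0.0 at 10 nM, 0.2 at 20 nM → low fraction crosses 0.9
        # at 15 nM; frac_high crosses 0.9 between 30 and 40 at 37.5 nM
        r = bimodality_range([dist(10.0, 0.0), dist(20.0, 0.2),
                              dist(30.0, 0.6), dist(40.0, 0.92, n=100)])
        assert r.cA_b1 == pytest.approx(15.0)
        assert r.cA_b2 == pytest.approx(30 + (0.9 - 0.6) / (0.92 - 0.6) * 10)

    def test_unsorted_input_rejected(self):
        with pytest.raises(ValueError):
            bimodality_range([dist(10.0, 0.0), dist(5.0, 0.5)])


class TestMfpt:
    def test_inverse_cdf_quantiles_on_small_sample(self):
        s = FptSample(10.0, np.arange(1.0, 11.0), np.zeros(10, dtype=bool))
        m = mfpt_and_quantiles(s)
        assert m.mfpt_h == pytest.approx(5.5)
        assert m.q10_h == 1.0
        assert m.q90_h == 9.0
        assert not m.mfpt_is_lower_bound

    def test_all_censored_reports_horizon_bound(self):
        s = FptSample(5.0, np.full(8, 100.0), np.ones(8, dtype=bool))
        m = mfpt_and_quantiles(s)
        assert m.mfpt_h == 100.0
        assert m.mfpt_is_lower_bound
        assert m.censored_fraction == 1.0

    def test_partial_censoring_flags_bias(self):
        s = FptSample(5.0, np.array([2.0, 4.0, 50.0]),
                      np.array([False, False, True]))
        m = mfpt_and_quantiles(s)
        assert m.mfpt_h == pytest.approx(3.0)
        assert m.mfpt_is_lower_bound


def _traj(times, gfp_nM_matrix, vol=1.5):
    g = np.asarray(gfp_nM_matrix, dtype=float)
    T, N = g.shape
    f = 0.6022
    return Trajectory(times=np.asarray(times, dtype=float),
                      ids=np.tile(np.arange(N), (T, 1)),
                      gfp_counts=(g * f * vol),
                      volumes=np.full((T, N), vol),
                      aext=np.zeros(T), species=None)


class TestPopulationAverage:
    def test_constant_trajectories_average_to_constant(self):
        tr = _traj([0, 10, 20], np.full((3, 4), 42.0))
        pa = population_average([tr, tr], gfp_max_nM=42.0)
        np.testing.assert_allclose(pa.mean, 1.0)
        np.testing.assert_allclose(pa.sem, 0.0, atol=1e-12)

    def test_mismatched_grids_rejected(self):
        a = _traj([0, 10], np.zeros((2, 2)))
        b = _traj([0, 20], np.zeros((2, 2)))
        with pytest.raises(ValueError):
            population_average([a, b], 1.0)


class TestLineage:
    def test_one_division_two_edges(self):
        log = EventLog()
        log.append(Event(45.0, "division", 0, (1, 2)))
        edges = analysis.lineage_edges(log)
        assert len(edges) == 2
        assert set(edges.child) == {1, 2}
        assert not edges.truncated.any()

    def test_every_birth_has_one_removal_in_constant_n_run(self):
        log = EventLog()
        log.append(Event(45.0, "division", 0, (2, 3)))
        log.append(Event(45.0, "removal", 1, ()))
        log.append(Event(90.0, "division", 2, (4, 5)))
        log.append(Event(90.0, "removal", 5, ()))
        edges = analysis.lineage_edges(log)
        assert len(edges) == 4
        assert edges.truncated.sum() == 1        # child 5 washed out
        assert len(log.of_kind("removal")) == len(log.of_kind("division"))

    def test_gfp_attached_from_trajectory(self):
        log = EventLog()
        log.append(Event(10.0, "division", 0, (1, 2)))
        tr = _traj([0.0, 10.0, 20.0], [[10.0, 10.0], [10.0, 10.0],
                                       [20.0, 20.0]])
        tr.ids = np.array([[0, 9], [1, 2], [1, 2]])
        edges = analysis.lineage_edges(log, tr, gfp_max_nM=20.0)
        assert edges.gfp_norm.notna().all()
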