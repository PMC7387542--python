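"""Trace shape metrics: smoothing, curl origin/length/curvature,
raggedness, neighbour correlations, fixtures, file round-trips."""

import hashlib

import numpy as np
import pytest

from mtflare import tip_analysis as ta
from mtflare.energetics import MechanicalParams
from mtflare.lattice_sim import MicrotubuleState


def arc_trace(radius=20.0, quarter=True, n=60, mt=0, pf=0):
    ang = np.linspace(0, np.pi / 2 if quarter else np.pi / 4, n)
    return ta.PFTrace(mt, pf, np.column_stack(
        [radius * np.sin(ang), radius * (1 - np.cos(ang))]))


def piecewise_trace(wall_z=50.0, radius=20.0):
    wall = np.column_stack([np.linspace(0, wall_z, 26), np.zeros(26)])
    ang = np.linspace(0, np.pi / 2, 40)[1:]
    arc = np.column_stack([wall_z + radius * np.sin(ang),
                           radius * (1 - np.cos(ang))])
    return ta.PFTrace(0, 0, np.vstack([wall, arc]))


class TestSmoothing:
    def test_straight_line_passes_through(self):
        tr = ta.PFTrace(0, 0, np.column_stack([np.arange(20.0),
                                               np.zeros(20)]))
        sm = ta.smooth_trace(tr)
        assert np.abs(sm.points - tr.points).max() < 1e-6

    def test_endpoints_retained(self):
        rng = np.random.default_rng(0)
        tr = arc_trace()
        noisy = ta.PFTrace(0, 0, tr.points + rng.normal(0, 0.5,
                                                        tr.points.shape))
        sm = ta.smooth_trace(noisy)
        assert np.array_equal(sm.points[0], noisy.points[0])
        assert np.array_equal(sm.points[-1], noisy.points[-1])

    def test_noiseless_arc_curvature_preserved(self):
        tr = arc_trace(radius=20.0)
        sm = ta.smooth_trace(tr, span=0.25)
        o = ta.curl_origin(sm)
        _, curv = ta.curl_metrics(sm, o)
        assert curv == pytest.approx(0.05, rel=0.02)

    def test_noisy_arc_curvature_bias_small(self):
        rng = np.random.default_rng(1)
        curvs = []
        for _ in range(30):
            tr = arc_trace(radius=20.0)
            noisy = ta.PFTrace(0, 0, tr.points
                               + rng.normal(0, 1.0, tr.points.shape))
            sm = ta.smooth_trace(noisy)
            o = ta.curl_origin(sm)
            _, c = ta.curl_metrics(sm, o)
            curvs.append(c)
        assert np.mean(curvs) == pytest.approx(0.05, rel=0.10)

    def test_too_few_points(self):
        with pytest.raises(ValueError):
            ta.smooth_trace(ta.PFTrace(0, 0, np.zeros((3, 2))))


class TestCurlOrigin:
    def test_wall_only_trace_is_blunt(self):
        tr = ta.PFTrace(0, 0, np.column_stack([np.arange(10.0),
                                               np.full(10, 0.3)]))
        o = ta.curl_origin(tr)
        assert o.blunt
        assert o.origin_z == pytest.approx(9.0)
        assert ta.curl_metrics(tr, o)[0] == 0.0

    def test_piecewise_wall_then_arc(self):
        o = ta.curl_origin(piecewise_trace(wall_z=50.0))
        assert not o.blunt
        assert o.origin_z == pytest.approx(50.0, abs=0.5)

    def test_axial_translation_equivariance(self):
        tr = piecewise_trace()
        o0 = ta.curl_origin(tr)
        shifted = ta.PFTrace(0, 0, tr.points + np.array([123.0, 0.0]))
        o1 = ta.curl_origin(shifted)
        assert o1.origin_z - o0.origin_z == pytest.approx(123.0, abs=1e-9)


class TestCurlMetrics:
    def test_quarter_circle(self):
        tr = arc_trace(radius=20.0)
        length, curv = ta.curl_metrics(tr, ta.curl_origin(tr))
        assert length == pytest.approx(10 * np.pi, rel=0.01)
        assert curv == pytest.approx(0.05, rel=0.01)

    def test_straight_diagonal_curl_has_zero_curvature(self):
        z = np.linspace(0, 30, 40)
        tr = ta.PFTrace(0, 0, np.column_stack([z, 0.5 * z]))
        length, curv = ta.curl_metrics(tr, ta.curl_origin(tr))
        assert curv == pytest.approx(0.0, abs=1e-9)
        assert length > 0

    def test_coordinate_doubling_halves_curvature(self):
        tr = arc_trace(radius=20.0)
        big = ta.PFTrace(0, 0, 2.0 * tr.points)
        l1, c1 = ta.curl_metrics(tr, ta.curl_origin(tr))
        l2, c2 = ta.curl_metrics(big, ta.curl_origin(big))
        assert c2 == pytest.approx(c1 / 2, rel=0.05)
        assert l2 == pytest.approx(2 * l1, rel=0.05)


class TestRaggedness:
    def test_hand_computed_sample_sd(self):
        tip = ta.TipMetrics(0, np.arange(3), np.array([0.0, 6.0, 12.0]),
                            np.zeros(3), np.zeros(3))
        assert ta.raggedness(tip) == pytest.approx(6.0)

    def test_equal_origins_give_zero(self):
        tip = ta.TipMetrics(0, np.arange(4), np.full(4, 30.0),
                            np.zeros(4), np.zeros(4))
        assert ta.raggedness(tip) == 0.0

    def test_invariant_under_constant_shift(self):
        o = np.array([3.0, 9.0, 1.0, 7.0])
        t1 = ta.TipMetrics(0, np.arange(4), o, np.zeros(4), np.zeros(4))
        t2 = ta.TipMetrics(0, np.arange(4), o + 55.5, np.zeros(4),
                           np.zeros(4))
        assert ta.raggedness(t1) == pytest.approx(ta.raggedness(t2))

    def test_single_pf_errors(self):
        tip = ta.TipMetrics(0, np.arange(1), np.zeros(1), np.zeros(1),
                            np.zeros(1))
        with pytest.raises(ValueError):
            ta.raggedness(tip)


class TestNeighborCorrelation:
    @staticmethod
    def tips_from_lengths(lengths_per_mt):
        tips = []
        for mt, lengths in enumerate(lengths_per_mt):
            n = len(lengths)
            tips.append(ta.TipMetrics(mt, np.arange(n),
                                      np.zeros(n), np.asarray(lengths,
                                                              dtype=float),
                                      np.zeros(n)))
        return tips

    def test_identical_values_flagged_as_all_ties(self):
        tips = self.tips_from_lengths([[5.0] * 13])
        res = ta.neighbor_correlation(tips)
        assert res.all_tied and np.isnan(res.r_s)

    def test_perfectly_monotone_neighbors(self):
        # values increasing around the ring (wrap pair removed by a
        # partial ring) give rank correlation 1
        tips = self.tips_from_lengths([list(range(12))] * 2)
        res = ta.neighbor_correlation(tips)
        assert res.r_s == pytest.approx(1.0)

    def test_insufficient_pairs_error(self):
        tips = self.tips_from_lengths([[1.0, 2.0, 3.0]])
        with pytest.raises(ValueError, match="pairs"):
            ta.neighbor_correlation(tips)

    def test_independent_values_uncorrelated(self, rng):
        tips = self.tips_from_lengths(rng.exponential(20.0, (40, 13)))
        res = ta.neighbor_correlation(tips)
        assert abs(res.r_s) < 0.15
        assert res.p_value > 0.01


class TestFixturesAndIO:
    def test_noiseless_recovery_within_discretization(self, tmp_path):
        spec = ta.FixtureSpec(n_mt=6, curvature=0.04, curl_length=30.0,
                              noise=0.0)
        traces, truth = ta.make_fixture_traces(spec, seed=1)
        s = ta.summarize(traces, span=None)
        assert s.mean_curl_length.mean() == pytest.approx(30.0, rel=0.03)
        assert s.mean_curvature.mean() == pytest.approx(0.04, rel=0.03)

    def test_origin_spread_recovered_as_raggedness(self):
        spec = ta.FixtureSpec(n_mt=50, origin_spread=6.0, noise=0.3)
        traces, _ = ta.make_fixture_traces(spec, seed=2)
        s = ta.summarize(traces)
        assert s.raggedness.mean() == pytest.approx(6.0, abs=1.0)

    def test_file_round_trip(self, tmp_path):
        spec = ta.FixtureSpec(n_mt=3, noise=0.5)
        path = tmp_path / "traces.tsv"
        traces, truth = ta.make_fixture_traces(spec, seed=3, path=path)
        back = ta.read_traces(path)
        assert len(back) == len(traces)
        for a, b in zip(traces, back):
            assert (a.mt_id, a.pf_index) == (b.mt_id, b.pf_index)
            assert np.allclose(a.points, b.points)

    def test_seeded_determinism_identical_file_hash(self, tmp_path):
        spec = ta.FixtureSpec(n_mt=4, noise=1.0)
        h = []
        for name in ("a.tsv", "b.tsv"):
            p = tmp_path / name
            ta.make_fixture_traces(spec, seed=9, path=p)
            h.append(hashlib.sha256(p.read_bytes()).hexdigest())
        assert h[0] == h[1]

    def test_partial_rings_tolerated(self, tmp_path):
        # cryoET-like: only 5 of 13 PFs present
        spec = ta.FixtureSpec(n_mt=2, pf_per_mt=5)
        path = tmp_path / "partial.tsv"
        ta.make_fixture_traces(spec, seed=0, path=path)
        back = ta.read_traces(path)
        tips = ta.group_by_mt(back)
        assert all(len(v) == 5 for v in tips.values())
        ta.summarize(back)  # must not raise

    def test_simulated_state_projection_matches_export(self, tmp_path,
                                                       mech):
        # metrics computed on in-memory PF polylines equal metrics on
        # the exported-and-reloaded trace file of the same snapshot
        st = MicrotubuleState.straight_lattice(8, "GTP", mech)
        rng = np.random.default_rng(5)
        st.x[:, 10:16] += np.abs(rng.normal(1.0, 1.0, (13, 6)))
        traces = [ta.PFTrace(0, n, st.pf_polyline(n)) for n in range(13)]
        path = tmp_path / "sim.tsv"
        ta.write_traces(path, traces)
        back = ta.read_traces(path)
        tip_mem = ta.analyze_tip(traces, span=None)
        tip_file = ta.analyze_tip(back, span=None)
        assert np.array_equal(tip_mem.origin_z, tip_file.origin_z)
        assert np.array_equal(tip_mem.curl_length, tip_file.curl_length)
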