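"""Metric-suite unit tests: oracles, limit cases, statistics."""

import itertools
import warnings

import numpy as np
import pytest

from crstim import analysis
from crstim.model import mexican_hat_matrix
from crstim.params import NetworkParams, StimParams
from crstim.stimulation import build_schedule


class TestMeanWeights:
    def test_zero_and_all_one_limits(self, rng):
        p = NetworkParams.with_geometry(N=10, Ns=2)
        M = mexican_hat_matrix(p)
        n_ee, n_ii = analysis.synapse_counts(M)
        C, cee, cii = analysis.mean_weights(np.zeros((10, 10)), M)
        assert (C, cee, cii) == (0.0, 0.0, 0.0)
        c = np.ones((10, 10))
        np.fill_diagonal(c, 0.0)
        C, cee, cii = analysis.mean_weights(c, M)
        assert C == pytest.approx((n_ee - n_ii) / 100.0, rel=1e-12)
        assert cee == pytest.approx(n_ee / n_ee**2, rel=1e-12)
        assert cii == pytest.approx(n_ii / n_ii**2, rel=1e-12)

    def test_matches_brute_force_oracle(self, rng):
        p = NetworkParams.with_geometry(N=6, Ns=2)
        M = mexican_hat_matrix(p)
        c = rng.uniform(0, 1, (6, 6))
        np.fill_diagonal(c, 0.0)
        C, cee, cii = analysis.mean_weights(c, M)
        # explicit double loops
        s = se = si = 0.0
        n_ee = n_ii = 0
        for i in range(6):
            for j in range(6):
                s += np.sign(M[i, j]) * c[i, j]
                if i != j and M[i, j] > 0:
                    se += c[i, j]
                    n_ee += 1
                if i != j and M[i, j] < 0:
                    si += c[i, j]
                    n_ii += 1
        assert C == pytest.approx(s / 36.0, abs=1e-12)
        assert cee == pytest.approx(se / n_ee**2, abs=1e-12)
        assert cii == pytest.approx(si / n_ii**2, abs=1e-12)


class TestSortConnectivity:
    def test_pair_placement(self):
        M = np.array([[1.0, 0.4], [0.4, 1.0]])
        c = np.array([[0.0, 0.9], [0.1, 0.0]])
        out = analysis.sort_connectivity(c, M)
        assert out[0, 1] == 0.9  # stronger at (min, max)
        assert out[1, 0] == 0.1

    def test_symmetric_input_unchanged(self, rng):
        p = NetworkParams.with_geometry(N=8, Ns=2)
        M = mexican_hat_matrix(p)
        c = rng.uniform(0, 1, (8, 8))
        c = (c + c.T) / 2
        out = analysis.sort_connectivity(c, M)
        assert np.allclose(out, np.sign(M) * c)

    def test_matches_brute_force_oracle(self, rng):
        p = NetworkParams.with_geometry(N=8, Ns=2)
        M = mexican_hat_matrix(p)
        c = rng.uniform(0, 1, (8, 8))
        np.fill_diagonal(c, 0.0)
        out = analysis.sort_connectivity(c, M)
        for i in range(8):
            for j in range(8):
                if i < j:
                    expect = max(c[i, j], c[j, i])
                elif i > j:
                    expect = min(c[i, j], c[j, i])
                else:
                    expect = c[i, i]
                assert out[i, j] == pytest.approx(np.sign(M[i, j]) * expect, abs=1e-15)
        # construction property: |lower (min,max) entry| >= |mirror|
        mag = np.abs(out)
        iu = np.triu_indices(8, k=1)
        assert np.all(mag[iu] >= mag[(iu[1], iu[0])])


class TestMedianIqr:
    def test_identical_matrices_have_zero_iqr(self):
        mats = [np.full((3, 3), 0.7)] * 5
        med, iqr = analysis.median_iqr_stack(mats)
        assert np.allclose(med, 0.7)
        assert np.allclose(iqr, 0.0)

    def test_eleven_values_quartiles(self):
        """Cells 1..11: median 6; IQR 5 under linear interpolation."""
        mats = [np.full((2, 2), float(v)) for v in range(1, 12)]
        med, iqr = analysis.median_iqr_stack(mats)
        assert np.allclose(med, 6.0)
        q1, q3 = np.percentile(np.arange(1.0, 12.0), [25, 75])
        assert np.allclose(iqr, q3 - q1)

    def test_sign_preserved_and_shape_checked(self):
        mats = [np.full((2, 2), -0.3)] * 3
        med, _ = analysis.median_iqr_stack(mats)
        assert np.all(med == -0.3)
        with pytest.raises(ValueError):
            analysis.median_iqr_stack([np.zeros((2, 2)), np.zeros((3, 3))])
        with pytest.raises(ValueError):
            analysis.median_iqr_stack([np.zeros((2, 2))])


class TestPhasesAndOrderParameter:
    def test_linear_phase_values(self):
        spikes = np.array([0.0, 14.0, 28.0])
        assert analysis.linear_phase(spikes, 0.0) == 0.0
        assert analysis.linear_phase(spikes, 7.0) == pytest.approx(np.pi)
        assert analysis.linear_phase(spikes, 21.0) == pytest.approx(np.pi)
        assert np.isnan(analysis.linear_phase(spikes, -1.0))
        assert np.isnan(analysis.linear_phase(spikes, 28.0))  # not bracketed

    def test_phase_series_matches_scalar(self, rng):
        spikes = np.sort(rng.uniform(0, 100, 12))
        ts = rng.uniform(-5, 105, 50)
        vec = analysis.phase_series(spikes, ts)
        for t, v in zip(ts, vec):
            scalar = analysis.linear_phase(spikes, t)
            if np.isnan(scalar):
                assert np.isnan(v)
            else:
                assert v == pytest.approx(scalar, rel=1e-12)

    @pytest.mark.parametrize(
        "phases, R",
        [
            ([0.3, 0.3, 0.3], 1.0),                       # perfect in-phase
            ([0.0, np.pi / 2, np.pi, 3 * np.pi / 2], 0.0),  # full cancellation
            ([0.0, 0.0, np.pi], 1.0 / 3.0),
        ],
    )
    def test_order_parameter_limits(self, phases, R):
        r, _ = analysis.order_parameter(phases)
        assert r == pytest.approx(R, abs=1e-12)

    def test_undefined_phases_excluded(self):
        r, _ = analysis.order_parameter([0.5, np.nan, 0.5])
        assert r == pytest.approx(1.0)
        r, phi = analysis.order_parameter([np.nan, np.nan])
        assert np.isnan(r) and np.isnan(phi)


class TestRav:
    def test_constant_and_ramp(self):
        t = np.arange(0.0, 6001.0)
        assert analysis.r_av(np.full_like(t, 0.7), t, 6000.0) == pytest.approx(0.7)
        ramp = np.linspace(0, 1, t.size)
        got = analysis.r_av(ramp, t, 6000.0)
        # mean of the last 5000 samples of a 0..1 ramp over 6000
        assert got == pytest.approx(ramp[t > 1000.0].mean(), abs=1e-9)
        alt = np.where(t % 2 == 0, 0.0, 1.0)
        assert analysis.r_av(alt, t, 6000.0) == pytest.approx(0.5, abs=1e-3)

    def test_insufficient_history_rejected(self):
        t = np.arange(0.0, 3000.0)
        with pytest.raises(ValueError):
            analysis.r_av(np.ones_like(t), t, 3000.0)


class TestAcuteEffects:
    @pytest.mark.parametrize(
        "pre, on, off, stim, after",
        [
            (0.8, 0.8, 0.8, 0.0, 0.0),
            (0.8, 0.0, 0.8, 1.0, 0.0),        # complete desynchronization
            (0.9, 0.9, 0.99, 0.0, -0.1),      # synchronizing after-effect
        ],
    )
    def test_values(self, pre, on, off, stim, after):
        se, ae = analysis.acute_effects(pre, on, off)
        assert se == pytest.approx(stim, abs=1e-12)
        assert ae == pytest.approx(after, abs=1e-12)

    def test_zero_baseline_rejected(self):
        with pytest.raises(ValueError):
            analysis.acute_effects(0.0, 0.5, 0.5)


class TestSubpopulations:
    def test_default_geometry_partition(self):
        """49 members per site; boundary neurons 50/100/150/200 excluded."""
        net = NetworkParams()
        sm = analysis.subpopulation_map(net)
        bound = set(analysis.boundary_neurons(net).tolist())
        assert bound == {50, 100, 150, 200}
        assert set(sm[2].tolist()) == set(range(51, 100))
        all_members = set()
        for k in range(1, 5):
            assert len(sm[k]) == 49
            all_members |= set(sm[k].tolist())
        assert all_members.isdisjoint(bound)
        assert len(all_members) + len(bound) == net.N


class TestCrossTrialAndResettingIndex:
    def _uniform_dist(self, rng, L=1600, n_lags=65):
        ph = rng.uniform(0, 2 * np.pi, (L, n_lags))
        return analysis.CrossTrialDistribution(
            site=1, lags_ms=np.arange(-32.0, 33.0), phases=ph
        )

    def test_point_mass_gives_E_one(self):
        ph = np.full((50, 65), 1.234)
        d = analysis.CrossTrialDistribution(1, np.arange(-32.0, 33.0), ph)
        assert np.allclose(analysis.resetting_index(d), 1.0)

    def test_symmetric_phases_cancel(self):
        ph = np.tile(np.array([0.0, np.pi / 2, np.pi, 3 * np.pi / 2]), (1, 1)).T
        d = analysis.CrossTrialDistribution(1, np.zeros(1), ph)
        assert analysis.resetting_index(d)[0] == pytest.approx(0.0, abs=1e-12)

    def test_uniform_phases_rayleigh_scale(self, rng):
        """i.i.d. uniform phases: E concentrates near sqrt(pi)/(2 sqrt(L))."""
        d = self._uniform_dist(rng)
        E = analysis.resetting_index(d)
        expect = np.sqrt(np.pi) / (2.0 * np.sqrt(d.L))  # ~0.022 at L=1600
        assert 0.2 * expect < E.mean() < 3.0 * expect

    def test_matches_brute_force_oracle(self, rng):
        ph = rng.uniform(0, 2 * np.pi, (40, 5))
        d = analysis.CrossTrialDistribution(1, np.arange(5.0), ph)
        E = analysis.resetting_index(d)
        for l in range(5):
            acc = np.mean([np.exp(1j * p) for p in ph[:, l]])
            assert E[l] == pytest.approx(abs(acc), abs=1e-12)

    def test_cross_trial_counts_and_point_mass(self):
        """L reflects rank filtering and window clipping; constant phase
        trains give point-mass distributions."""
        stim = StimParams(Ns=2, stim_on_duration_s=12.0)
        sched = build_schedule("fixed_CR", stim, [5])
        net = NetworkParams.with_geometry(N=20, Ns=2)
        # synthetic raster: every neuron fires strictly periodically, phase
        # locked across the population; the period divides the cycle length
        # so every onset sees the same population phase
        period = 8.0
        spikes = np.arange(-96.0, 12200.0, period)
        raster = [spikes for _ in range(net.N)]
        members = analysis.subpopulation_map(net)[1]
        full = analysis.cross_trial(raster, members, sched, site=1)
        assert full.L == sched.times[0].size
        r1 = analysis.cross_trial(raster, members, sched, site=1, rank_filter=1)
        assert r1.L == sched.times[0].size // 3
        clipped = analysis.cross_trial(
            raster, members, sched, site=1, t_record=(0.0, 12000.0)
        )
        assert clipped.L < full.L
        # identical periodic rasters: each lag is a point mass -> E = 1
        E = analysis.resetting_index(full)
        assert np.allclose(E, 1.0, atol=1e-9)


class TestRankSum:
    def test_exhaustive_enumeration_oracle(self):
        """A={1,2,3} vs B={4,5,6}, side less: 1 of C(6,3)=20 orderings."""
        A, B = [1.0, 2.0, 3.0], [4.0, 5.0, 6.0]
        res = analysis.rank_sum_compare(A, B, side="less")
        # enumeration oracle: rank-sum of A under the permutation null
        pooled = A + B
        obs = sum(sorted(pooled).index(a) + 1 for a in A)
        count = 0
        total = 0
        for comb in itertools.combinations(range(6), 3):
            stat = sum(c + 1 for c in comb)
            total += 1
            if stat <= obs:
                count += 1
        assert count / total == pytest.approx(0.05)
        assert res.p_value == pytest.approx(0.05, rel=1e-9)
        assert res.significant is False  # p = alpha is not below alpha

    def test_identical_samples_not_significant(self, rng):
        x = rng.normal(size=11)
        res = analysis.rank_sum_compare(x, x, side="less")
        assert res.p_value >= 0.5

    def test_sides_complementary_for_extreme_split(self):
        A, B = [1.0, 2.0, 3.0], [4.0, 5.0, 6.0]
        less = analysis.rank_sum_compare(A, B, side="less").p_value
        greater = analysis.rank_sum_compare(A, B, side="greater").p_value
        assert less == pytest.approx(0.05)
        assert greater == pytest.approx(1.0)

    def test_degenerate_ties_warn_p_one(self):
        with pytest.warns(UserWarning):
            res = analysis.rank_sum_compare([1.0, 1.0], [1.0, 1.0])
        assert res.p_value == 1.0 and res.tie_warning


class TestSpikeCounts:
    def test_conservation_and_limits(self, rng):
        raster = [np.sort(rng.uniform(0, 100, rng.integers(0, 20))) for _ in range(30)]
        edges, counts = analysis.spike_counts(raster, (0.0, 100.0))
        total = sum(r.size for r in raster)
        assert counts.sum() <= total  # events at exactly t=100 fall outside
        assert counts.sum() >= total - sum((r == 100.0).sum() for r in raster)
        empty_edges, empty_counts = analysis.spike_counts(
            [np.empty(0)] * 5, (0.0, 50.0)
        )
        assert empty_counts.sum() == 0
        sim = [np.array([10.5])] * 7
        _, c = analysis.spike_counts(sim, (0.0, 20.0))
        assert c[10] == 7
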