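"""Response quantification: SDF, baseline, BCSC, Monte-Carlo null, FRA."""

import numpy as np
import pytest

from conftest import poisson_raster
from oddball import response as rq
from oddball.response import (
    SDF,
    ResponseMeasure,
    TrialRaster,
    average_std,
    baseline_rate,
    bcsc,
    compute_fra,
    inclusion_filter,
    measure_response,
    monte_carlo_significance,
    select_std_trials,
    spike_density,
)
import pandas as pd


def flat_sdf(level_hz):
    t = np.arange(-75.0, 250.0) + 0.5
    return SDF(time_ms=t, rate_hz=np.full(t.size, float(level_hz)))


class TestSpikeDensity:
    def test_no_spikes_gives_zero_sdf(self):
        sdf = spike_density(TrialRaster(trials=[np.empty(0)] * 5))
        assert np.all(sdf.rate_hz == 0)

    def test_single_spike_is_gaussian_bump_of_unit_area(self):
        sdf = spike_density(TrialRaster(trials=[np.array([50.0])]))
        assert sdf.time_ms[np.argmax(sdf.rate_hz)] == pytest.approx(50.5, abs=1.0)
        assert sdf.area_spikes() == pytest.approx(1.0, rel=0.02)
        # ~6 ms SD of the bump
        halfmax = sdf.rate_hz > sdf.rate_hz.max() / 2
        assert 10 < halfmax.sum() < 18  # FWHM of a 6-ms Gaussian is ~14 ms

    def test_homogeneous_poisson_recovers_flat_rate(self):
        rng = np.random.default_rng(0)
        raster = TrialRaster(trials=poisson_raster(20.0, 200, rng))
        sdf = spike_density(raster)
        interior = (sdf.time_ms > -40) & (sdf.time_ms < 215)
        assert sdf.rate_hz[interior].mean() == pytest.approx(20.0, rel=0.05)

    def test_mass_conservation_away_from_edges(self):
        """SDF area equals mean spike count/trial within 2% for interior
        spikes."""
        rng = np.random.default_rng(1)
        trials = [np.sort(rng.uniform(-40.0, 200.0, size=8)) for _ in range(40)]
        raster = TrialRaster(trials=trials)
        sdf = spike_density(raster)
        assert sdf.area_spikes() == pytest.approx(8.0, rel=0.02)

    def test_empty_raster_rejected(self):
        with pytest.raises(ValueError):
            spike_density(TrialRaster(trials=[]))

    def test_spike_outside_window_rejected(self):
        with pytest.raises(ValueError):
            TrialRaster(trials=[np.array([300.0])])


class TestBaseline:
    def test_three_preonset_spikes_forty_trials(self):
        trials = [np.array([-50.0]), np.array([-10.0, 20.0]), np.array([-30.0])]
        trials += [np.empty(0)] * 37
        assert baseline_rate(TrialRaster(trials=trials)) == pytest.approx(1.0)

    def test_no_preonset_spikes(self):
        raster = TrialRaster(trials=[np.array([50.0])] * 10)
        assert baseline_rate(raster) == 0.0

    def test_homogeneous_poisson(self):
        rng = np.random.default_rng(2)
        raster = TrialRaster(trials=poisson_raster(10.0, 400, rng))
        assert baseline_rate(raster) == pytest.approx(10.0, rel=0.1)


class TestBCSC:
    def test_sdf_at_baseline_gives_zero(self):
        assert bcsc(flat_sdf(7.0), 7.0) == 0.0

    def test_rectangle_above_baseline(self):
        sdf = flat_sdf(5.0)
        sdf.rate_hz[(sdf.time_ms > 20) & (sdf.time_ms < 120)] += 10.0
        assert bcsc(sdf, 5.0) == pytest.approx(1.0)

    def test_suppression_ignored(self):
        assert bcsc(flat_sdf(2.0), 8.0) == 0.0

    def test_activity_outside_window_ignored(self):
        sdf = flat_sdf(0.0)
        sdf.rate_hz[sdf.time_ms > 200] = 50.0
        assert bcsc(sdf, 0.0) == 0.0


class TestSelectStdTrials:
    def _oddball_raster(self, n=400, dev_every=10):
        pos = np.arange(n)
        dev = np.zeros(n, dtype=bool)
        dev[dev_every - 1 :: dev_every] = True
        trials = [np.array([float(p % 200)]) for p in pos]
        return TrialRaster(trials=trials, positions=pos, is_deviant=dev)

    def test_selects_one_trial_per_deviant(self):
        r = self._oddball_raster()
        out = select_std_trials(r)
        assert out.n_trials == 40
        assert np.array_equal(out.positions, np.arange(8, 400, 10))

    def test_zero_deviants_gives_empty_selection(self):
        r = TrialRaster(
            trials=[np.empty(0)] * 10,
            positions=np.arange(10),
            is_deviant=np.zeros(10, dtype=bool),
        )
        assert select_std_trials(r).n_trials == 0

    def test_missing_labels_rejected(self):
        with pytest.raises(ValueError):
            select_std_trials(TrialRaster(trials=[np.empty(0)]))


class TestAverageStd:
    def _m(self, b, p=0.01):
        return ResponseMeasure(bcsc=b, baseline_rate_hz=1.0, p_value=p, n_trials=40)

    def test_arithmetic_mean(self):
        out = average_std(self._m(0.2), self._m(0.4))
        assert out.bcsc == pytest.approx(0.3)

    def test_single_direction_passthrough_flagged(self):
        out = average_std(self._m(0.5), None)
        assert out.bcsc == 0.5
        assert "single_direction" in out.flags

    def test_equal_inputs_identity(self):
        out = average_std(self._m(0.7), self._m(0.7))
        assert out.bcsc == pytest.approx(0.7)


class TestMonteCarlo:
    def test_p_value_formula_bounds(self):
        # a huge observed value beats every null draw: p = 1/(N+1)
        p = monte_carlo_significance(1e9, 5.0, 40, n_null=1000, seed=0)
        assert p == pytest.approx(1.0 / 1001.0)
        # zero observed is never beaten: p = 1
        p = monte_carlo_significance(0.0, 5.0, 40, n_null=1000, seed=0)
        assert p == 1.0

    def test_null_p_values_super_uniform(self):
        """Under the null the p-value distribution should not be
        anti-conservative: P(p <= a) close to (or below) a."""
        rng = np.random.default_rng(11)
        ps = []
        for _ in range(400):
            raster = TrialRaster(trials=poisson_raster(5.0, 40, rng))
            # pooled spontaneous estimate as the pipeline provides it
            pooled = rng.poisson(5.0 * 0.075 * 2000) / (0.075 * 2000)
            m = measure_response(raster, n_null=200, seed=rng, null_rate_hz=pooled)
            ps.append(m.p_value)
        ps = np.asarray(ps)
        assert (ps <= 0.05).mean() <= 0.10
        assert (ps <= 0.2).mean() <= 0.27

    def test_strong_response_detected(self):
        rng = np.random.default_rng(3)
        trials = []
        for _ in range(40):
            spont = np.array(poisson_raster(5.0, 1, rng)[0])
            evoked = rng.uniform(10.0, 60.0, size=5)
            trials.append(np.sort(np.concatenate([spont, evoked])))
        m = measure_response(TrialRaster(trials=trials), n_null=500, seed=rng)
        assert m.p_value <= 0.01
        assert m.bcsc > 1.0


class TestInclusionFilter:
    def _m(self, p):
        return ResponseMeasure(bcsc=1.0, baseline_rate_hz=1.0, p_value=p)

    @pytest.mark.parametrize(
        "ps,keep",
        [
            ((0.01, 0.8, 0.9), True),
            ((0.2, 0.3, 0.9), False),
            ((0.05, 0.5, 0.5), True),  # boundary inclusive
            ((0.9, 0.9, 0.05), True),
        ],
    )
    def test_rule(self, ps, keep):
        assert inclusion_filter(*(self._m(p) for p in ps)) is keep

    def test_missing_condition_rejected(self):
        with pytest.raises(ValueError):
            inclusion_filter(self._m(0.1), None, self._m(0.2))


class TestFRA:
    def _table(self, sig_cells, freqs, levels):
        rows = []
        for lv in levels:
            for f in freqs:
                sig = (f, lv) in sig_cells
                rows.append(
                    dict(freq_hz=f, level_db=lv, bcsc=1.0 if sig else 0.0,
                         p_value=0.01 if sig else 0.9)
                )
        return pd.DataFrame(rows)

    def test_q30_of_one_octave_bandwidth(self):
        cf = 10_000.0
        freqs = cf * 2.0 ** np.arange(-2.0, 2.01, 0.25)
        levels = [10, 20, 30, 40]
        sig = {(cf, 10)}
        band = [f for f in freqs if cf * 2**-0.5 - 1 <= f <= cf * 2**0.5 + 1]
        sig |= {(f, 40) for f in band}
        res = compute_fra(self._table(sig, freqs, levels))
        assert res.cf_hz == pytest.approx(cf)
        assert not res.untuned
        assert res.q30 == pytest.approx(1.0 / (2**0.5 - 2**-0.5), rel=1e-6)

    def test_v_shaped_map_cf_at_tip(self):
        freqs = [1000.0, 2000.0, 4000.0, 8000.0, 16000.0]
        levels = [10, 20, 30]
        sig = {(4000.0, 10)}
        sig |= {(f, 20) for f in (2000.0, 4000.0, 8000.0)}
        sig |= {(f, 30) for f in freqs}
        res = compute_fra(self._table(sig, freqs, levels))
        assert res.cf_hz == 4000.0

    def test_fragmented_map_untuned(self):
        freqs = [1000.0, 2000.0, 4000.0, 8000.0, 16000.0]
        levels = [10, 20, 30, 40]
        sig = {(4000.0, 10), (1000.0, 40), (4000.0, 40), (16000.0, 40)}
        res = compute_fra(self._table(sig, freqs, levels))
        assert res.untuned
        assert res.q30 is None

    def test_all_nonsignificant_no_cf(self):
        freqs = [1000.0, 2000.0, 4000.0]
        res = compute_fra(self._table(set(), freqs, [10, 20, 30]))
        assert res.cf_hz is None and res.untuned
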