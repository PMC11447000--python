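"""Activity scans, electrode selection, population rate, burst detection."""

import numpy as np
import pytest

from ephyskit.mea import (
    BurstDetectionParams,
    SpikeRaster,
    burst_metrics,
    detect_network_bursts,
    population_rate,
    select_top_electrodes,
    summarize_activity_scan,
)
from ephyskit.synth import RasterSpec, generate_raster


def raster_from(times, ids=None, duration=30.0, n_total=26400):
    times = np.asarray(times, dtype=float)
    if ids is None:
        ids = np.zeros(times.size, dtype=int)
    return SpikeRaster(np.asarray(ids), times, duration, n_total)


class TestActivityScan:
    def test_rate_arithmetic(self):
        r = raster_from(np.linspace(0.1, 29.9, 60))
        scan = summarize_activity_scan(r, 30.0)
        assert scan.rates[0] == pytest.approx(2.0)
        assert scan.rates[1:].max() == 0.0

    def test_silent_chip(self):
        scan = summarize_activity_scan(raster_from([]), 30.0)
        assert scan.rates.shape == (26400,)
        assert scan.rates.max() == 0.0

    def test_poisson_rates_within_sampling_error(self):
        spec = RasterSpec(n_electrodes=200, baseline_rate=5.0, duration=30.0, seed=21)
        raster, _ = generate_raster(spec)
        scan = summarize_activity_scan(raster, 30.0)
        sd = np.sqrt(5.0 / 30.0)
        assert np.all(np.abs(scan.rates[:200] - 5.0) <= 4 * sd)


class TestSelection:
    def test_full_chip_yields_1024(self):
        rng = np.random.default_rng(3)
        scan = summarize_activity_scan(
            raster_from(rng.uniform(0, 30, 100000),
                        ids=rng.integers(0, 26400, 100000)),
            30.0,
        )
        assert select_top_electrodes(scan).size == 1024

    def test_equal_rates_tie_break_by_id(self):
        from ephyskit.mea import ActivityScanResult

        scan = ActivityScanResult(np.ones(2000), 30.0)
        assert np.array_equal(select_top_electrodes(scan, 100), np.arange(100))

    def test_rates_equal_id_selects_largest_ids(self):
        from ephyskit.mea import ActivityScanResult

        scan = ActivityScanResult(np.arange(2000, dtype=float), 30.0)
        assert np.array_equal(select_top_electrodes(scan, 50), np.arange(1950, 2000))

    def test_too_few_electrodes_raises(self):
        from ephyskit.mea import ActivityScanResult

        with pytest.raises(ValueError, match="500"):
            select_top_electrodes(ActivityScanResult(np.ones(500), 30.0), 1024)


class TestPopulationRate:
    def test_empty_raster_zero_rate(self):
        rate = population_rate(raster_from([], duration=60.0))
        assert rate.rate.max() == 0.0

    def test_spike_count_conserved(self, rng):
        times = rng.uniform(0, 60, 5000)
        rate = population_rate(raster_from(times, duration=60.0))
        assert rate.integral() == pytest.approx(5000, rel=1e-3)

    def test_single_spike_gaussian_bump(self):
        rate = population_rate(raster_from([30.0], duration=60.0))
        params = BurstDetectionParams()
        peak = rate.times[np.argmax(rate.rate)]
        assert peak == pytest.approx(30.0, abs=2 * params.bin_width)
        # empirical sd of the bump matches the kernel sd
        w = rate.rate / rate.rate.sum()
        sd = np.sqrt(np.sum(w * (rate.times - peak) ** 2))
        assert sd == pytest.approx(params.gaussian_sigma, rel=0.05)

    def test_too_short_raster_rejected(self):
        with pytest.raises(ValueError, match="duration"):
            population_rate(raster_from([0.1], duration=0.5))


class TestBurstDetection:
    def test_ten_planted_bursts_recovered(self):
        spec = RasterSpec(burst_times=[15.0 + 30 * k for k in range(10)], seed=8)
        raster, truth = generate_raster(spec)
        bursts = detect_network_bursts(population_rate(raster), raster)
        assert len(bursts) == 10
        for b, t in zip(bursts, truth):
            assert abs(b.peak_time - t["center"]) <= 0.05

    def test_homogeneous_poisson_no_bursts(self):
        for seed in range(5):
            raster, _ = generate_raster(RasterSpec(seed=seed))
            assert detect_network_bursts(population_rate(raster), raster) == []

    def test_ibi_matches_planted_spacing(self):
        spec = RasterSpec(burst_times=[10.0 * (k + 1) for k in range(25)],
                          duration=300.0, seed=4)
        raster, _ = generate_raster(spec)
        bursts = detect_network_bursts(population_rate(raster), raster)
        m = burst_metrics(bursts)
        assert m.mean_ibi == pytest.approx(10.0, abs=BurstDetectionParams().bin_width)

    def test_spike_count_matches_brute_force(self):
        spec = RasterSpec(burst_times=[50.0, 150.0, 250.0], seed=14)
        raster, _ = generate_raster(spec)
        bursts = detect_network_bursts(population_rate(raster), raster)
        for b in bursts:
            brute = np.sum((raster.spike_times >= b.start)
                           & (raster.spike_times <= b.end))
            assert b.spike_count == brute

    def test_relabeling_electrodes_invariant(self):
        spec = RasterSpec(burst_times=[60.0, 180.0], seed=17)
        raster, _ = generate_raster(spec)
        perm = np.random.default_rng(1).permutation(raster.n_electrodes_total)
        relabeled = SpikeRaster(perm[raster.electrode_ids], raster.spike_times,
                                raster.duration, raster.n_electrodes_total)
        b1 = detect_network_bursts(population_rate(raster), raster)
        b2 = detect_network_bursts(population_rate(relabeled), relabeled)
        assert [(b.peak_time, b.start, b.end, b.spike_count) for b in b1] == [
            (b.peak_time, b.start, b.end, b.spike_count) for b in b2
        ]

    def test_closer_spacing_shrinks_ibi(self):
        def mean_ibi(spacing):
            centers = [spacing * (k + 1) for k in range(int(280 // spacing))]
            raster, _ = generate_raster(
                RasterSpec(burst_times=centers, duration=300.0, seed=6))
            bursts = detect_network_bursts(population_rate(raster), raster)
            return burst_metrics(bursts).mean_ibi

        assert mean_ibi(10.0) < mean_ibi(15.0) < mean_ibi(30.0)


class TestBurstMetrics:
    def test_empty(self):
        m = burst_metrics([])
        assert m.n_bursts == 0
        assert m.mean_ibi is None and m.mean_spikes_per_burst is None

    def test_arithmetic(self):
        from ephyskit.mea import NetworkBurst

        bursts = [
            NetworkBurst(peak_time=p, start=p - 0.2, end=p + 0.2,
                         spike_count=120, electrode_count=50, peak_rate=1e4)
            for p in (10.0, 20.0, 30.0)
        ]
        m = burst_metrics(bursts)
        assert m.mean_ibi == pytest.approx(10.0)
        assert m.mean_spikes_per_burst == pytest.approx(120.0)
        assert m.mean_burst_duration == pytest.approx(0.4)

    def test_single_burst_ibi_undefined(self):
        from ephyskit.mea import NetworkBurst

        m = burst_metrics([NetworkBurst(10.0, 9.9, 10.1, 100, 40, 1e4)])
        assert m.n_bursts == 1 and m.mean_ibi is None
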