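"""Network-activity measures, burst detection vs brute-force oracle, staging."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mea_nmj import (
    BurstSpec,
    NetworkActivitySummary,
    SpikeTrainSet,
    active_electrodes,
    bin_spike_counts,
    burst_spike_fraction,
    classify_stage,
    detect_network_bursts,
    exclude_low_activity,
    gen_spike_trains,
    network_firing_rate,
    summarize_network,
)
from conftest import burst_oracle


def _trains(d, duration=240.0, **kw):
    return SpikeTrainSet(trains={k: np.asarray(v, float) for k, v in d.items()},
                         duration=duration, **kw)


class TestFiringRateAndActive:
    def test_empty_trains_rate_zero(self):
        assert network_firing_rate(_trains({"E1": [], "E2": []})) == 0.0

    def test_rate_is_total_count_over_duration(self):
        sts = _trains({"E1": np.linspace(1, 200, 300), "E2": np.linspace(1, 200, 300)})
        assert network_firing_rate(sts) == pytest.approx(600 / 240)

    def test_poisson_rate_estimate_within_four_sd(self):
        sts, _ = gen_spike_trains(50, 2.0, duration=240, seed=1)  # aggregate 100 Hz
        sd = np.sqrt(100 * 240) / 240
        assert abs(network_firing_rate(sts) - 100.0) < 4 * sd

    def test_active_electrode_boundary_is_inclusive(self):
        sts = _trains({"E1": np.linspace(1, 239, 24), "E2": [5.0]})
        assert active_electrodes(sts, 0.1) == {"E1"}  # 24/240 = 0.1 exactly
        assert active_electrodes(sts, 0.0) == {"E1", "E2"}
        assert active_electrodes(_trains({"E1": [], "E2": []}), 0.1) == set()


class TestBinning:
    def test_half_open_bin_assignment(self):
        hist, flags, order = bin_spike_counts(_trains({"E1": [0.049, 0.050]}, duration=1.0))
        assert hist[0] == 1 and hist[1] == 1
        assert flags[0, 0] and flags[1, 0]

    @pytest.mark.parametrize("seed", range(3))
    def test_histogram_conserves_total_spike_count(self, seed):
        sts, _ = gen_spike_trains(12, 4.0, duration=30, seed=seed)
        hist, flags, _ = bin_spike_counts(sts)
        assert hist.sum() == sts.n_spikes
        assert np.all(hist >= flags.sum(axis=1))


class TestBurstDetection:
    def test_constant_histogram_yields_no_bursts(self):
        n_el = 4
        order = [f"E{i}" for i in range(n_el)]
        hist = np.full(100, 5)
        flags = np.ones((100, n_el), bool)
        bs = detect_network_bursts(hist, flags, order, set(order))
        assert len(bs) == 0

    def test_planted_three_bin_epoch_found_as_single_burst(self):
        order = [f"E{i:02d}" for i in range(60)]
        hist = np.ones(200, dtype=int)
        flags = np.zeros((200, 60), bool)
        flags[:, 0] = True
        hist[50:53] = 100
        flags[50:53, :48] = True  # 80% of electrodes
        bs = detect_network_bursts(hist, flags, order, set(order))
        assert len(bs) == 1
        b = bs.bursts[0]
        assert (b.start_s, b.end_s) == (50 * 0.05, 53 * 0.05)
        assert b.n_spikes == 300
        oracle = burst_oracle(hist, flags, order, set(order))
        assert [(x.start_s, x.end_s, x.n_spikes, x.electrodes) for x in bs] == oracle

    def test_low_participation_bin_is_pruned(self):
        order = [f"E{i:02d}" for i in range(60)]
        hist = np.ones(200, dtype=int)
        flags = np.zeros((200, 60), bool)
        hist[50] = 100
        flags[50, :6] = True  # 10% of active electrodes
        bs = detect_network_bursts(hist, flags, order, set(order))
        assert len(bs) == 0

    def test_exact_participation_boundary_survives(self):
        order = [f"E{i:02d}" for i in range(10)]
        hist = np.ones(100, dtype=int)
        flags = np.zeros((100, 10), bool)
        hist[40] = 50
        flags[40, :2] = True  # exactly 20%: "fewer than 20%" does not prune
        bs = detect_network_bursts(hist, flags, order, set(order))
        assert len(bs) == 1

    def test_empty_active_set_returns_empty_with_warning(self, caplog):
        hist = np.ones(50, dtype=int)
        hist[10] = 100
        flags = np.ones((50, 3), bool)
        with caplog.at_level("WARNING", logger="mea_nmj.network"):
            bs = detect_network_bursts(hist, flags, ["A", "B", "C"], set())
        assert len(bs) == 0
        assert any("active set" in r.message for r in caplog.records)

    @pytest.mark.parametrize("seed", range(300))
    def test_equals_brute_force_oracle_on_random_instances(self, seed):
        rng = np.random.default_rng(seed)
        n_bins = int(rng.integers(5, 201))
        n_el = int(rng.integers(1, 11))
        order = [f"E{i}" for i in range(n_el)]
        hist = rng.poisson(3, n_bins)
        hist[rng.random(n_bins) < 0.1] += int(rng.integers(20, 200))
        flags = rng.random((n_bins, n_el)) < rng.uniform(0.05, 0.9)
        active = {e for e in order if rng.random() < 0.8}
        k = float(rng.uniform(0.5, 6))
        part = float(rng.uniform(0.05, 0.6))
        bs = detect_network_bursts(
            hist, flags, order, active, threshold_sd=k, min_participation=part
        )
        oracle = burst_oracle(hist, flags, order, active, k, part)
        got = [(b.start_s, b.end_s, b.n_spikes, b.electrodes) for b in bs]
        assert got == oracle

    @pytest.mark.parametrize("seed", range(20))
    def test_no_two_bursts_in_adjacent_bins(self, seed):
        rng = np.random.default_rng(1_000 + seed)
        hist = rng.poisson(2, 150)
        hist[rng.random(150) < 0.2] += 50
        flags = rng.random((150, 6)) < 0.7
        order = [f"E{i}" for i in range(6)]
        bs = detect_network_bursts(hist, flags, order, set(order))
        for a, b in zip(bs.bursts, bs.bursts[1:]):
            assert b.start_s - a.end_s >= bs.bin_s - 1e-12
        for b in bs.bursts:
            n_bins = round((b.end_s - b.start_s) / bs.bin_s)
            assert n_bins >= 1
            assert b.end_s - b.start_s == pytest.approx(n_bins * bs.bin_s)


class TestBurstFraction:
    def test_zero_without_bursts_or_spikes(self):
        sts, _ = gen_spike_trains(5, 1.0, duration=20, seed=0)
        _, bursts = summarize_network(_trains({"E1": []}, duration=20))
        assert burst_spike_fraction(sts, bursts) == 0.0

    def test_one_when_every_spike_inside_a_burst(self):
        sts = _trains({"E1": [1.01, 1.02], "E2": [1.03]}, duration=10)
        hist, flags, order = bin_spike_counts(sts)
        bursts = detect_network_bursts(hist, flags, order, {"E1", "E2"})
        assert len(bursts) == 1
        assert burst_spike_fraction(sts, bursts) == 1.0

    @pytest.mark.parametrize("seed", range(5))
    def test_recovered_fraction_close_to_planted_share(self, seed):
        specs = [BurstSpec(20 + 40 * i, 0.5, 40.0, 0.8) for i in range(5)]
        sts, gt = gen_spike_trains(60, 2.0, specs, duration=240, seed=seed)
        planted = 0
        for start, end, _ in gt.true_burst_epochs:
            for t in sts.trains.values():
                planted += np.count_nonzero((t >= start) & (t < end))
        share = planted / sts.n_spikes
        _, bursts = summarize_network(sts)
        assert burst_spike_fraction(sts, bursts) == pytest.approx(share, abs=0.05)


class TestStagingAndExclusion:
    @pytest.mark.parametrize(
        "div,stage",
        [(15, "young"), (22, "young"), (28, "young"), (35, "young"),
         (42, "middle_aged"), (49, "middle_aged"), (56, "middle_aged"),
         (63, "old"), (70, "old"),
         (38, "unstaged"), (58, "unstaged"), (8, "unstaged"), (90, "unstaged")],
    )
    def test_stage_boundaries(self, div, stage):
        assert classify_stage(div) == stage

    def test_recording_days_partition_into_4_3_2(self):
        days = [15, 22, 28, 35, 42, 49, 56, 63, 70]
        stages = [classify_stage(d) for d in days]
        assert stages.count("young") == 4
        assert stages.count("middle_aged") == 3
        assert stages.count("old") == 2
        assert "unstaged" not in stages

    def test_low_activity_exclusion_boundary(self):
        mk = lambda r: NetworkActivitySummary(firing_rate_hz=r, burst_fraction=0,
                                              n_active_electrodes=0)
        assert exclude_low_activity(mk(0.0)) is True
        assert exclude_low_activity(mk(2.5)) is False
        assert exclude_low_activity(mk(0.05)) is False  # strict <


@given(
    times=st.lists(st.floats(min_value=0, max_value=9.999), max_size=50),
    bin_s=st.sampled_from([0.05, 0.1, 0.5]),
)
@settings(max_examples=100, deadline=None, derandomize=True)
def test_binning_conserves_counts_property(times, bin_s):
    sts = _trains({"E1": sorted(times)}, duration=10.0)
    hist, flags, _ = bin_spike_counts(sts, bin_s)
    assert hist.sum() == len(times)
    assert hist.size == int(np.ceil(10.0 / bin_s - 1e-9))
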