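"""Analysis tests: burst/network-burst detection against hand-derived
outputs, rate filters, STH alignment, fit recovery, Victor-Purpura metric."""

import itertools

import numpy as np
import pandas as pd
import pytest

from cortexstack.spiketrains import SpikeTrainSet
from cortexstack.spikemetrics import (
    detect_bursts,
    burst_table,
    detect_network_bursts,
    compute_rates,
    build_sth_ifr,
    plateau_bounds,
    fit_rise,
    fit_decay,
    victor_purpura_distance,
    layer_similarity_map,
)
from cortexstack.workbench import make_fixtures


def trainset(ids, times, n_neurons, duration=60.0, layer_of=None):
    return SpikeTrainSet(
        neuron_ids=np.asarray(ids, dtype=np.int64),
        times=np.asarray(times, dtype=float),
        n_neurons=n_neurons,
        duration=duration,
        layer_of=layer_of,
    )


# ---------------------------------------------------------------- bursts

class TestBurstDetection:
    @pytest.mark.parametrize(
        "train,expected",
        [
            (np.arange(5) * 0.050, [(0.0, 0.200, 5)]),        # 4 ISIs of 50 ms
            (np.arange(4) * 0.050, []),                        # below min spikes
            (np.arange(10) * 0.150, []),                       # ISIs above limit
            (np.array([]), []),
            # exactly at the 100 ms boundary still counts as in-burst
            (np.arange(5) * 0.100, [(0.0, 0.400, 5)]),
            # two separated runs
            (np.concatenate([np.arange(5) * 0.05, 1.0 + np.arange(6) * 0.08]),
             [(0.0, 0.200, 5), (1.0, 1.400, 6)]),
        ],
    )
    def test_string_method_hand_derived(self, train, expected):
        got = detect_bursts(train)
        assert len(got) == len(expected)
        for (s, e, c), (es, ee, ec) in zip(got, expected):
            assert s == pytest.approx(es) and e == pytest.approx(ee) and c == ec

    def test_unsorted_train_rejected(self):
        with pytest.raises(ValueError):
            detect_bursts(np.array([0.5, 0.1, 0.2, 0.3, 0.4]))

    def test_burst_spikes_subset_of_train(self):
        rng = np.random.default_rng(0)
        ids = rng.integers(0, 5, 400)
        times = np.sort(rng.uniform(0, 20, 400))
        st = trainset(ids, times, 5, 20.0)
        bt = burst_table(st)
        assert (bt["n_spikes"] >= 5).all()
        assert bt["n_spikes"].sum() <= len(st)
        for _, row in bt.iterrows():
            tr = st.train(int(row["neuron_id"]))
            inside = tr[(tr >= row["start"]) & (tr <= row["end"])]
            assert len(inside) == row["n_spikes"]
            isi = np.diff(inside)
            assert (isi <= 0.100 + 1e-12).all()


# ---------------------------------------------------------------- network bursts

class TestNetworkBurstDetection:
    def test_pooled_spike_reading_single_event(self):
        # 300 of 1091 neurons fire once within 50 ms -> ~27.5% > 20%
        ids = np.arange(300)
        times = np.linspace(1.0, 1.05, 300)
        ev = detect_network_bursts(trainset(ids, times, 1091))
        assert len(ev) == 1
        assert ev.loc[0, "n_involved"] == 300

    def test_pooled_spike_reading_below_participation(self):
        ids = np.arange(100)
        times = np.linspace(1.0, 1.05, 100)
        ev = detect_network_bursts(trainset(ids, times, 1091))
        assert len(ev) == 0

    def test_pooled_spike_reading_gap_splits_events(self):
        ids = np.tile(np.arange(300), 2)
        times = np.concatenate([np.linspace(1.0, 1.05, 300),
                                np.linspace(1.55, 1.60, 300)])
        ev = detect_network_bursts(trainset(ids, times, 1091))
        assert len(ev) == 2

    def test_empty_input(self):
        ev = detect_network_bursts(trainset([], [], 1091))
        assert len(ev) == 0

    def test_burst_cluster_reading_hand_derived(self):
        """Burst-event clustering: 30 of 100 neurons burst together twice,
        500 ms apart -> two events; their spans cover first..last burst."""
        ids, times = [], []
        for k in range(30):
            start = 1.0 + 0.001 * k
            ids += [k] * 5
            times += list(start + np.arange(5) * 0.05)
            start2 = 2.0 + 0.001 * k
            ids += [k] * 5
            times += list(start2 + np.arange(5) * 0.05)
        st = trainset(ids, times, 100, 10.0)
        ev = detect_network_bursts(st, method="bursts")
        assert len(ev) == 2
        assert (ev["n_involved"] == 30).all()
        assert ev.loc[0, "start"] == pytest.approx(1.0)
        assert ev.loc[0, "end"] == pytest.approx(1.029 + 0.2)

    def test_burst_cluster_reading_participation_filter(self):
        ids, times = [], []
        for k in range(10):                    # 10% of 100 nodes: below 20%
            ids += [k] * 5
            times += list(1.0 + 0.001 * k + np.arange(5) * 0.05)
        ev = detect_network_bursts(trainset(ids, times, 100, 10.0), method="bursts")
        assert len(ev) == 0

    def test_events_disjoint_and_gap_respected(self):
        rng = np.random.default_rng(1)
        ids = rng.integers(0, 50, 3000)
        times = np.sort(rng.uniform(0, 30, 3000))
        for method in ("spikes", "bursts"):
            ev = detect_network_bursts(trainset(ids, times, 50, 30.0), method=method)
            if len(ev) > 1:
                gaps = ev["start"].to_numpy()[1:] - ev["end"].to_numpy()[:-1]
                assert (gaps > 0.100).all()

    def test_unknown_method_rejected(self):
        with pytest.raises(ValueError):
            detect_network_bursts(trainset([], [], 10), method="magic")


# ---------------------------------------------------------------- rates

class TestRates:
    def test_single_neuron_rate(self):
        st = trainset([0] * 60, np.linspace(0, 59, 60), 1, 60.0)
        report = compute_rates(st)
        assert report.mfr_sps == pytest.approx(1.0)

    def test_low_rate_neurons_excluded_from_averages(self):
        # neuron 0 at 2 sp/s, neuron 1 at 0.08 sp/s (below the 0.1 threshold)
        ids = [0] * 120 + [1] * 5
        times = list(np.linspace(0, 59.9, 120)) + list(np.linspace(0, 50, 5))
        report = compute_rates(trainset(ids, times, 2, 60.0))
        assert report.n_active == 1
        assert report.mfr_sps == pytest.approx(2.0)

    def test_sparse_burster_excluded_from_mbr(self):
        # 3 bursts/min < 4/min activity requirement for burst statistics
        ids, times = [], []
        for b in range(3):
            ids += [0] * 6
            times += list(10.0 * b + np.arange(6) * 0.05)
        ids += [0] * 120
        times += list(40.0 + np.linspace(0, 19, 120))
        report = compute_rates(trainset(ids, times, 1, 60.0))
        assert report.n_burst_active == 0
        assert np.isnan(report.mbr_per_min)

    def test_inactive_network_flagged(self):
        report = compute_rates(trainset([0], [1.0], 5, 60.0))
        assert report.inactive
        assert np.isnan(report.mfr_sps)


# ---------------------------------------------------------------- STH / fits

def synthetic_events(n_events, n_neurons=100, shift_ms=0):
    """Identical triangular population events, optionally shifting one."""
    rng = np.random.default_rng(0)
    ids, times = [], []
    starts = 2.0 + np.arange(n_events) * 3.0
    offsets = np.sort(rng.uniform(0.0, 0.4, 400))   # one aperiodic template
    for k, s in enumerate(starts):
        offset = shift_ms / 1000.0 if k == 1 else 0.0
        for spike in range(400):
            ids.append(rng.integers(0, n_neurons))
            times.append(s + offset + offsets[spike])
    order = np.argsort(times)
    st = trainset(np.array(ids)[order], np.array(times)[order], n_neurons, 60.0)
    ev = pd.DataFrame({
        "start": starts, "end": starts + 0.5,
        "n_involved": n_neurons, "nbd_s": 0.5,
    })
    return st, ev


class TestShapeAnalysis:
    def test_identical_events_align_at_zero_lag(self):
        st, ev = synthetic_events(4)
        shape = build_sth_ifr(st, ev, seed=0)
        assert np.all(shape["lags"] == 0)
        assert np.all(shape["correlations"] > 0.99)
        assert shape["sth"] is not None

    def test_constructed_shift_recovered(self):
        st, ev = synthetic_events(4, shift_ms=30)
        shape = build_sth_ifr(st, ev, seed=0)
        ref = shape["reference"]
        expected = 30 if ref != 1 else -30
        assert shape["lags"][1] == expected

    def test_uncorrelated_noise_events_rejected(self):
        rng = np.random.default_rng(3)
        ids = rng.integers(0, 100, 6000)
        times = np.sort(rng.uniform(0, 60, 6000))
        st = trainset(ids, times, 100, 60.0)
        ev = pd.DataFrame({
            "start": [5.0, 20.0, 40.0], "end": [7.0, 22.0, 42.0],
            "n_involved": 100, "nbd_s": 2.0,
        })
        shape = build_sth_ifr(st, ev, seed=0, min_corr=0.4)
        assert shape["accepted"].sum() < 3

    def test_needs_two_events(self):
        st, ev = synthetic_events(3)
        with pytest.raises(ValueError):
            build_sth_ifr(st, ev.iloc[:1], seed=0)

    def test_plateau_bounds(self):
        sth = np.concatenate([np.linspace(0, 1, 50), np.ones(30),
                              np.linspace(1, 0, 60)])
        t_on, t_off = plateau_bounds(sth, fraction=0.8)
        assert t_on == 40           # first crossing of 0.8
        assert t_off == 50 + 30 + 11  # last bin >= 0.8 on the way down


class TestFitRecovery:
    def test_rise_value_at_origin(self):
        t = np.arange(0.0, 800.0)
        a0, a1, a3, b0, b1 = -30.0, -10.0, 45.0, 1 - 1 / 900.0, 1 - 1 / 80.0
        y = a0 * np.exp((b0 - 1) * t) + a1 * np.exp((b1 - 1) * t) + a3
        assert y[0] == pytest.approx(a0 + a1 + a3)

    def test_recovery_on_synthetic_shapes(self):
        """Median recovered-parameter error < 5% at 1% noise."""
        shapes = make_fixtures("synthetic_sth_shapes", seed=1)["shapes"]
        rng = np.random.default_rng(7)
        errors = []
        for shape in shapes:
            t = shape["t_ms"]
            y = shape["rise"]
            noisy = y + 0.01 * np.abs(y).max() * rng.standard_normal(len(y))
            fit = fit_rise(t, noisy)
            truth = shape["rise_params"]
            # exchange symmetry: compare sorted exponent pairs
            got = sorted([fit["b0"] - 1.0, fit["b1"] - 1.0])
            want = sorted([truth["b0"] - 1.0, truth["b1"] - 1.0])
            for g, w in zip(got, want):
                errors.append(abs(g - w) / abs(w))
            errors.append(abs(fit["a3"] - truth["a3"]) / abs(truth["a3"]))

            yd = shape["decay"]
            noisy = yd + 0.01 * np.abs(yd).max() * rng.standard_normal(len(yd))
            fitd = fit_decay(t, noisy)
            td = shape["decay_params"]
            got = sorted([fitd["d0"], fitd["d1"]])
            want = sorted([td["d0"], td["d1"]])
            for g, w in zip(got, want):
                errors.append(abs(g - w) / abs(w))
        assert np.median(errors) < 0.05

    def test_single_exponential_special_case(self):
        t = np.arange(0.0, 1000.0)
        tau = 250.0
        y = 40.0 * np.exp(-t / tau)
        fit = fit_decay(t, y)
        assert fit["tau_decay_ms"] == pytest.approx(tau, rel=0.05)
        assert fit["c0"] * np.exp(fit["d0"] * 0) + fit["c1"] == pytest.approx(40.0, rel=0.02)


# ---------------------------------------------------------------- Victor-Purpura

def vp_bruteforce(a, b, q):
    """Independent oracle: minimum cost over all monotone spike matchings."""
    na, nb = len(a), len(b)
    best = float(na + nb)
    for k in range(1, min(na, nb) + 1):
        for ia in itertools.combinations(range(na), k):
            for ib in itertools.combinations(range(nb), k):
                cost = (na - k) + (nb - k) + sum(
                    q * abs(a[i] - b[j]) for i, j in zip(ia, ib)
                )
                best = min(best, cost)
    return best


class TestVictorPurpura:
    def test_identical_trains(self):
        t = np.array([0.1, 0.5, 0.9])
        assert victor_purpura_distance(t, t, 10.0) == 0.0

    def test_single_extra_spike(self):
        a = np.array([0.1, 0.5, 0.9])
        b = np.array([0.1, 0.5, 0.7, 0.9])
        for q in (0.0, 1.0, 100.0):
            assert victor_purpura_distance(a, b, q) == pytest.approx(1.0)

    def test_single_spikes_shift_cheaper_than_reinsertion(self):
        assert victor_purpura_distance([0.0], [0.15], 10.0) == pytest.approx(1.5)
        assert victor_purpura_distance([0.0], [0.5], 10.0) == pytest.approx(2.0)

    def test_negative_cost_rejected(self):
        with pytest.raises(ValueError):
            victor_purpura_distance([0.1], [0.2], -1.0)

    def test_matches_bruteforce_oracle(self):
        rng = np.random.default_rng(11)
        for _ in range(60):
            a = np.sort(rng.uniform(0, 1, rng.integers(0, 5)))
            b = np.sort(rng.uniform(0, 1, rng.integers(0, 5)))
            q = float(rng.uniform(0, 20))
            assert victor_purpura_distance(a, b, q) == pytest.approx(
                vp_bruteforce(a, b, q)
            )

    def test_metric_axioms(self):
        rng = np.random.default_rng(13)
        trains = [np.sort(rng.uniform(0, 1, rng.integers(0, 5))) for _ in range(8)]
        q = 8.0
        for x in trains:
            assert victor_purpura_distance(x, x, q) == 0.0
        for x, y in itertools.combinations(trains, 2):
            dxy = victor_purpura_distance(x, y, q)
            assert dxy == pytest.approx(victor_purpura_distance(y, x, q))
        for x, y, z in itertools.combinations(trains, 3):
            assert (
                victor_purpura_distance(x, z, q)
                <= victor_purpura_distance(x, y, q)
                + victor_purpura_distance(y, z, q)
                + 1e-9
            )


class TestLayerSimilarity:
    def test_duplicated_layers_maximally_similar(self):
        rng = np.random.default_rng(5)
        times = np.sort(rng.uniform(0, 10, 200))
        ids = np.concatenate([np.zeros(200), np.ones(200)]).astype(int)
        st = trainset(ids, np.concatenate([times, times]), 2, 10.0,
                      layer_of=np.array([0, 1]))
        result = layer_similarity_map(st, q=10.0)
        assert result["normalized"][0, 1] == pytest.approx(1.0)
        # diagonal (self) similarity dominates
        assert result["similarity"][0, 0] >= result["similarity"][0, 1]

    def test_four_layer_step_classes(self):
        rng = np.random.default_rng(6)
        ids, times, layer_of = [], [], []
        for layer in range(4):
            t = np.sort(rng.uniform(0, 10, 150))
            ids += [layer] * 150
            times += list(t)
            layer_of.append(layer)
        st = trainset(ids, times, 4, 10.0, layer_of=np.array(layer_of))
        result = layer_similarity_map(st, q=10.0)
        assert set(result["top_step_distances"]).issubset({1, 2, 3})
        assert len(result["top_step_distances"]) == 3

    def test_requires_two_layers(self):
        st = trainset([0], [1.0], 1, 10.0, layer_of=np.array([0]))
        with pytest.raises(ValueError):
            layer_similarity_map(st)


# ---------------------------------------------------------------- container I/O

class TestSpikeTrainSet:
    def test_tsv_roundtrip(self, tmp_path):
        rng = np.random.default_rng(2)
        times = np.round(np.sort(rng.uniform(0, 10, 100)), 4)
        ids = rng.integers(0, 7, 100)
        st = trainset(ids, times, 7, 10.0, layer_of=np.zeros(7, dtype=int))
        path = tmp_path / "run.spk"
        st.to_tsv(str(path))
        back = SpikeTrainSet.from_tsv(str(path))
        np.testing.assert_array_equal(back.neuron_ids, st.neuron_ids)
        np.testing.assert_allclose(back.times, st.times, atol=1e-9)
        assert back.n_neurons == 7 and back.duration == 10.0

    def test_layer_extraction_reindexes(self):
        st = trainset([0, 1, 2, 3], [0.1, 0.2, 0.3, 0.4], 4, 1.0,
                      layer_of=np.array([0, 0, 1, 1]))
        sub = st.for_layer(1)
        assert sub.n_neurons == 2
        np.testing.assert_array_equal(sub.neuron_ids, [0, 1])
        np.testing.assert_allclose(sub.times, [0.3, 0.4])
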