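"""Leaky integrate-and-fire network simulation.

Model
-----
Each neuron follows ``tau_m dV/dt = (E_L - V) + (I_noise + I_syn)/g_L`` and
is integrated with the exponential Euler method on a 0.1 ms grid: inputs are
held constant over a step, so the per-step membrane update is the exact
closed-form relaxation towards ``V_inf = E_L + (I_noise + I_synEX -
I_synIN)/g_L``.  Crossing -50 mV emits a spike, resets the membrane to
-70 mV and freezes it for the 5 ms refractory period (synaptic currents keep
decaying and accumulating).

The two synaptic currents decay exponentially with a common 10 ms time
constant.  A presynaptic spike arriving over an edge increments the
excitatory (inhibitory) current of the target by ``alpha_EX * w``
(``alpha_IN * w``); the net drive in the membrane equation is
``I_synEX - I_synIN``.  Deliveries are scheduled through a ring buffer at
the edge's conduction delay (distance / 0.5 mm/ms, ceiled to the grid).

The sub-threshold noise drive is redrawn independently per neuron every
millisecond as ``g_L * U{0..5} * noise_unit``.  All currents are handled as
voltage drives I/g_L (mV), which removes the conductance from the arithmetic
without changing the model.

The hot loop is compiled with numba; spikes are recorded at 10 kHz from the
end of the settle window onward.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from numba import njit

from .config import SimConfig
from .spiketrains import SpikeTrainSet

log = logging.getLogger(__name__)


@njit(cache=True)
def _run_chunk(
    V, syn_ex, syn_in, refr_until,
    noise,                      # (n_epochs, N) voltage drive, mV
    drive,                      # (N,) constant external drive, mV
    indptr, post, delay_steps, inc, pre_is_inh,
    ex_buf, in_buf,             # (D, N) ring buffers
    t0, steps_per_epoch,
    decay_m, decay_s,
    e_l, v_th, v_reset, refr_steps,
    rec_start, spike_n, spike_t, n_spikes, counts,
    v_out,                      # (total_steps, N) or empty: membrane trace
):
    N = V.shape[0]
    D = ex_buf.shape[0]
    max_spikes = spike_n.shape[0]
    t = t0
    for e in range(noise.shape[0]):
        for _ in range(steps_per_epoch):
            slot = t % D
            for i in range(N):
                syn_ex[i] = syn_ex[i] * decay_s + ex_buf[slot, i]
                syn_in[i] = syn_in[i] * decay_s + in_buf[slot, i]
                ex_buf[slot, i] = 0.0
                in_buf[slot, i] = 0.0
                if t < refr_until[i]:
                    V[i] = v_reset
                    if v_out.shape[0] > 0:
                        v_out[t, i] = V[i]
                    continue
                v_inf = e_l + drive[i] + noise[e, i] + syn_ex[i] - syn_in[i]
                V[i] = v_inf + (V[i] - v_inf) * decay_m
                if V[i] >= v_th:
                    V[i] = v_reset
                    refr_until[i] = t + refr_steps
                    if t >= rec_start:
                        counts[i] += 1
                        if n_spikes < max_spikes:
                            spike_n[n_spikes] = i
                            spike_t[n_spikes] = t
                            n_spikes += 1
                    for j in range(indptr[i], indptr[i + 1]):
                        s2 = (t + delay_steps[j]) % D
                        if pre_is_inh[i]:
                            in_buf[s2, post[j]] += inc[j]
                        else:
                            ex_buf[s2, post[j]] += inc[j]
                if v_out.shape[0] > 0:
                    v_out[t, i] = V[i]
            t += 1
    return n_spikes


def _build_csr(
    neurons: pd.DataFrame, synapses: pd.DataFrame, config: SimConfig
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Sort edges by presynaptic neuron into CSR arrays for the kernel."""
    n = len(neurons)
    ids = neurons["id"].to_numpy()
    id_to_row = np.full(ids.max() + 1 if n else 1, -1, dtype=np.int64)
    id_to_row[ids] = np.arange(n)

    pre = id_to_row[synapses["pre_id"].to_numpy(dtype=np.int64)]
    post = id_to_row[synapses["post_id"].to_numpy(dtype=np.int64)]
    is_inh = neurons["is_inhibitory"].to_numpy()
    alpha = np.where(is_inh[pre], config.alpha_in, config.alpha_ex)
    inc = alpha * synapses["weight"].to_numpy()
    delay_steps = np.maximum(
        np.round(synapses["delay"].to_numpy() / config.dt_ms).astype(np.int64), 1
    )

    order = np.argsort(pre, kind="stable")
    pre, post, inc, delay_steps = pre[order], post[order], inc[order], delay_steps[order]
    indptr = np.zeros(n + 1, dtype=np.int64)
    np.add.at(indptr, pre + 1, 1)
    np.cumsum(indptr, out=indptr)
    return indptr, post.astype(np.int64), delay_steps, inc.astype(float), is_inh


def run(
    neurons: pd.DataFrame,
    synapses: pd.DataFrame,
    config: SimConfig | None = None,
    seed: int = 0,
    max_stored_spikes: int = 20_000_000,
    drive_mv: np.ndarray | None = None,
    record_v: bool = False,
) -> SpikeTrainSet:
    """Simulate the network and return the recorded spike trains.

    ``drive_mv`` adds a constant per-neuron external drive (I/g_L, mV) on
    top of the noise — useful for controlled single-neuron protocols.  With
    ``record_v`` the full membrane trace is kept (attribute ``v_trace`` of
    the result; only sensible for small networks/durations).

    The settle window is simulated but not recorded.  If the network fires so
    much that the spike store fills up, exact per-neuron counts are still
    kept and the result is flagged ``truncated``; if the population mean rate
    exceeds the runaway guard the result is flagged ``guard_tripped`` (the
    run is returned either way).
    """
    config = config or SimConfig()
    config.validate()
    rng = np.random.default_rng(seed)

    n = len(neurons)
    if n == 0:
        raise ValueError("empty neuron table")
    indptr, post, delay_steps, inc, is_inh = _build_csr(neurons, synapses, config)

    steps_per_epoch = int(round(config.noise_refresh_ms / config.dt_ms))
    total_ms = (config.settle_s + config.record_s) * 1000.0
    n_epochs = int(round(total_ms / config.noise_refresh_ms))
    rec_start = int(round(config.settle_s * 1000.0 / config.dt_ms))

    D = int(delay_steps.max()) + 1 if len(delay_steps) else 2
    ex_buf = np.zeros((D, n))
    in_buf = np.zeros((D, n))
    V = np.full(n, config.e_leak_mv)
    syn_ex = np.zeros(n)
    syn_in = np.zeros(n)
    refr_until = np.zeros(n, dtype=np.int64)
    counts = np.zeros(n, dtype=np.int64)

    cap = min(max_stored_spikes, int(n * config.record_s * config.guard_rate_sps) + 1)
    spike_n = np.empty(cap, dtype=np.int64)
    spike_t = np.empty(cap, dtype=np.int64)
    n_spikes = 0

    drive = (
        np.zeros(n) if drive_mv is None else np.asarray(drive_mv, dtype=float)
    )
    if drive.shape != (n,):
        raise ValueError("drive_mv must have one entry per neuron")
    total_steps = n_epochs * steps_per_epoch
    v_out = np.empty((total_steps if record_v else 0, n))
    decay_m = float(np.exp(-config.dt_ms / config.tau_m_ms))
    decay_s = float(np.exp(-config.dt_ms / config.tau_syn_ms))
    refr_steps = int(round(config.refractory_ms / config.dt_ms))

    epochs_per_call = 1000  # one second of noise per kernel call
    t = 0
    done = 0
    while done < n_epochs:
        batch = min(epochs_per_call, n_epochs - done)
        noise = (
            rng.integers(0, config.noise_levels + 1, size=(batch, n)).astype(float)
            * config.noise_unit_mv
        )
        n_spikes = _run_chunk(
            V, syn_ex, syn_in, refr_until, noise, drive,
            indptr, post, delay_steps, inc, is_inh,
            ex_buf, in_buf,
            t, steps_per_epoch, decay_m, decay_s,
            config.e_leak_mv, config.v_threshold_mv, config.v_reset_mv, refr_steps,
            rec_start, spike_n, spike_t, n_spikes, counts, v_out,
        )
        t += batch * steps_per_epoch
        done += batch

    truncated = bool(counts.sum() > n_spikes)
    times_s = (spike_t[:n_spikes] - rec_start) * config.dt_ms / 1000.0
    mfr_all = counts.mean() / config.record_s
    guard = bool(mfr_all > config.guard_rate_sps)
    if guard:
        log.warning("runaway firing: population mean rate %.1f sp/s", mfr_all)
    if truncated:
        log.warning("spike store full: times truncated, counts remain exact")

    result = SpikeTrainSet(
        neuron_ids=spike_n[:n_spikes].copy(),
        times=times_s,
        n_neurons=n,
        duration=config.record_s,
        layer_of=neurons["layer"].to_numpy().copy(),
        is_inhibitory=neurons["is_inhibitory"].to_numpy().copy(),
        counts=counts,
        truncated=truncated,
        guard_tripped=guard,
    )
    if record_v:
        result.v_trace = v_out        # (steps, N), settle window included
    return result
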