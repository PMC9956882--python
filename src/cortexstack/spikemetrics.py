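"""Spike-train analytics for cultured-network recordings.

Implements the standard MEA analysis chain on a :class:`SpikeTrainSet`:

* single-neuron burst detection with the string method (>= 5 spikes, all
  inter-spike intervals <= 100 ms);
* network-burst detection (clusters bounded by > 100 ms gaps, participation
  >= 20% of the nodes) in two readings: over the pooled spike train or over
  the single-neuron burst events;
* rate metrics (MFR in sp/s, MBR in bursts/min, burst duration BD, network
  burst duration NBD) averaged over *active* neurons only (MFR > 0.1 sp/s;
  for burst statistics additionally MBR > 4 bursts/min);
* network-burst shape analysis: 1 ms spike-time histograms (STH) aligned by
  cross-correlation against a randomly chosen reference event, the smoothed
  instantaneous firing rate (IFR), and double-exponential fits of the rising
  and decaying phases yielding the recruitment (tau_rise) and modulation
  (tau_decay) time constants;
* the Victor-Purpura spike-train edit distance and layer-by-layer
  similarity maps.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter1d
from scipy.optimize import curve_fit

from .spiketrains import SpikeTrainSet

log = logging.getLogger(__name__)

MIN_BURST_SPIKES = 5
MAX_BURST_ISI_S = 0.100
NB_GAP_S = 0.100
NB_PARTICIPATION = 0.20
ACTIVE_MFR_SPS = 0.1
ACTIVE_MBR_PER_MIN = 4.0
ALIGN_MIN_CORR = 0.4
STH_BIN_S = 0.001
IFR_SMOOTH_MS = 10.0
PLATEAU_FRACTION = 0.8


# ---------------------------------------------------------------------------
# burst detection

def detect_bursts(
    train: np.ndarray,
    min_spikes: int = MIN_BURST_SPIKES,
    max_isi: float = MAX_BURST_ISI_S,
) -> list[tuple[float, float, int]]:
    """String-method burst detection on one sorted spike train.

    Returns maximal runs of consecutive spikes whose inter-spike intervals
    are all <= ``max_isi`` (seconds) and that contain at least ``min_spikes``
    spikes, as ``(start_s, end_s, n_spikes)`` tuples.
    """
    train = np.asarray(train, dtype=float)
    if len(train) > 1 and np.any(np.diff(train) < 0):
        raise ValueError("spike train must be sorted")
    if len(train) < min_spikes:
        return []
    isi = np.diff(train)
    # runs of consecutive ISIs <= max_isi; a run of k ISIs spans k+1 spikes
    # (tiny tolerance so grid-exact boundary intervals stay inside the burst)
    breaks = np.flatnonzero(isi > max_isi + 1e-9)
    starts = np.concatenate([[0], breaks + 1])
    ends = np.concatenate([breaks, [len(train) - 1]])
    out = []
    for s, e in zip(starts, ends):
        if e - s + 1 >= min_spikes:
            out.append((float(train[s]), float(train[e]), int(e - s + 1)))
    return out


def burst_table(spikes: SpikeTrainSet, min_spikes: int = MIN_BURST_SPIKES,
                max_isi: float = MAX_BURST_ISI_S) -> pd.DataFrame:
    """Per-neuron burst events: neuron_id, start/end (s), n_spikes, bd_ms."""
    rows = []
    for nid, train in enumerate(spikes.trains()):
        for start, end, count in detect_bursts(train, min_spikes, max_isi):
            rows.append((nid, start, end, count, (end - start) * 1000.0))
    return pd.DataFrame(
        rows, columns=["neuron_id", "start", "end", "n_spikes", "bd_ms"]
    )


def detect_network_bursts(
    spikes: SpikeTrainSet,
    gap: float = NB_GAP_S,
    participation: float = NB_PARTICIPATION,
    method: str = "spikes",
    bursts: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Network bursts of the analysed population.

    Two readings of the two-threshold population-event algorithm are
    provided.  ``method="spikes"`` clusters the pooled spike train wherever
    consecutive spikes are closer than ``gap`` seconds.  ``method="bursts"``
    (used for the network statistics; see docs/methods.md) clusters the
    single-neuron burst events instead: bursts whose intervals (end of one
    to start of the next) are at most ``gap`` apart merge into one
    population event, which tolerates the tonic background firing of a
    noise-driven culture.  Either way, clusters engaging at least
    ``participation`` of the ``n_neurons`` nodes are kept.  Returns
    start/end (s), n_involved, nbd_s (cluster span).
    """
    cols = ["start", "end", "n_involved", "nbd_s"]
    if method == "spikes":
        if len(spikes) == 0:
            return pd.DataFrame(columns=cols)
        times = spikes.times
        ids = spikes.neuron_ids
        breaks = np.flatnonzero(np.diff(times) > gap)
        starts = np.concatenate([[0], breaks + 1])
        ends = np.concatenate([breaks, [len(times) - 1]])
        threshold = participation * spikes.n_neurons
        rows = []
        for s, e in zip(starts, ends):
            involved = len(np.unique(ids[s : e + 1]))
            if involved >= threshold:
                rows.append(
                    (float(times[s]), float(times[e]), involved, float(times[e] - times[s]))
                )
        return pd.DataFrame(rows, columns=cols)
    if method != "bursts":
        raise ValueError(f"unknown network-burst method {method!r}")
    if bursts is None:
        bursts = burst_table(spikes)
    if len(bursts) == 0:
        return pd.DataFrame(columns=cols)
    ev = bursts.sort_values("start").reset_index(drop=True)
    starts_arr = ev["start"].to_numpy()
    ends_arr = ev["end"].to_numpy()
    ids_arr = ev["neuron_id"].to_numpy()
    threshold = participation * spikes.n_neurons
    rows = []
    cluster = [0]
    running_end = ends_arr[0]
    for i in range(1, len(ev) + 1):
        if i < len(ev) and starts_arr[i] - running_end <= gap:
            cluster.append(i)
            running_end = max(running_end, ends_arr[i])
        else:
            involved = len(np.unique(ids_arr[cluster]))
            if involved >= threshold:
                first = starts_arr[cluster].min()
                last = ends_arr[cluster].max()
                rows.append((float(first), float(last), involved, float(last - first)))
            if i < len(ev):
                cluster = [i]
                running_end = ends_arr[i]
    return pd.DataFrame(rows, columns=cols)


# ---------------------------------------------------------------------------
# rate metrics

@dataclass
class MetricsReport:
    """Per-network summary metrics (averages over active neurons)."""

    n_neurons: int = 0
    n_active: int = 0
    n_burst_active: int = 0
    mfr_sps: float = float("nan")          # mean firing rate over active neurons
    mbr_per_min: float = float("nan")      # mean bursting rate over burst-active
    bd_ms: float = float("nan")            # mean burst duration
    nb_rate_per_min: float = float("nan")  # network bursts per minute
    nbd_s: float = float("nan")            # mean network burst duration
    tau_rise_ms: float = float("nan")
    tau_decay_ms: float = float("nan")
    align_corr: float = float("nan")
    inactive: bool = False
    guard_tripped: bool = False

    def as_dict(self) -> dict:
        return {k: getattr(self, k) for k in self.__dataclass_fields__}


def compute_rates(
    spikes: SpikeTrainSet,
    bursts: pd.DataFrame | None = None,
    duration: float | None = None,
) -> MetricsReport:
    """Firing/bursting rates with the activity filters applied.

    A neuron enters the MFR average only if its rate exceeds 0.1 sp/s; it
    enters the MBR/BD averages only if it additionally produces more than
    4 bursts per minute.
    """
    duration = duration if duration is not None else spikes.duration
    if duration <= 0:
        raise ValueError("duration must be positive")
    if bursts is None:
        bursts = burst_table(spikes)

    rates = spikes.counts / duration
    active = rates > ACTIVE_MFR_SPS
    report = MetricsReport(
        n_neurons=spikes.n_neurons,
        n_active=int(active.sum()),
        guard_tripped=spikes.guard_tripped,
    )
    if report.n_active == 0:
        report.inactive = True
        return report
    report.mfr_sps = float(rates[active].mean())

    burst_counts = np.zeros(spikes.n_neurons, dtype=np.int64)
    if len(bursts):
        np.add.at(burst_counts, bursts["neuron_id"].to_numpy(), 1)
    mbr = burst_counts / duration * 60.0
    burst_active = active & (mbr > ACTIVE_MBR_PER_MIN)
    report.n_burst_active = int(burst_active.sum())
    if report.n_burst_active:
        report.mbr_per_min = float(mbr[burst_active].mean())
        sel = bursts[bursts["neuron_id"].isin(np.flatnonzero(burst_active))]
        report.bd_ms = float(sel["bd_ms"].mean())
    return report


# ---------------------------------------------------------------------------
# network-burst shape

def build_sth_ifr(
    spikes: SpikeTrainSet,
    events: pd.DataFrame,
    bin_s: float = STH_BIN_S,
    min_corr: float = ALIGN_MIN_CORR,
    seed: int = 0,
    smooth_ms: float = IFR_SMOOTH_MS,
) -> dict:
    """Average spike-time histogram of the network bursts, after alignment.

    One event is chosen (seeded) as the reference; every other event's 1 ms
    histogram is shifted by the lag that maximises the absolute
    cross-correlation with it and accepted when the correlation coefficient
    at that lag exceeds ``min_corr``.  The IFR is the Gaussian-smoothed
    average STH.
    """
    if len(events) < 2:
        raise ValueError("need at least two network bursts to build an average STH")
    rng = np.random.default_rng(seed)
    span = float(events["nbd_s"].max())
    n_bins = int(np.ceil(span / bin_s)) + 1
    hists = []
    for _, ev in events.iterrows():
        sel = (spikes.times >= ev["start"]) & (spikes.times <= ev["end"])
        rel = spikes.times[sel] - ev["start"]
        hist, _ = np.histogram(rel, bins=n_bins, range=(0.0, n_bins * bin_s))
        hists.append(hist.astype(float))
    hists = np.array(hists)

    ref = int(rng.integers(len(hists)))
    lags = np.zeros(len(hists), dtype=int)
    corrs = np.ones(len(hists))
    accepted = np.ones(len(hists), dtype=bool)
    ref_hist = hists[ref]
    for i, hist in enumerate(hists):
        if i == ref:
            continue
        xc = np.correlate(hist - hist.mean(), ref_hist - ref_hist.mean(), mode="full")
        lag = int(np.argmax(np.abs(xc))) - (n_bins - 1)
        lags[i] = lag
        shifted = np.roll(hist, -lag)
        r = np.corrcoef(shifted, ref_hist)[0, 1]
        corrs[i] = 0.0 if np.isnan(r) else float(r)
        accepted[i] = corrs[i] > min_corr

    aligned = np.array([np.roll(h, -l) for h, l in zip(hists, lags)])
    if accepted.sum() < 2:
        sth = None
        ifr = None
    else:
        sth = aligned[accepted].mean(axis=0)
        ifr = gaussian_filter1d(sth, smooth_ms * (0.001 / bin_s))
    return {
        "sth": sth,
        "ifr": ifr,
        "bin_s": bin_s,
        "lags": lags,
        "correlations": corrs,
        "accepted": accepted,
        "reference": ref,
        "per_event": hists,
    }


def plateau_bounds(sth: np.ndarray, fraction: float = PLATEAU_FRACTION) -> tuple[int, int]:
    """First/last bin where the STH crosses ``fraction`` of its peak
    (t_on, t_off of the plateau phase)."""
    level = fraction * sth.max()
    above = np.flatnonzero(sth >= level)
    return int(above[0]), int(above[-1])


def _double_exp_rise(t, a0, a1, a3, l0, l1):
    return a0 * np.exp(l0 * t) + a1 * np.exp(l1 * t) + a3


def _double_exp_decay(t, c0, c1, d0, d1):
    return c0 * np.exp(d0 * t) + c1 * np.exp(d1 * t)


def _multistart_fit(model, t, y, n_params, rng, exponent_bounds, n_exp=2):
    """Nonlinear least squares from 8 log-spaced exponent starting points."""
    best = None
    best_cost = np.inf
    scale = max(abs(y).max(), 1e-12)
    for mag in np.logspace(-4, -1, 8):
        for signs in ([-1, -1], [-1, 1]) if exponent_bounds is None else ([-1, -1],):
            p0 = np.concatenate(
                [np.full(n_params - n_exp, scale / 2.0), [signs[0] * mag, signs[1] * mag * 3]]
            )
            try:
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    popt, _ = curve_fit(model, t, y, p0=p0, maxfev=20000)
            except (RuntimeError, ValueError):
                continue
            with np.errstate(over="ignore", invalid="ignore"):
                resid = model(t, *popt) - y
                cost = float(np.sum(resid * resid))
            if not np.isfinite(cost):
                continue
            if cost < best_cost:
                best_cost = cost
                best = popt
    if best is None:
        raise RuntimeError("double-exponential fit failed from all starting points")
    return best


def fit_rise(t_ms: np.ndarray, y: np.ndarray, seed: int = 0) -> dict:
    """Fit the rising phase ``r(t) = a0 e^{(b0-1)t} + a1 e^{(b1-1)t} + a3``.

    ``t_ms`` runs from event onset to the plateau start, in ms.  The smaller
    of the two exponents ``b0, b1`` defines the neuron recruitment rate;
    tau_rise is reported as ``1 / |min(b0, b1) - 1|`` in ms.
    """
    rng = np.random.default_rng(seed)
    popt = _multistart_fit(_double_exp_rise, np.asarray(t_ms, float), np.asarray(y, float),
                          5, rng, exponent_bounds=None)
    a0, a1, a3, l0, l1 = popt
    b0, b1 = l0 + 1.0, l1 + 1.0
    b_min = min(b0, b1)
    tau = 1.0 / abs(b_min - 1.0) if b_min != 1.0 else np.inf
    return {"a0": a0, "a1": a1, "a3": a3, "b0": b0, "b1": b1,
            "recruitment_exponent": b_min, "tau_rise_ms": tau}


def fit_decay(t_ms: np.ndarray, y: np.ndarray, seed: int = 0) -> dict:
    """Fit the decaying phase ``s(t) = c0 e^{d0 t} + c1 e^{d1 t}``.

    tau_decay is the reciprocal magnitude of the smaller (more negative)
    exponent, in ms.
    """
    rng = np.random.default_rng(seed)
    popt = _multistart_fit(_double_exp_decay, np.asarray(t_ms, float), np.asarray(y, float),
                          4, rng, exponent_bounds="negative")
    c0, c1, d0, d1 = popt
    d_min = min(d0, d1)
    tau = 1.0 / abs(d_min) if d_min != 0.0 else np.inf
    return {"c0": c0, "c1": c1, "d0": d0, "d1": d1,
            "modulation_exponent": d_min, "tau_decay_ms": tau}


def fit_event_shape(sth: np.ndarray, bin_s: float = STH_BIN_S, seed: int = 0) -> dict:
    """Plateau bounds plus rise/decay fits of an average STH."""
    t_on, t_off = plateau_bounds(sth)
    out = {"t_on_bin": t_on, "t_off_bin": t_off}
    bin_ms = bin_s * 1000.0
    rise_t = np.arange(t_on + 1) * bin_ms
    decay_t = np.arange(len(sth) - t_off) * bin_ms
    try:
        out.update(fit_rise(rise_t, sth[: t_on + 1], seed))
    except RuntimeError:
        out["tau_rise_ms"] = float("nan")
    try:
        out.update(fit_decay(decay_t, sth[t_off:], seed))
    except RuntimeError:
        out["tau_decay_ms"] = float("nan")
    return out


# ---------------------------------------------------------------------------
# end-to-end report

def analyze(
    spikes: SpikeTrainSet,
    layer: int | None = None,
    include_shape: bool = True,
    seed: int = 0,
) -> MetricsReport:
    """Full analysis of one recording (optionally restricted to one layer)."""
    if layer is not None:
        spikes = spikes.for_layer(layer)
    bursts = burst_table(spikes)
    report = compute_rates(spikes, bursts)
    events = detect_network_bursts(spikes, method="bursts", bursts=bursts)
    if len(events):
        report.nb_rate_per_min = float(len(events) / spikes.duration * 60.0)
        report.nbd_s = float(events["nbd_s"].mean())
    if include_shape and len(events) >= 2:
        try:
            shape = build_sth_ifr(spikes, events, seed=seed)
            if shape["sth"] is not None:
                report.align_corr = float(
                    np.mean(shape["correlations"][shape["accepted"]])
                )
                fits = fit_event_shape(shape["sth"], shape["bin_s"], seed)
                report.tau_rise_ms = float(fits.get("tau_rise_ms", float("nan")))
                report.tau_decay_ms = float(fits.get("tau_decay_ms", float("nan")))
        except (RuntimeError, ValueError) as err:
            log.warning("shape analysis unavailable: %s", err)
    return report


# ---------------------------------------------------------------------------
# Victor-Purpura

def victor_purpura_distance(
    train_a: np.ndarray, train_b: np.ndarray, q: float
) -> float:
    """Victor-Purpura edit distance between two sorted spike trains.

    Insertion/deletion cost 1, shifting a spike by dt costs ``q * |dt|``
    (``q`` in 1/s for times in seconds).  Computed by the standard dynamic
    programme.
    """
    if q < 0:
        raise ValueError("q must be non-negative")
    a = np.asarray(train_a, dtype=float)
    b = np.asarray(train_b, dtype=float)
    na, nb = len(a), len(b)
    if na == 0 or nb == 0:
        return float(na + nb)
    cost = np.empty((na + 1, nb + 1))
    cost[:, 0] = np.arange(na + 1)
    cost[0, :] = np.arange(nb + 1)
    for i in range(1, na + 1):
        shift = q * np.abs(a[i - 1] - b)          # (nb,)
        for j in range(1, nb + 1):
            cost[i, j] = min(
                cost[i - 1, j] + 1.0,
                cost[i, j - 1] + 1.0,
                cost[i - 1, j - 1] + shift[j - 1],
            )
    return float(cost[na, nb])


def layer_similarity_map(
    spikes: SpikeTrainSet,
    q: float = 10.0,
    max_spikes: int = 2000,
) -> dict:
    """Normalised layer-by-layer Victor-Purpura similarity map.

    Each layer's pooled train (uniformly subsampled to ``max_spikes`` when
    longer, to keep the quadratic edit distance tractable) is compared with
    every other; similarity is ``1 / (1 + VP distance)``, normalised to the
    maximum off-diagonal entry.  The top three similarities are classified by
    layer step distance (consecutive layers are 1-step apart).
    """
    if spikes.layer_of is None:
        raise ValueError("no layer metadata attached")
    layers = np.unique(spikes.layer_of)
    if len(layers) < 2:
        raise ValueError("need at least two layers")
    pooled = {}
    for layer in layers:
        sub = spikes.for_layer(int(layer))
        if len(sub) == 0:
            warnings.warn(f"layer {layer} is silent; excluded from similarity map")
            continue
        train = sub.times
        if len(train) > max_spikes:
            idx = np.linspace(0, len(train) - 1, max_spikes).astype(int)
            train = train[idx]
        pooled[int(layer)] = train
    keys = sorted(pooled)
    k = len(keys)
    sim = np.zeros((k, k))
    for i in range(k):
        for j in range(i, k):
            d = victor_purpura_distance(pooled[keys[i]], pooled[keys[j]], q)
            sim[i, j] = sim[j, i] = 1.0 / (1.0 + d)

    off = sim[~np.eye(k, dtype=bool)]
    norm = sim / off.max() if off.max() > 0 else sim
    pairs = [(i, j) for i in range(k) for j in range(i + 1, k)]
    ranked = sorted(pairs, key=lambda p: -sim[p])
    steps = [abs(keys[i] - keys[j]) for i, j in ranked[:3]]
    return {"layers": keys, "similarity": sim, "normalized": norm,
            "top_step_distances": steps}
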