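"""Experiment orchestration: presets, batch runs, group statistics, fixtures.

The study design couples each connectivity preset with a replicate count and
(for 3D presets) a spread of layer counts.  ``paper_plan`` reproduces the
full design (n = 20 G2D, 28 SF2D, 25 G3D over 2-6 layers, 22 SFall3D,
12 SFL03D, 12 restricted-source 4-layer networks); ``desk_plan`` is the
scaled profile used for quick replication on a workstation.

All randomness derives from one master seed: run k of the plan uses seed
``master_seed * 1000 + k`` for placement, wiring, noise and the analysis
reference choice alike.
"""

from __future__ import annotations

import hashlib
import json
import logging
import warnings
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .config import GeometryConfig, ConnectivityConfig, SimConfig
from .topology import assemble_network
from .dynamics import run
from .spikemetrics import analyze, MetricsReport
from .spiketrains import SpikeTrainSet

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class PlanEntry:
    preset: str
    n_layers: int
    n_replicates: int


@dataclass
class ExperimentPlan:
    entries: list[PlanEntry]
    master_seed: int = 0

    def runs(self) -> list[tuple[int, str, int, int]]:
        """Enumerate (run_index, preset, n_layers, seed) deterministically."""
        out = []
        counter = 0
        for entry in self.entries:
            if entry.n_replicates < 1:
                raise ValueError("replicate counts must be >= 1")
            for _ in range(entry.n_replicates):
                seed = (self.master_seed * 1000 + counter) % (2**31 - 1)
                out.append((counter, entry.preset, entry.n_layers, seed))
                counter += 1
        return out


def paper_plan(master_seed: int = 0) -> ExperimentPlan:
    """The full dataset design (one entry per preset/layer-count cell)."""
    entries = [PlanEntry("G2D", 1, 20), PlanEntry("SF2D", 1, 28)]
    entries += [PlanEntry("G3D", k, 5) for k in range(2, 7)]
    entries += [PlanEntry("SFall3D", k, n) for k, n in zip(range(2, 7), (5, 5, 4, 4, 4))]
    entries += [PlanEntry("SFL03D", 4, 12)]
    entries += [PlanEntry(p, 4, 4) for p in ("Grnd3D", "GC3D", "G5C3D")]
    return ExperimentPlan(entries, master_seed)


def desk_plan(master_seed: int = 0, replicates: int = 5) -> ExperimentPlan:
    """Scaled profile: ``replicates`` runs per group, 4 layers for 3D."""
    entries = [
        PlanEntry("G2D", 1, replicates),
        PlanEntry("SF2D", 1, replicates),
        PlanEntry("G3D", 4, replicates),
        PlanEntry("SFall3D", 4, replicates),
        PlanEntry("SFL03D", 4, replicates),
        PlanEntry("Grnd3D", 4, replicates),
        PlanEntry("GC3D", 4, replicates),
        PlanEntry("G5C3D", 4, replicates),
    ]
    return ExperimentPlan(entries, master_seed)


def _config_hash(*configs) -> str:
    payload = json.dumps([asdict(c) for c in configs], sort_keys=True)
    return hashlib.sha256(payload.encode()).hexdigest()[:16]


def run_one(
    preset: str,
    n_layers: int,
    seed: int,
    geometry: GeometryConfig | None = None,
    connectivity: ConnectivityConfig | None = None,
    sim: SimConfig | None = None,
    layer: int | None = 0,
) -> tuple[MetricsReport, SpikeTrainSet]:
    """Build, simulate and analyse a single network.

    By default the metrics are computed on the readout (bottom) layer, the
    only one a planar MEA observes.
    """
    sim = sim or SimConfig()
    neurons, synapses = assemble_network(
        preset, n_layers, seed, geometry, connectivity, dt_ms=sim.dt_ms
    )
    spikes = run(neurons, synapses, sim, seed=seed)
    which = None if (layer is None or n_layers == 1) else layer
    report = analyze(spikes, layer=which, seed=seed)
    return report, spikes


def run_experiment(
    plan: ExperimentPlan,
    output_root: str | Path,
    geometry: GeometryConfig | None = None,
    connectivity: ConnectivityConfig | None = None,
    sim: SimConfig | None = None,
    save_spikes: bool = False,
) -> pd.DataFrame:
    """Execute every run of the plan, resumably.

    Each run writes ``run_<k>.metrics.json`` (plus optionally the spike
    table) under ``output_root``; runs whose metrics file already exists are
    skipped.  A ``manifest.json`` maps every run to its preset, seed and
    config hash.  Individual failures are logged and the batch continues.
    Returns the collected metrics as a DataFrame.
    """
    root = Path(output_root)
    root.mkdir(parents=True, exist_ok=True)
    geometry = geometry or GeometryConfig()
    connectivity = connectivity or ConnectivityConfig()
    sim = sim or SimConfig()
    chash = _config_hash(geometry, connectivity, sim)

    manifest = []
    rows = []
    for k, preset, n_layers, seed in plan.runs():
        metrics_path = root / f"run_{k:04d}.metrics.json"
        entry = {
            "run": k, "preset": preset, "n_layers": n_layers, "seed": seed,
            "metrics": metrics_path.name, "config_hash": chash,
        }
        manifest.append(entry)
        if metrics_path.exists():
            rows.append(json.loads(metrics_path.read_text()))
            continue
        try:
            report, spikes = run_one(
                preset, n_layers, seed, geometry, connectivity, sim
            )
        except Exception:                       # noqa: BLE001 - batch continues
            log.exception("run %d (%s, seed %d) failed", k, preset, seed)
            continue
        record = {"run": k, "preset": preset, "n_layers": n_layers, "seed": seed}
        record.update(report.as_dict())
        metrics_path.write_text(json.dumps(record))
        if save_spikes:
            spikes.to_tsv(str(root / f"run_{k:04d}.spk"))
        rows.append(record)
    (root / "manifest.json").write_text(json.dumps(manifest, indent=1))
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# group statistics

@dataclass
class GroupComparison:
    metric: str
    summaries: pd.DataFrame          # per-group mean/median/p25/p75/sd/n
    h_statistic: float = float("nan")
    p_value: float = float("nan")
    test_performed: bool = False


def compare_groups(groups: dict[str, "np.ndarray | list"], metric: str = "") -> GroupComparison:
    """Kruskal-Wallis comparison plus 25-75-percentile box summaries.

    Summaries are computed from per-network values.  With fewer than two
    groups of >= 3 runs each, only the summaries are returned.
    """
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    rows = []
    for name, values in groups.items():
        v = np.asarray(list(values), dtype=float)
        v = v[~np.isnan(v)]
        rows.append({
            "group": name, "n": len(v),
            "mean": v.mean() if len(v) else np.nan,
            "median": np.median(v) if len(v) else np.nan,
            "p25": np.percentile(v, 25) if len(v) else np.nan,
            "p75": np.percentile(v, 75) if len(v) else np.nan,
            "sd": v.std(ddof=1) if len(v) > 1 else np.nan,
        })
    summary = pd.DataFrame(rows).set_index("group")
    comparison = GroupComparison(metric=metric, summaries=summary)

    samples = [np.asarray(list(v), dtype=float) for v in groups.values()]
    samples = [s[~np.isnan(s)] for s in samples]
    if all(len(s) >= 3 for s in samples):
        if all(np.array_equal(s, samples[0]) for s in samples[1:]):
            comparison.h_statistic, comparison.p_value = 0.0, 1.0
        else:
            h, p = stats.kruskal(*samples)
            comparison.h_statistic, comparison.p_value = float(h), float(p)
        comparison.test_performed = True
    else:
        warnings.warn("fewer than 3 runs in a group: Kruskal-Wallis test omitted")
    return comparison


# ---------------------------------------------------------------------------
# fixtures

def make_fixtures(kind: str, seed: int = 0) -> dict:
    """Deterministic miniature inputs for tests and demos.

    ``toy_network``: a <= 50-neuron jittered grid wired with Rule 1, plus a
    two-neuron pair 1 mm apart (conduction delay exactly 2 ms).
    ``crafted_spike_trains``: hand-built trains exercising every burst- and
    network-burst detection branch.
    ``synthetic_sth_shapes``: double-exponential rise/decay curves with known
    parameters for fit-recovery tests.
    """
    rng = np.random.default_rng(seed)
    if kind == "toy_network":
        geometry = GeometryConfig(area_um2=(7 * 26.0) ** 2, n_per_layer=49)
        from .topology import place_neurons_2d, build_gaussian_layer
        neurons = place_neurons_2d(geometry, rng)
        synapses = build_gaussian_layer(neurons, ConnectivityConfig(), rng)
        pair = pd.DataFrame({
            "id": [0, 1], "x": [0.0, 1000.0], "y": [0.0, 0.0], "z": 0.0,
            "is_inhibitory": [False, False], "layer": 0,
        })
        pair_syn = pd.DataFrame({
            "pre_id": [0], "post_id": [1], "weight": [1.0],
            "delay": [2.0], "is_interlayer": [False],
        })
        return {"neurons": neurons, "synapses": synapses,
                "two_neuron": (pair, pair_syn)}
    if kind == "crafted_spike_trains":
        return {
            "five_at_50ms": np.arange(5) * 0.050,            # one burst, BD 200 ms
            "four_at_50ms": np.arange(4) * 0.050,            # below min spike count
            "sparse_150ms": np.arange(10) * 0.150,           # ISIs above the limit
            "silent": np.array([]),
            "runaway": np.arange(0.0, 10.0, 0.005),          # 200 sp/s tonic
            "two_bursts": np.concatenate([np.arange(5) * 0.05,
                                          1.0 + np.arange(6) * 0.08]),
        }
    if kind == "synthetic_sth_shapes":
        shapes = []
        for _ in range(10):
            a0, a1 = -rng.uniform(20, 60), -rng.uniform(5, 30)
            a3 = -(a0 + a1) + rng.uniform(10, 40)
            l0 = -1.0 / rng.uniform(500, 4000)   # exponents (b-1), 1/ms
            l1 = -1.0 / rng.uniform(20, 300)
            t = np.arange(0.0, 1500.0, 1.0)
            rise = a0 * np.exp(l0 * t) + a1 * np.exp(l1 * t) + a3
            c0, c1 = rng.uniform(20, 60), rng.uniform(5, 30)
            d0 = -1.0 / rng.uniform(500, 6000)
            d1 = -1.0 / rng.uniform(20, 300)
            decay = c0 * np.exp(d0 * t) + c1 * np.exp(d1 * t)
            shapes.append({
                "t_ms": t, "rise": rise, "decay": decay,
                "rise_params": {"a0": a0, "a1": a1, "a3": a3,
                                "b0": l0 + 1.0, "b1": l1 + 1.0},
                "decay_params": {"c0": c0, "c1": c1, "d0": d0, "d1": d1},
            })
        return {"shapes": shapes}
    raise ValueError(f"unknown fixture kind {kind!r}")
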