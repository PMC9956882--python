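"""Container and on-disk format for recorded spike trains.

A :class:`SpikeTrainSet` holds the spikes of one recording window as two
parallel arrays (neuron id, spike time in seconds, sorted by time) plus the
per-neuron metadata needed by the analysis layer (layer index, E/I flag).
Times are quantised on the 0.1 ms simulation grid and round-trip losslessly
through the two-column TSV format.
"""

from __future__ import annotations

import io
from dataclasses import dataclass

import numpy as np
import pandas as pd


@dataclass
class SpikeTrainSet:
    """Spikes of ``n_neurons`` cells over ``[0, duration]`` seconds."""

    neuron_ids: np.ndarray          # int64, parallel to times
    times: np.ndarray               # float64 s, sorted ascending
    n_neurons: int
    duration: float                 # s
    layer_of: np.ndarray | None = None       # per-neuron layer index
    is_inhibitory: np.ndarray | None = None  # per-neuron E/I flag
    counts: np.ndarray | None = None         # per-neuron spike counts
    truncated: bool = False         # storage cap hit (counts stay exact)
    guard_tripped: bool = False     # runaway-firing guard flag

    def __post_init__(self) -> None:
        self.neuron_ids = np.asarray(self.neuron_ids, dtype=np.int64)
        self.times = np.asarray(self.times, dtype=float)
        if len(self.neuron_ids) != len(self.times):
            raise ValueError("neuron_ids and times must be parallel")
        if len(self.times) > 1 and np.any(np.diff(self.times) < 0):
            order = np.argsort(self.times, kind="stable")
            self.times = self.times[order]
            self.neuron_ids = self.neuron_ids[order]
        if self.counts is None:
            self.counts = np.bincount(self.neuron_ids, minlength=self.n_neurons).astype(
                np.int64
            )

    def __len__(self) -> int:
        return len(self.times)

    def train(self, neuron: int) -> np.ndarray:
        """Sorted spike times (s) of one neuron."""
        return self.times[self.neuron_ids == neuron]

    def trains(self) -> list[np.ndarray]:
        """Per-neuron sorted spike-time arrays, indexed by neuron id."""
        order = np.argsort(self.neuron_ids, kind="stable")
        sorted_ids = self.neuron_ids[order]
        sorted_times = self.times[order]
        out: list[np.ndarray] = [np.empty(0)] * self.n_neurons
        if len(sorted_ids) == 0:
            return out
        boundaries = np.flatnonzero(np.diff(sorted_ids)) + 1
        for chunk in np.split(np.arange(len(sorted_ids)), boundaries):
            out[sorted_ids[chunk[0]]] = sorted_times[chunk]
        return out

    def for_layer(self, layer: int) -> "SpikeTrainSet":
        """Sub-train of one layer, with neuron ids re-indexed from 0."""
        if self.layer_of is None:
            raise ValueError("no layer metadata attached")
        members = np.flatnonzero(self.layer_of == layer)
        if len(members) == 0:
            raise ValueError(f"no neurons in layer {layer}")
        remap = np.full(self.n_neurons, -1, dtype=np.int64)
        remap[members] = np.arange(len(members))
        mask = remap[self.neuron_ids] >= 0
        return SpikeTrainSet(
            neuron_ids=remap[self.neuron_ids[mask]],
            times=self.times[mask],
            n_neurons=len(members),
            duration=self.duration,
            layer_of=np.zeros(len(members), dtype=np.int64),
            is_inhibitory=None if self.is_inhibitory is None else self.is_inhibitory[members],
            counts=self.counts[members] if self.truncated else None,
            truncated=self.truncated,
            guard_tripped=self.guard_tripped,
        )

    # ---------------------------------------------------------------- I/O

    def to_tsv(self, path: str) -> None:
        """Write as a two-column TSV (neuron_id, time_s) with metadata header."""
        with open(path, "w") as fh:
            fh.write(f"# n_neurons={self.n_neurons}\n")
            fh.write(f"# duration_s={self.duration:.4f}\n")
            if self.layer_of is not None:
                fh.write("# layer_of=" + ",".join(map(str, self.layer_of)) + "\n")
            if self.is_inhibitory is not None:
                fh.write(
                    "# is_inhibitory="
                    + ",".join("1" if v else "0" for v in self.is_inhibitory)
                    + "\n"
                )
            fh.write("neuron_id\ttime_s\n")
            for nid, t in zip(self.neuron_ids, self.times):
                fh.write(f"{nid}\t{t:.4f}\n")

    @classmethod
    def from_tsv(cls, path: str) -> "SpikeTrainSet":
        meta: dict[str, str] = {}
        body = io.StringIO()
        with open(path) as fh:
            for line in fh:
                if line.startswith("#"):
                    key, _, value = line[1:].strip().partition("=")
                    meta[key.strip()] = value
                else:
                    body.write(line)
        body.seek(0)
        table = pd.read_csv(body, sep="\t")
        n = int(meta.get("n_neurons", table["neuron_id"].max() + 1 if len(table) else 0))
        duration = float(meta.get("duration_s", table["time_s"].max() if len(table) else 0.0))
        layer_of = None
        if "layer_of" in meta:
            layer_of = np.array([int(v) for v in meta["layer_of"].split(",")])
        is_inh = None
        if "is_inhibitory" in meta:
            is_inh = np.array([v == "1" for v in meta["is_inhibitory"].split(",")])
        return cls(
            neuron_ids=table["neuron_id"].to_numpy(),
            times=table["time_s"].to_numpy(),
            n_neurons=n,
            duration=duration,
            layer_of=layer_of,
            is_inhibitory=is_inh,
        )
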