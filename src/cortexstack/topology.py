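"""Structural connectivity of layered cortical cultures.

A network is a pair of pandas tables:

* ``NeuronTable`` — one row per cell: ``id, x, y, z, is_inhibitory, layer``
  (positions in um; ``layer`` 0 is the bottom/readout layer).
* ``SynapseTable`` — one row per directed edge: ``pre_id, post_id, weight,
  delay, is_interlayer`` (weight as voltage drive w/g_L in mV, delay in ms).

Wiring rules
------------
Within a layer the probability of a directed connection decays as a Gaussian
of the planar distance, ``p = p_max * exp(-d^2 / (2 sigma^2))``, and the
synaptic weight as ``w = c/(2 pi sigma^2) * exp(-d^2 / (2 sigma^2))``.
Rule 1 ("Gaussian") additionally caps every out-degree at 8% of the layer
population by uniform random pruning.  Rule 2 ("scale-free") replaces the cap
by per-neuron out-degree targets drawn from a discrete power law, producing
hub neurons at random positions.  Inter-layer edges originate only from a
configurable source population and use the same kernels on the full 3D
distance with peak probability ``p_max / 3``.

Structural constraints enforced everywhere: no autapses, and no
inhibitory-to-inhibitory connections.
"""

from __future__ import annotations

import logging
import math
import warnings

import numpy as np
import pandas as pd

from .config import ConnectivityConfig, GeometryConfig, AXONAL_VELOCITY_UM_PER_MS

log = logging.getLogger(__name__)

NEURON_COLUMNS = ["id", "x", "y", "z", "is_inhibitory", "layer"]
SYNAPSE_COLUMNS = ["pre_id", "post_id", "weight", "delay", "is_interlayer"]

#: Presets: (intra-layer rule per layer, inter-layer source scheme, default n_layers)
PRESETS = {
    "G2D": dict(rules="gaussian", scheme=None, n_layers=1),
    "SF2D": dict(rules="scale_free", scheme=None, n_layers=1),
    "G3D": dict(rules="gaussian", scheme="unrestricted", n_layers=4),
    "SFL03D": dict(rules="sf_layer0", scheme="unrestricted", n_layers=4),
    "SFall3D": dict(rules="scale_free", scheme="unrestricted", n_layers=4),
    "Grnd3D": dict(rules="gaussian", scheme="random", n_layers=4),
    "GC3D": dict(rules="gaussian", scheme="central", n_layers=4),
    "G5C3D": dict(rules="gaussian", scheme="five_centers", n_layers=4),
}


# ---------------------------------------------------------------------------
# kernels

def gaussian_weight(d, sigma: float, c: float):
    """Distance-dependent synaptic weight ``c/(2 pi sigma^2) exp(-d^2/2 sigma^2)``.

    ``d`` and ``sigma`` in um; ``c`` fixes amplitude and units of the weight.
    """
    d = np.asarray(d, dtype=float)
    if np.any(d < 0):
        raise ValueError("distance must be non-negative")
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    return c / (2.0 * math.pi * sigma**2) * np.exp(-(d**2) / (2.0 * sigma**2))


def connection_probability(d, p_max: float, sigma: float):
    """Gaussian fall-off of connection probability, peak ``p_max`` at d = 0."""
    d = np.asarray(d, dtype=float)
    if np.any(d < 0):
        raise ValueError("distance must be non-negative")
    if not 0.0 <= p_max <= 1.0:
        raise ValueError("p_max must lie in [0, 1]")
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    return p_max * np.exp(-(d**2) / (2.0 * sigma**2))


# ---------------------------------------------------------------------------
# placement

def _lattice_sites(geometry: GeometryConfig) -> np.ndarray:
    """Square-lattice candidate sites covering the culture area.

    The target population is not a perfect square, so the lattice is laid out
    as nx x ny sites at the configured pitch and the surplus sites farthest
    from the centre are dropped symmetrically.
    """
    side = geometry.side_um
    pitch = geometry.spacing_um
    nx = int(side // pitch) + 1
    ny = nx - 1
    if nx * ny < geometry.n_per_layer:
        ny = nx
    xs = (np.arange(nx) - (nx - 1) / 2.0) * pitch + side / 2.0
    ys = (np.arange(ny) - (ny - 1) / 2.0) * pitch + side / 2.0
    gx, gy = np.meshgrid(xs, ys, indexing="ij")
    sites = np.column_stack([gx.ravel(), gy.ravel()])
    # drop the outermost surplus sites (ties broken by site index for determinism)
    centre = np.array([side / 2.0, side / 2.0])
    r = np.hypot(*(sites - centre).T)
    order = np.lexsort((np.arange(len(sites)), r))
    keep = np.sort(order[: geometry.n_per_layer])
    return sites[keep]


def place_neurons_2d(
    geometry: GeometryConfig | None = None,
    seed: int | np.random.Generator = 0,
    layer: int = 0,
) -> pd.DataFrame:
    """Place one layer of neurons on a jittered square lattice.

    Inhibitory identities are assigned uniformly at random to
    ``round(inhibitory_fraction * n)`` cells.  Reproducible given ``seed``.
    """
    geometry = geometry or GeometryConfig()
    geometry.validate()
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed

    sites = _lattice_sites(geometry)
    n = geometry.n_per_layer
    jitter = rng.uniform(-geometry.jitter_um, geometry.jitter_um, size=(n, 2))
    xy = sites + jitter

    n_inh = int(round(geometry.inhibitory_fraction * n))
    is_inh = np.zeros(n, dtype=bool)
    is_inh[rng.choice(n, size=n_inh, replace=False)] = True

    return pd.DataFrame(
        {
            "id": np.arange(n, dtype=np.int64),
            "x": xy[:, 0],
            "y": xy[:, 1],
            "z": float(layer * geometry.layer_spacing_um),
            "is_inhibitory": is_inh,
            "layer": np.int64(layer),
        }
    )


def stack_layers(
    n_layers: int,
    geometry: GeometryConfig | None = None,
    seed: int | np.random.Generator = 0,
) -> pd.DataFrame:
    """Pile up ``n_layers`` independently jittered copies of the 2D unit."""
    if n_layers < 1:
        raise ValueError("n_layers must be >= 1")
    geometry = geometry or GeometryConfig()
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    frames = []
    for layer in range(n_layers):
        frame = place_neurons_2d(geometry, rng, layer=layer)
        frame["id"] = frame["id"] + layer * geometry.n_per_layer
        frames.append(frame)
    return pd.concat(frames, ignore_index=True)


# ---------------------------------------------------------------------------
# wiring helpers

def _delay_ms(dist_um: np.ndarray, velocity: float, dt_ms: float) -> np.ndarray:
    """Conduction delay: distance / axonal velocity, ceiled to the time grid."""
    steps = np.ceil(dist_um / velocity / dt_ms).astype(np.int64)
    return np.maximum(steps, 1) * dt_ms


def _admissible(is_inh: np.ndarray) -> np.ndarray:
    """Mask of allowed directed pairs: no autapse, no inhibitory->inhibitory."""
    n = len(is_inh)
    mask = ~(is_inh[:, None] & is_inh[None, :])
    np.fill_diagonal(mask, False)
    return mask


def _edges_to_table(
    pre: np.ndarray,
    post: np.ndarray,
    dist: np.ndarray,
    config: ConnectivityConfig,
    dt_ms: float,
    is_interlayer: bool,
    pre_is_inh: np.ndarray | None = None,
) -> pd.DataFrame:
    weight = gaussian_weight(dist, config.sigma_um, config.weight_scale_mv)
    if pre_is_inh is not None and config.inhibitory_weight_factor != 1.0:
        weight = np.where(
            pre_is_inh, weight * config.inhibitory_weight_factor, weight
        )
    delay = _delay_ms(dist, AXONAL_VELOCITY_UM_PER_MS, dt_ms)
    return pd.DataFrame(
        {
            "pre_id": pre.astype(np.int64),
            "post_id": post.astype(np.int64),
            "weight": weight,
            "delay": delay,
            "is_interlayer": is_interlayer,
        }
    )


def _cap_outdegree(
    pre: np.ndarray, keep_max: int, rng: np.random.Generator
) -> np.ndarray:
    """Boolean mask keeping at most ``keep_max`` edges per presynaptic neuron.

    Excess edges are removed uniformly at random.
    """
    keep = np.ones(len(pre), dtype=bool)
    order = np.argsort(pre, kind="stable")
    sorted_pre = pre[order]
    boundaries = np.flatnonzero(np.diff(sorted_pre)) + 1
    for group in np.split(order, boundaries):
        if len(group) > keep_max:
            drop = rng.choice(group, size=len(group) - keep_max, replace=False)
            keep[drop] = False
    return keep


def _propose_edges(
    positions: np.ndarray,
    is_inh: np.ndarray,
    config: ConnectivityConfig,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Bernoulli edge proposal from the Gaussian probability kernel."""
    diff = positions[:, None, :] - positions[None, :, :]
    dist = np.sqrt((diff**2).sum(axis=-1))
    p = connection_probability(dist, config.p_max, config.sigma_um)
    mask = _admissible(is_inh)
    draw = rng.random(p.shape)
    edges = mask & (draw < p)
    pre, post = np.nonzero(edges)
    return pre, post, dist[pre, post]


# ---------------------------------------------------------------------------
# intra-layer rules

def build_gaussian_layer(
    neurons: pd.DataFrame,
    config: ConnectivityConfig | None = None,
    seed: int | np.random.Generator = 0,
    dt_ms: float = 0.1,
) -> pd.DataFrame:
    """Rule 1: Gaussian probabilistic wiring with an 8% out-degree cap.

    Every admissible ordered pair is connected with the Gaussian probability
    of its planar distance; neurons whose out-degree exceeds
    ``floor(outdegree_cap_fraction * n)`` lose the excess edges uniformly at
    random.
    """
    if len(neurons) == 0:
        raise ValueError("empty neuron table")
    config = config or ConnectivityConfig()
    config.validate()
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed

    positions = neurons[["x", "y"]].to_numpy()
    is_inh = neurons["is_inhibitory"].to_numpy()
    pre, post, dist = _propose_edges(positions, is_inh, config, rng)

    cap = int(math.floor(config.outdegree_cap_fraction * len(neurons)))
    keep = _cap_outdegree(pre, cap, rng)
    pre, post, dist = pre[keep], post[keep], dist[keep]

    ids = neurons["id"].to_numpy()
    return _edges_to_table(ids[pre], ids[post], dist, config, dt_ms, False, is_inh[pre])


def sample_sf_degrees(
    n: int, config: ConnectivityConfig, rng: np.random.Generator
) -> np.ndarray:
    """Draw per-neuron out-degree targets from a discrete power law.

    The degree axis [kmin, kmax] is discretised into ``sf_nvalues`` evenly
    spaced values; each value k is drawn with probability proportional to
    ``k**sf_slope`` (slope -0.61: shallow power law, hubs at random neurons).
    """
    k_values = np.linspace(config.sf_kmin, config.sf_kmax, config.sf_nvalues)
    prob = k_values**config.sf_slope
    prob = prob / prob.sum()
    drawn = rng.choice(len(k_values), size=n, p=prob)
    return np.round(k_values[drawn]).astype(np.int64)


def build_scale_free_layer(
    neurons: pd.DataFrame,
    config: ConnectivityConfig | None = None,
    seed: int | np.random.Generator = 0,
    dt_ms: float = 0.1,
) -> pd.DataFrame:
    """Rule 2: scale-free out-degree wiring.

    Edges are first proposed with the Gaussian probability kernel, then each
    neuron's out-degree is pruned down (uniformly at random) to its power-law
    target.  Targets that exceed the proposed edge count are kept at the
    feasible value with a logged warning.
    """
    if len(neurons) == 0:
        raise ValueError("empty neuron table")
    config = config or ConnectivityConfig()
    config.validate()
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed

    positions = neurons[["x", "y"]].to_numpy()
    is_inh = neurons["is_inhibitory"].to_numpy()
    pre, post, dist = _propose_edges(positions, is_inh, config, rng)

    targets = sample_sf_degrees(len(neurons), config, rng)
    keep = np.ones(len(pre), dtype=bool)
    order = np.argsort(pre, kind="stable")
    infeasible = 0
    boundaries = np.flatnonzero(np.diff(pre[order])) + 1
    for group in np.split(order, boundaries):
        target = targets[pre[group[0]]]
        if len(group) > target:
            drop = rng.choice(group, size=len(group) - target, replace=False)
            keep[drop] = False
        elif len(group) < target:
            infeasible += 1
    if infeasible:
        log.warning(
            "scale-free rule: %d neurons had fewer admissible partners than "
            "their degree target; capped at the feasible count", infeasible
        )
    pre, post, dist = pre[keep], post[keep], dist[keep]
    ids = neurons["id"].to_numpy()
    return _edges_to_table(ids[pre], ids[post], dist, config, dt_ms, False, is_inh[pre])


# ---------------------------------------------------------------------------
# inter-layer wiring

def _layer_centre(layer_neurons: pd.DataFrame) -> np.ndarray:
    return layer_neurons[["x", "y"]].to_numpy().mean(axis=0)


def _five_centres(side: float) -> np.ndarray:
    """Default source-cluster centres: layer centre plus the four midpoints
    between the centre and the corners."""
    c = side / 2.0
    return np.array(
        [[c, c], [c / 2, c / 2], [c / 2, 3 * c / 2], [3 * c / 2, c / 2], [3 * c / 2, 3 * c / 2]]
    )


def select_interlayer_sources(
    neurons: pd.DataFrame,
    scheme: str,
    config: ConnectivityConfig | None = None,
    seed: int | np.random.Generator = 0,
    centres: np.ndarray | None = None,
) -> dict[int, np.ndarray]:
    """Choose, per layer, the neurons allowed to project across layers.

    Restricted schemes (``random``, ``central``, ``five_centers``) are
    equalised to exactly ``round(source_fraction * n_layer)`` sources per
    layer so that the schemes stay comparable: geometric capture beyond the
    quota is trimmed uniformly at random, a shortfall is topped up with the
    nearest neurons outside the configured radii.
    """
    config = config or ConnectivityConfig()
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    valid = {"unrestricted", "random", "central", "five_centers"}
    if scheme not in valid:
        raise ValueError(f"unknown inter-layer source scheme {scheme!r}")

    sources: dict[int, np.ndarray] = {}
    for layer, group in neurons.groupby("layer"):
        ids = group["id"].to_numpy()
        n_layer = len(group)
        quota = int(round(config.source_fraction * n_layer))
        if scheme == "unrestricted":
            sources[int(layer)] = ids
            continue
        if scheme == "random":
            chosen = rng.choice(ids, size=quota, replace=False)
            sources[int(layer)] = np.sort(chosen)
            continue
        xy = group[["x", "y"]].to_numpy()
        if scheme == "central":
            centre = _layer_centre(group)
            r = np.hypot(*(xy - centre).T)
            radius = config.central_radius_um
        else:  # five_centers
            cs = centres if centres is not None else _five_centres(2 * _layer_centre(group)[0])
            r = np.min(
                np.sqrt(((xy[:, None, :] - cs[None, :, :]) ** 2).sum(axis=-1)), axis=1
            )
            radius = config.five_center_radius_um
        inside = np.flatnonzero(r <= radius)
        if len(inside) >= quota:
            chosen = rng.choice(inside, size=quota, replace=False)
        else:
            outside = np.flatnonzero(r > radius)
            extra = outside[np.argsort(r[outside], kind="stable")][: quota - len(inside)]
            chosen = np.concatenate([inside, extra])
        sources[int(layer)] = np.sort(ids[chosen])
    return sources


def build_interlayer(
    neurons: pd.DataFrame,
    sources: dict[int, np.ndarray],
    config: ConnectivityConfig | None = None,
    seed: int | np.random.Generator = 0,
    dt_ms: float = 0.1,
) -> pd.DataFrame:
    """Wire source neurons across layers with the scaled Gaussian kernel.

    Probability and weight use the full 3D distance; the peak probability is
    ``p_max * interlayer_p_scale`` (default one third).  The Rule-1 out-degree
    cap is applied to each source's inter-layer edge set.
    """
    config = config or ConnectivityConfig()
    config.validate()
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed

    layers = neurons["layer"].to_numpy()
    if len(np.unique(layers)) < 2:
        warnings.warn("single-layer network: no inter-layer edges to build")
        return pd.DataFrame(columns=SYNAPSE_COLUMNS).astype(
            {"pre_id": np.int64, "post_id": np.int64, "weight": float,
             "delay": float, "is_interlayer": bool}
        )

    ids = neurons["id"].to_numpy()
    id_to_row = np.full(ids.max() + 1, -1, dtype=np.int64)
    id_to_row[ids] = np.arange(len(ids))
    source_rows = np.concatenate([id_to_row[v] for v in sources.values()])
    source_rows.sort()

    pos = neurons[["x", "y", "z"]].to_numpy()
    is_inh = neurons["is_inhibitory"].to_numpy()

    pre_parts, post_parts, dist_parts = [], [], []
    p_peak = config.p_max * config.interlayer_p_scale
    for start in range(0, len(source_rows), 512):
        chunk = source_rows[start : start + 512]
        diff = pos[chunk, None, :] - pos[None, :, :]
        dist = np.sqrt((diff**2).sum(axis=-1))
        p = connection_probability(dist, p_peak, config.sigma_um)
        cross = layers[chunk][:, None] != layers[None, :]
        allowed = ~(is_inh[chunk][:, None] & is_inh[None, :])
        edges = cross & allowed & (rng.random(p.shape) < p)
        pre_local, post_c = np.nonzero(edges)
        pre_parts.append(chunk[pre_local])
        post_parts.append(post_c)
        dist_parts.append(dist[pre_local, post_c])
    pre = np.concatenate(pre_parts)
    post = np.concatenate(post_parts)
    d = np.concatenate(dist_parts)

    if config.interlayer_outdegree_cap:
        n_layer = int((layers == layers[0]).sum())
        cap = int(math.floor(config.outdegree_cap_fraction * n_layer))
        keep = _cap_outdegree(pre, cap, rng)
        pre, post, d = pre[keep], post[keep], d[keep]

    return _edges_to_table(ids[pre], ids[post], d, config, dt_ms, True, is_inh[pre])


# ---------------------------------------------------------------------------
# presets

def assemble_network(
    preset: str,
    n_layers: int | None = None,
    seed: int = 0,
    geometry: GeometryConfig | None = None,
    connectivity: ConnectivityConfig | None = None,
    dt_ms: float = 0.1,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Build a complete (NeuronTable, SynapseTable) pair for a named preset.

    Presets: G2D, SF2D (single layer), G3D, SFL03D, SFall3D (unrestricted
    inter-layer sources), Grnd3D, GC3D, G5C3D (restricted source schemes,
    Gaussian intra-layer).  Deterministic per seed.
    """
    if preset not in PRESETS:
        raise ValueError(f"unknown preset {preset!r}; choose from {sorted(PRESETS)}")
    spec = PRESETS[preset]
    n_layers = spec["n_layers"] if n_layers is None else n_layers
    if spec["scheme"] is None and n_layers != 1:
        raise ValueError(f"preset {preset} is single-layer; got n_layers={n_layers}")
    if spec["scheme"] is not None and n_layers < 2:
        raise ValueError(f"preset {preset} needs n_layers >= 2; got {n_layers}")

    geometry = geometry or GeometryConfig()
    connectivity = connectivity or ConnectivityConfig()
    rng = np.random.default_rng(seed)

    neurons = stack_layers(n_layers, geometry, rng)

    tables = []
    for layer, group in neurons.groupby("layer"):
        rule = spec["rules"]
        if rule == "sf_layer0":
            rule = "scale_free" if layer == 0 else "gaussian"
        builder = build_scale_free_layer if rule == "scale_free" else build_gaussian_layer
        tables.append(builder(group.reset_index(drop=True), connectivity, rng, dt_ms))

    if spec["scheme"] is not None:
        sources = select_interlayer_sources(neurons, spec["scheme"], connectivity, rng)
        tables.append(build_interlayer(neurons, sources, connectivity, rng, dt_ms))

    synapses = pd.concat(tables, ignore_index=True)
    return neurons, synapses


# ---------------------------------------------------------------------------
# serialization

def write_network(neurons: pd.DataFrame, synapses: pd.DataFrame, prefix: str) -> None:
    """Write the two tables as headered TSV files ``<prefix>.neurons.tsv`` /
    ``<prefix>.synapses.tsv``."""
    neurons.to_csv(f"{prefix}.neurons.tsv", sep="\t", index=False)
    synapses.to_csv(f"{prefix}.synapses.tsv", sep="\t", index=False)


def read_network(prefix: str) -> tuple[pd.DataFrame, pd.DataFrame]:
    neurons = pd.read_csv(f"{prefix}.neurons.tsv", sep="\t")
    synapses = pd.read_csv(f"{prefix}.synapses.tsv", sep="\t")
    return neurons, synapses
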