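"""Configuration dataclasses and model constants.

All spatial quantities are in micrometres, times in milliseconds unless a
field name says otherwise.  Defaults reproduce the reference culture model:
a ~0.74 mm^2 square layer of 1091 cells at 26 um pitch (planar density
~1480 cells/mm^2), 20% inhibitory, layers stacked 50 um apart.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, asdict

#: Peak amplitude of the synaptic weight kernel, expressed as a voltage drive
#: (w / g_L, in mV) before the Gaussian normalisation 1/(2*pi*sigma^2) is
#: applied.  This is the single unit-fixing constant of the synaptic model:
#: weights carry current units only through the leak conductance, so the
#: engine works throughout in I/g_L (mV).  The magnitude was calibrated once
#: on 2D reference networks so that recurrent drive sustains stable,
#: in-vitro-scale spontaneous activity on top of the sub-threshold noise
#: without igniting runaway population firing; see docs/methods.md.
DEFAULT_WEIGHT_SCALE_MV = 2.7e6

#: Axonal conduction velocity, um/ms (0.5 mm/ms).
AXONAL_VELOCITY_UM_PER_MS = 500.0


@dataclass(frozen=True)
class GeometryConfig:
    """Geometry of one culture layer and of the layer stack."""

    area_um2: float = 736164.0          # square side ~858 um
    spacing_um: float = 26.0            # cell pitch on the lattice
    n_per_layer: int = 1091
    inhibitory_fraction: float = 0.20
    jitter_um: float = 6.5              # uniform positional noise, per axis
    layer_spacing_um: float = 50.0      # glass-microbead scaffold pitch

    @property
    def side_um(self) -> float:
        return math.sqrt(self.area_um2)

    def validate(self) -> None:
        nx = int(self.side_um // self.spacing_um) + 1
        ny = nx - 1
        if nx * ny < self.n_per_layer:
            raise ValueError(
                f"area {self.area_um2} um^2 at spacing {self.spacing_um} um "
                f"hosts only {nx * ny} lattice sites < {self.n_per_layer}"
            )
        if not 0.0 <= self.inhibitory_fraction <= 1.0:
            raise ValueError("inhibitory_fraction must lie in [0, 1]")


@dataclass(frozen=True)
class ConnectivityConfig:
    """Parameters of the intra- and inter-layer wiring rules."""

    p_max: float = 0.2                  # peak connection probability
    sigma_um: float = 1000.0            # spatial SD of both kernels
    weight_scale_mv: float = DEFAULT_WEIGHT_SCALE_MV
    #: extra multiplier on the weights of inhibitory efferents; the mean
    #: inhibitory synaptic weight is a calibrated quantity of the model
    #: (it sets where recurrent inhibition arrests an igniting population
    #: event; see docs/methods.md)
    inhibitory_weight_factor: float = 1.2
    outdegree_cap_fraction: float = 0.08
    # scale-free rule
    sf_slope: float = -0.61
    sf_kmin: int = 50
    sf_kmax: int = 200
    sf_nvalues: int = 100
    # inter-layer rule
    interlayer_scheme: str = "unrestricted"   # unrestricted|random|central|five_centers
    interlayer_p_scale: float = 1.0 / 3.0
    central_radius_um: float = 278.0
    five_center_radius_um: float = 129.0
    source_fraction: float = 0.33
    interlayer_outdegree_cap: bool = True

    def validate(self) -> None:
        if not 0.0 <= self.p_max <= 1.0:
            raise ValueError("p_max must lie in (0, 1]")
        if self.sigma_um <= 0:
            raise ValueError("sigma_um must be positive")
        if self.sf_kmin >= self.sf_kmax:
            raise ValueError("sf_kmin must be < sf_kmax")
        if self.central_radius_um <= 0 or self.five_center_radius_um <= 0:
            raise ValueError("source radii must be positive")


@dataclass(frozen=True)
class SimConfig:
    """LIF network simulation parameters (reference-model defaults)."""

    dt_ms: float = 0.1
    settle_s: float = 10.0
    record_s: float = 60.0
    v_threshold_mv: float = -50.0
    v_reset_mv: float = -70.0
    e_leak_mv: float = -70.0
    tau_m_ms: float = 10.0
    g_leak_ns: float = 10.0
    refractory_ms: float = 5.0
    tau_syn_ms: float = 10.0
    alpha_ex: float = 12.0
    alpha_in: float = 16.0
    noise_levels: int = 5               # I_noise = g_L * U{0..noise_levels} * unit
    noise_unit_mv: float = 5.4
    noise_refresh_ms: float = 1.0
    axonal_velocity_um_per_ms: float = AXONAL_VELOCITY_UM_PER_MS
    guard_rate_sps: float = 500.0       # runaway-firing flag threshold

    def validate(self) -> None:
        if self.dt_ms <= 0:
            raise ValueError("dt_ms must be positive")
        if self.refractory_ms < self.dt_ms:
            raise ValueError("refractory period must be >= dt")
        if self.noise_refresh_ms < self.dt_ms:
            raise ValueError("noise refresh interval must be >= dt")

    def as_dict(self) -> dict:
        return asdict(self)
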