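"""Domain types, unit conventions and reference constants.

The model describes ciprofloxacin (CFX) transport through the silicone wall
of an indwelling Foley urinary catheter, treated as a one-dimensional annular
cylinder (radial diffusion only).  Three consecutive stages are modelled:

* **load** — the catheter sits in a concentrated CFX bath; drug partitions
  into the outer wall surface and diffuses inward,
* **rest** — both surfaces are sealed (no flux); the loaded drug
  redistributes through the wall,
* **delivery** — the catheter sits in a finite, well-stirred PBS reservoir
  into which drug elutes; the reservoir concentration is tracked by a
  coupled ODE.

A layer-by-layer (LbL) polyelectrolyte coating is micron-thin relative to
the 1 mm wall, so it is represented only through altered partition
coefficients, not through a separate diffusivity field.

Canonical units throughout the package: **cm, hours, μg, μg/cm³**.
All constructors validate their invariants eagerly so downstream numerics
never see an inconsistent state.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "WELL_MIXED",
    "SINK",
    "DIFFUSIVITY_CM2_PER_H",
    "LOADING_CONCENTRATION_UG_CM3",
    "REFERENCE_PARTITIONS",
    "CATHETER_DIAMETERS_MM",
    "DEFAULT_SAMPLE_LENGTH_CM",
    "DEFAULT_RESERVOIR_VOLUME_CM3",
    "CatheterGeometry",
    "TransportParameters",
    "StageProtocol",
    "RadialGrid",
    "WallState",
    "ReservoirState",
    "ReleaseProfile",
    "FitResult",
    "standard_geometry",
    "reference_parameters",
    "default_protocol",
]

#: Sentinel for a convective (surface mass-transfer) coefficient in the
#: well-mixed limit k >> D, where the Robin boundary condition collapses to
#: a Dirichlet condition C(R2) = γ·C_bath.
WELL_MIXED = math.inf

#: Sentinel reservoir volume meaning a perfect sink: the delivery bath
#: concentration is pinned at zero and release is bookkept from the wall
#: mass decrement.
SINK = math.inf

#: CFX diffusivity in the silicone wall, shared by uncoated and coated
#: catheters (the coating is too thin to alter the diffusion path).
DIFFUSIVITY_CM2_PER_H = 1.744e-5

#: Loading-bath CFX concentration, 1.33 mg/mL in canonical units.
LOADING_CONCENTRATION_UG_CM3 = 1330.0

#: Equilibrium partition coefficients (γ_load, γ_delivery) per condition:
#: "control" is the uncoated silicone surface, "LbL" the
#: carboxymethylcellulose / chitosan–silver multilayer coating.
REFERENCE_PARTITIONS: dict[str, tuple[float, float]] = {
    "control": (1.478, 0.7688),
    "LbL": (3.928, 1.282),
}

#: Measured (inner, outer) diameters in mm of the two supported catheter
#: gauges.  These are the measured values for the commercial devices, which
#: do not follow the nominal 1 Fr = 1/3 mm convention; other sizes must be
#: supplied as explicit geometry.
CATHETER_DIAMETERS_MM: dict[str, tuple[float, float]] = {
    "14Fr": (2.7, 4.7),
    "20Fr": (4.7, 6.7),
}

DEFAULT_SAMPLE_LENGTH_CM = 2.5
DEFAULT_RESERVOIR_VOLUME_CM3 = 250.0


@dataclass(frozen=True)
class CatheterGeometry:
    """Annular diffusion domain: a catheter segment of length ``sample_length``.

    Parameters
    ----------
    inner_radius, outer_radius:
        Radii R1 < R2 of the lumen and external surface, in cm.
    sample_length:
        Axial length L of the segment, in cm.  Enters only through volumes
        and areas; there is no axial transport.
    """

    inner_radius: float
    outer_radius: float
    sample_length: float

    def __post_init__(self) -> None:
        if not (0 < self.inner_radius < self.outer_radius):
            raise ValueError(
                f"require 0 < inner_radius < outer_radius, got "
                f"R1={self.inner_radius}, R2={self.outer_radius}"
            )
        if not self.sample_length > 0:
            raise ValueError(f"sample_length must be > 0, got {self.sample_length}")

    def wall_thickness(self) -> float:
        return self.outer_radius - self.inner_radius

    def wall_volume(self) -> float:
        """Annulus volume π(R2² − R1²)L in cm³."""
        return math.pi * (self.outer_radius**2 - self.inner_radius**2) * self.sample_length

    def external_area(self) -> float:
        """External lateral surface area 2πR2L in cm² (the release-normalising area)."""
        return 2.0 * math.pi * self.outer_radius * self.sample_length


@dataclass(frozen=True)
class TransportParameters:
    """Kinetic parameters of one catheter condition.

    ``convective_load`` / ``convective_delivery`` are surface mass-transfer
    coefficients k (cm/h) in the Robin boundary conditions; the default
    :data:`WELL_MIXED` sentinel selects the k >> D reduction where the
    boundary concentration equals γ times the adjacent bath concentration.

    ``reservoir_volume`` may be :data:`SINK` to pin the delivery bath at
    zero concentration.
    """

    diffusivity: float = DIFFUSIVITY_CM2_PER_H
    partition_load: float = 1.0
    partition_delivery: float = 1.0
    convective_load: float = WELL_MIXED
    convective_delivery: float = WELL_MIXED
    bath_concentration: float = LOADING_CONCENTRATION_UG_CM3
    reservoir_volume: float = DEFAULT_RESERVOIR_VOLUME_CM3

    def __post_init__(self) -> None:
        if not self.diffusivity > 0:
            raise ValueError(f"diffusivity must be > 0, got {self.diffusivity}")
        if not self.partition_load > 0 or not self.partition_delivery > 0:
            raise ValueError("partition coefficients must be > 0")
        for name in ("convective_load", "convective_delivery"):
            k = getattr(self, name)
            if not (k == WELL_MIXED or (math.isfinite(k) and k > 0)):
                raise ValueError(f"{name} must be > 0 or the WELL_MIXED sentinel, got {k}")
        if self.bath_concentration < 0:
            raise ValueError("bath_concentration must be >= 0")
        if not self.reservoir_volume > 0:  # SINK = inf passes
            raise ValueError(f"reservoir_volume must be > 0 (or SINK), got {self.reservoir_volume}")

    @property
    def well_mixed_load(self) -> bool:
        return self.convective_load == WELL_MIXED

    @property
    def well_mixed_delivery(self) -> bool:
        return self.convective_delivery == WELL_MIXED

    @property
    def sink_delivery(self) -> bool:
        return self.reservoir_volume == SINK


@dataclass(frozen=True)
class StageProtocol:
    """Stage boundary times in hours: load on (0, t0], rest on (t0, t1],
    delivery on (t1, t_end].  ``rest_end == load_end`` is allowed and means
    the rest stage is skipped entirely."""

    load_end: float
    rest_end: float
    delivery_end: float

    def __post_init__(self) -> None:
        if not (0 < self.load_end <= self.rest_end < self.delivery_end):
            raise ValueError(
                f"require 0 < load_end <= rest_end < delivery_end, got "
                f"({self.load_end}, {self.rest_end}, {self.delivery_end})"
            )

    @property
    def rest_duration(self) -> float:
        return self.rest_end - self.load_end

    @property
    def delivery_duration(self) -> float:
        return self.delivery_end - self.rest_end


def default_protocol(delivery_hours: float = 360.0) -> StageProtocol:
    """The experimental protocol: 12 h load, 24 h rest, 15-day delivery."""
    return StageProtocol(load_end=12.0, rest_end=36.0, delivery_end=36.0 + delivery_hours)


@dataclass(frozen=True, eq=False)
class RadialGrid:
    """Vertex-centred finite-volume grid on [R1, R2].

    ``nodes[0] == R1`` and ``nodes[-1] == R2``; ``faces`` are the cell
    interfaces (midpoints between nodes, plus the two wall surfaces) and
    ``cell_volumes[i]`` is the exact annular-shell volume owned by node i,
    so the volumes telescope to π(R2²−R1²)L with no quadrature error.
    """

    nodes: np.ndarray
    faces: np.ndarray
    cell_volumes: np.ndarray
    spacing: float

    def __post_init__(self) -> None:
        if self.nodes.ndim != 1 or len(self.nodes) < 2:
            raise ValueError("grid needs at least two nodes")
        if not np.all(np.diff(self.nodes) > 0):
            raise ValueError("grid nodes must be strictly increasing")

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)


@dataclass(frozen=True, eq=False)
class WallState:
    """Radial CFX concentration profile C(r) at one instant (μg/cm³)."""

    time: float
    concentration: np.ndarray

    def __post_init__(self) -> None:
        c = np.asarray(self.concentration, dtype=float)
        object.__setattr__(self, "concentration", c)
        if c.ndim != 1:
            raise ValueError("concentration must be a 1-D nodal array")


@dataclass(frozen=True)
class ReservoirState:
    """Delivery-bath CFX concentration C_D at one instant (μg/cm³)."""

    time: float
    concentration: float

    def __post_init__(self) -> None:
        if self.concentration < 0:
            raise ValueError(f"reservoir concentration must be >= 0, got {self.concentration}")


@dataclass(eq=False)
class ReleaseProfile:
    """Cumulative release per external area versus delivery-relative time.

    ``times`` are hours measured from the start of the delivery stage and
    must be strictly increasing; ``release_per_area`` is μg/cm² normalised
    by the external lateral area 2πR2L.  ``metadata`` carries free-form
    provenance (condition, size, generator parameters, ...).
    """

    sample_id: str
    times: np.ndarray
    release_per_area: np.ndarray
    reservoir_concentration: np.ndarray | None = None
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        q = np.asarray(self.release_per_area, dtype=float)
        if t.shape != q.shape or t.ndim != 1:
            raise ValueError("times and release_per_area must be matching 1-D arrays")
        if len(t) and t[0] < 0:
            raise ValueError("times must start at >= 0 (delivery-relative hours)")
        if np.any(np.diff(t) <= 0):
            bad = int(np.flatnonzero(np.diff(t) <= 0)[0]) + 1
            raise ValueError(f"times must be strictly increasing (first violation at index {bad})")
        self.times = t
        self.release_per_area = q
        if self.reservoir_concentration is not None:
            cd = np.asarray(self.reservoir_concentration, dtype=float)
            if cd.shape != t.shape:
                raise ValueError("reservoir_concentration must match times")
            self.reservoir_concentration = cd

    def __len__(self) -> int:
        return len(self.times)


@dataclass
class FitResult:
    """Outcome of a (possibly joint, shared-D) least-squares fit.

    ``diffusivity`` is a single float when D was shared across conditions,
    otherwise a per-condition dict.  ``relative_uncertainty`` holds
    curvature-based (Gauss–Newton) relative standard errors per free
    parameter name; ``curvature_condition`` is the condition number of JᵀJ
    at the solution, a direct measure of identifiability.
    """

    diffusivity: float | dict[str, float]
    partition_load: dict[str, float]
    partition_delivery: dict[str, float]
    objective_value: float
    n_iterations: int
    converged: bool
    relative_uncertainty: dict[str, float] = field(default_factory=dict)
    curvature_condition: float = math.nan
    message: str = ""

    def parameters_for(self, condition: str, template: TransportParameters | None = None) -> TransportParameters:
        """Materialise TransportParameters for one fitted condition."""
        base = template if template is not None else TransportParameters()
        d = self.diffusivity if isinstance(self.diffusivity, float) else self.diffusivity[condition]
        return replace(
            base,
            diffusivity=d,
            partition_load=self.partition_load[condition],
            partition_delivery=self.partition_delivery[condition],
        )


def standard_geometry(size_code: str, sample_length: float = DEFAULT_SAMPLE_LENGTH_CM) -> CatheterGeometry:
    """Geometry of one of the two supported commercial catheter gauges.

    Measured diameters are converted mm → cm and halved to radii; both
    sizes have a 1 mm wall.  Arbitrary gauges are intentionally not
    inferred from the nominal French convention — supply an explicit
    :class:`CatheterGeometry` instead.
    """
    try:
        d_in, d_out = CATHETER_DIAMETERS_MM[size_code]
    except KeyError:
        supported = ", ".join(sorted(CATHETER_DIAMETERS_MM))
        raise ValueError(f"unknown catheter size {size_code!r}; supported sizes: {supported}") from None
    return CatheterGeometry(
        inner_radius=d_in / 20.0,
        outer_radius=d_out / 20.0,
        sample_length=sample_length,
    )


def reference_parameters(
    condition: str,
    reservoir_volume: float = DEFAULT_RESERVOIR_VOLUME_CM3,
    bath_concentration: float = LOADING_CONCENTRATION_UG_CM3,
) -> TransportParameters:
    """Kinetic parameters of the uncoated ("control") or coated ("LbL")
    catheter: the shared diffusivity plus condition-specific partition
    coefficients, in the well-mixed (k >> D) boundary reduction."""
    try:
        gamma_load, gamma_delivery = REFERENCE_PARTITIONS[condition]
    except KeyError:
        supported = ", ".join(sorted(REFERENCE_PARTITIONS))
        raise ValueError(f"unknown condition {condition!r}; supported: {supported}") from None
    return TransportParameters(
        diffusivity=DIFFUSIVITY_CM2_PER_H,
        partition_load=gamma_load,
        partition_delivery=gamma_delivery,
        bath_concentration=bath_concentration,
        reservoir_volume=reservoir_volume,
    )
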