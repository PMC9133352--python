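"""Core domain containers for the aneurysm hemodynamic-cloud pipeline.

Units are fixed package-wide: lengths in mm, wall shear stress and pressure
in Pa, velocities in m/s, flow rates in m^3/s, energy loss in W.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields
from typing import Optional, Sequence

import numpy as np

SHAPE_FLAGS = ("smooth", "irregular")
LOCATION_FLAGS = ("sidewall", "bifurcation")
LABELS = ("unruptured", "ruptured")

#: fixed column order of the region point matrix fed to the network
REGION_CHANNELS = ("x", "y", "z", "wss_sys", "osi", "pressure", "velocity", "tawss")


class ContractError(ValueError):
    """Raised when an operation's input contract is violated."""


class GeometryError(ContractError):
    """Raised for degenerate or invalid sac geometry."""


class RegionError(ContractError):
    """Raised when a hemodynamic region cannot be formed for a subject."""


@dataclass
class SacGeometry:
    """Point-sampled aneurysm sac surface with a parent-vessel reference.

    The sac is an open surface bounded by the neck curve; ``neck_ring``
    indexes the points lying on that closed curve.  ``point_areas`` are the
    per-point area weights of the surface quadrature (mm^2) and
    ``point_normals`` the outward unit normals used for volume integration.
    """

    surface_points: np.ndarray  # (n, 3) mm
    point_areas: np.ndarray  # (n,) mm^2
    point_normals: np.ndarray  # (n, 3) unit outward
    neck_ring: np.ndarray  # (m,) int indices into surface_points
    dome_tip: int
    parent_diameter: float  # mm
    shape_flag: str = "smooth"
    location_flag: str = "sidewall"

    def __post_init__(self) -> None:
        self.surface_points = np.asarray(self.surface_points, dtype=float)
        self.point_areas = np.asarray(self.point_areas, dtype=float)
        self.point_normals = np.asarray(self.point_normals, dtype=float)
        self.neck_ring = np.asarray(self.neck_ring, dtype=int)
        if self.surface_points.ndim != 2 or self.surface_points.shape[1] != 3:
            raise GeometryError("surface_points must be (n, 3)")
        n = self.surface_points.shape[0]
        if self.point_areas.shape != (n,) or self.point_normals.shape != (n, 3):
            raise GeometryError("point_areas/point_normals shape mismatch")
        if np.any(self.point_areas <= 0):
            raise GeometryError("all point_areas must be positive")
        if self.neck_ring.size == 0:
            raise GeometryError("neck_ring must be non-empty")
        if self.shape_flag not in SHAPE_FLAGS:
            raise GeometryError(f"shape_flag must be one of {SHAPE_FLAGS}")
        if self.location_flag not in LOCATION_FLAGS:
            raise GeometryError(f"location_flag must be one of {LOCATION_FLAGS}")
        if not self.parent_diameter > 0:
            raise GeometryError("parent_diameter must be positive")

    @property
    def n_points(self) -> int:
        return self.surface_points.shape[0]

    @property
    def surface_area(self) -> float:
        """Total sac surface area (mm^2), the accumulation of point weights."""
        return float(self.point_areas.sum())


@dataclass
class FlowWaveform:
    """Pulsatile inlet speed over one cardiac cycle, sampled uniformly."""

    period: float  # s
    timestep: float  # s
    velocities: np.ndarray  # (n_steps,) m/s

    def __post_init__(self) -> None:
        self.velocities = np.asarray(self.velocities, dtype=float)
        if self.period <= 0 or self.timestep <= 0:
            raise ContractError("period and timestep must be positive")
        ratio = self.period / self.timestep
        if abs(ratio - round(ratio)) > 1e-9 or round(ratio) < 1:
            raise ContractError("period / timestep must be a positive integer")
        if self.velocities.shape != (self.n_steps,):
            raise ContractError(
                f"waveform needs {self.n_steps} samples, got {self.velocities.shape}"
            )

    @property
    def n_steps(self) -> int:
        return int(round(self.period / self.timestep))

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.n_steps) * self.timestep

    @property
    def systolic_index(self) -> int:
        """Index of the systolic frame: the peak of the inlet waveform."""
        return int(np.argmax(self.velocities))


@dataclass
class FlowState:
    """Cross-section state at an inlet or outlet for energy-loss bookkeeping."""

    pressure: float  # Pa
    velocity: float  # m/s
    flow_rate: float  # m^3/s


@dataclass
class HemodynamicCloud:
    """Per-subject hemodynamic point cloud on the sac surface.

    ``wss_series`` holds the time-resolved WSS vector per point over one
    cardiac cycle; ``pressure`` and ``velocity`` are the systolic-frame
    scalar channels.  The cycle-derived channels (``tawss``, ``osi``,
    ``wss_sys``) are filled by :mod:`aneucloud.hemodynamics`.
    """

    geometry: SacGeometry
    waveform: FlowWaveform
    wss_series: np.ndarray  # (n, n_steps, 3) Pa
    pressure: np.ndarray  # (n,) Pa at the systolic frame
    velocity: np.ndarray  # (n,) m/s at the systolic frame
    label: str = "unruptured"
    subject_id: str = "subject"
    parent_mean_wss: float = 5.0  # Pa, parent-artery TAWSS reference
    inlet_state: Optional[FlowState] = None
    outlet_states: Sequence[FlowState] = field(default_factory=tuple)
    tawss: Optional[np.ndarray] = None
    osi: Optional[np.ndarray] = None
    wss_sys: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.wss_series = np.asarray(self.wss_series, dtype=float)
        self.pressure = np.asarray(self.pressure, dtype=float)
        self.velocity = np.asarray(self.velocity, dtype=float)
        n = self.geometry.n_points
        if self.wss_series.shape != (n, self.waveform.n_steps, 3):
            raise ContractError(
                "wss_series must be (n_points, n_steps, 3); waveform/geometry mismatch"
            )
        if self.pressure.shape != (n,) or self.velocity.shape != (n,):
            raise ContractError("pressure/velocity must be (n_points,)")
        if self.label not in LABELS:
            raise ContractError(f"label must be one of {LABELS}")

    @property
    def has_derived_channels(self) -> bool:
        return self.tawss is not None and self.osi is not None and self.wss_sys is not None


@dataclass
class MorphoVector:
    """The ten morphological variables of one aneurysm."""

    neck_width: float  # mm
    height: float  # mm
    vessel_diameter: float  # mm
    size_ratio: float  # height / vessel_diameter
    aspect_ratio: float  # height / neck_width
    surface_area: float  # mm^2
    volume: float  # mm^3
    s_over_v: float  # mm^-1
    shape_flag: int  # 0 smooth, 1 irregular
    location_flag: int  # 0 sidewall, 1 bifurcation

    FIELDS = (
        "neck_width",
        "height",
        "vessel_diameter",
        "size_ratio",
        "aspect_ratio",
        "surface_area",
        "volume",
        "s_over_v",
        "shape_flag",
        "location_flag",
    )

    def as_array(self) -> np.ndarray:
        return np.array([getattr(self, f) for f in self.FIELDS], dtype=float)


@dataclass
class HemoVector:
    """The eighteen scalar hemodynamic parameters of one aneurysm.

    Max/avg/min triples for WSS (systolic), TAWSS, OSI, pressure and
    velocity, plus high-OSI area, low-shear area and energy loss.
    """

    wss_max: float
    wss_avg: float
    wss_min: float
    tawss_max: float
    tawss_avg: float
    tawss_min: float
    osi_max: float
    osi_avg: float
    osi_min: float
    pressure_max: float
    pressure_avg: float
    pressure_min: float
    velocity_max: float
    velocity_avg: float
    velocity_min: float
    hoa: float  # fraction of sac area with high OSI
    lsa: float  # fraction of sac area with low shear
    energy_loss: float  # W

    FIELDS = (
        "wss_max", "wss_avg", "wss_min",
        "tawss_max", "tawss_avg", "tawss_min",
        "osi_max", "osi_avg", "osi_min",
        "pressure_max", "pressure_avg", "pressure_min",
        "velocity_max", "velocity_avg", "velocity_min",
        "hoa", "lsa", "energy_loss",
    )

    def as_array(self) -> np.ndarray:
        return np.array([getattr(self, f) for f in self.FIELDS], dtype=float)


# provenance codes for region points
MASK_IMPINGEMENT = 1
MASK_JET = 2
MASK_BOTH = 3


@dataclass
class RegionPointSet:
    """Fixed-size sample of the impingement-zone / inflow-jet point cloud.

    ``points`` is the N x 8 matrix in the fixed :data:`REGION_CHANNELS`
    column order; ``source_masks`` records per-row provenance
    (impingement, jet, or both).
    """

    points: np.ndarray  # (N, 8)
    source_masks: np.ndarray  # (N,) int codes
    subject_id: str

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=float)
        self.source_masks = np.asarray(self.source_masks, dtype=int)
        if self.points.ndim != 2 or self.points.shape[1] != len(REGION_CHANNELS):
            raise ContractError(
                f"region points must have {len(REGION_CHANNELS)} columns"
            )
        if self.source_masks.shape != (self.points.shape[0],):
            raise ContractError("source_masks length mismatch")

    @property
    def n_points(self) -> int:
        return self.points.shape[0]


@dataclass
class CloudFeature:
    """The 1,024-dimensional max-pooled network embedding of one subject."""

    values: np.ndarray
    subject_id: str

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float).ravel()
        if self.values.shape != (1024,):
            raise ContractError("cloud feature must have exactly 1,024 entries")
        if not np.all(np.isfinite(self.values)):
            raise ContractError("cloud feature entries must be finite")
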