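"""Synthetic aneurysm cohort generator.

Real cohorts of this kind come from patient angiography followed by CFD;
neither is reproducible from published material, so this module generates
sac geometries and pulsatile wall-shear-stress / pressure / velocity fields
with controllable, class-dependent structure.  Every output is a pure
function of its seed and parameters.

Class-signal placement (``signal_mode``):

``summary``
    Scalar descriptor distributions (WSS level, oscillation strength,
    velocity, energy loss, neck-width ratio) are shifted between classes
    while the spatial texture generator is shared, so rupture status is
    readable from ordinary summary statistics.
``spatial``
    Per-subject value histograms of WSS and velocity are rank-matched to
    target draws whose distribution is identical across classes, so every
    area-weighted scalar summary (mean, max, min, low-shear area, high-OSI
    area) is moment-matched by construction; the classes differ only in the
    spatial arrangement of the hot regions — one concentrated impingement
    patch and a narrow inflow jet for ruptured subjects versus several
    diffuse patches and a broad jet for unruptured ones.  This mirrors the
    qualitative clinical observation that ruptured aneurysms show small
    impingement regions and narrow inflow jets.
``both``
    Both effects; ``none``: exchangeable classes (no signal anywhere).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import List, Optional, Sequence

import numpy as np

from .types import (
    ContractError,
    FlowState,
    FlowWaveform,
    GeometryError,
    HemodynamicCloud,
    SacGeometry,
)

SIGNAL_MODES = ("summary", "spatial", "both", "none")

_GOLDEN_ANGLE = np.pi * (3.0 - np.sqrt(5.0))

#: blood density used for energy-loss states, kg/m^3
BLOOD_DENSITY = 1060.0


def two_harmonic_waveform(
    period: float = 0.8,
    timestep: float = 0.01,
    mean_velocity: float = 0.3,
    amp1: float = 0.4,
    amp2: float = 0.15,
    peak_time: float = 0.12,
) -> FlowWaveform:
    """Parametric pulsatile inlet waveform with a systolic peak.

    A two-harmonic stand-in for a Doppler-measured carotid waveform:
    ``v(t) = v0 (1 + a1 cos(2 pi (t - tp)/T) + a2 cos(4 pi (t - tp)/T))``
    whose maximum sits at ``tp`` (default 0.12 s into the 0.8 s cycle) and
    whose cycle mean is exactly ``mean_velocity``.
    """
    if amp1 < 0 or amp2 < 0 or amp1 + amp2 >= 1:
        raise ContractError("waveform amplitudes must be >= 0 with amp1+amp2 < 1")
    n = int(round(period / timestep))
    t = np.arange(n) * timestep
    phase = 2 * np.pi * (t - peak_time) / period
    v = mean_velocity * (1.0 + amp1 * np.cos(phase) + amp2 * np.cos(2 * phase))
    return FlowWaveform(period=period, timestep=timestep, velocities=v)


def flat_waveform(period: float = 0.8, timestep: float = 0.01,
                  velocity: float = 0.3) -> FlowWaveform:
    """Steady (non-pulsatile) waveform, useful for oscillation-free checks."""
    n = int(round(period / timestep))
    return FlowWaveform(period, timestep, np.full(n, float(velocity)))


def make_sac_geometry(
    radius: float,
    neck_width: float,
    parent_diameter: float,
    shape_flag: str = "smooth",
    location_flag: str = "sidewall",
    n_points: int = 2000,
    seed: int = 0,
    n_neck: int = 48,
) -> SacGeometry:
    """Sample a spherical-cap aneurysm sac quasi-uniformly.

    The sac is the major cap of a sphere of the given radius cut by the neck
    plane; the neck width is the chord diameter of that cut, so the sac
    height is ``r + sqrt(r^2 - (w/2)^2)``.  Points follow a Fibonacci
    lattice (uniform in cap height, golden-angle azimuth), with ``n_neck``
    extra points placed exactly on the neck circle.  ``irregular`` sacs get
    2-3 radial daughter-sac lobes on the dome; lobes taper to zero at the
    neck so the neck ring stays on the cut circle.

    Per-point area weights are uniform at ``cap_area / n_total`` (Fibonacci
    sampling is asymptotically equal-area), rescaled by the local radial
    stretch for irregular sacs.
    """
    if radius <= 0 or parent_diameter <= 0 or neck_width <= 0:
        raise GeometryError("radius, neck_width and parent_diameter must be positive")
    if neck_width > 2 * radius + 1e-12:
        raise GeometryError("neck_width cannot exceed the sac diameter")
    if n_points < 50:
        raise GeometryError("n_points must be at least 50")

    rng = np.random.default_rng(seed)
    a = neck_width / 2.0
    d = float(np.sqrt(max(radius**2 - a**2, 0.0)))
    height = radius + d
    # Fibonacci lattice on the cap z in [-d, radius] (sphere centred at origin)
    i = np.arange(n_points)
    z = radius - (i + 0.5) * height / n_points
    phi = i * _GOLDEN_ANGLE + rng.uniform(0, 2 * np.pi)
    rho = np.sqrt(np.maximum(radius**2 - z**2, 0.0))
    pts = np.column_stack([rho * np.cos(phi), rho * np.sin(phi), z])

    # explicit closed neck ring on the cut circle z = -d
    ang = np.linspace(0, 2 * np.pi, n_neck, endpoint=False)
    ring = np.column_stack([a * np.cos(ang), a * np.sin(ang), np.full(n_neck, -d)])
    pts = np.vstack([pts, ring])
    n_total = pts.shape[0]

    normals = pts / np.linalg.norm(pts, axis=1, keepdims=True)
    cap_area = 2 * np.pi * radius * height
    areas = np.full(n_total, cap_area / n_total)

    if shape_flag == "irregular":
        n_lobes = int(rng.integers(2, 4))
        stretch = np.ones(n_total)
        # taper: lobes act on the dome and vanish at the neck plane
        taper = np.clip((pts[:, 2] + d) / height, 0.0, 1.0) ** 2
        for _ in range(n_lobes):
            u = rng.normal(size=3)
            u[2] = abs(u[2]) + 0.3  # bias lobe directions toward the dome
            u /= np.linalg.norm(u)
            amp = rng.uniform(0.15, 0.3)
            width = rng.uniform(0.25, 0.45)
            cosang = normals @ u
            angdist = np.arccos(np.clip(cosang, -1, 1))
            stretch += amp * np.exp(-(angdist**2) / (2 * width**2)) * taper
        pts = pts * stretch[:, None]
        areas = areas * stretch**2
        normals = pts / np.linalg.norm(pts, axis=1, keepdims=True)

    neck_ring = np.arange(n_points, n_total)
    dome_tip = int(np.argmax(pts[:, 2]))
    return SacGeometry(
        surface_points=pts,
        point_areas=areas,
        point_normals=normals,
        neck_ring=neck_ring,
        dome_tip=dome_tip,
        parent_diameter=parent_diameter,
        shape_flag=shape_flag,
        location_flag=location_flag,
    )


@dataclass
class _ClassParams:
    """Per-subject simulation parameters drawn according to the signal mode."""

    n_foci: int
    wss_patch_frac: float  # Gaussian patch width as a fraction of sac height
    jet_width_frac: float
    wss_median: float  # Pa, median of the per-subject target WSS histogram
    vel_median: float  # m/s
    osc_beta: float  # oscillatory WSS component amplitude
    pressure_base: float  # Pa
    el_drop: float  # Pa, inlet-to-outlet total-pressure drop


def _draw_class_params(rng: np.random.Generator, label: str,
                       signal_mode: str) -> _ClassParams:
    ruptured = label == "ruptured"
    shift = signal_mode in ("summary", "both") and ruptured
    spatial = signal_mode in ("spatial", "both")

    if spatial:
        # concentrated single patch / narrow jet vs several diffuse patches
        n_foci = 1 if ruptured else 3
        wss_patch_frac = 0.12 if ruptured else 0.35
        jet_width_frac = 0.10 if ruptured else 0.30
    else:
        concentrated = rng.random() < 0.5
        n_foci = 1 if concentrated else 3
        wss_patch_frac = 0.12 if concentrated else 0.35
        jet_width_frac = 0.10 if concentrated else 0.30

    if shift:
        wss_median = rng.uniform(1.5, 3.5)  # ruptured: lower sac WSS
        vel_median = rng.uniform(0.30, 0.55)
        osc_beta = rng.uniform(0.25, 0.45)  # ruptured: more oscillatory
        pressure_base = rng.uniform(150.0, 250.0)
        el_drop = rng.uniform(40.0, 90.0)
    elif signal_mode in ("summary", "both"):
        wss_median = rng.uniform(3.0, 6.0)
        vel_median = rng.uniform(0.15, 0.40)
        osc_beta = rng.uniform(0.05, 0.20)
        pressure_base = rng.uniform(100.0, 200.0)
        el_drop = rng.uniform(10.0, 40.0)
    else:  # spatial / none: identical marginals for both classes
        wss_median = rng.uniform(2.5, 5.0)
        vel_median = rng.uniform(0.20, 0.45)
        osc_beta = rng.uniform(0.10, 0.30)
        pressure_base = rng.uniform(100.0, 200.0)
        el_drop = rng.uniform(15.0, 60.0)
    return _ClassParams(n_foci, wss_patch_frac, jet_width_frac, wss_median,
                        vel_median, osc_beta, pressure_base, el_drop)


def _rank_match(field: np.ndarray, targets: np.ndarray) -> np.ndarray:
    """Reassign values so `field`'s ranks carry `targets`'s sorted values.

    The output's value histogram equals the target sample exactly, for any
    input field — this is what decouples scalar summaries from the spatial
    pattern.
    """
    order = np.argsort(field, kind="stable")
    out = np.empty_like(field)
    out[order] = np.sort(targets)
    return out


def _tangent_frames(normals: np.ndarray, ref: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Per-point orthonormal tangent pair (u, s) with u along `ref` projected."""
    u = ref[None, :] - (normals @ ref)[:, None] * normals
    nrm = np.linalg.norm(u, axis=1, keepdims=True)
    # degenerate where ref is parallel to the normal: fall back to any tangent
    fallback = np.cross(normals, np.array([1.0, 0.0, 0.0]))
    fb_nrm = np.linalg.norm(fallback, axis=1, keepdims=True)
    fallback2 = np.cross(normals, np.array([0.0, 1.0, 0.0]))
    fallback = np.where(fb_nrm > 1e-8, fallback, fallback2)
    fb_nrm = np.linalg.norm(fallback, axis=1, keepdims=True)
    u = np.where(nrm > 1e-8, u / np.maximum(nrm, 1e-300), fallback / fb_nrm)
    s = np.cross(normals, u)
    s /= np.linalg.norm(s, axis=1, keepdims=True)
    return u, s


def _segment_distance(points: np.ndarray, a: np.ndarray, b: np.ndarray) -> np.ndarray:
    ab = b - a
    denom = float(ab @ ab)
    if denom < 1e-12:
        return np.linalg.norm(points - a, axis=1)
    t = np.clip((points - a) @ ab / denom, 0.0, 1.0)
    proj = a + t[:, None] * ab
    return np.linalg.norm(points - proj, axis=1)


def simulate_hemo_fields(
    geometry: SacGeometry,
    waveform: FlowWaveform,
    label: str = "unruptured",
    signal_mode: str = "both",
    noise_sd: float = 0.2,
    seed: int = 0,
    subject_id: str = "subject",
    class_params: Optional[_ClassParams] = None,
) -> HemodynamicCloud:
    """Simulate pulsatile WSS vectors plus pressure/velocity channels.

    The WSS vector at point *i* and time *t* is
    ``B_i [ m(t) u_i + beta q(t) s_i ] + noise`` where ``m(t)`` is the inlet
    waveform normalised to unit mean, ``q(t) = m(t) - 1`` its pulsatile
    deviation, ``(u_i, s_i)`` a tangent frame, and ``B_i`` a spatial
    amplitude whose histogram is rank-matched to a lognormal target.  With a
    flat waveform and no noise the WSS is steady and unidirectional, so the
    oscillatory shear index vanishes identically.
    """
    if signal_mode not in SIGNAL_MODES:
        raise ContractError(f"signal_mode must be one of {SIGNAL_MODES}")
    if noise_sd < 0:
        raise ContractError("noise_sd must be >= 0")

    rng = np.random.default_rng(seed)
    params = class_params or _draw_class_params(rng, label, signal_mode)

    pts = geometry.surface_points
    n = geometry.n_points
    neck_c = pts[geometry.neck_ring].mean(axis=0)
    tip = pts[geometry.dome_tip]
    axis = tip - neck_c
    height = float(np.linalg.norm(axis))
    if height < 1e-9:
        raise GeometryError("degenerate sac: dome tip coincides with neck centroid")
    axis /= height

    # jet foci: random surface points in the dome's upper half
    elev = (pts - neck_c) @ axis
    upper = np.flatnonzero(elev > 0.5 * height)
    if upper.size == 0:
        upper = np.array([geometry.dome_tip])
    foci_idx = rng.choice(upper, size=min(params.n_foci, upper.size), replace=False)
    foci = pts[foci_idx]

    # spatial WSS profile: max-of-Gaussians around the foci
    sigma_w = params.wss_patch_frac * height
    d2 = ((pts[:, None, :] - foci[None, :, :]) ** 2).sum(axis=2)
    e_wss = np.exp(-d2 / (2 * sigma_w**2)).max(axis=1)
    # tiny seeded jitter makes ranks unique without moving the histogram
    e_wss = e_wss + 1e-9 * rng.standard_normal(n)

    wss_targets = rng.lognormal(mean=np.log(params.wss_median), sigma=0.7, size=n)
    B = _rank_match(e_wss, wss_targets)

    u_t, s_t = _tangent_frames(geometry.point_normals, foci[0] - neck_c)

    v = waveform.velocities
    m = v / v.mean()
    q = m - 1.0
    # (n, T, 3) = B_i * (m(t) u_i + beta q(t) s_i)
    wss = (
        B[:, None, None] * m[None, :, None] * u_t[:, None, :]
        + params.osc_beta * B[:, None, None] * q[None, :, None] * s_t[:, None, :]
    )
    if noise_sd > 0:
        wss = wss + noise_sd * rng.standard_normal(wss.shape)

    # inflow-jet velocity channel: distance to neck-to-focus segments
    sigma_v = params.jet_width_frac * height
    jet_d = np.min(
        np.stack([_segment_distance(pts, neck_c, f) for f in foci]), axis=0
    )
    e_vel = np.exp(-(jet_d**2) / (2 * sigma_v**2)) + 1e-9 * rng.standard_normal(n)
    vel_targets = rng.lognormal(mean=np.log(params.vel_median), sigma=0.6, size=n)
    velocity = _rank_match(e_vel, vel_targets)

    # smooth pressure: axial gradient plus a mild patch elevation, rank-matched
    # to a normal target so pressure summaries carry no spatial-pattern imprint
    e_pre = (
        30.0 * (elev / height)
        + 10.0 * np.exp(-d2.min(axis=1) / (2 * (0.4 * height) ** 2))
        + (noise_sd * 2.0) * rng.standard_normal(n)
    )
    pressure_targets = rng.normal(params.pressure_base, 12.0, size=n)
    pressure = _rank_match(e_pre, pressure_targets)

    # inlet/outlet states for energy loss; drop el_drop in total pressure
    u_in = float(v.max())
    area_m2 = np.pi * (geometry.parent_diameter / 2 * 1e-3) ** 2
    q_in = u_in * area_m2
    p_in = params.pressure_base + params.el_drop
    inlet = FlowState(pressure=p_in, velocity=u_in, flow_rate=q_in)
    u_out = u_in * rng.uniform(0.85, 1.0)
    dyn = 0.5 * BLOOD_DENSITY * (u_in**2 - u_out**2)
    p_out = p_in + dyn - params.el_drop  # static pressure balancing the drop
    outlets = (
        FlowState(pressure=p_out, velocity=u_out, flow_rate=q_in / 2),
        FlowState(pressure=p_out, velocity=u_out, flow_rate=q_in / 2),
    )

    return HemodynamicCloud(
        geometry=geometry,
        waveform=waveform,
        wss_series=wss,
        pressure=pressure,
        velocity=velocity,
        label=label,
        subject_id=subject_id,
        parent_mean_wss=float(rng.uniform(4.0, 7.0)),
        inlet_state=inlet,
        outlet_states=outlets,
    )


@dataclass
class CohortConfig:
    """Geometry and field parameters for cohort generation.

    Ranges reflect small internal-carotid aneurysms: sac radii of 2-5 mm,
    parent vessels of 3-5 mm, and a 0.8 s cardiac cycle sampled at 10 ms.
    """

    n_geometry_points: int = 1500
    radius_range: tuple = (2.0, 5.0)
    neck_ratio_range: tuple = (0.5, 0.95)  # neck_width / (2 * radius)
    parent_diameter_range: tuple = (3.0, 5.0)
    irregular_prob: float = 0.3
    bifurcation_prob: float = 0.4
    noise_sd: float = 0.2
    waveform_mean_velocity: float = 0.3


def _random_rotation(rng: np.random.Generator) -> np.ndarray:
    """Uniform random rotation matrix (QR of a Gaussian with sign fix)."""
    m = rng.standard_normal((3, 3))
    q_mat, r = np.linalg.qr(m)
    q_mat = q_mat * np.sign(np.diag(r))
    if np.linalg.det(q_mat) < 0:
        q_mat[:, 0] = -q_mat[:, 0]
    return q_mat


def _apply_rigid(geom: SacGeometry, rot: np.ndarray, shift: np.ndarray) -> SacGeometry:
    return SacGeometry(
        surface_points=geom.surface_points @ rot.T + shift,
        point_areas=geom.point_areas,
        point_normals=geom.point_normals @ rot.T,
        neck_ring=geom.neck_ring,
        dome_tip=geom.dome_tip,
        parent_diameter=geom.parent_diameter,
        shape_flag=geom.shape_flag,
        location_flag=geom.location_flag,
    )


def generate_cohort(
    n_subjects: int,
    rupture_fraction: float = 39.0 / 148.0,
    signal_mode: str = "both",
    seed: int = 0,
    config: Optional[CohortConfig] = None,
) -> List[HemodynamicCloud]:
    """Generate a labelled synthetic cohort.

    ``round(n_subjects * rupture_fraction)`` subjects are ruptured (the
    default fraction matches a 39/148 imbalanced cohort).  Geometry
    parameters are drawn per subject from the config ranges; in ``summary``
    and ``both`` modes ruptured subjects additionally get narrower necks
    (higher aspect ratio), giving the morphological block its own signal.
    Subjects are placed at random rigid poses.  Fully reproducible: the
    cohort is a pure function of ``(n_subjects, rupture_fraction,
    signal_mode, seed, config)``.
    """
    if not 0 < rupture_fraction < 1:
        raise ContractError("rupture_fraction must be in (0, 1)")
    if signal_mode not in SIGNAL_MODES:
        raise ContractError(f"signal_mode must be one of {SIGNAL_MODES}")
    if n_subjects < 20:
        warnings.warn(
            "cohorts below 20 subjects make stratified 10-fold CV infeasible",
            stacklevel=2,
        )
    cfg = config or CohortConfig()
    n_rupt = int(round(n_subjects * rupture_fraction))
    labels = ["ruptured"] * n_rupt + ["unruptured"] * (n_subjects - n_rupt)

    waveform = two_harmonic_waveform(mean_velocity=cfg.waveform_mean_velocity)
    seeds = np.random.SeedSequence(seed).spawn(n_subjects)
    cohort: List[HemodynamicCloud] = []
    for k, (label, ss) in enumerate(zip(labels, seeds)):
        child = ss.generate_state(2)
        rng = np.random.default_rng(child[0])
        radius = rng.uniform(*cfg.radius_range)
        lo, hi = cfg.neck_ratio_range
        if signal_mode in ("summary", "both") and label == "ruptured":
            # narrower necks: the classic high-aspect-ratio rupture correlate
            ratio = rng.uniform(lo, lo + 0.5 * (hi - lo))
        else:
            ratio = rng.uniform(lo, hi)
        geom = make_sac_geometry(
            radius=radius,
            neck_width=2 * radius * ratio,
            parent_diameter=rng.uniform(*cfg.parent_diameter_range),
            shape_flag="irregular" if rng.random() < cfg.irregular_prob else "smooth",
            location_flag="bifurcation" if rng.random() < cfg.bifurcation_prob else "sidewall",
            n_points=cfg.n_geometry_points,
            seed=int(rng.integers(2**31)),
        )
        geom = _apply_rigid(geom, _random_rotation(rng), rng.uniform(-20, 20, size=3))
        cloud = simulate_hemo_fields(
            geom,
            waveform,
            label=label,
            signal_mode=signal_mode,
            noise_sd=cfg.noise_sd,
            seed=int(child[1] % (2**31)),
            subject_id=f"S{k:04d}",
        )
        cohort.append(cloud)
    return cohort
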