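"""Cycle-derived WSS channels and the 18 scalar hemodynamic parameters.

Per-point channels over one cardiac cycle:

* TAWSS — time-averaged WSS magnitude, ``(1/T) \\int |w(t)| dt``;
* OSI — oscillatory shear index,
  ``0.5 (1 - |\\int w dt| / \\int |w| dt)``, in [0, 0.5];
* systolic WSS magnitude at the waveform's peak frame.

Both cycle integrals use the trapezoidal rule on the periodic extension
(the sample at t = T wraps to t = 0).  Scalar summaries are area-weighted
over the sac surface; the regional fractions LSA (low-shear area, TAWSS
below a fraction of the parent-artery mean — default 10%) and HOA
(high-OSI area, OSI above 0.2 by default) are area fractions, and energy
loss is the drop in total-pressure flux between inlet and outlets.
"""

from __future__ import annotations

from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .types import ContractError, FlowState, FlowWaveform, HemodynamicCloud, HemoVector

#: default LSA threshold as a fraction of the parent-artery mean WSS
LSA_THRESHOLD_FRAC = 0.10
#: default OSI threshold defining the high-OSI area
HOA_OSI_THRESHOLD = 0.20
#: blood density for energy-loss computation, kg/m^3
DENSITY = 1060.0


def _periodic_trapz(values: np.ndarray, timestep: float) -> np.ndarray:
    """Trapezoidal cycle integral along the last axis, wrapping t=T to t=0."""
    closed = np.concatenate([values, values[..., :1]], axis=-1)
    return np.trapezoid(closed, dx=timestep, axis=-1)


def compute_tawss(wss_series: np.ndarray, waveform: FlowWaveform) -> np.ndarray:
    """Time-averaged WSS magnitude per point (Pa)."""
    wss_series = np.asarray(wss_series, dtype=float)
    if wss_series.ndim != 3 or wss_series.shape[1] < 2:
        raise ContractError("wss_series must be (n, n_steps>=2, 3)")
    if wss_series.shape[1] != waveform.n_steps:
        raise ContractError("wss_series step count does not match the waveform")
    mag = np.linalg.norm(wss_series, axis=2)
    return _periodic_trapz(mag, waveform.timestep) / waveform.period


def compute_osi(wss_series: np.ndarray, waveform: FlowWaveform) -> np.ndarray:
    """Oscillatory shear index per point, in [0, 0.5].

    Points with an identically zero WSS vector over the whole cycle get
    OSI = 0 by convention (no shear, hence no oscillation).
    """
    wss_series = np.asarray(wss_series, dtype=float)
    if wss_series.ndim != 3 or wss_series.shape[1] < 2:
        raise ContractError("wss_series must be (n, n_steps>=2, 3)")
    if wss_series.shape[1] != waveform.n_steps:
        raise ContractError("wss_series step count does not match the waveform")
    mean_vec = _periodic_trapz(np.moveaxis(wss_series, 1, 2), waveform.timestep)
    num = np.linalg.norm(mean_vec, axis=1)
    den = _periodic_trapz(np.linalg.norm(wss_series, axis=2), waveform.timestep)
    osi = np.zeros(wss_series.shape[0])
    nz = den > 0
    osi[nz] = 0.5 * (1.0 - num[nz] / den[nz])
    return np.clip(osi, 0.0, 0.5)


def derive_channels(cloud: HemodynamicCloud) -> HemodynamicCloud:
    """Fill the tawss / osi / systolic-WSS channels in place; returns the cloud."""
    cloud.tawss = compute_tawss(cloud.wss_series, cloud.waveform)
    cloud.osi = compute_osi(cloud.wss_series, cloud.waveform)
    sys_idx = cloud.waveform.systolic_index
    cloud.wss_sys = np.linalg.norm(cloud.wss_series[:, sys_idx, :], axis=1)
    return cloud


def _area_fraction(values: np.ndarray, areas: np.ndarray, mask: np.ndarray) -> float:
    return float(areas[mask].sum() / areas.sum())


def compute_lsa(cloud: HemodynamicCloud, parent_mean_wss: float | None = None,
                threshold_frac: float = LSA_THRESHOLD_FRAC) -> float:
    """Area fraction of the sac with TAWSS below a parent-artery fraction."""
    ref = cloud.parent_mean_wss if parent_mean_wss is None else parent_mean_wss
    if not ref > 0:
        raise ContractError("parent_mean_wss must be positive")
    if cloud.tawss is None:
        raise ContractError("derive_channels must run before compute_lsa")
    areas = cloud.geometry.point_areas
    return _area_fraction(cloud.tawss, areas, cloud.tawss < threshold_frac * ref)


def compute_hoa(cloud: HemodynamicCloud,
                osi_threshold: float = HOA_OSI_THRESHOLD) -> float:
    """Area fraction of the sac with OSI above the threshold."""
    if cloud.osi is None:
        raise ContractError("derive_channels must run before compute_hoa")
    areas = cloud.geometry.point_areas
    return _area_fraction(cloud.osi, areas, cloud.osi > osi_threshold)


def compute_energy_loss(inlet_state: FlowState,
                        outlet_states: Sequence[FlowState],
                        density: float = DENSITY) -> float:
    """Energy loss (W): total-pressure flux in minus total-pressure flux out.

    ``EL = (P_in + rho u_in^2 / 2) Q_in - sum_out (P + rho u^2 / 2) Q``.
    Requires inlet and outlet volume fluxes to balance within 1%.
    """
    q_in = inlet_state.flow_rate
    q_out = sum(s.flow_rate for s in outlet_states)
    if q_in <= 0 or abs(q_in - q_out) > 0.01 * q_in:
        raise ContractError("inlet/outlet flow rates must balance within 1%")

    def flux(s: FlowState) -> float:
        return (s.pressure + 0.5 * density * s.velocity**2) * s.flow_rate

    return flux(inlet_state) - sum(flux(s) for s in outlet_states)


def _weighted_stats(values: np.ndarray, areas: np.ndarray) -> tuple[float, float, float]:
    avg = float(np.average(values, weights=areas))
    return float(values.max()), avg, float(values.min())


def summarize_hemodynamics(
    cloud: HemodynamicCloud,
    parent_mean_wss: float | None = None,
    lsa_threshold_frac: float = LSA_THRESHOLD_FRAC,
    hoa_osi_threshold: float = HOA_OSI_THRESHOLD,
) -> HemoVector:
    """The 18 scalar hemodynamic parameters of one subject.

    Max / area-weighted average / min for systolic WSS, TAWSS, OSI,
    pressure and velocity (the latter two are systolic-frame channels),
    plus HOA, LSA and energy loss.
    """
    if not cloud.has_derived_channels:
        derive_channels(cloud)
    areas = cloud.geometry.point_areas
    wss = _weighted_stats(cloud.wss_sys, areas)
    tawss = _weighted_stats(cloud.tawss, areas)
    osi = _weighted_stats(cloud.osi, areas)
    pressure = _weighted_stats(cloud.pressure, areas)
    velocity = _weighted_stats(cloud.velocity, areas)
    if cloud.inlet_state is None or not cloud.outlet_states:
        raise ContractError("inlet/outlet states required for energy loss")
    el = compute_energy_loss(cloud.inlet_state, cloud.outlet_states)
    return HemoVector(
        wss_max=wss[0], wss_avg=wss[1], wss_min=wss[2],
        tawss_max=tawss[0], tawss_avg=tawss[1], tawss_min=tawss[2],
        osi_max=osi[0], osi_avg=osi[1], osi_min=osi[2],
        pressure_max=pressure[0], pressure_avg=pressure[1], pressure_min=pressure[2],
        velocity_max=velocity[0], velocity_avg=velocity[1], velocity_min=velocity[2],
        hoa=compute_hoa(cloud, hoa_osi_threshold),
        lsa=compute_lsa(cloud, parent_mean_wss, lsa_threshold_frac),
        energy_loss=el,
    )


def hemodynamics_table(clouds: Iterable[HemodynamicCloud], **kwargs) -> pd.DataFrame:
    """One row of the 18 hemodynamic parameters per subject."""
    rows = {}
    for cloud in clouds:
        rows[cloud.subject_id] = summarize_hemodynamics(cloud, **kwargs).as_array()
    df = pd.DataFrame.from_dict(rows, orient="index", columns=HemoVector.FIELDS)
    df.index.name = "subject_id"
    return df
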