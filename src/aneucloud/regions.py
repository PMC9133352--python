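"""Impingement zone and inflow jet extraction, and region point sampling.

The impingement zone is where the inflow jet strikes the sac wall.  It is
operationalised as the points whose systolic WSS exceeds a fraction of the
sac maximum (default 80%), unioned with the jet's surface footprint — the
points within a radius of the peak-velocity point (the "influence area" of
the jet).  The inflow jet itself is thresholded on the velocity channel by
the mirrored rule.

Thresholds use strict ``>``; on a degenerate uniform field (where nothing
strictly exceeds the fraction of the maximum) the rule falls back to
``>=`` at the maximum so a mask is never empty.
"""

from __future__ import annotations

from typing import Optional

import numpy as np

from .types import (
    MASK_BOTH,
    MASK_IMPINGEMENT,
    MASK_JET,
    REGION_CHANNELS,
    ContractError,
    HemodynamicCloud,
    RegionPointSet,
    RegionError,
)
from .hemodynamics import derive_channels

#: default WSS threshold fraction defining the impingement zone
WSS_FRAC = 0.8
#: default velocity threshold fraction defining the inflow jet
VEL_FRAC = 0.8
#: jet influence radius as a fraction of sac height
JET_INFLUENCE_FRAC = 0.10


def _threshold_mask(values: np.ndarray, frac: float) -> np.ndarray:
    vmax = values.max()
    mask = values > frac * vmax
    if not mask.any():  # uniform field: fall back to >= at the maximum
        mask = values >= vmax
    return mask


def _sac_height(cloud: HemodynamicCloud) -> float:
    geom = cloud.geometry
    neck_c = geom.surface_points[geom.neck_ring].mean(axis=0)
    return float(np.linalg.norm(geom.surface_points[geom.dome_tip] - neck_c))


def find_inflow_jet(cloud: HemodynamicCloud, vel_frac: float = VEL_FRAC) -> np.ndarray:
    """Boolean mask of sac points in the inflow jet (high-velocity rule)."""
    if not 0 < vel_frac < 1:
        raise ContractError("vel_frac must be in (0, 1)")
    return _threshold_mask(cloud.velocity, vel_frac)


def find_impingement_zone(
    cloud: HemodynamicCloud,
    frac: float = WSS_FRAC,
    jet_influence_frac: Optional[float] = JET_INFLUENCE_FRAC,
) -> np.ndarray:
    """Boolean mask of sac points in the impingement zone.

    High systolic WSS (above ``frac`` of the sac maximum) unioned with the
    jet's surface footprint: points within ``jet_influence_frac`` of the
    sac height from the peak-velocity point.  Pass
    ``jet_influence_frac=None`` for the bare WSS rule.
    """
    if not 0 < frac < 1:
        raise ContractError("frac must be in (0, 1)")
    if cloud.wss_sys is None:
        derive_channels(cloud)
    mask = _threshold_mask(cloud.wss_sys, frac)
    if jet_influence_frac is not None:
        radius = jet_influence_frac * _sac_height(cloud)
        peak = cloud.geometry.surface_points[int(np.argmax(cloud.velocity))]
        dist = np.linalg.norm(cloud.geometry.surface_points - peak, axis=1)
        mask = mask | (dist <= radius)
    return mask


def sample_region_points(
    cloud: HemodynamicCloud,
    impingement_mask: np.ndarray,
    jet_mask: np.ndarray,
    n: int = 5000,
    seed: int = 0,
) -> RegionPointSet:
    """Draw ``n`` points uniformly from the impingement-jet union.

    Sampling is without replacement while the union is large enough and
    with replacement otherwise, so the output size is always exactly ``n``
    (the network needs a fixed-size point matrix).  The 8 channels are
    assembled in the fixed order (x, y, z, systolic WSS, OSI, pressure,
    velocity, TAWSS).
    """
    if n < 1:
        raise ContractError("n must be >= 1")
    if not cloud.has_derived_channels:
        derive_channels(cloud)
    union = impingement_mask | jet_mask
    idx_pool = np.flatnonzero(union)
    if idx_pool.size == 0:
        raise RegionError(f"empty impingement/jet union for subject {cloud.subject_id}")
    rng = np.random.default_rng(seed)
    replace = idx_pool.size < n
    idx = rng.choice(idx_pool, size=n, replace=replace)

    pts = cloud.geometry.surface_points[idx]
    matrix = np.column_stack([
        pts[:, 0], pts[:, 1], pts[:, 2],
        cloud.wss_sys[idx], cloud.osi[idx], cloud.pressure[idx],
        cloud.velocity[idx], cloud.tawss[idx],
    ])
    assert matrix.shape[1] == len(REGION_CHANNELS)
    codes = np.where(
        impingement_mask[idx] & jet_mask[idx], MASK_BOTH,
        np.where(impingement_mask[idx], MASK_IMPINGEMENT, MASK_JET),
    )
    return RegionPointSet(points=matrix, source_masks=codes, subject_id=cloud.subject_id)


def extract_region(cloud: HemodynamicCloud, n: int = 5000, seed: int = 0,
                   wss_frac: float = WSS_FRAC, vel_frac: float = VEL_FRAC,
                   jet_influence_frac: Optional[float] = JET_INFLUENCE_FRAC) -> RegionPointSet:
    """Convenience: masks plus sampling in one call."""
    jet = find_inflow_jet(cloud, vel_frac)
    imp = find_impingement_zone(cloud, wss_frac, jet_influence_frac)
    return sample_region_points(cloud, imp, jet, n=n, seed=seed)
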