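"""Morphological variables of an aneurysm sac.

Ten variables: neck width, height, parent-vessel diameter, size ratio,
aspect ratio, surface area, volume, surface-to-volume ratio, and the two
categorical flags (shape, location).

Definitions follow the dominant usage in the aneurysm-morphometry
literature: aspect ratio = height / neck width, size ratio = height /
parent-vessel diameter.  Height is measured perpendicular to the
least-squares neck plane by default (``height_mode="plane"``); the
maximum point-to-neck-plane distance alternative that some groups use is
``height_mode="max_distance"`` (max distance from the neck *centroid*).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .types import GeometryError, MorphoVector, SacGeometry


def _neck_plane(geometry: SacGeometry) -> tuple[np.ndarray, np.ndarray]:
    """Least-squares plane through the neck ring: (centroid, unit normal).

    The normal is oriented toward the sac interior (dome side).
    """
    ring = geometry.surface_points[geometry.neck_ring]
    centroid = ring.mean(axis=0)
    centered = ring - centroid
    # smallest singular vector of the centred ring = plane normal
    _, s, vt = np.linalg.svd(centered, full_matrices=False)
    if s[1] < 1e-9 * max(s[0], 1.0):
        raise GeometryError("degenerate neck: ring points are collinear")
    normal = vt[2]
    tip = geometry.surface_points[geometry.dome_tip]
    if (tip - centroid) @ normal < 0:
        normal = -normal
    return centroid, normal


def compute_morphology(geometry: SacGeometry, height_mode: str = "plane") -> MorphoVector:
    """Compute the ten morphological variables from a sampled sac surface.

    Neck width is the maximum pairwise distance across neck-ring points;
    surface area is the accumulated point weight; volume comes from the
    divergence theorem over the closed surface formed by the sac samples
    and the flat neck cap (whose contribution vanishes when position
    vectors are taken from the neck centroid).
    """
    if height_mode not in ("plane", "max_distance"):
        raise GeometryError("height_mode must be 'plane' or 'max_distance'")
    centroid, normal = _neck_plane(geometry)
    ring = geometry.surface_points[geometry.neck_ring]
    diff = ring[:, None, :] - ring[None, :, :]
    neck_width = float(np.sqrt((diff**2).sum(axis=2)).max())

    pts = geometry.surface_points
    if height_mode == "plane":
        height = float(((pts - centroid) @ normal).max())
    else:
        height = float(np.linalg.norm(pts - centroid, axis=1).max())
    if height <= 0:
        raise GeometryError("sac has no extent above the neck plane")

    surface_area = geometry.surface_area
    # V = (1/3) sum (p - c) . n dA over the sac; the neck cap lies in the
    # plane through c so its term is zero.
    volume = float(
        np.einsum("ij,ij,i->", pts - centroid, geometry.point_normals,
                  geometry.point_areas) / 3.0
    )
    if volume <= 0:
        raise GeometryError("non-positive enclosed volume; check normals")

    return MorphoVector(
        neck_width=neck_width,
        height=height,
        vessel_diameter=float(geometry.parent_diameter),
        size_ratio=height / geometry.parent_diameter,
        aspect_ratio=height / neck_width,
        surface_area=surface_area,
        volume=volume,
        s_over_v=surface_area / volume,
        shape_flag=1 if geometry.shape_flag == "irregular" else 0,
        location_flag=1 if geometry.location_flag == "bifurcation" else 0,
    )


def morphology_table(clouds, height_mode: str = "plane") -> pd.DataFrame:
    """One row of the ten morphological variables per subject."""
    rows = {}
    for cloud in clouds:
        mv = compute_morphology(cloud.geometry, height_mode=height_mode)
        rows[cloud.subject_id] = mv.as_array()
    df = pd.DataFrame.from_dict(rows, orient="index", columns=MorphoVector.FIELDS)
    df.index.name = "subject_id"
    return df
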