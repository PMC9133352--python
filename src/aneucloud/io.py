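"""Plain-text serialization: ASCII VTK PolyData (.vtp), flat CSV, manifests.

The .vtp files are standard XML PolyData readable by ParaView: point
coordinates, per-point data arrays ``wss_t000..wss_t079`` (3-vectors, one
per cardiac-cycle step), ``pressure``, ``velocity``, ``area``, ``normal``
and, when derived, ``tawss``/``osi``/``wss_sys``; scalars and small
vectors (waveform, neck-ring indices, flow states, flags) ride in
FieldData.  The subject id is the file stem.

The flat CSV dialect is one row per point with columns
``x,y,z,area,nx,ny,nz,wss_x_t000,wss_y_t000,wss_z_t000,...,pressure,
velocity`` plus a JSON sidecar (``<stem>.meta.json``) holding the scalar
metadata; it exists for spreadsheet-level inspection and interchange.

All writers use a fixed ``%.17g`` float format, so identical inputs give
byte-identical files.
"""

from __future__ import annotations

import json
from pathlib import Path
from xml.etree import ElementTree as ET

import numpy as np
import pandas as pd

from .types import (
    ContractError,
    FlowState,
    FlowWaveform,
    HemodynamicCloud,
    SacGeometry,
)

_FMT = "%.17g"


def _fmt_array(a: np.ndarray) -> str:
    return " ".join(_FMT % v for v in np.asarray(a, dtype=float).ravel())


def _data_array(name: str, a: np.ndarray, n_comp: int) -> ET.Element:
    el = ET.Element("DataArray", {
        "type": "Float64", "Name": name,
        "NumberOfComponents": str(n_comp), "format": "ascii",
    })
    el.text = _fmt_array(a)
    return el


def _int_array(name: str, a: np.ndarray) -> ET.Element:
    el = ET.Element("DataArray", {
        "type": "Int64", "Name": name, "NumberOfComponents": "1",
        "format": "ascii",
    })
    el.text = " ".join(str(int(v)) for v in np.asarray(a).ravel())
    return el


_LABEL_CODES = {"unruptured": 0, "ruptured": 1}
_SHAPE_CODES = {"smooth": 0, "irregular": 1}
_LOCATION_CODES = {"sidewall": 0, "bifurcation": 1}


def write_vtp(cloud: HemodynamicCloud, path) -> Path:
    """Write one subject as ASCII VTK PolyData."""
    path = Path(path)
    geom = cloud.geometry
    n = geom.n_points
    root = ET.Element("VTKFile", {"type": "PolyData", "version": "1.0",
                                  "byte_order": "LittleEndian"})
    poly = ET.SubElement(root, "PolyData")
    piece = ET.SubElement(poly, "Piece", {
        "NumberOfPoints": str(n), "NumberOfVerts": "0", "NumberOfLines": "0",
        "NumberOfStrips": "0", "NumberOfPolys": "0",
    })
    points = ET.SubElement(piece, "Points")
    points.append(_data_array("Points", geom.surface_points, 3))

    pdata = ET.SubElement(piece, "PointData")
    for t in range(cloud.waveform.n_steps):
        pdata.append(_data_array(f"wss_t{t:03d}", cloud.wss_series[:, t, :], 3))
    pdata.append(_data_array("pressure", cloud.pressure, 1))
    pdata.append(_data_array("velocity", cloud.velocity, 1))
    pdata.append(_data_array("area", geom.point_areas, 1))
    pdata.append(_data_array("normal", geom.point_normals, 3))
    for name in ("tawss", "osi", "wss_sys"):
        channel = getattr(cloud, name)
        if channel is not None:
            pdata.append(_data_array(name, channel, 1))

    fdata = ET.SubElement(root, "FieldData")
    fdata.append(_data_array("parent_diameter", np.array([geom.parent_diameter]), 1))
    fdata.append(_data_array("parent_mean_wss", np.array([cloud.parent_mean_wss]), 1))
    fdata.append(_data_array("period", np.array([cloud.waveform.period]), 1))
    fdata.append(_data_array("timestep", np.array([cloud.waveform.timestep]), 1))
    fdata.append(_data_array("waveform", cloud.waveform.velocities, 1))
    fdata.append(_int_array("neck_ring", geom.neck_ring))
    fdata.append(_int_array("dome_tip", np.array([geom.dome_tip])))
    fdata.append(_int_array("label", np.array([_LABEL_CODES[cloud.label]])))
    fdata.append(_int_array("shape_flag", np.array([_SHAPE_CODES[geom.shape_flag]])))
    fdata.append(_int_array("location_flag",
                            np.array([_LOCATION_CODES[geom.location_flag]])))
    if cloud.inlet_state is not None:
        states = [cloud.inlet_state, *cloud.outlet_states]
        flat = np.array([[s.pressure, s.velocity, s.flow_rate] for s in states])
        fdata.append(_data_array("flow_states", flat, 3))

    ET.indent(root)
    path.write_text(ET.tostring(root, encoding="unicode") + "\n")
    return path


def _read_arrays(parent: ET.Element) -> dict:
    out = {}
    for el in parent.iter("DataArray"):
        name = el.get("Name")
        n_comp = int(el.get("NumberOfComponents", "1"))
        text = el.text or ""
        if el.get("type") == "Int64":
            arr = np.array([int(v) for v in text.split()], dtype=int)
        else:
            arr = np.array(text.split(), dtype=float)
        if n_comp > 1:
            arr = arr.reshape(-1, n_comp)
        out[name] = arr
    return out


def read_vtp(path) -> HemodynamicCloud:
    """Read a subject written by :func:`write_vtp`; subject id = file stem."""
    path = Path(path)
    root = ET.fromstring(path.read_text())
    piece = root.find("PolyData/Piece")
    if piece is None:
        raise ContractError(f"{path} is not a PolyData piece")
    points = _read_arrays(piece.find("Points"))["Points"]
    pdata = _read_arrays(piece.find("PointData"))
    fdata = _read_arrays(root.find("FieldData"))

    wss_names = sorted(k for k in pdata if k.startswith("wss_t"))
    if not wss_names:
        raise ContractError(f"{path} has no wss_t* arrays")
    wss = np.stack([pdata[k] for k in wss_names], axis=1)

    code = {v: k for k, v in _LABEL_CODES.items()}[int(fdata["label"][0])]
    shape = {v: k for k, v in _SHAPE_CODES.items()}[int(fdata["shape_flag"][0])]
    loc = {v: k for k, v in _LOCATION_CODES.items()}[int(fdata["location_flag"][0])]
    geom = SacGeometry(
        surface_points=points,
        point_areas=pdata["area"],
        point_normals=pdata["normal"],
        neck_ring=fdata["neck_ring"],
        dome_tip=int(fdata["dome_tip"][0]),
        parent_diameter=float(fdata["parent_diameter"][0]),
        shape_flag=shape,
        location_flag=loc,
    )
    waveform = FlowWaveform(period=float(fdata["period"][0]),
                            timestep=float(fdata["timestep"][0]),
                            velocities=fdata["waveform"])
    inlet = None
    outlets: tuple = ()
    if "flow_states" in fdata:
        rows = [FlowState(*row) for row in np.atleast_2d(fdata["flow_states"])]
        inlet, outlets = rows[0], tuple(rows[1:])
    cloud = HemodynamicCloud(
        geometry=geom, waveform=waveform, wss_series=wss,
        pressure=pdata["pressure"], velocity=pdata["velocity"],
        label=code, subject_id=path.stem,
        parent_mean_wss=float(fdata["parent_mean_wss"][0]),
        inlet_state=inlet, outlet_states=outlets,
        tawss=pdata.get("tawss"), osi=pdata.get("osi"),
        wss_sys=pdata.get("wss_sys"),
    )
    return cloud


def write_cloud_csv(cloud: HemodynamicCloud, path) -> Path:
    """Flat one-row-per-point CSV plus a JSON metadata sidecar."""
    path = Path(path)
    geom = cloud.geometry
    n_steps = cloud.waveform.n_steps
    cols = {"x": geom.surface_points[:, 0], "y": geom.surface_points[:, 1],
            "z": geom.surface_points[:, 2], "area": geom.point_areas,
            "nx": geom.point_normals[:, 0], "ny": geom.point_normals[:, 1],
            "nz": geom.point_normals[:, 2]}
    for t in range(n_steps):
        for j, ax in enumerate("xyz"):
            cols[f"wss_{ax}_t{t:03d}"] = cloud.wss_series[:, t, j]
    cols["pressure"] = cloud.pressure
    cols["velocity"] = cloud.velocity
    pd.DataFrame(cols).to_csv(path, index=False, float_format=_FMT)
    meta = {
        "subject_id": cloud.subject_id, "label": cloud.label,
        "parent_diameter": geom.parent_diameter,
        "parent_mean_wss": cloud.parent_mean_wss,
        "shape_flag": geom.shape_flag, "location_flag": geom.location_flag,
        "neck_ring": [int(i) for i in geom.neck_ring],
        "dome_tip": int(geom.dome_tip),
        "period": cloud.waveform.period, "timestep": cloud.waveform.timestep,
        "waveform": list(cloud.waveform.velocities),
    }
    if cloud.inlet_state is not None:
        meta["flow_states"] = [
            [s.pressure, s.velocity, s.flow_rate]
            for s in (cloud.inlet_state, *cloud.outlet_states)
        ]
    path.with_suffix(".meta.json").write_text(json.dumps(meta))
    return path


def write_region_csv(region, path) -> Path:
    """N x 8 region matrix plus provenance column, full float precision."""
    from .types import REGION_CHANNELS

    path = Path(path)
    df = pd.DataFrame(region.points, columns=list(REGION_CHANNELS))
    df["source_mask"] = region.source_masks
    df.to_csv(path, index=False, float_format=_FMT)
    return path


def read_region_csv(path, subject_id: str | None = None):
    """Bit-exact read of a region matrix written by :func:`write_region_csv`."""
    from .types import REGION_CHANNELS, RegionPointSet

    path = Path(path)
    df = pd.read_csv(path, float_precision="round_trip")
    if subject_id is None:
        subject_id = path.name.replace(".region.csv", "").replace(".csv", "")
    return RegionPointSet(points=df[list(REGION_CHANNELS)].to_numpy(),
                          source_masks=df["source_mask"].to_numpy(),
                          subject_id=subject_id)


def read_cloud_csv(path) -> HemodynamicCloud:
    """Read a subject written by :func:`write_cloud_csv`."""
    path = Path(path)
    df = pd.read_csv(path, float_precision="round_trip")
    meta = json.loads(path.with_suffix(".meta.json").read_text())
    wss_cols = sorted(c for c in df.columns if c.startswith("wss_"))
    n_steps = len(wss_cols) // 3
    wss = np.empty((len(df), n_steps, 3))
    for t in range(n_steps):
        for j, ax in enumerate("xyz"):
            wss[:, t, j] = df[f"wss_{ax}_t{t:03d}"]
    geom = SacGeometry(
        surface_points=df[["x", "y", "z"]].to_numpy(),
        point_areas=df["area"].to_numpy(),
        point_normals=df[["nx", "ny", "nz"]].to_numpy(),
        neck_ring=np.array(meta["neck_ring"], dtype=int),
        dome_tip=int(meta["dome_tip"]),
        parent_diameter=meta["parent_diameter"],
        shape_flag=meta["shape_flag"], location_flag=meta["location_flag"],
    )
    waveform = FlowWaveform(meta["period"], meta["timestep"],
                            np.array(meta["waveform"]))
    inlet = None
    outlets: tuple = ()
    if "flow_states" in meta:
        rows = [FlowState(*r) for r in meta["flow_states"]]
        inlet, outlets = rows[0], tuple(rows[1:])
    return HemodynamicCloud(
        geometry=geom, waveform=waveform, wss_series=wss,
        pressure=df["pressure"].to_numpy(), velocity=df["velocity"].to_numpy(),
        label=meta["label"], subject_id=meta["subject_id"],
        parent_mean_wss=meta["parent_mean_wss"],
        inlet_state=inlet, outlet_states=outlets,
    )


def write_cohort(cohort, out_dir, fmt: str = "vtp") -> Path:
    """Write every subject plus a manifest CSV; returns the manifest path."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rows = []
    for cloud in cohort:
        if fmt == "vtp":
            p = write_vtp(cloud, out_dir / f"{cloud.subject_id}.vtp")
        elif fmt == "csv":
            p = write_cloud_csv(cloud, out_dir / f"{cloud.subject_id}.csv")
        else:
            raise ContractError("fmt must be 'vtp' or 'csv'")
        rows.append({
            "subject_id": cloud.subject_id, "label": cloud.label,
            "parent_diameter": cloud.geometry.parent_diameter,
            "shape_flag": cloud.geometry.shape_flag,
            "location_flag": cloud.geometry.location_flag,
            "n_points": cloud.geometry.n_points, "path": p.name,
        })
    manifest = out_dir / "cohort_manifest.csv"
    pd.DataFrame(rows).to_csv(manifest, index=False, float_format=_FMT)
    return manifest


def read_cohort(manifest_path):
    """Load every subject listed in a manifest CSV."""
    manifest_path = Path(manifest_path)
    df = pd.read_csv(manifest_path)
    clouds = []
    for _, row in df.iterrows():
        p = manifest_path.parent / row["path"]
        clouds.append(read_vtp(p) if p.suffix == ".vtp" else read_cloud_csv(p))
    return clouds
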