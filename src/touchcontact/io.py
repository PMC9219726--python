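"""Reading and writing point clouds, meshes, series and configs.

Point clouds travel as PLY (ASCII written; ASCII and binary little-endian
read) or PCD (ASCII), meshes as OBJ or PLY via trimesh, attribute series
as CSV with a JSON sidecar carrying units and frame vectors, and configs
as YAML. All coordinates are metres.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import pandas as pd
import trimesh
import yaml

from .cloud import ArmSurface, HandMeshFrame, SurfacePointCloud
from .kinematics import ContactAttributeSeries
from .synth import GestureConfig, SyntheticTrial
from .segmentation import SegmentationConfig

__all__ = [
    "read_cloud", "write_cloud", "read_mesh", "write_mesh",
    "read_series", "write_series", "read_config", "write_config",
    "save_trial", "load_trial", "contact_frames_to_csv",
]

SERIES_COLUMNS = ["t", "contact", "Vabs", "Vlg", "Vlt", "Vvt", "area", "depth"]

_PLY_DTYPES = {
    "float": np.float32, "float32": np.float32,
    "double": np.float64, "float64": np.float64,
    "uchar": np.uint8, "uint8": np.uint8,
    "int": np.int32, "int32": np.int32,
    "uint": np.uint32, "short": np.int16, "ushort": np.uint16,
    "char": np.int8,
}


class ParseError(ValueError):
    """Malformed file; the message names the failing element and offset."""


def _read_ply(path: Path) -> SurfacePointCloud:
    with open(path, "rb") as fh:
        line = fh.readline().strip()
        if line != b"ply":
            raise ParseError(f"{path}: not a PLY file (missing 'ply' magic)")
        fmt = None
        elements = []  # (name, count, [(prop, dtype)])
        while True:
            raw = fh.readline()
            if not raw:
                raise ParseError(f"{path}: header truncated before end_header")
            parts = raw.decode("ascii", "replace").split()
            if not parts:
                continue
            if parts[0] == "format":
                fmt = parts[1]
            elif parts[0] == "element":
                elements.append((parts[1], int(parts[2]), []))
            elif parts[0] == "property":
                if parts[1] == "list":
                    elements[-1][2].append((parts[4], "list", parts[2], parts[3]))
                else:
                    elements[-1][2].append((parts[2], parts[1]))
            elif parts[0] == "end_header":
                break
        if fmt not in ("ascii", "binary_little_endian"):
            raise ParseError(f"{path}: unsupported PLY format {fmt!r}")
        data = {}
        for name, count, props in elements:
            if any(p[1] == "list" for p in props):
                # skip list elements (faces) — clouds only
                if fmt == "ascii":
                    for _ in range(count):
                        fh.readline()
                else:
                    for _ in range(count):
                        (n_items,) = np.frombuffer(fh.read(1), np.uint8)
                        fh.read(4 * int(n_items))
                continue
            dtype = np.dtype([(p[0], _PLY_DTYPES[p[1]]) for p in props])
            if fmt == "ascii":
                rows = []
                for i in range(count):
                    raw = fh.readline().split()
                    if len(raw) != len(props):
                        raise ParseError(
                            f"{path}: element '{name}' truncated at row {i}"
                        )
                    rows.append(tuple(float(v) for v in raw))
                data[name] = np.array(rows, dtype=dtype)
            else:
                buf = fh.read(dtype.itemsize * count)
                if len(buf) != dtype.itemsize * count:
                    raise ParseError(f"{path}: element '{name}' truncated")
                data[name] = np.frombuffer(buf, dtype=dtype)
    if "vertex" not in data:
        raise ParseError(f"{path}: no 'vertex' element")
    v = data["vertex"]
    names = v.dtype.names
    pts = np.column_stack([v["x"], v["y"], v["z"]]).astype(float)
    normals = None
    colors = None
    if {"nx", "ny", "nz"} <= set(names):
        normals = np.column_stack([v["nx"], v["ny"], v["nz"]]).astype(float)
        norms = np.linalg.norm(normals, axis=1)
        normals = np.divide(normals, norms[:, None],
                            out=np.zeros_like(normals), where=norms[:, None] > 0)
        if np.any(norms == 0):
            normals = None
    if {"red", "green", "blue"} <= set(names):
        colors = np.column_stack([v["red"], v["green"], v["blue"]]).astype(float) / 255.0
    return SurfacePointCloud(points=pts, colors=colors, normals=normals)


def _write_ply(cloud: SurfacePointCloud, path: Path) -> None:
    props = ["property double x", "property double y", "property double z"]
    cols = [cloud.points]
    fmts = ["%.17g"] * 3
    if cloud.normals is not None:
        props += ["property double nx", "property double ny", "property double nz"]
        cols.append(cloud.normals)
        fmts += ["%.17g"] * 3
    if cloud.colors is not None:
        props += ["property uchar red", "property uchar green", "property uchar blue"]
        cols.append(np.clip(np.round(cloud.colors * 255), 0, 255))
        fmts += ["%d"] * 3
    header = "\n".join(
        ["ply", "format ascii 1.0", f"element vertex {len(cloud)}"]
        + props + ["end_header"]
    )
    body = np.column_stack(cols)
    fmt = " ".join(fmts)
    with open(path, "w") as fh:
        fh.write(header + "\n")
        np.savetxt(fh, body, fmt=fmt)


def _read_pcd(path: Path) -> SurfacePointCloud:
    fields = sizes = None
    count = None
    header_done = False
    rows = []
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            parts = line.split()
            if not parts or parts[0].startswith("#"):
                continue
            if not header_done:
                key = parts[0].upper()
                if key == "FIELDS":
                    fields = parts[1:]
                elif key == "POINTS":
                    count = int(parts[1])
                elif key == "DATA":
                    if parts[1] != "ascii":
                        raise ParseError(f"{path}: only ascii PCD supported")
                    header_done = True
                continue
            if len(parts) != len(fields):
                raise ParseError(f"{path}: malformed point at line {ln}")
            rows.append([float(v) for v in parts])
    if fields is None or not header_done:
        raise ParseError(f"{path}: missing PCD header")
    arr = np.asarray(rows, dtype=float)
    if count is not None and len(arr) != count:
        raise ParseError(f"{path}: POINTS={count} but {len(arr)} data rows")
    col = {f: i for i, f in enumerate(fields)}
    pts = arr[:, [col["x"], col["y"], col["z"]]]
    normals = None
    if {"normal_x", "normal_y", "normal_z"} <= set(fields):
        normals = arr[:, [col["normal_x"], col["normal_y"], col["normal_z"]]]
    colors = None
    if {"r", "g", "b"} <= set(fields):
        colors = arr[:, [col["r"], col["g"], col["b"]]]
    return SurfacePointCloud(points=pts, colors=colors, normals=normals)


def _write_pcd(cloud: SurfacePointCloud, path: Path) -> None:
    fields = ["x", "y", "z"]
    cols = [cloud.points]
    if cloud.normals is not None:
        fields += ["normal_x", "normal_y", "normal_z"]
        cols.append(cloud.normals)
    if cloud.colors is not None:
        fields += ["r", "g", "b"]
        cols.append(cloud.colors)
    n = len(cloud)
    with open(path, "w") as fh:
        fh.write("# .PCD v0.7 - Point Cloud Data file format\n")
        fh.write("VERSION 0.7\n")
        fh.write("FIELDS " + " ".join(fields) + "\n")
        fh.write("SIZE " + " ".join(["8"] * len(fields)) + "\n")
        fh.write("TYPE " + " ".join(["F"] * len(fields)) + "\n")
        fh.write("COUNT " + " ".join(["1"] * len(fields)) + "\n")
        fh.write(f"WIDTH {n}\nHEIGHT 1\nVIEWPOINT 0 0 0 1 0 0 0\n")
        fh.write(f"POINTS {n}\nDATA ascii\n")
        np.savetxt(fh, np.column_stack(cols), fmt="%.17g")


def read_cloud(path) -> SurfacePointCloud:
    path = Path(path)
    if path.suffix == ".ply":
        return _read_ply(path)
    if path.suffix == ".pcd":
        return _read_pcd(path)
    raise ValueError(f"unknown point-cloud extension {path.suffix!r}")


def write_cloud(cloud: SurfacePointCloud, path) -> None:
    path = Path(path)
    if path.suffix == ".ply":
        _write_ply(cloud, path)
    elif path.suffix == ".pcd":
        _write_pcd(cloud, path)
    else:
        raise ValueError(f"unknown point-cloud extension {path.suffix!r}")


def read_mesh(path, joint_position=None, timestamp: float = 0.0) -> HandMeshFrame:
    """Load a hand mesh (OBJ or PLY) as a frame; vertex order is preserved."""
    path = Path(path)
    if path.suffix not in (".obj", ".ply"):
        raise ValueError(f"unknown mesh extension {path.suffix!r}")
    mesh = trimesh.load(path, process=False, maintain_order=True)
    vertices = np.asarray(mesh.vertices, dtype=float)
    faces = None
    if hasattr(mesh, "faces") and len(mesh.faces):
        faces = np.asarray(mesh.faces, dtype=int)
    if joint_position is None:
        joint_position = vertices.mean(axis=0)
    return HandMeshFrame(
        vertices=vertices, joint_position=joint_position,
        timestamp=timestamp, faces=faces,
    )


def write_mesh(frame: HandMeshFrame, path) -> None:
    path = Path(path)
    if path.suffix != ".obj":
        raise ValueError("meshes are written as OBJ")
    with open(path, "w") as fh:
        fh.write("# touchcontact hand mesh frame\n")
        fh.write(f"# joint {frame.joint_position[0]:.17g} "
                 f"{frame.joint_position[1]:.17g} {frame.joint_position[2]:.17g}\n")
        fh.write(f"# timestamp {frame.timestamp:.17g}\n")
        for v in frame.vertices:
            fh.write(f"v {v[0]:.17g} {v[1]:.17g} {v[2]:.17g}\n")
        if frame.faces is not None:
            for f in frame.faces:
                fh.write(f"f {f[0]+1} {f[1]+1} {f[2]+1}\n")


def read_hand_frame(path) -> HandMeshFrame:
    """Read an OBJ written by :func:`write_mesh`, restoring joint/timestamp."""
    joint = None
    timestamp = 0.0
    with open(path) as fh:
        for line in fh:
            if line.startswith("# joint "):
                joint = np.array([float(v) for v in line.split()[2:5]])
            elif line.startswith("# timestamp "):
                timestamp = float(line.split()[2])
            elif not line.startswith("#"):
                break
    frame = read_mesh(path, joint_position=joint, timestamp=timestamp)
    return frame


def write_series(series: ContactAttributeSeries, path) -> None:
    path = Path(path)
    series.to_dataframe().to_csv(path, index=False)
    sidecar = {
        "f": series.sampling_rate,
        "units": {"V": "cm/s", "area": "cm^2", "depth": "mm", "t": "s"},
        "duration": series.duration,
        "velocity_valid": series.velocity_valid.astype(int).tolist(),
        "metadata": {k: v for k, v in series.metadata.items()
                     if isinstance(v, (str, int, float, bool, list))},
    }
    for key in ("i_vt", "i_lg", "i_lt"):
        if key in series.metadata:
            sidecar[key] = list(np.asarray(series.metadata[key], float))
    path.with_suffix(".json").write_text(json.dumps(sidecar, indent=1))


def read_series(path) -> ContactAttributeSeries:
    path = Path(path)
    df = pd.read_csv(path)
    missing = [c for c in SERIES_COLUMNS if c not in df.columns]
    if missing:
        raise ParseError(f"{path}: series CSV missing columns {missing}")
    f = 30.0
    meta = {}
    sidecar = path.with_suffix(".json")
    valid = None
    if sidecar.exists():
        info = json.loads(sidecar.read_text())
        f = float(info.get("f", 30.0))
        meta = info.get("metadata", {})
        if "velocity_valid" in info:
            valid = np.asarray(info["velocity_valid"], dtype=bool)
    series = ContactAttributeSeries.from_dataframe(df, sampling_rate=f, **meta)
    if valid is not None:
        series.velocity_valid = valid
    return series


def contact_frames_to_csv(frames, timestamps, path) -> None:
    """Serialize per-frame contact states to the standard CSV row format."""
    rows = []
    for i, (cf, t) in enumerate(zip(frames, timestamps)):
        rows.append({
            "frame_index": i, "timestamp": t, "contact": int(cf.in_contact),
            "depth_mm": cf.depth, "area_cm2": cf.area,
            "n_hand_contacts": cf.n_hand_contacts,
            "n_arm_contacts": cf.n_arm_contacts,
        })
    pd.DataFrame(rows).to_csv(path, index=False)


_CONFIG_TYPES = {"gesture": GestureConfig, "segmentation": SegmentationConfig}


def write_config(config, path) -> None:
    path = Path(path)
    kind = "gesture" if isinstance(config, GestureConfig) else "segmentation"
    payload = {"kind": kind, **dataclasses.asdict(config)}
    path.write_text(yaml.safe_dump(payload, sort_keys=False))


def read_config(path):
    path = Path(path)
    payload = yaml.safe_load(path.read_text())
    if not isinstance(payload, dict) or "kind" not in payload:
        raise ParseError(f"{path}: config must be a mapping with a 'kind' key")
    kind = payload.pop("kind")
    cls = _CONFIG_TYPES.get(kind)
    if cls is None:
        raise ParseError(f"{path}: unknown config kind {kind!r}")
    fields = {f.name for f in dataclasses.fields(cls)}
    unknown = set(payload) - fields
    if unknown:
        raise ParseError(f"{path}: unknown config keys {sorted(unknown)}")
    def _tuplify(v):
        return tuple(_tuplify(x) for x in v) if isinstance(v, list) else v
    return cls(**{k: _tuplify(v) for k, v in payload.items()})


def save_trial(trial: SyntheticTrial, directory) -> None:
    """Write a trial directory: arm.ply, hand_%04d.obj, truth.csv, config.yaml."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    write_cloud(trial.arm.cloud, directory / "arm.ply")
    if trial.arm.marker_anchor is not None:
        (directory / "arm_marker.json").write_text(
            json.dumps({"marker_anchor": list(trial.arm.marker_anchor)})
        )
    for i, frame in enumerate(trial.hand_frames):
        write_mesh(frame, directory / f"hand_{i:04d}.obj")
    trial.truth.to_csv(directory / "truth.csv", index=False)
    if trial.config is not None:
        write_config(trial.config, directory / "config.yaml")


def load_trial(directory) -> SyntheticTrial:
    directory = Path(directory)
    cloud = read_cloud(directory / "arm.ply")
    anchor = None
    marker_file = directory / "arm_marker.json"
    if marker_file.exists():
        anchor = np.array(json.loads(marker_file.read_text())["marker_anchor"])
    arm = ArmSurface.from_cloud(cloud, marker_anchor=anchor)
    frames = [read_hand_frame(p) for p in sorted(directory.glob("hand_*.obj"))]
    truth = pd.read_csv(directory / "truth.csv")
    config = None
    cfg_file = directory / "config.yaml"
    if cfg_file.exists():
        config = read_config(cfg_file)
    return SyntheticTrial(arm=arm, hand_frames=frames, truth=truth, config=config)
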