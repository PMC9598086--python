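"""Readers/writers for point-cloud interchange formats and flat-file
persistence of an assemblage store.

Point clouds: PLY (ascii and binary little-endian, vertex elements only),
OBJ (``v`` lines only) and whitespace-separated XYZ. Store persistence is
flat CSV (marks, specimens) plus JSON (templates, crop masks); numeric CSV
fields are written with 9 significant digits.
"""

from __future__ import annotations

import json
import struct
from pathlib import Path

import numpy as np
import pandas as pd

from .core import AssemblageStore, BoneTemplate, MarkRecord, SpecimenRecord
from .errors import ValidationError

MARKS_COLUMNS = [
    "mark_id", "specimen_id", "template_id", "mark_type",
    "x", "y", "z", "x1", "y1", "z1", "x2", "y2", "z2",
]
SPECIMENS_COLUMNS = [
    "specimen_id", "site", "taxon", "element", "side",
    "size_class", "age", "fracture_state", "shaft_circumference_type",
]

_PLY_DTYPES = {
    "float": ("f", 4), "float32": ("f", 4),
    "double": ("d", 8), "float64": ("d", 8),
    "uchar": ("B", 1), "uint8": ("B", 1), "char": ("b", 1), "int8": ("b", 1),
    "short": ("h", 2), "int16": ("h", 2), "ushort": ("H", 2), "uint16": ("H", 2),
    "int": ("i", 4), "int32": ("i", 4), "uint": ("I", 4), "uint32": ("I", 4),
}


# ---------------------------------------------------------------------------
# point clouds
# ---------------------------------------------------------------------------

def read_point_cloud(path: str | Path) -> np.ndarray:
    """Dispatch on file extension; returns an (n, 3) float64 array."""
    path = Path(path)
    suffix = path.suffix.lower()
    if suffix == ".ply":
        return read_ply(path)
    if suffix == ".obj":
        return read_obj(path)
    if suffix in (".xyz", ".txt", ".pts"):
        return read_xyz(path)
    raise ValidationError(f"unsupported point cloud format {suffix!r}")


def read_ply(path: str | Path) -> np.ndarray:
    with open(path, "rb") as fh:
        magic = fh.readline().strip()
        if magic != b"ply":
            raise ValidationError(f"{path}: not a PLY file")
        fmt = None
        n_vertex = 0
        props: list[tuple[str, str]] = []
        in_vertex = False
        while True:
            line = fh.readline()
            if not line:
                raise ValidationError(f"{path}: truncated PLY header")
            tokens = line.decode("ascii", "replace").split()
            if not tokens:
                continue
            if tokens[0] == "format":
                fmt = tokens[1]
            elif tokens[0] == "element":
                in_vertex = tokens[1] == "vertex"
                if in_vertex:
                    n_vertex = int(tokens[2])
            elif tokens[0] == "property" and in_vertex:
                props.append((tokens[1], tokens[2]))
            elif tokens[0] == "end_header":
                break
        names = [p[1] for p in props]
        for axis in "xyz":
            if axis not in names:
                raise ValidationError(f"{path}: vertex property {axis!r} missing")
        if fmt == "ascii":
            rows = []
            for _ in range(n_vertex):
                rows.append([float(v) for v in fh.readline().split()])
            data = np.asarray(rows, dtype=np.float64)
        elif fmt in ("binary_little_endian", "binary_big_endian"):
            endian = "<" if fmt == "binary_little_endian" else ">"
            codes = "".join(_PLY_DTYPES[t][0] for t, _ in props)
            rec = struct.Struct(endian + codes)
            raw = fh.read(rec.size * n_vertex)
            data = np.asarray(
                [rec.unpack_from(raw, i * rec.size) for i in range(n_vertex)],
                dtype=np.float64,
            )
        else:
            raise ValidationError(f"{path}: unsupported PLY format {fmt!r}")
    idx = [names.index(a) for a in "xyz"]
    return data[:, idx]


def write_ply(
    path: str | Path,
    points: np.ndarray,
    *,
    binary: bool = False,
    scalar: np.ndarray | None = None,
    scalar_name: str = "quality",
) -> None:
    """Write a vertex-only PLY, optionally with one per-vertex scalar."""
    points = np.asarray(points, dtype=np.float64).reshape(-1, 3)
    header = ["ply"]
    header.append("format binary_little_endian 1.0" if binary else "format ascii 1.0")
    header.append(f"element vertex {len(points)}")
    header += ["property double x", "property double y", "property double z"]
    if scalar is not None:
        scalar = np.asarray(scalar, dtype=np.float64).reshape(-1)
        if len(scalar) != len(points):
            raise ValidationError("scalar length must match point count")
        header.append(f"property double {scalar_name}")
    header.append("end_header")
    cols = points if scalar is None else np.column_stack([points, scalar])
    if binary:
        with open(path, "wb") as fh:
            fh.write(("\n".join(header) + "\n").encode("ascii"))
            fh.write(cols.astype("<f8").tobytes())
    else:
        with open(path, "w") as fh:
            fh.write("\n".join(header) + "\n")
            for row in cols:
                fh.write(" ".join(f"{v:.9g}" for v in row) + "\n")


def read_obj(path: str | Path) -> np.ndarray:
    rows = []
    with open(path) as fh:
        for line in fh:
            if line.startswith("v "):
                parts = line.split()
                rows.append([float(parts[1]), float(parts[2]), float(parts[3])])
    if not rows:
        raise ValidationError(f"{path}: no vertices found")
    return np.asarray(rows, dtype=np.float64)


def write_obj(path: str | Path, points: np.ndarray) -> None:
    with open(path, "w") as fh:
        for x, y, z in np.asarray(points, dtype=np.float64).reshape(-1, 3):
            fh.write(f"v {x:.9g} {y:.9g} {z:.9g}\n")


def read_xyz(path: str | Path) -> np.ndarray:
    data = np.loadtxt(path, dtype=np.float64, ndmin=2)
    if data.shape[1] < 3:
        raise ValidationError(f"{path}: expected >= 3 columns")
    return data[:, :3]


def write_xyz(path: str | Path, points: np.ndarray) -> None:
    np.savetxt(path, np.asarray(points).reshape(-1, 3), fmt="%.9g")


# ---------------------------------------------------------------------------
# store persistence
# ---------------------------------------------------------------------------

def marks_to_frame(store: AssemblageStore) -> pd.DataFrame:
    rows = []
    for mark in sorted(store.marks.values(), key=lambda m: m.mark_id):
        row = {
            "mark_id": mark.mark_id,
            "specimen_id": mark.specimen_id,
            "template_id": mark.template_id,
            "mark_type": mark.mark_type,
            "x": mark.position[0], "y": mark.position[1], "z": mark.position[2],
        }
        if mark.endpoints is not None:
            (row["x1"], row["y1"], row["z1"]), (row["x2"], row["y2"], row["z2"]) = (
                mark.endpoints[0], mark.endpoints[1])
        rows.append(row)
    return pd.DataFrame(rows, columns=MARKS_COLUMNS)


def save_store(store: AssemblageStore, directory: str | Path) -> None:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    marks_to_frame(store).to_csv(
        directory / "marks.csv", index=False, float_format="%.9g"
    )
    spec_rows = [
        {c: getattr(s, c) for c in SPECIMENS_COLUMNS} | {"template_id": s.template_id}
        for s in sorted(store.specimens.values(), key=lambda s: s.specimen_id)
    ]
    pd.DataFrame(spec_rows, columns=SPECIMENS_COLUMNS + ["template_id"]).to_csv(
        directory / "specimens.csv", index=False
    )
    templates = {
        tid: {
            "template_id": t.template_id,
            "element": t.element,
            "side": t.side,
            "size_class": t.size_class,
            "length": t.length,
            "points": t.points.tolist(),
        }
        for tid, t in store.templates.items()
    }
    (directory / "templates.json").write_text(json.dumps(templates))
    crops = {
        sid: {
            "specimen_id": m.specimen_id,
            "template_id": m.template_id,
            "retained": np.asarray(m.retained, dtype=bool).astype(int).tolist(),
        }
        for sid, m in store.crop_masks.items()
    }
    (directory / "crops.json").write_text(json.dumps(crops))


def load_store(directory: str | Path) -> AssemblageStore:
    from .survivorship import CropMask

    directory = Path(directory)
    store = AssemblageStore()
    templates = json.loads((directory / "templates.json").read_text())
    for tid, t in templates.items():
        store.templates[tid] = BoneTemplate(
            template_id=t["template_id"],
            element=t["element"],
            side=t["side"],
            size_class=int(t["size_class"]),
            points=np.asarray(t["points"], dtype=np.float64),
            length=float(t["length"]),
        )
    spec_df = pd.read_csv(directory / "specimens.csv", dtype={"specimen_id": str})
    for _, row in spec_df.iterrows():
        store.specimens[row["specimen_id"]] = SpecimenRecord(
            specimen_id=row["specimen_id"],
            site=str(row["site"]),
            taxon=str(row["taxon"]),
            element=row["element"],
            side=row["side"],
            size_class=int(row["size_class"]),
            age=str(row["age"]),
            fracture_state=str(row["fracture_state"]),
            shaft_circumference_type=str(row["shaft_circumference_type"]),
            template_id=None if pd.isna(row.get("template_id")) else str(row["template_id"]),
        )
    marks_df = pd.read_csv(directory / "marks.csv", dtype={"mark_id": str})
    max_counter = 0
    for _, row in marks_df.iterrows():
        endpoints = None
        if not pd.isna(row["x1"]):
            endpoints = np.array(
                [[row["x1"], row["y1"], row["z1"]], [row["x2"], row["y2"], row["z2"]]]
            )
        mark = MarkRecord(
            mark_id=row["mark_id"],
            specimen_id=row["specimen_id"],
            template_id=row["template_id"],
            mark_type=row["mark_type"],
            position=np.array([row["x"], row["y"], row["z"]]),
            endpoints=endpoints,
        )
        store.marks[mark.mark_id] = mark
        if mark.mark_id.startswith("M"):
            max_counter = max(max_counter, int(mark.mark_id[1:]))
    store._mark_counter = max_counter
    crops_path = directory / "crops.json"
    if crops_path.exists():
        for sid, c in json.loads(crops_path.read_text()).items():
            store.crop_masks[sid] = CropMask(
                specimen_id=c["specimen_id"],
                template_id=c["template_id"],
                retained=np.asarray(c["retained"], dtype=bool),
            )
    return store
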