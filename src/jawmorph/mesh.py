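"""Labelled tetrahedral mesh container and legacy-VTK serialisation.

The mesh is the common currency of the package: the synthetic rudiment
generator produces one, the elasticity solver consumes one, and
morphogenesis deforms one.  Regions are the four tissue labels of the
larval lower jaw assembly: Meckel's cartilage (MC), palatoquadrate (PQ),
ceratohyal (CH) and the soft interzone bridging MC and PQ.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

REGION_IDS = {"MC": 1, "PQ": 2, "CH": 3, "interzone": 4}
REGION_NAMES = {v: k for k, v in REGION_IDS.items()}

#: anatomical axis names in canonical storage order
AXIS_ORDER = ("AP", "ML", "VD")


@dataclass(frozen=True)
class AnatomicalFrame:
    """Right-handed orthonormal anatomical frame.

    ``ap`` points anteriorly, ``ml`` laterally, ``vd`` dorsally.  The
    default frame is the world frame (x=AP, y=ML, z=VD); meshes that have
    been rigidly moved carry the rotated frame with them.
    """

    ap: np.ndarray
    ml: np.ndarray
    vd: np.ndarray

    def __post_init__(self):
        for name in ("ap", "ml", "vd"):
            object.__setattr__(self, name, np.asarray(getattr(self, name), float))
        M = self.matrix()
        if not np.allclose(M @ M.T, np.eye(3), atol=1e-10):
            raise ValueError("anatomical frame axes must be orthonormal")

    def matrix(self) -> np.ndarray:
        """Rows are the AP, ML, VD axis vectors (world coordinates)."""
        return np.stack([self.ap, self.ml, self.vd])

    def axis(self, label: str) -> np.ndarray:
        return {"AP": self.ap, "ML": self.ml, "VD": self.vd}[label]

    def rotated(self, R: np.ndarray) -> "AnatomicalFrame":
        return AnatomicalFrame(R @ self.ap, R @ self.ml, R @ self.vd)


CANONICAL_FRAME = AnatomicalFrame(
    ap=np.array([1.0, 0.0, 0.0]),
    ml=np.array([0.0, 1.0, 0.0]),
    vd=np.array([0.0, 0.0, 1.0]),
)


@dataclass
class LabelledTetMesh:
    """Linear (4-node) tetrahedral mesh with per-element tissue labels.

    ``points`` are node coordinates in micrometres, ``cells`` the (M, 4)
    connectivity, ``region`` the per-element integer label (values of
    :data:`REGION_IDS`).  ``landmarks`` holds the joint-line centre and the
    retroarticular process; ``attachments`` the four muscle insertion
    points.  Both are coordinates, not node indices, so they deform with
    the mesh through explicit updates.
    """

    points: np.ndarray
    cells: np.ndarray
    region: np.ndarray
    landmarks: dict = field(default_factory=dict)
    attachments: dict = field(default_factory=dict)
    frame: AnatomicalFrame = field(default_factory=lambda: CANONICAL_FRAME)

    def __post_init__(self):
        self.points = np.asarray(self.points, float)
        self.cells = np.asarray(self.cells, np.int64)
        self.region = np.asarray(self.region, np.int64)
        if self.cells.shape[0] != self.region.shape[0]:
            raise ValueError("one region label per element is required")

    # ------------------------------------------------------------------
    # basic queries
    # ------------------------------------------------------------------
    @property
    def n_points(self) -> int:
        return self.points.shape[0]

    @property
    def n_cells(self) -> int:
        return self.cells.shape[0]

    def cell_volumes(self, points: np.ndarray | None = None) -> np.ndarray:
        """Signed tetrahedron volumes (positive for the stored orientation)."""
        p = self.points if points is None else points
        a, b, c, d = (p[self.cells[:, i]] for i in range(4))
        return np.einsum("ij,ij->i", np.cross(b - a, c - a), d - a) / 6.0

    def volume(self, label: str | None = None) -> float:
        v = self.cell_volumes()
        if label is None:
            return float(np.abs(v).sum())
        return float(np.abs(v[self.region_mask(label)]).sum())

    def region_mask(self, label: str) -> np.ndarray:
        return self.region == REGION_IDS[label]

    def region_nodes(self, label: str) -> np.ndarray:
        """Indices of nodes used by at least one element of ``label``."""
        return np.unique(self.cells[self.region_mask(label)])

    def cell_centroids(self) -> np.ndarray:
        return self.points[self.cells].mean(axis=1)

    def edges(self) -> np.ndarray:
        """Unique undirected node-index pairs (i < j) of all tet edges."""
        c = self.cells
        pairs = np.concatenate(
            [c[:, [0, 1]], c[:, [0, 2]], c[:, [0, 3]],
             c[:, [1, 2]], c[:, [1, 3]], c[:, [2, 3]]]
        )
        pairs = np.sort(pairs, axis=1)
        return np.unique(pairs, axis=0)

    def node_neighbours(self) -> list:
        """Adjacency list of edge-connected node neighbourhoods."""
        e = self.edges()
        adj = [[] for _ in range(self.n_points)]
        for i, j in e:
            adj[i].append(j)
            adj[j].append(i)
        return [np.array(a, np.int64) for a in adj]

    def boundary_triangles(self, label: str | None = None) -> np.ndarray:
        """Triangles on the surface of the mesh (or of one region)."""
        cells = self.cells if label is None else self.cells[self.region_mask(label)]
        faces = np.concatenate(
            [cells[:, [0, 1, 2]], cells[:, [0, 1, 3]],
             cells[:, [0, 2, 3]], cells[:, [1, 2, 3]]]
        )
        key = np.sort(faces, axis=1)
        _, idx, counts = np.unique(key, axis=0, return_index=True, return_counts=True)
        return faces[idx[counts == 1]]

    def with_points(self, points: np.ndarray) -> "LabelledTetMesh":
        """Copy of the mesh with replaced node coordinates."""
        return LabelledTetMesh(
            points=np.asarray(points, float),
            cells=self.cells.copy(),
            region=self.region.copy(),
            landmarks={k: np.array(v, float) for k, v in self.landmarks.items()},
            attachments={k: np.array(v, float) for k, v in self.attachments.items()},
            frame=self.frame,
        )

    def transformed(self, R: np.ndarray, t: np.ndarray) -> "LabelledTetMesh":
        """Rigidly moved copy: x -> R x + t (frame and markers follow)."""
        R = np.asarray(R, float)
        t = np.asarray(t, float)
        out = self.with_points(self.points @ R.T + t)
        out.landmarks = {k: R @ v + t for k, v in self.landmarks.items()}
        out.attachments = {k: R @ v + t for k, v in self.attachments.items()}
        out.frame = self.frame.rotated(R)
        return out

    def nearest_node(self, point) -> int:
        d = np.linalg.norm(self.points - np.asarray(point, float), axis=1)
        return int(np.argmin(d))


# ----------------------------------------------------------------------
# legacy VTK unstructured-grid I/O (ASCII)
# ----------------------------------------------------------------------

def write_vtk(mesh: LabelledTetMesh, path) -> None:
    """Write the mesh as a legacy ASCII VTK unstructured grid.

    The per-element label is stored as CELL_DATA scalars named ``region``;
    landmarks, attachment points and the anatomical frame go into a FIELD
    block so a round trip through :func:`read_vtk` is lossless.
    """
    path = Path(path)
    lines = ["# vtk DataFile Version 3.0", "jawmorph labelled tet mesh",
             "ASCII", "DATASET UNSTRUCTURED_GRID"]
    lines.append(f"POINTS {mesh.n_points} double")
    lines += [" ".join(f"{x:.10g}" for x in p) for p in mesh.points]
    lines.append(f"CELLS {mesh.n_cells} {5 * mesh.n_cells}")
    lines += ["4 " + " ".join(str(i) for i in c) for c in mesh.cells]
    lines.append(f"CELL_TYPES {mesh.n_cells}")
    lines += ["10"] * mesh.n_cells
    lines.append(f"CELL_DATA {mesh.n_cells}")
    lines.append("SCALARS region int 1")
    lines.append("LOOKUP_TABLE default")
    lines += [str(r) for r in mesh.region]

    extra = {f"landmark_{k}": v for k, v in mesh.landmarks.items()}
    extra.update({f"attachment_{k}": v for k, v in mesh.attachments.items()})
    extra["frame_AP"] = mesh.frame.ap
    extra["frame_ML"] = mesh.frame.ml
    extra["frame_VD"] = mesh.frame.vd
    lines.append(f"FIELD meta {len(extra)}")
    for name, vec in extra.items():
        lines.append(f"{name} 3 1 double")
        lines.append(" ".join(f"{x:.10g}" for x in vec))
    path.write_text("\n".join(lines) + "\n")


def read_vtk(path) -> LabelledTetMesh:
    """Read a mesh previously written by :func:`write_vtk`."""
    tokens = Path(path).read_text().split("\n")
    it = iter(tokens)
    points = cells = region = None
    landmarks, attachments = {}, {}
    frame_vecs = {}
    line = next(it)
    try:
        while True:
            parts = line.split()
            if not parts:
                line = next(it)
                continue
            kw = parts[0].upper()
            if kw == "POINTS":
                n = int(parts[1])
                vals = []
                while len(vals) < 3 * n:
                    line = next(it)
                    vals += [float(x) for x in line.split()]
                points = np.array(vals).reshape(n, 3)
            elif kw == "CELLS":
                n = int(parts[1])
                vals = []
                while len(vals) < 5 * n:
                    line = next(it)
                    vals += [int(x) for x in line.split()]
                cells = np.array(vals).reshape(n, 5)[:, 1:]
            elif kw == "SCALARS" and parts[1] == "region":
                next(it)  # LOOKUP_TABLE
                vals = []
                while len(vals) < cells.shape[0]:
                    line = next(it)
                    vals += [int(x) for x in line.split()]
                region = np.array(vals)
            elif kw == "FIELD":
                n_arrays = int(parts[2])
                for _ in range(n_arrays):
                    header = next(it).split()
                    name = header[0]
                    vec = np.array([float(x) for x in next(it).split()])
                    if name.startswith("landmark_"):
                        landmarks[name[len("landmark_"):]] = vec
                    elif name.startswith("attachment_"):
                        attachments[name[len("attachment_"):]] = vec
                    elif name.startswith("frame_"):
                        frame_vecs[name[len("frame_"):]] = vec
            line = next(it)
    except StopIteration:
        pass
    if points is None or cells is None or region is None:
        raise ValueError(f"{path}: not a jawmorph VTK mesh")
    frame = CANONICAL_FRAME
    if frame_vecs:
        frame = AnatomicalFrame(frame_vecs["AP"], frame_vecs["ML"], frame_vecs["VD"])
    return LabelledTetMesh(points, cells, region, landmarks, attachments, frame)


def write_point_data_vtk(mesh: LabelledTetMesh, fields: dict, path) -> None:
    """Write the mesh plus named per-node scalar fields (POINT_DATA)."""
    write_vtk(mesh, path)
    lines = [f"POINT_DATA {mesh.n_points}"]
    for name, values in fields.items():
        values = np.asarray(values, float)
        lines.append(f"SCALARS {name} double 1")
        lines.append("LOOKUP_TABLE default")
        lines += [f"{v:.10g}" for v in values]
    with open(path, "a") as fh:
        fh.write("\n".join(lines) + "\n")
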