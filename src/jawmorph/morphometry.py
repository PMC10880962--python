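"""Landmark alignment, average shapes and organ-level jaw measurements.

Measurements follow the study conventions for the Meckel's cartilage:
length is the anteroposterior extent, depth the ventrodorsal extent, and
width the widest mediolateral extent within a thin slab at the level of
the joint line.  All half-jaw shapes are first aligned so the joint line
sits at the origin and the anatomical axes coincide with the canonical
frame (x=AP, y=ML, z=VD).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import config
from .mesh import AnatomicalFrame, CANONICAL_FRAME, LabelledTetMesh

#: canonical joint-line -> retroarticular unit direction (AP-VD plane);
#: used to recover orientation when a shape carries no anatomical frame
CANONICAL_RETRO_DIRECTION = np.array([0.3, 0.0, -np.sqrt(1 - 0.09)])


@dataclass
class Morphometrics:
    """Organ-level MC measurements (μm)."""

    length: float
    depth: float
    width: float

    def as_array(self) -> np.ndarray:
        return np.array([self.length, self.depth, self.width])


@dataclass
class ShapeStack:
    """Ordered transversal slices of a half-jaw outline.

    Each slice is a closed outline (P, 2) in in-plane (ML, VD) coordinates
    at a stated anteroposterior position.  Slice positions must be
    strictly increasing.
    """

    positions: np.ndarray                  # (S,)
    outlines: list                         # S arrays (P_s, 2)
    frame: AnatomicalFrame = field(default_factory=lambda: CANONICAL_FRAME)

    def __post_init__(self):
        self.positions = np.asarray(self.positions, float)
        if len(self.positions) != len(self.outlines):
            raise ValueError("one outline per slice position")
        if len(self.positions) > 1 and not np.all(np.diff(self.positions) > 0):
            raise ValueError("slice positions must be strictly increasing")
        self.outlines = [np.asarray(o, float) for o in self.outlines]

    def __len__(self):
        return len(self.positions)

    def to_csv(self, path) -> None:
        rows = []
        for s, (pos, o) in enumerate(zip(self.positions, self.outlines)):
            for p, (u, v) in enumerate(o):
                rows.append((s, pos, p, u, v))
        pd.DataFrame(rows, columns=["slice_index", "axial_pos",
                                    "point_index", "u", "v"]).to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "ShapeStack":
        df = pd.read_csv(path)
        positions, outlines = [], []
        for s, grp in df.groupby("slice_index"):
            grp = grp.sort_values("point_index")
            positions.append(grp["axial_pos"].iloc[0])
            outlines.append(grp[["u", "v"]].to_numpy())
        return cls(np.array(positions), outlines)


# ----------------------------------------------------------------------
# alignment
# ----------------------------------------------------------------------

@dataclass
class RigidTransform:
    """x -> R x + t."""

    R: np.ndarray
    t: np.ndarray

    def apply(self, points: np.ndarray) -> np.ndarray:
        return np.atleast_2d(points) @ self.R.T + self.t

    def inverse(self) -> "RigidTransform":
        return RigidTransform(self.R.T, -self.R.T @ self.t)


def _rotation_between(u: np.ndarray, v: np.ndarray) -> np.ndarray:
    """Minimal rotation taking unit vector u onto unit vector v."""
    c = float(np.dot(u, v))
    axis = np.cross(u, v)
    s = np.linalg.norm(axis)
    if s < 1e-12:
        if c > 0:
            return np.eye(3)
        # antiparallel: rotate pi about any perpendicular axis
        perp = np.eye(3)[np.argmin(np.abs(u))]
        axis = np.cross(u, perp)
        axis /= np.linalg.norm(axis)
        K = np.array([[0, -axis[2], axis[1]],
                      [axis[2], 0, -axis[0]],
                      [-axis[1], axis[0], 0]])
        return np.eye(3) + 2 * K @ K
    axis /= s
    K = np.array([[0, -axis[2], axis[1]],
                  [axis[2], 0, -axis[0]],
                  [-axis[1], axis[0], 0]])
    return np.eye(3) + s * K + (1 - c) * K @ K


def align_to_landmarks(shape, joint_line, retroarticular,
                       frame: AnatomicalFrame | None = None):
    """Rigidly align a shape by its joint-line and retroarticular landmarks.

    Returns ``(transform, aligned_shape)``.  The joint line moves to the
    origin.  If the shape (or the ``frame`` argument) carries an anatomical
    frame, the frame axes are rotated onto the canonical axes — a full
    rigid registration.  Without a frame, the joint -> retroarticular
    direction is rotated onto its canonical direction in the AP-VD plane
    (a minimal rotation; roll about that direction is unresolved, which is
    adequate for rotations about the ML axis).
    """
    joint_line = np.asarray(joint_line, float)
    retroarticular = np.asarray(retroarticular, float)
    d = retroarticular - joint_line
    n = np.linalg.norm(d)
    if n < 1e-9:
        raise ValueError("joint-line and retroarticular landmarks coincide")

    if frame is None and isinstance(shape, LabelledTetMesh):
        frame = shape.frame
    if frame is not None:
        R = frame.matrix()          # rows AP, ML, VD -> canonical axes
        # reorder rows to canonical (x=AP, y=ML, z=VD) storage
        R = np.stack([frame.ap, frame.ml, frame.vd])
    else:
        R = _rotation_between(d / n, CANONICAL_RETRO_DIRECTION)
    t = -R @ joint_line
    tf = RigidTransform(R, t)

    if isinstance(shape, LabelledTetMesh):
        aligned = shape.transformed(R, t)
    elif isinstance(shape, np.ndarray):
        aligned = tf.apply(shape)
    else:
        raise TypeError("shape must be a LabelledTetMesh or point array")
    return tf, aligned


# ----------------------------------------------------------------------
# outlines and average shapes
# ----------------------------------------------------------------------

def resample_outline(outline: np.ndarray, n_points: int) -> np.ndarray:
    """Resample a closed outline to n_points, uniform in arc length.

    The outline is oriented counter-clockwise and the start point placed
    where the polar angle about the slice centroid crosses zero, giving
    angular point correspondence between shapes.
    """
    o = np.asarray(outline, float)
    if np.allclose(o[0], o[-1]):
        o = o[:-1]
    if len(o) < 3:
        raise ValueError("outline needs at least 3 distinct points")
    # counter-clockwise by signed area
    x, y = o[:, 0], o[:, 1]
    area = 0.5 * np.sum(x * np.roll(y, -1) - np.roll(x, -1) * y)
    if area < 0:
        o = o[::-1]
    centroid = o.mean(axis=0)
    rel = o - centroid
    theta = np.mod(np.arctan2(rel[:, 1], rel[:, 0]), 2 * np.pi)
    # find the CCW edge on which the angle wraps through zero
    wrap = np.nonzero(theta > np.roll(theta, -1))[0]
    k = int(wrap[0]) if len(wrap) else 0
    t0, t1 = theta[k], np.roll(theta, -1)[k] + 2 * np.pi
    s = (2 * np.pi - t0) / (t1 - t0) if t1 > t0 else 0.0
    start = o[k] + s * (o[(k + 1) % len(o)] - o[k])
    o = np.vstack([start, np.roll(o, -(k + 1), axis=0)])
    seg = np.linalg.norm(np.diff(np.vstack([o, o[:1]]), axis=0), axis=1)
    cum = np.concatenate([[0.0], np.cumsum(seg)])
    total = cum[-1]
    targets = np.linspace(0.0, total, n_points, endpoint=False)
    closed = np.vstack([o, o[:1]])
    out = np.empty((n_points, 2))
    out[:, 0] = np.interp(targets, cum, closed[:, 0])
    out[:, 1] = np.interp(targets, cum, closed[:, 1])
    return out


def _outline_at(stack: ShapeStack, pos: float, n_points: int) -> np.ndarray:
    """Resampled outline at an axial position (linear between slices)."""
    p = stack.positions
    if pos <= p[0]:
        return resample_outline(stack.outlines[0], n_points)
    if pos >= p[-1]:
        return resample_outline(stack.outlines[-1], n_points)
    j = int(np.searchsorted(p, pos))
    a = resample_outline(stack.outlines[j - 1], n_points)
    b = resample_outline(stack.outlines[j], n_points)
    w = (pos - p[j - 1]) / (p[j] - p[j - 1])
    return (1 - w) * a + w * b


def average_shape(shapes: list, n_slices: int = 20,
                  n_points: int = 100) -> ShapeStack:
    """Pointwise average of aligned shape stacks.

    Slices are taken over the common axial range; per slice, each outline
    is resampled to ``n_points`` with angular correspondence from the
    slice centroid and the corresponding points averaged.
    """
    if len(shapes) < 2:
        raise ValueError("need at least two shapes to average")
    lo = max(s.positions[0] for s in shapes)
    hi = min(s.positions[-1] for s in shapes)
    if hi <= lo:
        raise ValueError("shapes have no overlapping axial range")
    positions = np.linspace(lo, hi, n_slices)
    outlines = []
    for pos in positions:
        per_shape = [_outline_at(s, pos, n_points) for s in shapes]
        outlines.append(np.mean(per_shape, axis=0))
    return ShapeStack(positions, outlines, frame=shapes[0].frame)


def shape_stack_from_mesh(mesh: LabelledTetMesh, region: str = "MC",
                          n_slices: int = 30) -> ShapeStack:
    """Transversal slice outlines of a region's boundary surface."""
    import trimesh

    tris = mesh.boundary_triangles(region)
    tm = trimesh.Trimesh(vertices=mesh.points, faces=tris, process=False)
    nodes = mesh.points[mesh.region_nodes(region)]
    x0, x1 = nodes[:, 0].min(), nodes[:, 0].max()
    eps = 1e-3 * (x1 - x0)
    positions, outlines = [], []
    for pos in np.linspace(x0 + eps, x1 - eps, n_slices):
        sec = tm.section(plane_origin=[pos, 0, 0], plane_normal=[1, 0, 0])
        if sec is None:
            continue
        planar, _ = sec.to_2D()
        polys = planar.polygons_closed
        polys = [p for p in polys if p is not None]
        if not polys:
            continue
        poly = max(polys, key=lambda p: p.area)
        # to_2D for an x-normal plane maps (y, z) into the plane frame;
        # recover world (y, z) from the 3D section vertices instead
        loops = sec.discrete
        loop = max(loops, key=lambda l: len(l))
        outlines.append(np.asarray(loop)[:, 1:3])
        positions.append(pos)
    return ShapeStack(np.array(positions), outlines, frame=mesh.frame)


# ----------------------------------------------------------------------
# measurements
# ----------------------------------------------------------------------

def crop_anteroposterior(shape, distance: float):
    """Keep only material within ``distance`` of the joint line along AP."""
    if distance <= 0:
        raise ValueError("crop distance must be positive")
    if isinstance(shape, LabelledTetMesh):
        keep = shape.cell_centroids()[:, 0] <= distance
        cells = shape.cells[keep]
        used, inv = np.unique(cells, return_inverse=True)
        out = LabelledTetMesh(points=shape.points[used],
                              cells=inv.reshape(cells.shape),
                              region=shape.region[keep],
                              landmarks=dict(shape.landmarks),
                              attachments=dict(shape.attachments),
                              frame=shape.frame)
        return out
    if isinstance(shape, ShapeStack):
        keep = shape.positions <= distance
        if not keep.any():
            raise ValueError("crop removes the whole shape")
        return ShapeStack(shape.positions[keep],
                          [o for o, k in zip(shape.outlines, keep) if k],
                          frame=shape.frame)
    raise TypeError("shape must be a LabelledTetMesh or ShapeStack")


def measure_morphometrics(shape, joint_slab: float = config.JOINT_SLAB_UM,
                          region: str = "MC",
                          joint_position: float = 0.0) -> Morphometrics:
    """MC length / depth / width of an aligned shape.

    Width is the widest mediolateral extent among slices within
    ``joint_slab`` μm of the joint line.
    """
    if isinstance(shape, LabelledTetMesh):
        idx = shape.region_nodes(region) if shape.region_mask(region).any() \
            else np.arange(shape.n_points)
        pts = shape.points[idx]
        if pts.size == 0:
            raise ValueError("empty shape")
        length = pts[:, 0].max() - pts[:, 0].min()
        depth = pts[:, 2].max() - pts[:, 2].min()
        slab = np.abs(pts[:, 0] - joint_position) <= joint_slab
        if not slab.any():
            slab = pts[:, 0] <= pts[:, 0].min() + joint_slab
        width = pts[slab, 1].max() - pts[slab, 1].min()
        return Morphometrics(float(length), float(depth), float(width))
    if isinstance(shape, ShapeStack):
        if len(shape) == 0:
            raise ValueError("empty shape")
        length = shape.positions[-1] - shape.positions[0]
        vd = [(o[:, 1].min(), o[:, 1].max()) for o in shape.outlines]
        depth = max(v[1] for v in vd) - min(v[0] for v in vd)
        width = 0.0
        for pos, o in zip(shape.positions, shape.outlines):
            if abs(pos - joint_position) <= joint_slab:
                width = max(width, o[:, 0].max() - o[:, 0].min())
        return Morphometrics(float(length), float(depth), float(width))
    raise TypeError("shape must be a LabelledTetMesh or ShapeStack")


def percent_change(before: Morphometrics, after: Morphometrics) -> np.ndarray:
    """Signed percent changes (length, depth, width)."""
    b, a = before.as_array(), after.as_array()
    if np.any(b <= 0):
        raise ValueError("baseline measurements must be positive")
    return 100.0 * (a - b) / b
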