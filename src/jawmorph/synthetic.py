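"""Synthetic larval-jaw rudiment: geometry, meshing and ground-truth growth.

Everything the real study obtained from confocal imaging is generated
here: a labelled tetrahedral mesh of the half-jaw assembly (Meckel's
cartilage, palatoquadrate, ceratohyal, interzone), chondrocyte centroids
inside the MC, and tracked centroid pairs advected by a known ("ground
truth") deformation field.  The ground-truth fields for the free-to-move
and immobilised conditions are calibrated numerically so that integrating
them over the 24 h study period reproduces the configured organ-level
percent changes of MC length, depth and width.

Geometry is a parametric solid, not a reconstruction: a tapered, gently
curved rod with a spherical joint head for the MC, a block for the PQ, a
compliant interzone filling the joint gap, and a CH anchor bar providing
the fixed boundary.  The joint line sits at the origin of the canonical
anatomical frame (x = anteroposterior, y = mediolateral, z = ventrodorsal).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import connected_components

from . import config
from .mesh import AnatomicalFrame, CANONICAL_FRAME, LabelledTetMesh, REGION_IDS


class MeshingError(RuntimeError):
    """Raised when a rudiment specification cannot be meshed."""


# ----------------------------------------------------------------------
# rudiment specification
# ----------------------------------------------------------------------

#: ventral dip of the MC axis at the anterior tip (μm); gives the rod its
#: gentle curvature
_MC_CURVE_DIP = 3.0
#: CH anchor bar half-width and length (μm)
_CH_HALF_WIDTH = 5.0
_CH_LENGTH = 18.0
#: interzone radius as a fraction of the joint head radius
_INTERZONE_RADIUS_FRACTION = 0.8
#: PQ block half-extent as a fraction of the joint head radius
_PQ_HALF_FRACTION = 0.85


def _default_radius_profile(mc_length: float) -> Callable[[np.ndarray], np.ndarray]:
    def profile(x):
        return 12.0 - 4.0 * np.clip(np.asarray(x, float) / mc_length, 0.0, 1.0)
    return profile


@dataclass(frozen=True)
class RudimentSpec:
    """Parametric description of the synthetic half-jaw assembly (μm)."""

    mc_length: float = 90.0
    joint_head_radius: float = 14.0
    interzone_gap: float = 4.0
    pq_length: float = 50.0
    ch_anchor_offset: tuple = (-39.0, 0.0, -10.0)
    target_edge_length: float = 3.0
    mc_radius_profile: Callable | None = None
    frame: AnatomicalFrame = field(default_factory=lambda: CANONICAL_FRAME)

    def __post_init__(self):
        for name in ("mc_length", "joint_head_radius", "interzone_gap",
                     "pq_length", "target_edge_length"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.interzone_gap >= self.joint_head_radius:
            raise ValueError("interzone_gap must be smaller than joint_head_radius")

    def radius(self, x) -> np.ndarray:
        prof = self.mc_radius_profile or _default_radius_profile(self.mc_length)
        return np.asarray(prof(x), float)

    def axis_dip(self, x) -> np.ndarray:
        """Ventral offset of the MC rod axis at AP position ``x``."""
        t = np.clip(np.asarray(x, float) / self.mc_length, 0.0, 1.0)
        return -_MC_CURVE_DIP * t**2


# ----------------------------------------------------------------------
# point-membership of the parametric solid
# ----------------------------------------------------------------------

def region_of_points(spec: RudimentSpec, pts: np.ndarray) -> np.ndarray:
    """Region id (0 = outside) for each query point, canonical frame."""
    pts = np.atleast_2d(np.asarray(pts, float))
    x, y, z = pts[:, 0], pts[:, 1], pts[:, 2]
    rh = spec.joint_head_radius
    out = np.zeros(len(pts), np.int64)

    # MC: hemispherical joint head (flat articular face at the joint plane
    # x = 0, facing the PQ) plus a tapered, gently curved rod
    head = (x >= 0) & (x**2 + y**2 + z**2 <= rh**2)
    rod_r = spec.radius(x)
    rod = (x >= 0) & (x <= spec.mc_length) & (
        y**2 + (z - spec.axis_dip(x)) ** 2 <= rod_r**2
    )
    mc = head | rod

    # PQ: block posterior of the interzone
    half = _PQ_HALF_FRACTION * rh
    pq = (
        (x >= -spec.interzone_gap - spec.pq_length)
        & (x <= -spec.interzone_gap)
        & (np.abs(y) <= half)
        & (np.abs(z) <= half)
    )

    # CH: anchor bar hanging from the PQ ventral face
    cx, cy, cz = spec.ch_anchor_offset
    ch = (
        (np.abs(x - cx) <= _CH_HALF_WIDTH)
        & (np.abs(y - cy) <= _CH_HALF_WIDTH)
        & (z <= cz)
        & (z >= cz - _CH_LENGTH)
    )

    # interzone: cylindrical slab bridging the PQ face and the flat MC
    # articular face
    iz_r = _INTERZONE_RADIUS_FRACTION * rh
    iz = (
        (x >= -spec.interzone_gap)
        & (x <= 0)
        & (y**2 + z**2 <= iz_r**2)
    )

    out[iz] = REGION_IDS["interzone"]
    out[ch] = REGION_IDS["CH"]
    out[pq] = REGION_IDS["PQ"]
    out[mc] = REGION_IDS["MC"]
    return out


# ----------------------------------------------------------------------
# meshing: Kuhn-subdivided voxel lattice
# ----------------------------------------------------------------------

# the six tetrahedra of the Kuhn subdivision share the (0,0,0)-(1,1,1)
# diagonal, so neighbouring cubes triangulate their shared face identically
_KUHN = np.array(
    [
        [(0, 0, 0), (1, 0, 0), (1, 1, 0), (1, 1, 1)],
        [(0, 0, 0), (1, 1, 0), (0, 1, 0), (1, 1, 1)],
        [(0, 0, 0), (0, 1, 0), (0, 1, 1), (1, 1, 1)],
        [(0, 0, 0), (0, 1, 1), (0, 0, 1), (1, 1, 1)],
        [(0, 0, 0), (0, 0, 1), (1, 0, 1), (1, 1, 1)],
        [(0, 0, 0), (1, 0, 1), (1, 0, 0), (1, 1, 1)],
    ]
)


def build_rudiment_mesh(spec: RudimentSpec | None = None, seed: int = 0) -> LabelledTetMesh:
    """Mesh the parametric half-jaw with linear tetrahedra.

    A regular lattice (spacing ``spec.target_edge_length``, anchored so the
    joint plane x=0 lies on lattice nodes) is subdivided into six
    tetrahedra per cube; tetrahedra whose centroid falls inside the solid
    are kept and labelled by region.  The construction is deterministic;
    ``seed`` is accepted for interface symmetry with the samplers.
    """
    spec = spec or RudimentSpec()
    h = spec.target_edge_length
    rh = spec.joint_head_radius
    if h > 2 * spec.interzone_gap:
        raise MeshingError(
            f"target_edge_length={h} too coarse for interzone_gap={spec.interzone_gap}"
        )
    if h > rh / 2:
        raise MeshingError(
            f"target_edge_length={h} too coarse for joint_head_radius={rh}"
        )

    cz = spec.ch_anchor_offset[2]
    lo = np.array([-spec.interzone_gap - spec.pq_length - h,
                   -rh - h, min(-rh, cz - _CH_LENGTH) - h])
    hi = np.array([spec.mc_length + h, rh + h, rh + h])
    i_lo = np.floor(lo / h).astype(int)
    i_hi = np.ceil(hi / h).astype(int)
    nx, ny, nz = i_hi - i_lo

    # lattice nodes
    xs = (np.arange(i_lo[0], i_hi[0] + 1)) * h
    ys = (np.arange(i_lo[1], i_hi[1] + 1)) * h
    zs = (np.arange(i_lo[2], i_hi[2] + 1)) * h
    X, Y, Z = np.meshgrid(xs, ys, zs, indexing="ij")
    nodes = np.stack([X.ravel(), Y.ravel(), Z.ravel()], axis=1)

    def nid(ix, iy, iz):
        return (ix * (ny + 1) + iy) * (nz + 1) + iz

    ix, iy, iz = np.meshgrid(np.arange(nx), np.arange(ny), np.arange(nz),
                             indexing="ij")
    ix, iy, iz = ix.ravel(), iy.ravel(), iz.ravel()
    tets = []
    for tet in _KUHN:
        ids = [nid(ix + dx, iy + dy, iz + dz) for dx, dy, dz in tet]
        tets.append(np.stack(ids, axis=1))
    cells = np.concatenate(tets)

    centroids = nodes[cells].mean(axis=1)
    labels = region_of_points(spec, centroids)
    keep = labels > 0
    cells, labels = cells[keep], labels[keep]
    if not keep.any():
        raise MeshingError("specification produced an empty solid")
    for name, rid in REGION_IDS.items():
        if not (labels == rid).any():
            raise MeshingError(f"region {name} received no elements; "
                               f"check its governing dimensions")

    # compact node numbering
    used, inv = np.unique(cells, return_inverse=True)
    cells = inv.reshape(cells.shape)
    points = nodes[used]

    mesh = LabelledTetMesh(points=points, cells=cells, region=labels)
    # fix orientation (positive volumes)
    vol = mesh.cell_volumes()
    flip = vol < 0
    mesh.cells[flip] = mesh.cells[flip][:, [0, 1, 3, 2]]
    if (mesh.cell_volumes() <= 0).any():
        raise MeshingError("degenerate elements produced")

    # connectivity check: the assembly must be a single load path
    e = mesh.edges()
    g = coo_matrix((np.ones(len(e)), (e[:, 0], e[:, 1])),
                   shape=(mesh.n_points, mesh.n_points))
    n_comp, _ = connected_components(g, directed=False)
    if n_comp != 1:
        raise MeshingError("assembly is disconnected; check ch_anchor_offset "
                           "and interzone_gap")

    mesh.landmarks = {
        "joint_line": np.zeros(3),
        # ventral bulge of the joint head, slightly anterior of the joint
        "retroarticular": np.array([0.3 * rh, 0.0,
                                    -math.sqrt(rh**2 - (0.3 * rh) ** 2)]),
    }
    L = spec.mc_length
    mesh.attachments = {
        "am": np.array([0.35 * L, 0.0, float(spec.radius(0.35 * L) + spec.axis_dip(0.35 * L))]),
        "ima": np.array([0.85 * L, 0.0, float(-spec.radius(0.85 * L) + spec.axis_dip(0.85 * L))]),
        "imp": np.array([0.60 * L, 0.0, float(-spec.radius(0.60 * L) + spec.axis_dip(0.60 * L))]),
        "ih": np.array([spec.ch_anchor_offset[0], 0.0, cz - 0.6 * _CH_LENGTH]),
    }
    mesh.frame = spec.frame
    return mesh


def solid_volume(spec: RudimentSpec, h: float = 0.5) -> float:
    """Reference volume of the parametric solid by fine-grid quadrature.

    Independent of the mesher: integrates the point-membership indicator
    on a lattice of spacing ``h`` (midpoint rule).
    """
    cz = spec.ch_anchor_offset[2]
    rh = spec.joint_head_radius
    xs = np.arange(-spec.interzone_gap - spec.pq_length - 1, spec.mc_length + 1, h)
    ys = np.arange(-rh - 1, rh + 1, h)
    zs = np.arange(min(-rh, cz - _CH_LENGTH) - 1, rh + 1, h)
    total = 0.0
    # slab-wise to bound memory
    for x in xs:
        Y, Z = np.meshgrid(ys + h / 2, zs + h / 2, indexing="ij")
        P = np.stack([np.full(Y.size, x + h / 2), Y.ravel(), Z.ravel()], axis=1)
        total += np.count_nonzero(region_of_points(spec, P)) * h**3
    return total


# ----------------------------------------------------------------------
# ground-truth deformation fields
# ----------------------------------------------------------------------

@dataclass
class GroundTruthDeformation:
    """Separable per-axis growth-velocity field in the canonical frame.

    The velocity of a material point p is
    ``v_i = A_i * phi_i(|p_AP|) * p_i`` per anatomical axis i, with the
    smooth axial profile ``phi_i(s) = (1-beta_i) + beta_i*exp(-(s/lam)^2)``
    peaking at the joint line.  ``amplitudes`` are the per-axis base rates
    (s⁻¹) in the order (AP, ML, VD); ``betas`` the per-axis profile
    contrasts.  Anteroposterior elongation is distributed along the rod
    (flat profile) whereas ML/VD growth concentrates at the joint, so the
    free-to-move mode is VD-dominant near the joint; the immobilised mode
    has a slightly negative VD rate.
    """

    mode: str = "free"
    amplitudes: np.ndarray = field(default_factory=lambda: np.zeros(3))
    betas: np.ndarray = field(default_factory=lambda: np.array([0.0, 0.4, 0.4]))
    lam: float = 40.0
    window: float = config.WINDOW_SECONDS

    def __post_init__(self):
        self.amplitudes = np.asarray(self.amplitudes, float)
        self.betas = np.asarray(self.betas, float)
        if not np.all(np.isfinite(self.amplitudes)):
            raise ValueError("growth rates must be finite")

    def profile(self, s) -> np.ndarray:
        """(N, 3) per-axis profile values at AP distances ``s``."""
        s = np.atleast_1d(np.asarray(s, float))
        bump = np.exp(-((s / self.lam) ** 2))
        return (1.0 - self.betas)[None, :] + self.betas[None, :] * bump[:, None]

    def rates(self, points: np.ndarray) -> np.ndarray:
        """Per-point diagonal rates (N, 3) in (AP, ML, VD) order (s⁻¹)."""
        points = np.atleast_2d(np.asarray(points, float))
        return self.profile(np.abs(points[:, 0])) * self.amplitudes[None, :]

    def velocity(self, points: np.ndarray) -> np.ndarray:
        points = np.atleast_2d(np.asarray(points, float))
        return self.rates(points) * points


def zero_deformation(window: float = config.WINDOW_SECONDS) -> GroundTruthDeformation:
    return GroundTruthDeformation(mode="zero", amplitudes=np.zeros(3), window=window)


def uniform_deformation(rate: float | np.ndarray,
                        window: float = config.WINDOW_SECONDS) -> GroundTruthDeformation:
    """Spatially uniform field (betas = 0) with the given per-axis rate."""
    amp = np.broadcast_to(np.asarray(rate, float), (3,)).copy()
    return GroundTruthDeformation(mode="uniform", amplitudes=amp,
                                  betas=np.zeros(3), window=window)


def advect_points(points: np.ndarray, fld: GroundTruthDeformation,
                  delta_t: float, substeps: int | None = None) -> np.ndarray:
    """Integrate the flow dx/dt = v(x) with classical RK4 sub-stepping."""
    points = np.array(points, float)
    if delta_t == 0:
        return points
    if substeps is None:
        substeps = max(1, math.ceil(abs(delta_t) / config.WINDOW_SECONDS
                                    * config.FLOW_SUBSTEPS_PER_WINDOW))
    dt = delta_t / substeps
    x = points
    for _ in range(substeps):
        k1 = fld.velocity(x)
        k2 = fld.velocity(x + 0.5 * dt * k1)
        k3 = fld.velocity(x + 0.5 * dt * k2)
        k4 = fld.velocity(x + dt * k3)
        x = x + dt / 6.0 * (k1 + 2 * k2 + 2 * k3 + k4)
    return x


def _mc_measurements(points: np.ndarray) -> tuple[float, float, float]:
    """(length, depth, width-at-joint) of MC node coordinates."""
    length = points[:, 0].max() - points[:, 0].min()
    depth = points[:, 2].max() - points[:, 2].min()
    slab = np.abs(points[:, 0]) <= config.JOINT_SLAB_UM  # joint plane at x=0
    if not slab.any():
        slab = points[:, 0] <= points[:, 0].min() + config.JOINT_SLAB_UM
    width = points[slab, 1].max() - points[slab, 1].min()
    return float(length), float(depth), float(width)


def calibrate_ground_truth(mode: str, spec: RudimentSpec | None = None,
                           targets: dict | None = None,
                           betas=(0.0, 0.4, 0.4), lam: float = 40.0) -> GroundTruthDeformation:
    """Solve for per-axis amplitudes hitting the organ-level percent changes.

    The oracle is direct advection of the MC node cloud over the 24 h study
    period; each axis amplitude is found by scalar root finding (the AP
    flow is autonomous, so it is solved first; the ML/VD flows depend on AP
    only through the axial profile).
    """
    spec = spec or RudimentSpec()
    targets = targets or config.ORGAN_PERCENT_CHANGES[mode]
    mesh = _default_mesh_for(spec)
    mc_pts = mesh.points[mesh.region_nodes("MC")]
    base = _mc_measurements(mc_pts)
    T = config.STUDY_SECONDS

    amps = np.zeros(3)
    order = [(0, "length", targets["length"]),
             (2, "depth", targets["depth"]),
             (1, "width", targets["width"])]
    for axis, name, target in order:
        def err(a):
            trial = amps.copy()
            trial[axis] = a
            fld = GroundTruthDeformation(mode=mode, amplitudes=trial,
                                         betas=np.asarray(betas, float), lam=lam)
            moved = advect_points(mc_pts, fld, T)
            meas = _mc_measurements(moved)
            idx = {"length": 0, "depth": 1, "width": 2}[name]
            return 100.0 * (meas[idx] - base[idx]) / base[idx] - target

        amps[axis] = brentq(err, -3e-5, 8e-5, xtol=1e-12)
    return GroundTruthDeformation(mode=mode, amplitudes=amps,
                                  betas=np.asarray(betas, float), lam=lam)


_MESH_CACHE: dict = {}
_FIELD_CACHE: dict = {}


def _default_mesh_for(spec: RudimentSpec) -> LabelledTetMesh:
    key = id(spec) if spec.mc_radius_profile else (
        spec.mc_length, spec.joint_head_radius, spec.interzone_gap,
        spec.pq_length, spec.ch_anchor_offset, spec.target_edge_length)
    if key not in _MESH_CACHE:
        _MESH_CACHE[key] = build_rudiment_mesh(spec)
    return _MESH_CACHE[key]


def default_ground_truth(mode: str, spec: RudimentSpec | None = None) -> GroundTruthDeformation:
    """Calibrated default field for ``mode`` in {'free', 'immobilised'}."""
    if mode not in config.ORGAN_PERCENT_CHANGES:
        raise ValueError(f"unknown mode {mode!r}")
    spec = spec or RudimentSpec()
    if spec.mc_radius_profile is not None:
        return calibrate_ground_truth(mode, spec)
    key = (mode, spec.mc_length, spec.joint_head_radius, spec.interzone_gap,
           spec.pq_length, spec.ch_anchor_offset, spec.target_edge_length)
    if key not in _FIELD_CACHE:
        _FIELD_CACHE[key] = calibrate_ground_truth(mode, spec)
    return _FIELD_CACHE[key]


# ----------------------------------------------------------------------
# centroids and tracked pairs
# ----------------------------------------------------------------------

@dataclass
class CentroidSet:
    """Identified 3D cell centroids at one timepoint (μm, dpf label)."""

    cell_ids: np.ndarray
    positions: np.ndarray
    timepoint_dpf: float = 4.0

    def __post_init__(self):
        self.cell_ids = np.asarray(self.cell_ids, np.int64)
        self.positions = np.asarray(self.positions, float)
        if len(np.unique(self.cell_ids)) != len(self.cell_ids):
            raise ValueError("cell ids must be unique")
        if self.positions.shape != (len(self.cell_ids), 3):
            raise ValueError("positions must be (n, 3)")

    def __len__(self):
        return len(self.cell_ids)

    def sorted_by_id(self) -> "CentroidSet":
        order = np.argsort(self.cell_ids)
        return CentroidSet(self.cell_ids[order], self.positions[order],
                           self.timepoint_dpf)

    def to_csv(self, path) -> None:
        pd.DataFrame({
            "cell_id": self.cell_ids,
            "x_um": self.positions[:, 0],
            "y_um": self.positions[:, 1],
            "z_um": self.positions[:, 2],
            "timepoint_dpf": self.timepoint_dpf,
        }).to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "CentroidSet":
        df = pd.read_csv(path)
        return cls(df["cell_id"].to_numpy(),
                   df[["x_um", "y_um", "z_um"]].to_numpy(),
                   float(df["timepoint_dpf"].iloc[0]))


@dataclass
class TrackedPair:
    """Two centroid sets sharing cell ids, ``delta_t`` seconds apart."""

    t0: CentroidSet
    t1: CentroidSet
    delta_t: float = config.WINDOW_SECONDS

    def __post_init__(self):
        if self.delta_t <= 0:
            raise ValueError("delta_t must be positive")
        if set(self.t0.cell_ids) != set(self.t1.cell_ids):
            raise ValueError("tracked pair must share the same cell ids")
        self.t0 = self.t0.sorted_by_id()
        self.t1 = self.t1.sorted_by_id()

    def __len__(self):
        return len(self.t0)


def sample_cell_centroids(mesh: LabelledTetMesh, region: str = "MC",
                          n: int = config.N_TRACKED_CELLS,
                          min_spacing: float = config.MIN_CELL_SPACING_UM,
                          seed: int = 0,
                          timepoint_dpf: float = 4.0) -> CentroidSet:
    """Poisson-disk (dart-throwing) sample of cell centroids in a region."""
    rng = config.rng_from_seed(seed)
    mask = mesh.region_mask(region)
    if not mask.any():
        raise ValueError(f"region {region!r} not present in mesh")
    cells = mesh.cells[mask]
    vols = np.abs(mesh.cell_volumes()[mask])
    probs = vols / vols.sum()

    accepted = []
    max_attempts = max(2000, 500 * n)
    for _ in range(max_attempts):
        tet = cells[rng.choice(len(cells), p=probs)]
        # uniform barycentric point (folded-coordinates method)
        s, t, u = np.sort(rng.random(3))
        w = np.array([s, t - s, u - t, 1.0 - u])
        p = w @ mesh.points[tet]
        if min_spacing > 0 and accepted:
            d = np.linalg.norm(np.array(accepted) - p, axis=1)
            if d.min() < min_spacing:
                continue
        accepted.append(p)
        if len(accepted) == n:
            break
    else:
        raise RuntimeError(
            f"could not place {n} centroids at spacing {min_spacing} μm "
            f"after {max_attempts} attempts")
    return CentroidSet(np.arange(n), np.array(accepted), timepoint_dpf)


def advect_tracked_pair(cells: CentroidSet, fld: GroundTruthDeformation,
                        delta_t: float = config.WINDOW_SECONDS,
                        noise_sd: float = 0.0, seed: int = 0) -> TrackedPair:
    """Advect centroids by the flow and add isotropic localisation noise."""
    if delta_t <= 0:
        raise ValueError("delta_t must be positive")
    if noise_sd < 0:
        raise ValueError("noise_sd must be non-negative")
    rng = config.rng_from_seed(seed)
    moved = advect_points(cells.positions, fld, delta_t)
    if noise_sd > 0:
        moved = moved + rng.normal(0.0, noise_sd, moved.shape)
    t1 = CentroidSet(cells.cell_ids.copy(), moved,
                     cells.timepoint_dpf + delta_t / 86400.0)
    return TrackedPair(cells, t1, delta_t)


def tracked_timepoint_series(cells: CentroidSet, fld: GroundTruthDeformation,
                             n_windows: int = 2,
                             window: float = config.WINDOW_SECONDS,
                             noise_sd: float = config.CENTROID_NOISE_SD_UM,
                             seed: int = 0) -> list[TrackedPair]:
    """Longitudinal observation series: one TrackedPair per window.

    True trajectories are maintained internally; each observed timepoint is
    the true positions plus independent localisation noise, mimicking one
    confocal image per timepoint (so consecutive pairs share the noisy
    middle image, as real longitudinal data would).
    """
    rng = config.rng_from_seed(seed)
    true_pos = [cells.positions]
    for _ in range(n_windows):
        true_pos.append(advect_points(true_pos[-1], fld, window))
    obs = []
    for k, pos in enumerate(true_pos):
        noisy = pos + (rng.normal(0.0, noise_sd, pos.shape) if noise_sd > 0 else 0.0)
        obs.append(CentroidSet(cells.cell_ids.copy(), noisy,
                               cells.timepoint_dpf + k * window / 86400.0))
    return [TrackedPair(obs[k], obs[k + 1], window) for k in range(n_windows)]


def deform_mesh_ground_truth(mesh: LabelledTetMesh, fld: GroundTruthDeformation,
                             delta_t: float) -> LabelledTetMesh:
    """Advect every mesh node (and landmark) by the ground-truth flow."""
    moved = advect_points(mesh.points, fld, delta_t)
    out = mesh.with_points(moved)
    out.landmarks = {k: advect_points(v[None], fld, delta_t)[0]
                     for k, v in mesh.landmarks.items()}
    out.attachments = {k: advect_points(v[None], fld, delta_t)[0]
                       for k, v in mesh.attachments.items()}
    vol = out.cell_volumes()
    bad = np.nonzero(vol <= 0)[0]
    if bad.size:
        raise RuntimeError(f"deformation inverted elements {bad[:10].tolist()}")
    return out
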