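"""Growth-tensor estimation from tracked cell centroids.

The local growth measure is the statistical symmetrised velocity gradient
of Graner and co-workers: from the link vectors l connecting neighbouring
cell centroids, form the texture M = <l ⊗ l> and the link-change
C = <l ⊗ (l' − l)>/Δt over links conserved between the two timepoints;
the velocity gradient is V = M⁻¹ C and the growth tensor its symmetric
part (V + Vᵀ)/2, a strain-rate-equivalent statistic in s⁻¹.  Tensors are
evaluated on a lattice of cubic regions of interest (ROIs), using every
conserved link with at least one endpoint inside the ROI, and growth maps
are interpolated trilinearly between ROI centres.
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.spatial import Delaunay, QhullError, cKDTree

from . import config
from .mesh import AnatomicalFrame, CANONICAL_FRAME, AXIS_ORDER
from .synthetic import CentroidSet, TrackedPair

#: label assignment priority used to break angular ties (the ventrodorsal
#: axis is the axis of interest, so it is assigned first)
LABEL_PRIORITY = ("VD", "AP", "ML")


# ----------------------------------------------------------------------
# links
# ----------------------------------------------------------------------

@dataclass
class LinkSet:
    """Undirected neighbour links between identified centroids."""

    id_pairs: np.ndarray      # (L, 2) cell ids, id_i < id_j
    vectors: np.ndarray       # (L, 3) position_j − position_i (μm)
    neighbour_rule: dict = field(default_factory=dict)

    def __len__(self):
        return len(self.id_pairs)


def auto_cutoff(cells: CentroidSet,
                factor: float = config.LINK_CUTOFF_FACTOR) -> float:
    """Link cutoff: ``factor`` times the median nearest-neighbour distance."""
    tree = cKDTree(cells.positions)
    d, _ = tree.query(cells.positions, k=2)
    return factor * float(np.median(d[:, 1]))


def build_links(cells: CentroidSet, cutoff: float | None = None) -> LinkSet:
    """Delaunay neighbour links, deduplicated, with an edge-length cutoff."""
    if len(cells) < 4:
        raise ValueError("at least 4 centroids are required to build links")
    if cutoff is None:
        cutoff = auto_cutoff(cells)
    cs = cells.sorted_by_id()
    try:
        tri = Delaunay(cs.positions)
    except QhullError as exc:
        raise ValueError(f"degenerate (coplanar?) centroid set: {exc}") from exc
    edges = set()
    for simplex in tri.simplices:
        for a, b in itertools.combinations(simplex, 2):
            edges.add((min(a, b), max(a, b)))
    idx = np.array(sorted(edges), np.int64).reshape(-1, 2)
    vec = cs.positions[idx[:, 1]] - cs.positions[idx[:, 0]]
    keep = np.linalg.norm(vec, axis=1) <= cutoff
    return LinkSet(
        id_pairs=cs.cell_ids[idx[keep]],
        vectors=vec[keep],
        neighbour_rule={"method": "delaunay", "cutoff": float(cutoff)},
    )


@dataclass
class ConservedLinks:
    """Links built at t and re-measured from the same cell ids at t+Δt."""

    id_pairs: np.ndarray     # (L, 2)
    l0: np.ndarray           # (L, 3) link vectors at t
    l1: np.ndarray           # (L, 3) link vectors at t+Δt
    endpoints0: np.ndarray   # (L, 2, 3) endpoint positions at t
    delta_t: float
    neighbour_rule: dict = field(default_factory=dict)

    def __len__(self):
        return len(self.id_pairs)


def conserved_link_pairs(pair: TrackedPair,
                         cutoff: float | None = None) -> ConservedLinks:
    """Build links at the first timepoint and match them by id at the second.

    Cells absent at either timepoint would drop their links; with the
    near-zero proliferation of the tracked window, id sets are identical
    and every link is conserved.
    """
    links = build_links(pair.t0, cutoff)
    pos0 = {cid: p for cid, p in zip(pair.t0.cell_ids, pair.t0.positions)}
    pos1 = {cid: p for cid, p in zip(pair.t1.cell_ids, pair.t1.positions)}
    keep, l0, l1, ep0 = [], [], [], []
    for (i, j), v in zip(links.id_pairs, links.vectors):
        if i in pos1 and j in pos1:
            keep.append((i, j))
            l0.append(v)
            l1.append(pos1[j] - pos1[i])
            ep0.append((pos0[i], pos0[j]))
    if not keep:
        raise ValueError("no conserved links between the two timepoints")
    return ConservedLinks(
        id_pairs=np.array(keep, np.int64),
        l0=np.array(l0), l1=np.array(l1), endpoints0=np.array(ep0),
        delta_t=pair.delta_t, neighbour_rule=links.neighbour_rule,
    )


# ----------------------------------------------------------------------
# per-ROI tensor
# ----------------------------------------------------------------------

class SingularTextureError(ValueError):
    """The texture matrix of an ROI is singular or ill-conditioned."""


@dataclass
class GrowthTensor:
    """Symmetric growth-rate tensor with its ellipsoid decomposition.

    ``eigenvectors`` columns are the ellipsoid axes; ``axis_labels`` maps
    each anatomical label to the eigen index whose direction is closest to
    that anatomical axis; ``angles`` records the angular mismatch (deg).
    """

    tensor: np.ndarray
    eigenvalues: np.ndarray
    eigenvectors: np.ndarray
    axis_labels: dict
    angles: dict
    n_links: int = 0

    @classmethod
    def from_tensor(cls, T: np.ndarray, frame: AnatomicalFrame = CANONICAL_FRAME,
                    n_links: int = 0) -> "GrowthTensor":
        T = np.asarray(T, float)
        T = 0.5 * (T + T.T)
        w, v = np.linalg.eigh(T)
        labels, angles = label_axes_assignment(v, frame)
        return cls(tensor=T, eigenvalues=w, eigenvectors=v,
                   axis_labels=labels, angles=angles, n_links=n_links)

    def rate(self, label: str) -> float:
        """Growth rate (s⁻¹) along the anatomically labelled axis."""
        return float(self.eigenvalues[self.axis_labels[label]])


def label_axes_assignment(eigenvectors: np.ndarray,
                          frame: AnatomicalFrame) -> tuple[dict, dict]:
    """Bijection anatomical label -> eigen index, minimal total angle.

    Each eigenvector is labelled by the anatomical axis it is closest to
    (sign-free angles); among assignments the one with the smallest total
    angular mismatch wins, ties broken by the VD > AP > ML priority.
    """
    cosines = np.empty((3, 3))
    for a, lab in enumerate(LABEL_PRIORITY):
        axis = frame.axis(lab)
        for e in range(3):
            cosines[a, e] = abs(float(axis @ eigenvectors[:, e]))
    ang = np.degrees(np.arccos(np.clip(cosines, -1.0, 1.0)))
    best = None
    for perm in itertools.permutations(range(3)):
        total = sum(ang[a, perm[a]] for a in range(3))
        key = (round(total, 9),) + tuple(ang[a, perm[a]] for a in range(3))
        if best is None or key < best[0]:
            best = (key, perm)
    perm = best[1]
    labels = {lab: int(perm[a]) for a, lab in enumerate(LABEL_PRIORITY)}
    angles = {lab: float(ang[a, perm[a]]) for a, lab in enumerate(LABEL_PRIORITY)}
    return labels, angles


def label_axes(t: GrowthTensor, frame: AnatomicalFrame) -> GrowthTensor:
    """Re-label an existing tensor against a (possibly different) frame."""
    labels, angles = label_axes_assignment(t.eigenvectors, frame)
    return GrowthTensor(t.tensor, t.eigenvalues, t.eigenvectors,
                        labels, angles, t.n_links)


def velocity_gradient_roi(l0: np.ndarray, l1: np.ndarray, delta_t: float,
                          frame: AnatomicalFrame = CANONICAL_FRAME,
                          min_links: int = config.MIN_LINKS_PER_ROI,
                          cond_limit: float = config.TEXTURE_CONDITION_LIMIT,
                          ) -> GrowthTensor:
    """Symmetrised velocity gradient from conserved link vectors.

    M = <l⊗l>, C = <l⊗(l'−l)>/Δt, V = M⁻¹C, tensor = (V+Vᵀ)/2.
    """
    l0 = np.atleast_2d(l0)
    l1 = np.atleast_2d(l1)
    n = len(l0)
    if n < min_links:
        raise SingularTextureError(f"only {n} links (minimum {min_links})")
    M = np.einsum("li,lj->ij", l0, l0) / n
    C = np.einsum("li,lj->ij", l0, (l1 - l0) / delta_t) / n
    if np.linalg.cond(M) > cond_limit:
        raise SingularTextureError("texture matrix is ill-conditioned")
    V = np.linalg.solve(M, C)
    return GrowthTensor.from_tensor(0.5 * (V + V.T), frame, n_links=n)


# ----------------------------------------------------------------------
# ROI grid and growth map
# ----------------------------------------------------------------------

@dataclass
class ROIGrid:
    """Cubic ROI lattice aligned with the anatomical frame.

    ``origin`` is anchored at the joint-line landmark; cell (i, j, k)
    spans origin + [i, i+1) * side per axis.
    """

    origin: np.ndarray
    cube_side: float = config.ROI_SIZE_UM
    occupied: np.ndarray = field(default_factory=lambda: np.zeros((0, 3), np.int64))
    frame: AnatomicalFrame = field(default_factory=lambda: CANONICAL_FRAME)

    def __post_init__(self):
        if self.cube_side <= 0:
            raise ValueError("cube_side must be positive")
        self.origin = np.asarray(self.origin, float)
        self.occupied = np.asarray(self.occupied, np.int64).reshape(-1, 3)

    def cell_of(self, points: np.ndarray) -> np.ndarray:
        points = np.atleast_2d(np.asarray(points, float))
        return np.floor((points - self.origin) / self.cube_side).astype(np.int64)

    def centres(self) -> np.ndarray:
        return self.origin + (self.occupied + 0.5) * self.cube_side

    @classmethod
    def covering(cls, cells: CentroidSet, origin=(0.0, 0.0, 0.0),
                 cube_side: float = config.ROI_SIZE_UM,
                 frame: AnatomicalFrame = CANONICAL_FRAME) -> "ROIGrid":
        grid = cls(origin=np.asarray(origin, float), cube_side=cube_side,
                   frame=frame)
        grid.occupied = np.unique(grid.cell_of(cells.positions), axis=0)
        return grid


@dataclass
class GrowthMap:
    """Growth tensors at ROI centres with trilinear interpolation."""

    grid: ROIGrid
    roi_indices: np.ndarray          # (K, 3) occupied+valid lattice indices
    tensors: list                    # K GrowthTensor
    invalid_rois: list = field(default_factory=list)   # [(ijk, reason)]
    interpolation_rule: str = "componentwise trilinear, nearest outside hull"

    def __post_init__(self):
        if len(self.tensors) == 0:
            raise ValueError("a growth map needs at least one valid ROI")
        self._lattice = None
        self._tree = None

    @property
    def roi_centres(self) -> np.ndarray:
        return self.grid.origin + (self.roi_indices + 0.5) * self.grid.cube_side

    def _build_lattice(self):
        idx = self.roi_indices
        lo, hi = idx.min(axis=0), idx.max(axis=0)
        shape = tuple(hi - lo + 1)
        lattice = np.full(shape + (3, 3), np.nan)
        for ijk, t in zip(idx, self.tensors):
            lattice[tuple(ijk - lo)] = t.tensor
        # fill unoccupied lattice sites from the nearest valid ROI so the
        # trilinear stencil is complete everywhere in the hull
        tree = cKDTree(self.roi_centres)
        nan_sites = np.argwhere(np.isnan(lattice[..., 0, 0]))
        if len(nan_sites):
            pts = self.grid.origin + (nan_sites + lo + 0.5) * self.grid.cube_side
            _, nearest = tree.query(pts)
            for site, src in zip(nan_sites, nearest):
                lattice[tuple(site)] = self.tensors[src].tensor
        self._lattice = (lattice, lo, hi)
        self._tree = tree

    def interpolate(self, points: np.ndarray) -> np.ndarray:
        """Componentwise trilinear tensors at query points (N, 3, 3).

        Outside the lattice hull the nearest ROI's tensor is returned.
        """
        if self._lattice is None:
            self._build_lattice()
        lattice, lo, hi = self._lattice
        points = np.atleast_2d(np.asarray(points, float))
        # continuous lattice coordinates: ROI centre (i,j,k) sits at i,j,k
        f = (points - self.grid.origin) / self.grid.cube_side - 0.5 - lo
        fmax = (hi - lo).astype(float)
        outside = np.any((f < 0) | (f > fmax), axis=1)
        fc = np.clip(f, 0.0, fmax)
        i0 = np.minimum(np.floor(fc).astype(np.int64),
                        np.maximum(hi - lo - 1, 0))
        w = fc - i0
        out = np.zeros((len(points), 3, 3))
        for dx in (0, 1):
            for dy in (0, 1):
                for dz in (0, 1):
                    ii = np.minimum(i0 + [dx, dy, dz], hi - lo)
                    wt = (np.where(dx, w[:, 0], 1 - w[:, 0])
                          * np.where(dy, w[:, 1], 1 - w[:, 1])
                          * np.where(dz, w[:, 2], 1 - w[:, 2]))
                    out += wt[:, None, None] * lattice[ii[:, 0], ii[:, 1], ii[:, 2]]
        if outside.any():
            _, nearest = self._tree.query(points[outside])
            out[outside] = np.array([self.tensors[k].tensor for k in nearest])
        return 0.5 * (out + np.transpose(out, (0, 2, 1)))

    def rates_matrix(self) -> pd.DataFrame:
        """Tabular view: one row per valid ROI (indices, centre, tensor,
        labelled rates, mismatch angles, link count)."""
        rows = []
        for ijk, c, t in zip(self.roi_indices, self.roi_centres, self.tensors):
            row = {"roi_i": ijk[0], "roi_j": ijk[1], "roi_k": ijk[2],
                   "cx": c[0], "cy": c[1], "cz": c[2], "n_links": t.n_links}
            T = t.tensor
            for (a, b), name in zip([(0, 0), (1, 1), (2, 2), (0, 1), (0, 2), (1, 2)],
                                    ["txx", "tyy", "tzz", "txy", "txz", "tyz"]):
                row[name] = T[a, b]
            for lab in AXIS_ORDER:
                row[f"rate_{lab}"] = t.rate(lab)
                row[f"angle_{lab}"] = t.angles[lab]
            rows.append(row)
        return pd.DataFrame(rows)

    def to_csv(self, path) -> None:
        path = Path(path)
        self.rates_matrix().to_csv(path, index=False)
        meta = {
            "origin": self.grid.origin.tolist(),
            "cube_side": self.grid.cube_side,
            "frame": {k: self.grid.frame.axis(k).tolist() for k in AXIS_ORDER},
            "interpolation_rule": self.interpolation_rule,
            "invalid_rois": [[list(map(int, ijk)), reason]
                             for ijk, reason in self.invalid_rois],
        }
        path.with_suffix(".json").write_text(json.dumps(meta, indent=1))

    @classmethod
    def from_csv(cls, path) -> "GrowthMap":
        path = Path(path)
        df = pd.read_csv(path)
        meta = json.loads(path.with_suffix(".json").read_text())
        frame = AnatomicalFrame(*(np.array(meta["frame"][k]) for k in AXIS_ORDER))
        grid = ROIGrid(origin=np.array(meta["origin"]),
                       cube_side=meta["cube_side"], frame=frame)
        idx = df[["roi_i", "roi_j", "roi_k"]].to_numpy(np.int64)
        grid.occupied = idx
        tensors = []
        for _, r in df.iterrows():
            T = np.array([[r.txx, r.txy, r.txz],
                          [r.txy, r.tyy, r.tyz],
                          [r.txz, r.tyz, r.tzz]])
            tensors.append(GrowthTensor.from_tensor(T, frame, int(r.n_links)))
        return cls(grid=grid, roi_indices=idx, tensors=tensors,
                   invalid_rois=[(tuple(i), s) for i, s in meta["invalid_rois"]])


def assemble_growth_map(pair: TrackedPair, grid: ROIGrid | None = None,
                        cutoff: float | None = None,
                        min_links: int = config.MIN_LINKS_PER_ROI,
                        cond_limit: float = config.TEXTURE_CONDITION_LIMIT,
                        ) -> GrowthMap:
    """One growth tensor per occupied ROI from conserved link pairs.

    Every conserved link with at least one endpoint inside the ROI
    contributes, so links crossing ROI boundaries are shared between the
    neighbouring ROIs.
    """
    if grid is None:
        grid = ROIGrid.covering(pair.t0)
    links = conserved_link_pairs(pair, cutoff)
    ep_cells = np.stack([grid.cell_of(links.endpoints0[:, 0]),
                         grid.cell_of(links.endpoints0[:, 1])], axis=1)
    indices, tensors, invalid = [], [], []
    for ijk in grid.occupied:
        touches = np.any(np.all(ep_cells == ijk, axis=2), axis=1)
        try:
            t = velocity_gradient_roi(links.l0[touches], links.l1[touches],
                                      links.delta_t, grid.frame,
                                      min_links, cond_limit)
        except SingularTextureError as exc:
            invalid.append((tuple(int(v) for v in ijk), str(exc)))
            continue
        indices.append(ijk)
        tensors.append(t)
    if not tensors:
        raise ValueError("no ROI produced a valid growth tensor")
    return GrowthMap(grid=grid, roi_indices=np.array(indices, np.int64),
                     tensors=tensors, invalid_rois=invalid)


def interpolate_growth(growth_map: GrowthMap, points: np.ndarray) -> np.ndarray:
    """Functional alias for :meth:`GrowthMap.interpolate`."""
    return growth_map.interpolate(points)
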