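import numpy as np
import pytest

from jawmorph.mesh import LabelledTetMesh
from jawmorph.synthetic import _KUHN


def kuhn_box_mesh(L, W, H, h, origin=(0.0, 0.0, 0.0), region=1):
    """Structured tetrahedral box mesh (Kuhn subdivision), for oracles."""
    nx, ny, nz = round(L / h), round(W / h), round(H / h)
    xs = origin[0] + np.arange(nx + 1) * h
    ys = origin[1] + np.arange(ny + 1) * h
    zs = origin[2] + np.arange(nz + 1) * h
    X, Y, Z = np.meshgrid(xs, ys, zs, indexing="ij")
    pts = np.stack([X.ravel(), Y.ravel(), Z.ravel()], 1)

    def nid(i, j, k):
        return (i * (ny + 1) + j) * (nz + 1) + k

    ix, iy, iz = np.meshgrid(np.arange(nx), np.arange(ny), np.arange(nz),
                             indexing="ij")
    ix, iy, iz = ix.ravel(), iy.ravel(), iz.ravel()
    cells = np.concatenate(
        [np.stack([nid(ix + d[0], iy + d[1], iz + d[2]) for d in tet], 1)
         for tet in _KUHN])
    m = LabelledTetMesh(pts, cells, np.full(len(cells), region))
    v = m.cell_volumes()
    m.cells[v < 0] = m.cells[v < 0][:, [0, 1, 3, 2]]
    m.landmarks = {"joint_line": np.zeros(3)}
    return m


def voxel_solid_mesh(inside_fn, h, lo, hi, region=1):
    """Voxel tet mesh of an implicit solid (centroid inclusion)."""
    lo = np.asarray(lo, float)
    hi = np.asarray(hi, float)
    m = kuhn_box_mesh(hi[0] - lo[0], hi[1] - lo[1], hi[2] - lo[2], h,
                      origin=lo, region=region)
    keep = inside_fn(m.cell_centroids())
    cells = m.cells[keep]
    used, inv = np.unique(cells, return_inverse=True)
    out = LabelledTetMesh(m.points[used], inv.reshape(cells.shape),
                          np.full(keep.sum(), region))
    out.landmarks = {"joint_line": np.zeros(3)}
    return out


@pytest.fixture(scope="session")
def default_mesh():
    from jawmorph.synthetic import build_rudiment_mesh
    return build_rudiment_mesh()


@pytest.fixture(scope="session")
def free_field():
    from jawmorph.synthetic import default_ground_truth
    return default_ground_truth("free")


@pytest.fixture(scope="session")
def imm_field():
    from jawmorph.synthetic import default_ground_truth
    return default_ground_truth("immobilised")


@pytest.fixture(scope="session")
def cells30(default_mesh):
    from jawmorph.synthetic import sample_cell_centroids
    return sample_cell_centroids(default_mesh, "MC", seed=1)


@pytest.fixture(scope="session")
def noisefree_pair(cells30, free_field):
    from jawmorph import config
    from jawmorph.synthetic import advect_tracked_pair
    return advect_tracked_pair(cells30, free_field, config.WINDOW_SECONDS,
                               noise_sd=0.0, seed=2)


@pytest.fixture(scope="session")
def noisefree_map(noisefree_pair):
    from jawmorph.growth import assemble_growth_map
    return assemble_growth_map(noisefree_pair)


@pytest.fixture(scope="session")
def jaw_mechanics_setup(default_mesh):
    """Calibrated default jaw: (materials, bcs, scaled loads, history)."""
    from jawmorph.mechanics import (MaterialModel, calibrate_muscle_forces,
                                    default_jaw_bcs, default_muscle_loads,
                                    simulate_jaw_cycle)
    mat = MaterialModel.from_study("free", "4-4.5")
    bcs = default_jaw_bcs(default_mesh)
    loads = default_muscle_loads(default_mesh, "4")
    scale, achieved, scaled = calibrate_muscle_forces(default_mesh, mat, bcs,
                                                      loads)
    hist = simulate_jaw_cycle(default_mesh, mat, bcs, scaled)
    return {"materials": mat, "bcs": bcs, "loads": loads, "scale": scale,
            "achieved": achieved, "scaled_loads": scaled, "history": hist}


@pytest.fixture(scope="session")
def default_pipeline_manifest():
    """One full default-configuration pipeline run (shared by tests)."""
    from jawmorph.morphogenesis import PipelineConfig, run_pipeline
    return run_pipeline(PipelineConfig(seed=1))
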