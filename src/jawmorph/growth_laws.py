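"""Mechanobiological growth laws combining baseline growth with stress.

Three hypotheses convert mechanics into growth, each supplementing the
immobilised ("biological baseline") growth map G_imm at every mesh node:

* average stress:        G_ave  = G_imm − a · S · I₃
* stress gradients:      G_grad = G_imm + b · |∇σ_h(open) − ∇σ_h(close)|
* compressive gradients: G_comp_grad — as G_grad but the hydrostatic
  fields are clamped to their compressive part before differentiation.

``S`` is the cycle-averaged hydrostatic stress (kPa), so compression
(S < 0) promotes growth isotropically in G_ave; the gradient laws are
anisotropic (the |·| acts per diagonal entry of the diagonal gradient
matrices).  In the μm/nN/s system ``a`` has units μm²·nN⁻¹·s⁻¹ and ``b``
μm³·nN⁻¹·s⁻¹, making a·S and b·|Δ∇σ_h| growth rates (s⁻¹).

The modulating variables are chosen by the sensitivity procedure: sweep
the variable, simulate one growth window per value, and keep the value
whose predicted MC depth change is closest to the physiological one.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .growth import GrowthMap
from .mechanics import compressive_clamp, nodal_gradient
from .mesh import LabelledTetMesh

GROWTH_MAP_KINDS = ("G_ave", "G_grad", "G_comp_grad")


@dataclass
class ModulatingVariables:
    """Stress-to-growth coefficients (μm²·nN⁻¹·s⁻¹ and μm³·nN⁻¹·s⁻¹)."""

    a: float = 0.0
    b: float = 0.0
    provenance: str = "calibrated"

    def __post_init__(self):
        if self.a < 0 or self.b < 0:
            raise ValueError("modulating variables must be non-negative")


@dataclass
class MechanoGrowthMap:
    """Per-node growth tensors produced by one mechanobiological law."""

    kind: str
    mesh: LabelledTetMesh
    node_tensors: np.ndarray            # (N, 3, 3) s⁻¹
    parameters: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.kind not in GROWTH_MAP_KINDS + ("G_imm", "G_free"):
            raise ValueError(f"unknown growth-map kind {self.kind!r}")
        if self.node_tensors.shape != (self.mesh.n_points, 3, 3):
            raise ValueError("one tensor per mesh node is required")
        asym = np.abs(self.node_tensors
                      - np.transpose(self.node_tensors, (0, 2, 1))).max()
        if asym > 1e-10:
            raise ValueError("growth tensors must be symmetric")

    def element_tensors(self) -> np.ndarray:
        """FE-interpolated tensors at element centroids (mean of nodes)."""
        return self.node_tensors[self.mesh.cells].mean(axis=1)


def baseline_on_mesh(baseline: GrowthMap, mesh: LabelledTetMesh) -> np.ndarray:
    """Interpolate an ROI growth map to the mesh nodes (N, 3, 3)."""
    return baseline.interpolate(mesh.points)


def _check_registration(mesh: LabelledTetMesh, *fields):
    for f in fields:
        if np.asarray(f).shape[0] != mesh.n_points:
            raise ValueError("field is not registered on the mesh nodes")


def growth_ave(g_imm_nodes: np.ndarray, S: np.ndarray, a: float,
               mesh: LabelledTetMesh) -> MechanoGrowthMap:
    """Average-stress law: isotropic increment −a·S·I₃ per node.

    Compression (S < 0) increases all three diagonal rates; tension
    decreases them.
    """
    _check_registration(mesh, g_imm_nodes, S)
    S = np.asarray(S, float)
    tensors = g_imm_nodes - a * S[:, None, None] * np.eye(3)[None]
    return MechanoGrowthMap("G_ave", mesh, tensors, {"a": a})


def growth_grad(g_imm_nodes: np.ndarray, grad_open: np.ndarray,
                grad_close: np.ndarray, b: float,
                mesh: LabelledTetMesh) -> MechanoGrowthMap:
    """Stress-gradient law: anisotropic increment b·|∇σ_h,open − ∇σ_h,close|.

    The gradients are diagonal matrices (one entry per anatomical axis);
    the absolute difference is taken entrywise, so the increment is
    non-negative on every axis and symmetric in the two peaks.
    """
    _check_registration(mesh, g_imm_nodes, grad_open, grad_close)
    stim = b * np.abs(np.asarray(grad_open) - np.asarray(grad_close))  # (N,3)
    tensors = g_imm_nodes.copy()
    tensors[:, np.arange(3), np.arange(3)] += stim
    return MechanoGrowthMap("G_grad", mesh, tensors, {"b": b})


def growth_comp_grad(g_imm_nodes: np.ndarray, sh_open: np.ndarray,
                     sh_close: np.ndarray, b: float,
                     mesh: LabelledTetMesh,
                     neighbours: list | None = None) -> MechanoGrowthMap:
    """Compressive-gradient law: clamp the hydrostatic fields to their
    compressive part, then apply the gradient rule with the same b."""
    _check_registration(mesh, g_imm_nodes, sh_open, sh_close)
    go = nodal_gradient(compressive_clamp(sh_open), mesh, neighbours)
    gc = nodal_gradient(compressive_clamp(sh_close), mesh, neighbours)
    out = growth_grad(g_imm_nodes, go, gc, b, mesh)
    out.kind = "G_comp_grad"
    return out


def calibrate_modulating_variable(which: str, sweep, evaluate,
                                  criterion_target: float):
    """Sensitivity sweep for a modulating variable.

    ``evaluate(value)`` must run one growth window with the candidate
    value and return the predicted MC depth percent change; the value
    minimising |depth change − criterion_target| is chosen.  Returns
    ``(chosen_value, table)`` with the full sweep table.
    """
    if which not in ("a", "b"):
        raise ValueError("which must be 'a' or 'b'")
    sweep = list(sweep)
    if len(sweep) < 2:
        raise ValueError("sweep needs at least two values")
    rows = []
    for v in sweep:
        try:
            depth = float(evaluate(v))
        except (ValueError, RuntimeError) as exc:
            warnings.warn(f"sweep value {v:g} failed ({exc}); excluded")
            depth = np.nan
        err = abs(depth - criterion_target) if np.isfinite(depth) else np.inf
        rows.append({"value": v, "depth_percent_change": depth,
                     "abs_error": err})
    table = pd.DataFrame(rows)
    errs = table["abs_error"].to_numpy()
    best = int(np.argmin(errs))
    if np.sum(errs == errs[best]) > 1:
        warnings.warn(f"multiple sweep optima for {which}; keeping the first")
    if best in (0, len(sweep) - 1) and len(sweep) > 2:
        warnings.warn(f"optimum for {which} lies on the sweep boundary")
    return float(table["value"].iloc[best]), table
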