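"""Quasi-static volume-conductor FEM on the voxel grid, solved by geometric multigrid.

Discretizes ``div(sigma grad phi) = 0`` with 8-node trilinear hexahedral
elements (one element per conductive voxel, per-element constant
conductivity) and nodal current sources, giving a symmetric positive
semidefinite system with the constant vector in its nullspace (pure Neumann
problem).  The solver is a V(2,2) geometric multigrid with damped-Jacobi
smoothing, trilinear prolongation, full-weighting restriction (the
transpose) and Galerkin coarse operators, used by default as a
preconditioner for conjugate gradients; convergence is measured by the
Euclidean relative residual (default 1e-6).

Units: SI internally -- node spacing in metres, currents in amperes,
potentials in volts.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.ndimage as ndi
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from .phantom import VoxelHeadModel
from .tissues import TissueTable

MM = 1e-3
MA = 1e-3

# local node offsets of a hexahedron, bit order (di, dj, dk)
_OFFSETS = np.array([(i, j, k) for i in (0, 1) for j in (0, 1) for k in (0, 1)])


def _reference_stiffness() -> np.ndarray:
    """8x8 stiffness of the unit cube with unit conductivity (times edge h
    it gives the element stiffness; exact via 2x2x2 Gauss quadrature)."""
    g = np.array([0.5 - 0.5 / np.sqrt(3.0), 0.5 + 0.5 / np.sqrt(3.0)])
    K = np.zeros((8, 8))
    for gx in g:
        for gy in g:
            for gz in g:
                grads = np.empty((8, 3))
                for a, (i, j, k) in enumerate(_OFFSETS):
                    fx, fy, fz = (
                        gx if i else 1 - gx,
                        gy if j else 1 - gy,
                        gz if k else 1 - gz,
                    )
                    dfx = 1.0 if i else -1.0
                    dfy = 1.0 if j else -1.0
                    dfz = 1.0 if k else -1.0
                    grads[a] = (dfx * fy * fz, fx * dfy * fz, fx * fy * dfz)
                K += (grads @ grads.T) / 8.0
    return K


_K_REF = _reference_stiffness()


@dataclass
class LinearSystem:
    """Assembled node-based stiffness system for one head model."""

    A: sp.csr_matrix
    b: np.ndarray
    node_shape: tuple[int, int, int]
    active: np.ndarray  # boolean per node: touches a conductive element
    spacing_m: float
    model: VoxelHeadModel | None = None

    @property
    def n_nodes(self) -> int:
        return self.A.shape[0]


@dataclass
class PotentialField:
    """Nodal scalar potential (V) with solver diagnostics."""

    phi: np.ndarray  # node grid, shape = node_shape
    relative_residual: float
    residual_history: list[float] = field(default_factory=list)
    cycles: int = 0

    def diagnostics(self) -> dict:
        return {
            "relative_residual": self.relative_residual,
            "cycles": self.cycles,
            "residual_history": list(self.residual_history),
        }


def _node_ids(shape_nodes, idx):
    return np.ravel_multi_index(idx, shape_nodes)


def _element_node_ids(elem_idx, shape_nodes):
    """Node ids (n_elem x 8) of the elements given by index triples."""
    out = np.empty((elem_idx[0].size, 8), dtype=np.int64)
    for a, (di, dj, dk) in enumerate(_OFFSETS):
        out[:, a] = _node_ids(
            shape_nodes, (elem_idx[0] + di, elem_idx[1] + dj, elem_idx[2] + dk)
        )
    return out


def _check_current_path(model: VoxelHeadModel, sigma: np.ndarray) -> None:
    """Every electrode must share one conductive connected component."""
    mask = sigma > 0
    structure = ndi.generate_binary_structure(3, 1)  # 6-connectivity
    comp, _ = ndi.label(mask, structure=structure)
    comp_ids = []
    for e in model.electrodes:
        labels_here = comp[model.labels == e.rubber_label]
        comp_ids.append(set(np.unique(labels_here)) - {0})
    if model.point_sources:
        for (i, j, k), _c in model.point_sources:
            # a node touches up to 8 voxels; take any conductive one
            sl = comp[max(i - 1, 0) : i + 1, max(j - 1, 0) : j + 1, max(k - 1, 0) : k + 1]
            comp_ids.append(set(np.unique(sl)) - {0})
    comp_ids = [c for c in comp_ids if c]
    if len(comp_ids) >= 2 and not set.intersection(*comp_ids):
        raise ValueError("no current path: electrodes lie in disconnected conductive regions")


def assemble_system(model: VoxelHeadModel, tissues: TissueTable | None = None) -> LinearSystem:
    """Assemble stiffness operator and nodal current RHS for the model.

    Pad-electrode currents are lumped equally onto the nodes of the rubber
    compartment voxels; explicit point sources go onto their stated nodes.
    """
    tissues = tissues or TissueTable()
    sigma = model.conductivity_grid(tissues)
    if not model.electrodes and not model.point_sources:
        raise ValueError("model has no current sources")
    total = model.total_current_ma()
    if abs(total) > 1e-12:
        raise ValueError(f"injected currents must sum to zero, got {total} mA")
    _check_current_path(model, sigma)

    h = model.voxel_size_mm * MM
    shape_nodes = tuple(s + 1 for s in model.shape)
    n_nodes = int(np.prod(shape_nodes))

    elem_idx = np.nonzero(sigma > 0)
    sig_e = sigma[elem_idx]
    nid = _element_node_ids(elem_idx, shape_nodes)

    n_el = sig_e.size
    rows = np.empty(64 * n_el, dtype=np.int64)
    cols = np.empty(64 * n_el, dtype=np.int64)
    data = np.empty(64 * n_el)
    pos = 0
    for a in range(8):
        for c in range(8):
            rows[pos : pos + n_el] = nid[:, a]
            cols[pos : pos + n_el] = nid[:, c]
            data[pos : pos + n_el] = sig_e * (h * _K_REF[a, c])
            pos += n_el
    A = sp.coo_matrix((data, (rows, cols)), shape=(n_nodes, n_nodes)).tocsr()
    del rows, cols, data

    diag = A.diagonal()
    active = diag > 0
    if active.sum() == 0:
        raise ValueError("no conductive elements")
    # give inactive (exterior) nodes a decoupled diagonal of typical scale so
    # smoothers and Galerkin coarsening stay well conditioned
    fill = float(diag[active].mean())
    inactive_idx = np.nonzero(~active)[0]
    A = A + sp.coo_matrix(
        (np.full(inactive_idx.size, fill), (inactive_idx, inactive_idx)),
        shape=A.shape,
    ).tocsr()

    b = np.zeros(n_nodes)
    for e in model.electrodes:
        vox = np.nonzero(model.labels == e.rubber_label)
        nodes = np.unique(_element_node_ids(vox, shape_nodes))
        b[nodes] += (e.current_ma * MA) / nodes.size
    for (i, j, k), current_ma in model.point_sources:
        b[_node_ids(shape_nodes, ([i], [j], [k]))[0]] += current_ma * MA

    return LinearSystem(
        A=A, b=b, node_shape=shape_nodes, active=active, spacing_m=h, model=model
    )


# --------------------------------------------------------------------------
# geometric multigrid hierarchy
# --------------------------------------------------------------------------


def cut_current_ma(system: LinearSystem, potential: PotentialField, node_mask: np.ndarray) -> float:
    """Discrete current (mA) flowing into the node set through its cut.

    Sums the stiffness-weighted potential differences ``A_ij (phi_j - phi_i)``
    over all operator edges crossing the boundary of ``node_mask`` -- the
    FEM-consistent flux, which equals the enclosed injected current up to the
    solver residual.
    """
    mask = np.asarray(node_mask, dtype=bool).ravel()
    if mask.shape[0] != system.A.shape[0]:
        raise ValueError("node mask does not match the system size")
    phi = potential.phi.ravel()
    S = np.nonzero(mask)[0]
    B = np.nonzero(~mask)[0]
    A_SB = system.A[S][:, B]
    inflow = float(np.ones(len(S)) @ (A_SB @ phi[B])) - float(
        (A_SB @ np.ones(len(B))) @ phi[S]
    )
    return inflow / MA


def _prolongation_1d(n_fine: int) -> sp.csr_matrix:
    """1-D linear interpolation from the coarse grid (every other node)."""
    n_coarse = (n_fine + 1) // 2
    rows, cols, vals = [], [], []
    for i in range(n_fine):
        if i % 2 == 0:
            rows.append(i)
            cols.append(i // 2)
            vals.append(1.0)
        else:
            c = i // 2
            if c + 1 < n_coarse:
                rows += [i, i]
                cols += [c, c + 1]
                vals += [0.5, 0.5]
            else:
                rows.append(i)
                cols.append(c)
                vals.append(1.0)
    return sp.csr_matrix((vals, (rows, cols)), shape=(n_fine, n_coarse))


def _prolongation(shape_fine) -> tuple[sp.csr_matrix, tuple[int, int, int]]:
    Ps = [_prolongation_1d(s) for s in shape_fine]
    shape_coarse = tuple(p.shape[1] for p in Ps)
    P = sp.kron(sp.kron(Ps[0], Ps[1]), Ps[2]).tocsr()
    return P, shape_coarse  # node id = (i * ny + j) * nz + k matches kron order


class MultigridHierarchy:
    """Galerkin-coarsened level stack with a dense pseudo-inverse at the bottom."""

    def __init__(self, A: sp.csr_matrix, node_shape, coarsest_nodes: int = 4000):
        self.levels: list[dict] = []
        shape = tuple(node_shape)
        while np.prod(shape) > coarsest_nodes and min(shape) >= 5:
            P, shape_c = _prolongation(shape)
            self.levels.append(
                {"A": A, "diag": A.diagonal(), "P": P, "shape": shape}
            )
            A = (P.T @ (A @ P)).tocsr()
            shape = shape_c
        self.coarse_pinv = np.linalg.pinv(A.toarray(), rcond=1e-10)
        self.coarse_shape = shape

    def v_cycle(self, b: np.ndarray, level: int = 0, nu: int = 2, omega: float = 0.7) -> np.ndarray:
        if level == len(self.levels):
            return self.coarse_pinv @ b
        lv = self.levels[level]
        A, d, P = lv["A"], lv["diag"], lv["P"]
        x = np.zeros_like(b)
        for _ in range(nu):  # pre-smoothing
            x += omega * (b - A @ x) / d
        r_c = P.T @ (b - A @ x)
        x += P @ self.v_cycle(r_c, level + 1, nu, omega)
        for _ in range(nu):  # post-smoothing
            x += omega * (b - A @ x) / d
        return x


def _project_constant(x: np.ndarray, active: np.ndarray) -> np.ndarray:
    x = x.copy()
    x[active] -= x[active].mean()
    return x


def solve(
    system: LinearSystem,
    tol: float = 1e-6,
    max_cycles: int = 200,
    accel: str | None = "cg",
    direct_threshold: int = 20000,
    coarsest_nodes: int = 4000,
) -> PotentialField:
    """Solve for the potential to the requested relative residual.

    ``accel="cg"`` (default) runs conjugate gradients preconditioned with one
    V(2,2) cycle; ``accel=None`` iterates plain V-cycles.  Systems with at
    most ``direct_threshold`` active nodes are solved directly (sparse
    factorization with one pinned node); the contract is identical.  The
    returned potential has zero mean over active nodes.
    """
    if not (0 < tol < 1):
        raise ValueError("tol must be in (0, 1)")
    A, b, active = system.A, system.b, system.active
    bnorm = float(np.linalg.norm(b))
    shape = system.node_shape
    if bnorm == 0.0:
        return PotentialField(np.zeros(shape), 0.0, [0.0], 0)
    if abs(b.sum()) > 1e-10 * np.abs(b).sum():
        raise ValueError("incompatible Neumann problem: RHS does not sum to zero")

    n_active = int(active.sum())
    if n_active <= direct_threshold:
        idx = np.nonzero(active)[0][1:]  # pin the first active node at 0
        x = np.zeros(A.shape[0])
        x[idx] = spla.spsolve(A[idx][:, idx].tocsc(), b[idx])
        x = _project_constant(x, active)
        res = float(np.linalg.norm(b - A @ x) / bnorm)
        return PotentialField(x.reshape(shape), res, [res], 0)

    mg = MultigridHierarchy(A, shape, coarsest_nodes=coarsest_nodes)
    x = np.zeros(A.shape[0])
    history: list[float] = []

    if accel == "cg":
        r = b - A @ x
        z = _project_constant(mg.v_cycle(r), active)
        p = z.copy()
        rz = float(r @ z)
        for it in range(1, max_cycles + 1):
            Ap = A @ p
            alpha = rz / float(p @ Ap)
            x += alpha * p
            r -= alpha * Ap
            res = float(np.linalg.norm(r) / bnorm)
            history.append(res)
            if res <= tol:
                x = _project_constant(x, active)
                return PotentialField(x.reshape(shape), res, history, it)
            z = _project_constant(mg.v_cycle(r), active)
            rz_new = float(r @ z)
            p = z + (rz_new / rz) * p
            rz = rz_new
    else:
        for it in range(1, max_cycles + 1):
            r = b - A @ x
            x = _project_constant(x + mg.v_cycle(r), active)
            res = float(np.linalg.norm(b - A @ x) / bnorm)
            history.append(res)
            if res <= tol:
                return PotentialField(x.reshape(shape), res, history, it)

    raise RuntimeError(
        f"multigrid did not reach tol={tol} in {max_cycles} cycles; "
        f"residual history: {history[-5:]}"
    )
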