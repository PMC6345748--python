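"""Electric-field extraction: gradients, cortical sampling, template averaging.

The field is computed per element as ``E = -grad(phi)`` from the trilinear
shape functions evaluated at element centres, then sampled on a cortical
surface mesh at a fixed depth below the grey-matter surface along the inner
(into-cortex) normal.  Both the magnitude ``E_abs = |E|`` and the normal
component ``E_n = n . E`` (positive when the field points into the cortex)
are recorded.  Subject maps on the shared icosphere template are stacked and
averaged vertex-wise with an identity correspondence.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
import trimesh
from scipy.interpolate import RegularGridInterpolator

from .fem import MA, MM, PotentialField
from .phantom import VoxelHeadModel
from .tissues import TissueTable

log = logging.getLogger(__name__)


@dataclass
class CorticalSurfaceMesh:
    """Triangulated cortical surface with unit inner normals.

    Inner normals point from the grey-matter surface toward the white matter
    (for the spherical phantom: radially inward).
    """

    vertices: np.ndarray  # (n, 3) mm
    faces: np.ndarray  # (m, 3) int
    inner_normals: np.ndarray  # (n, 3) unit vectors

    def __post_init__(self) -> None:
        norms = np.linalg.norm(self.inner_normals, axis=1)
        if not np.allclose(norms, 1.0, atol=1e-6):
            raise ValueError("inner normals must be unit length")

    @property
    def n_vertices(self) -> int:
        return len(self.vertices)

    @classmethod
    def icosphere_template(cls, subdivisions: int = 4, radius_mm: float = 75.0) -> "CorticalSurfaceMesh":
        """Shared spherical template at the grey-matter surface radius."""
        m = trimesh.creation.icosphere(subdivisions=subdivisions, radius=radius_mm)
        v = np.asarray(m.vertices)
        inner = -v / np.linalg.norm(v, axis=1, keepdims=True)
        return cls(vertices=v, faces=np.asarray(m.faces), inner_normals=inner)

    def edge_length_mm(self) -> float:
        e = self.vertices[self.faces[:, 0]] - self.vertices[self.faces[:, 1]]
        return float(np.linalg.norm(e, axis=1).mean())

    def save_ply(self, path: str) -> None:
        m = trimesh.Trimesh(
            vertices=self.vertices,
            faces=self.faces,
            vertex_normals=self.inner_normals,
            process=False,
        )
        m.export(path)

    @classmethod
    def load_ply(cls, path: str) -> "CorticalSurfaceMesh":
        m = trimesh.load(path, process=False)
        normals = np.asarray(m.vertex_normals, dtype=float)
        normals = normals / np.linalg.norm(normals, axis=1, keepdims=True)
        return cls(vertices=np.asarray(m.vertices, float), faces=np.asarray(m.faces), inner_normals=normals)


@dataclass
class CorticalFieldMap:
    """Per-vertex field magnitude and inner-normal component (V/m)."""

    e_abs: np.ndarray
    e_n: np.ndarray
    depth_mm: float
    space: str = "subject"  # "subject" | "template"

    def __post_init__(self) -> None:
        if np.any(self.e_abs < -1e-12):
            raise ValueError("E_abs must be non-negative")
        if np.any(np.abs(self.e_n) > self.e_abs * (1 + 1e-9) + 1e-15):
            raise ValueError("|E_n| cannot exceed E_abs")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"vertex": np.arange(len(self.e_abs)), "E_abs": self.e_abs, "E_n": self.e_n}
        )

    def save_csv(self, path: str) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def load_csv(cls, path: str, depth_mm: float = 1.0, space: str = "subject") -> "CorticalFieldMap":
        df = pd.read_csv(path)
        return cls(df["E_abs"].to_numpy(), df["E_n"].to_numpy(), depth_mm, space)


def electric_field(potential: PotentialField, model: VoxelHeadModel) -> np.ndarray:
    """Per-element constant field (V/m), shape ``model.shape + (3,)``.

    Exact gradient of the trilinear interpolant at element centres: the mean
    of the four nodal differences along each axis, divided by the spacing.
    """
    phi = potential.phi
    if phi.shape != tuple(s + 1 for s in model.shape):
        raise ValueError(f"potential shape {phi.shape} does not match model grid {model.shape}")
    h = model.voxel_size_mm * MM
    E = np.empty(model.shape + (3,))
    for axis in range(3):
        d = np.diff(phi, axis=axis)
        for other in (ax for ax in range(3) if ax != axis):
            sl_lo = [slice(None)] * 3
            sl_hi = [slice(None)] * 3
            sl_lo[other] = slice(None, -1)
            sl_hi[other] = slice(1, None)
            d = 0.5 * (d[tuple(sl_lo)] + d[tuple(sl_hi)])
        E[..., axis] = -d / h
    return E


def sample_cortical(
    field: np.ndarray,
    mesh: CorticalSurfaceMesh,
    model: VoxelHeadModel,
    depth_mm: float = 1.0,
    space: str = "subject",
    method: str = "trilinear",
    tissue: str = "grey_matter",
) -> CorticalFieldMap:
    """Sample the element field at ``vertex + depth * inner_normal``.

    ``method="trilinear"`` (default) interpolates element-centre values;
    sample points must lie inside the grid (offending vertices are listed in
    the error).  ``method="restricted"`` instead inverse-distance-weights the
    interface-free elements of ``tissue`` within a ball of two voxel
    spacings: element fields next to a conductivity jump carry the jump's
    discretization noise, so excluding them is more robust on voxel models
    (at the price of effectively smoothing over ~2 voxels).
    """
    pts = mesh.vertices + depth_mm * mesh.inner_normals
    coords = [model.axis_coords(a) for a in range(3)]
    lo = np.array([c[0] for c in coords])
    hi = np.array([c[-1] for c in coords])
    bad = np.nonzero(np.any((pts < lo) | (pts > hi), axis=1))[0]
    if bad.size:
        raise ValueError(
            f"{bad.size} sample points outside the grid; first offenders: {bad[:10].tolist()}"
        )
    if method == "restricted":
        Ev = _sample_restricted(field, model, pts, tissue)
    elif method == "trilinear":
        interp = RegularGridInterpolator(coords, field, method="linear")
        Ev = interp(pts)
    else:
        raise ValueError(f"unknown sampling method {method!r}")
    e_abs = np.linalg.norm(Ev, axis=1)
    e_n = np.einsum("ij,ij->i", mesh.inner_normals, Ev)
    return CorticalFieldMap(e_abs=e_abs, e_n=e_n, depth_mm=depth_mm, space=space)


def _sample_restricted(field, model, pts, tissue):
    import scipy.ndimage as ndi
    from scipy.spatial import cKDTree

    lab = None
    for k, name in model.label_names.items():
        if name == tissue:
            lab = k
    if lab is None:
        raise ValueError(f"model has no {tissue!r} label")
    mask = model.labels == lab
    pure = ndi.minimum_filter(mask.astype(np.uint8), size=3).astype(bool)
    if not pure.any():
        raise ValueError(f"no interface-free {tissue!r} elements to sample from")
    centres = np.stack(
        np.meshgrid(*[model.axis_coords(a) for a in range(3)], indexing="ij"), axis=-1
    )[pure]
    values = field[pure]
    tree = cKDTree(centres)
    radius = 2.0 * model.voxel_size_mm
    out = np.empty((len(pts), 3))
    n_fallback = 0
    for i, p in enumerate(pts):
        ids = tree.query_ball_point(p, radius)
        if not ids:
            _, j = tree.query(p)
            ids = [j]
            n_fallback += 1
        d = np.linalg.norm(centres[ids] - p, axis=1)
        w = 1.0 / np.maximum(d, 1e-9) ** 2
        out[i] = (w[:, None] * values[ids]).sum(axis=0) / w.sum()
    if n_fallback:
        log.info("restricted sampling fell back to nearest element at %d points", n_fallback)
    return out


def map_and_average(
    maps: list[CorticalFieldMap],
) -> tuple[CorticalFieldMap, np.ndarray, np.ndarray]:
    """Stack subject maps (identity template correspondence) and average.

    Returns the vertex-wise mean map plus the cohort matrices
    (subjects x vertices) for ``E_abs`` and ``E_n``.
    """
    if not maps:
        raise ValueError("no maps given")
    n = {len(m.e_abs) for m in maps}
    if len(n) != 1:
        raise ValueError(f"inconsistent vertex counts: {sorted(n)}")
    abs_mat = np.vstack([m.e_abs for m in maps])
    n_mat = np.vstack([m.e_n for m in maps])
    mean_abs = abs_mat.mean(axis=0)
    mean_n = n_mat.mean(axis=0)
    # mean(E_abs) >= mean(|E_n|) >= |mean(E_n)|, so the map invariant holds
    mean_map = CorticalFieldMap(
        e_abs=mean_abs,
        e_n=mean_n,
        depth_mm=maps[0].depth_mm,
        space="template",
    )
    return mean_map, abs_mat, n_mat


def enclosed_current_ma(
    model: VoxelHeadModel,
    field: np.ndarray,
    tissues: TissueTable,
    lo: tuple[int, int, int],
    hi: tuple[int, int, int],
) -> float:
    """Net outward current (mA) through the faces of an element-index box.

    The flux on each face uses the conductivity and constant field of the
    element just inside the box; with a converged solve this conserves the
    current of any single enclosed electrode to discretization accuracy.
    """
    sigma = model.conductivity_grid(tissues)
    h = model.voxel_size_mm * MM
    area = h * h
    total = 0.0
    for axis in range(3):
        for side, sign in ((lo[axis], -1.0), (hi[axis] - 1, +1.0)):
            sl = [slice(l, u) for l, u in zip(lo, hi)]
            sl[axis] = side
            J = sigma[tuple(sl)] * field[tuple(sl) + (axis,)]
            total += sign * float(J.sum()) * area
    return total / MA
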