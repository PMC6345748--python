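"""Voxelized multi-layer head phantoms with sponge/rubber electrode pads.

The phantom stands in for segmented MRI: concentric spherical tissue shells
(scalp / skull / CSF / grey matter, optionally white matter) on a regular
voxel grid, with an optional sinusoidally perturbed grey-matter interface to
emulate gyral variability, and a two-compartment electrode model (saline
sponge + conductive rubber) conforming to the scalp.  Cohorts of phantoms
with randomized layer thicknesses emulate inter-individual anatomy.

Coordinates: voxel indices are 0-based; world coordinates are voxel-centre
millimetres with the origin at the sphere centre.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import nibabel as nib
import numpy as np
import pandas as pd

from .tissues import TissueTable

BACKGROUND_LABEL = 0  # non-conductive exterior (air); excluded from the FEM


@dataclass(frozen=True)
class ElectrodeMontage:
    """Two-pad montage: anode and cathode as geodesic square patches.

    Pad size is the arc-length side of the square patch on the scalp sphere;
    the thicknesses follow the two-compartment electrode model (6 mm saline
    sponge at 1.6 S/m carrying a 1 mm rubber pad at 0.1 S/m).  The source and
    sink currents (+I / -I, default 1 mA) are injected inside the rubber
    compartments.
    """

    anode_direction: tuple[float, float, float] = (0.0, 0.0, 1.0)
    cathode_direction: tuple[float, float, float] = (
        0.9396926207859084,  # 110 degrees from the anode, in the x-z plane
        0.0,
        -0.3420201433256687,
    )
    pad_size_mm: float = 50.0
    sponge_thickness_mm: float = 6.0
    rubber_thickness_mm: float = 1.0
    current_ma: float = 1.0


@dataclass(frozen=True)
class AnatomySpec:
    """Layer geometry of a spherical phantom.

    ``layers`` maps tissue names to outer radii (mm), ordered from the scalp
    inwards with strictly decreasing radii; the innermost layer fills the
    remaining core.  The optional gyral perturbation displaces the grey-matter
    outer interface radially by ``amplitude * cos(wavenumber * azimuth +
    phase) * sin(polar)**2``.
    """

    layers: tuple[tuple[str, float], ...] = (
        ("skin", 92.0),
        ("compact_bone", 85.0),
        ("csf", 79.0),
        ("grey_matter", 75.0),
    )
    gyral_amplitude_mm: float = 0.0
    gyral_wavenumber: int = 6
    gyral_phase: float = 0.0
    montage: ElectrodeMontage | None = field(default_factory=ElectrodeMontage)

    def __post_init__(self) -> None:
        radii = [r for _, r in self.layers]
        if len(radii) < 1:
            raise ValueError("at least one layer required")
        if any(b >= a for a, b in zip(radii, radii[1:])):
            raise ValueError("layer radii must be strictly decreasing")
        if self.gyral_amplitude_mm < 0:
            raise ValueError("gyral amplitude must be >= 0")
        if len(radii) >= 2 and self.gyral_amplitude_mm > 0:
            gaps = [a - b for a, b in zip(radii, radii[1:])]
            if self.gyral_amplitude_mm >= min(gaps):
                raise ValueError("gyral perturbation would invert layer order")

    @property
    def outer_radius(self) -> float:
        return self.layers[0][1]

    @property
    def grey_surface_radius(self) -> float:
        """Outer radius of the grey-matter layer (the cortical surface)."""
        for name, r in self.layers:
            if name == "grey_matter":
                return r
        raise ValueError("spec has no grey_matter layer")

    def to_config(self) -> dict:
        d = dataclasses.asdict(self)
        d["layers"] = [[n, float(r)] for n, r in self.layers]
        if self.montage is not None:
            d["montage"] = dataclasses.asdict(self.montage)
        return d

    @classmethod
    def from_config(cls, d: dict) -> "AnatomySpec":
        d = dict(d)
        d["layers"] = tuple((str(n), float(r)) for n, r in d["layers"])
        if d.get("montage") is not None:
            m = dict(d["montage"])
            m["anode_direction"] = tuple(m["anode_direction"])
            m["cathode_direction"] = tuple(m["cathode_direction"])
            d["montage"] = ElectrodeMontage(**m)
        return cls(**d)


@dataclass
class Electrode:
    """One attached pad: compartment labels and its signed injected current."""

    name: str
    current_ma: float
    rubber_label: int
    sponge_label: int


@dataclass
class VoxelHeadModel:
    """Tissue-label voxel grid plus electrode compartments and sources.

    ``labels`` holds integer labels (0 = exterior air); ``label_names`` maps
    each nonzero label to a tissue in the conductivity table.  Sources are
    either pad electrodes (current lumped onto the nodes of the rubber
    compartment) or explicit nodal point currents, used when validating the
    solver against the analytic sphere solution.
    """

    labels: np.ndarray
    voxel_size_mm: float
    origin_mm: np.ndarray  # world coordinate of voxel (0,0,0) centre
    label_names: dict[int, str]
    electrodes: list[Electrode] = field(default_factory=list)
    point_sources: list[tuple[tuple[int, int, int], float]] = field(
        default_factory=list
    )  # (node index triple, current mA)
    spec: AnatomySpec | None = None

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.labels.shape

    def axis_coords(self, axis: int) -> np.ndarray:
        """World coordinates of voxel centres along one axis (mm)."""
        n = self.labels.shape[axis]
        return self.origin_mm[axis] + self.voxel_size_mm * np.arange(n)

    def node_coords(self, axis: int) -> np.ndarray:
        """World coordinates of grid nodes (element corners) along one axis."""
        n = self.labels.shape[axis] + 1
        return self.origin_mm[axis] - 0.5 * self.voxel_size_mm + self.voxel_size_mm * np.arange(n)

    def voxel_centres(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        return tuple(self.axis_coords(a) for a in range(3))  # type: ignore[return-value]

    def total_current_ma(self) -> float:
        s = sum(e.current_ma for e in self.electrodes)
        s += sum(c for _, c in self.point_sources)
        return s

    def conductivity_grid(self, tissues: TissueTable) -> np.ndarray:
        """Per-voxel conductivity (S/m); 0 for the exterior."""
        max_label = int(self.labels.max(initial=0))
        lut = np.zeros(max_label + 1)
        for lab, name in self.label_names.items():
            if name not in tissues:
                raise KeyError(f"tissue {name!r} (label {lab}) not in table")
            lut[lab] = tissues[name]
        return lut[self.labels]

    # -- NIfTI round trip -------------------------------------------------
    def to_nifti(self) -> nib.Nifti1Image:
        affine = np.diag([self.voxel_size_mm] * 3 + [1.0])
        affine[:3, 3] = self.origin_mm
        return nib.Nifti1Image(self.labels.astype(np.int16), affine)

    def save(self, path: str) -> None:
        nib.save(self.to_nifti(), path)

    @classmethod
    def from_nifti(cls, img: nib.Nifti1Image, label_names: dict[int, str]) -> "VoxelHeadModel":
        affine = np.asarray(img.affine)
        h = float(affine[0, 0])
        if not np.allclose(np.diag(affine)[:3], h):
            raise ValueError("expected isotropic diagonal affine")
        return cls(
            labels=np.asanyarray(img.dataobj).astype(np.int16),
            voxel_size_mm=h,
            origin_mm=affine[:3, 3].copy(),
            label_names=dict(label_names),
        )


def _radius_grid(model_shape, origin, h):
    xs = origin[0] + h * np.arange(model_shape[0])
    ys = origin[1] + h * np.arange(model_shape[1])
    zs = origin[2] + h * np.arange(model_shape[2])
    X, Y, Z = np.meshgrid(xs, ys, zs, indexing="ij", sparse=True)
    return X, Y, Z


def gyral_offset(spec: AnatomySpec, x, y, z, r):
    """Radial displacement of the grey interface at direction (x,y,z)/r."""
    if spec.gyral_amplitude_mm == 0:
        return 0.0
    with np.errstate(invalid="ignore", divide="ignore"):
        az = np.arctan2(y, x)
        sin_polar_sq = np.where(r > 0, (x**2 + y**2) / np.maximum(r**2, 1e-30), 0.0)
    return spec.gyral_amplitude_mm * np.cos(spec.gyral_wavenumber * az + spec.gyral_phase) * sin_polar_sq


def build_layered_head(
    spec: AnatomySpec,
    voxel_size_mm: float,
    tissues: TissueTable | None = None,
    pad_margin_mm: float | None = None,
) -> VoxelHeadModel:
    """Voxelize the layered sphere of ``spec`` on a regular grid.

    Each voxel centre is assigned the innermost shell containing it; the
    exterior is labelled 0 (non-conductive, excluded from the FEM system).
    The grid leaves room above the scalp for electrode pads.
    """
    tissues = tissues or TissueTable()
    if voxel_size_mm <= 0:
        raise ValueError("voxel size must be > 0")
    radii = np.array([r for _, r in spec.layers])
    names = [n for n, _ in spec.layers]
    thicknesses = -np.diff(radii)
    if thicknesses.size and voxel_size_mm > thicknesses.min():
        raise ValueError(
            f"unresolvable layer: voxel size {voxel_size_mm} mm exceeds the "
            f"thinnest shell ({thicknesses.min():.3f} mm)"
        )
    for n in names:
        if n not in tissues:
            raise KeyError(f"layer tissue {n!r} not in conductivity table")

    if pad_margin_mm is None:
        m = spec.montage
        pad_margin_mm = (
            (m.sponge_thickness_mm + m.rubber_thickness_mm + voxel_size_mm) if m else voxel_size_mm
        )
    half = spec.outer_radius + pad_margin_mm
    n_half = int(np.ceil(half / voxel_size_mm))
    n = 2 * n_half + 1  # odd count; centre voxel at the origin
    origin = np.full(3, -n_half * voxel_size_mm)

    X, Y, Z = _radius_grid((n, n, n), origin, voxel_size_mm)
    R = np.sqrt(X**2 + Y**2 + Z**2)

    grey_r = spec.grey_surface_radius if "grey_matter" in names else None
    labels = np.zeros((n, n, n), dtype=np.int16)
    # innermost shell containing the voxel = last layer whose (possibly
    # perturbed) outer radius still encloses it
    offset = gyral_offset(spec, X, Y, Z, R) if spec.gyral_amplitude_mm else 0.0
    for i, (name, r_out) in enumerate(spec.layers):
        r_eff = r_out + offset if (grey_r is not None and name == "grey_matter") else r_out
        labels[R <= r_eff] = i + 1

    label_names = {i + 1: name for i, name in enumerate(names)}
    return VoxelHeadModel(
        labels=labels,
        voxel_size_mm=float(voxel_size_mm),
        origin_mm=origin,
        label_names=label_names,
        spec=spec,
    )


def _pad_masks(model: VoxelHeadModel, direction, montage: ElectrodeMontage):
    """Sponge and rubber voxel masks for one pad centred on ``direction``."""
    d = np.asarray(direction, dtype=float)
    nd = np.linalg.norm(d)
    if nd == 0:
        raise ValueError("pad centre direction must be nonzero")
    d = d / nd
    spec = model.spec
    if spec is None:
        raise ValueError("model lacks an AnatomySpec; cannot locate the scalp")
    R = spec.outer_radius
    h = model.voxel_size_mm

    X, Y, Z = _radius_grid(model.shape, model.origin_mm, h)
    r = np.sqrt(X**2 + Y**2 + Z**2)
    with np.errstate(invalid="ignore", divide="ignore"):
        ux, uy, uz = X / r, Y / r, Z / r
    cosang = ux * d[0] + uy * d[1] + uz * d[2]

    # orthonormal tangent frame for the geodesic square footprint
    ref = np.array([0.0, 0.0, 1.0])
    if abs(d @ ref) > 0.9:
        ref = np.array([1.0, 0.0, 0.0])
    e1 = np.cross(d, ref)
    e1 /= np.linalg.norm(e1)
    e2 = np.cross(d, e1)
    t1 = R * np.arctan2(ux * e1[0] + uy * e1[1] + uz * e1[2], cosang)
    t2 = R * np.arctan2(ux * e2[0] + uy * e2[1] + uz * e2[2], cosang)
    half_side = montage.pad_size_mm / 2.0
    in_footprint = (cosang > 0) & (np.abs(t1) <= half_side) & (np.abs(t2) <= half_side)

    sponge_hi = R + montage.sponge_thickness_mm
    rubber_hi = sponge_hi + montage.rubber_thickness_mm
    exterior = model.labels == BACKGROUND_LABEL
    sponge = in_footprint & exterior & (r > R) & (r <= sponge_hi)
    rubber = in_footprint & exterior & (r > sponge_hi) & (r <= rubber_hi)
    if not sponge.any() or not rubber.any():
        raise ValueError("pad footprint produced an empty compartment; centre off scalp?")
    return sponge, rubber


def attach_electrodes(model: VoxelHeadModel, montage: ElectrodeMontage | None = None) -> VoxelHeadModel:
    """Attach sponge+rubber pads and register the +-I mA sources.

    Returns a new model; the anode carries +I and the cathode -I so the total
    injected current is exactly zero.
    """
    montage = montage or (model.spec.montage if model.spec else None)
    if montage is None:
        raise ValueError("no montage given and the model's spec has none")

    labels = model.labels.copy()
    next_label = int(labels.max()) + 1
    label_names = dict(model.label_names)
    electrodes: list[Electrode] = []
    masks = []
    for name, direction, current in (
        ("anode", montage.anode_direction, +montage.current_ma),
        ("cathode", montage.cathode_direction, -montage.current_ma),
    ):
        sponge, rubber = _pad_masks(model, direction, montage)
        masks.append(sponge | rubber)
        sponge_label, rubber_label = next_label, next_label + 1
        next_label += 2
        labels[sponge] = sponge_label
        labels[rubber] = rubber_label
        label_names[sponge_label] = "sponge"
        label_names[rubber_label] = "rubber"
        electrodes.append(Electrode(name, current, rubber_label, sponge_label))
    if (masks[0] & masks[1]).any():
        raise ValueError("electrode pads overlap")

    return VoxelHeadModel(
        labels=labels,
        voxel_size_mm=model.voxel_size_mm,
        origin_mm=model.origin_mm.copy(),
        label_names=label_names,
        electrodes=electrodes,
        point_sources=list(model.point_sources),
        spec=model.spec,
    )


@dataclass(frozen=True)
class CohortVariability:
    """Per-parameter SDs of the cohort's anatomical draws (mm / radians).

    Defaults are the calibration constants that make the downstream spread of
    the cortical normal field bracket the 0.20-0.60 V/m range observed in
    individualized models of a real cohort.
    """

    scalp_thickness_sd: float = 0.8
    skull_thickness_sd: float = 1.6
    csf_thickness_sd: float = 1.0
    gyral_amplitude_sd: float = 0.8
    min_thickness_mm: float = 2.0  # keeps drawn shells resolvable at the default voxel size

    def __post_init__(self) -> None:
        for f in dataclasses.fields(self):
            if getattr(self, f.name) < 0:
                raise ValueError(f"{f.name} must be >= 0")


def draw_cohort_specs(
    n_subjects: int,
    variability: CohortVariability | None = None,
    seed: int = 0,
    base_spec: AnatomySpec | None = None,
) -> tuple[list[AnatomySpec], pd.DataFrame]:
    """Draw per-subject anatomy specs; returns specs plus a manifest table."""
    if n_subjects < 1:
        raise ValueError("n_subjects must be >= 1")
    variability = variability or CohortVariability()
    base = base_spec or AnatomySpec()
    rng = np.random.default_rng(seed)

    names = [n for n, _ in base.layers]
    radii = np.array([r for _, r in base.layers])
    base_thick = -np.diff(radii)  # thickness of each shell except the core
    sd_by_name = {
        "skin": variability.scalp_thickness_sd,
        "compact_bone": variability.skull_thickness_sd,
        "spongy_bone": variability.skull_thickness_sd,
        "csf": variability.csf_thickness_sd,
    }
    specs, rows = [], []
    for s in range(n_subjects):
        thick = base_thick.copy()
        for i, name in enumerate(names[:-1]):
            sd = sd_by_name.get(name, 0.0)
            t = thick[i] + rng.normal(0.0, sd) if sd > 0 else thick[i]
            thick[i] = max(t, variability.min_thickness_mm)  # truncate: keep layer order
        if np.any(thick <= 0):
            raise ValueError("variability produced inverted layers after truncation")
        new_radii = [radii[0]]
        for t in thick:
            new_radii.append(new_radii[-1] - t)
        amp = abs(rng.normal(0.0, variability.gyral_amplitude_sd))
        gaps = -np.diff(new_radii)
        amp = min(amp, 0.45 * gaps.min()) if gaps.size else 0.0
        phase = rng.uniform(0, 2 * np.pi)
        spec = AnatomySpec(
            layers=tuple((n, float(r)) for n, r in zip(names, new_radii[:-1] + [new_radii[-1]])),
            gyral_amplitude_mm=float(amp),
            gyral_wavenumber=base.gyral_wavenumber,
            gyral_phase=float(phase),
            montage=base.montage,
        )
        specs.append(spec)
        rows.append(
            {
                "subject": s,
                "seed": seed,
                **{f"radius_{n}": r for n, r in spec.layers},
                "gyral_amplitude_mm": amp,
                "gyral_phase": phase,
            }
        )
    return specs, pd.DataFrame(rows)


def generate_cohort(
    n_subjects: int,
    variability: CohortVariability | None = None,
    seed: int = 0,
    base_spec: AnatomySpec | None = None,
    voxel_size_mm: float = 2.0,
    tissues: TissueTable | None = None,
    with_electrodes: bool = True,
) -> list[tuple[VoxelHeadModel, AnatomySpec]]:
    """Generate a cohort of voxel phantoms with inter-individual anatomy.

    Drawn shell thicknesses are truncated below at the voxel size so every
    phantom stays resolvable on the requested grid.
    """
    variability = variability or CohortVariability()
    floor = max(variability.min_thickness_mm, voxel_size_mm)
    variability = dataclasses.replace(variability, min_thickness_mm=floor)
    specs, _ = draw_cohort_specs(n_subjects, variability, seed, base_spec)
    out = []
    for spec in specs:
        model = build_layered_head(spec, voxel_size_mm, tissues)
        if with_electrodes and spec.montage is not None:
            model = attach_electrodes(model)
        out.append((model, spec))
    return out
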