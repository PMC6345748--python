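"""Validation experiments: solver-vs-oracle agreement and statistical calibration.

These routines run the package end-to-end under controlled conditions and
return the measured figures of merit.  They back both the acceptance
checks and the accuracy numbers quoted in the methods note.
"""

from __future__ import annotations

import numpy as np

from . import fem, fields, mep, phantom, pls, sphere, synth


def _point_source_model(spec, voxel_size_mm, source_radius_mm, separation_deg):
    """Phantom with nodal point sources under the pad centres, plus the
    matching oracle source positions (snapped to grid nodes)."""
    model = phantom.build_layered_head(
        phantom.AnatomySpec(layers=spec.layers, montage=None), voxel_size_mm
    )
    th = np.deg2rad(separation_deg)
    positions = [
        np.array([0.0, 0.0, source_radius_mm]),
        source_radius_mm * np.array([np.sin(th), 0.0, np.cos(th)]),
    ]
    nodes, world = [], []
    for p in positions:
        n = tuple(
            int(round((p[a] - model.node_coords(a)[0]) / voxel_size_mm)) for a in range(3)
        )
        nodes.append(n)
        world.append(np.array([model.node_coords(a)[n[a]] for a in range(3)]))
    model.point_sources = [(nodes[0], 1.0), (nodes[1], -1.0)]
    return model, world


def fem_oracle_comparison(
    voxel_sizes_mm=(4.0, 3.0, 2.0),
    spec: phantom.AnatomySpec | None = None,
    subdivisions: int = 3,
    depth_mm: float = 1.0,
    source_radius_mm: float = 88.0,
    separation_deg: float = 110.0,
    n_terms: int = 400,
    sampling_method: str = "trilinear",
) -> dict[float, float]:
    """Relative RMS error of |E| on the cortical sampling surface, per voxel size.

    The FEM uses nodal point currents at the oracle's source positions so
    both sides solve the same boundary-value problem; the comparison is the
    sampled cortical map (default: the production trilinear sampling at the
    1 mm depth).
    """
    spec = spec or phantom.AnatomySpec()
    tissues_by_layer = [n for n, _ in spec.layers]
    from .tissues import TissueTable

    table = TissueTable()
    out = {}
    for h in voxel_sizes_mm:
        model, world = _point_source_model(spec, h, source_radius_mm, separation_deg)
        pot = fem.solve(fem.assemble_system(model, table))
        E = fields.electric_field(pot, model)
        mesh = fields.CorticalSurfaceMesh.icosphere_template(
            subdivisions, spec.grey_surface_radius
        )
        fmap = fields.sample_cortical(E, mesh, model, depth_mm, method=sampling_method)
        ospec = sphere.SphereLayerSpec(
            radii_mm=tuple(r for _, r in spec.layers),
            conductivities=tuple(table[n] for n in tissues_by_layer),
            sources=((tuple(world[0]), 1.0), (tuple(world[1]), -1.0)),
            n_terms=n_terms,
        )
        _, E_o = sphere.analytic_potential_and_field(
            ospec, mesh.vertices + depth_mm * mesh.inner_normals
        )
        e_o = np.linalg.norm(E_o, axis=1)
        out[h] = float(
            np.sqrt(np.mean((fmap.e_abs - e_o) ** 2)) / np.sqrt(np.mean(e_o**2))
        )
    return out


def sham_q2_rate(
    n_datasets: int = 200,
    n_subjects: int = 27,
    n_vertices: int = 300,
    r_e_percent: float = 10.0,
    folds: int = 10,
    cv_reps: int = 50,
    seed: int = 0,
) -> float:
    """Fraction of signal-free datasets whose first PLS component is flagged
    NOT predictively significant (the sham-condition behaviour)."""
    rng = np.random.default_rng(seed)
    verts = rng.normal(size=(n_vertices, 3))
    verts = 75.0 * verts / np.linalg.norm(verts, axis=1, keepdims=True)
    nonsig = 0
    for k in range(n_datasets):
        _, e_n = synth.synthetic_field_cohort(
            n_subjects, verts, seed=int(rng.integers(2**31))
        )
        y = rng.normal(1.0, 0.3, size=n_subjects)  # unrelated to the fields
        block = pls.select_vertices(e_n, "e_n", r_e_percent)
        _, sig = pls.cross_validate_q2(
            block, y, 1, folds=folds, reps=cv_reps, seed=int(rng.integers(2**31))
        )
        nonsig += not bool(sig[0])
    return nonsig / n_datasets


def calibration_suite(reps: int = 2000, seed: int = 0, alpha: float = 0.05) -> dict:
    """Type-I error of the LRT, contrast F, paired t and Wilcoxon tests.

    Null generators: random-intercept Gaussian data with the tested
    fixed-effect block truly zero (LRT and F), and paired standard-normal
    samples with no shift (t and Wilcoxon).
    """
    rng = np.random.default_rng(seed)
    m, k_obs = 30, 4
    g = np.repeat(np.arange(m), k_obs)
    n = m * k_obs

    lrt_hits = f_hits = 0
    for _ in range(reps):
        X0 = np.column_stack([np.ones(n), rng.normal(size=n)])
        Xe = np.column_stack([X0, rng.normal(size=(n, 2))])
        y = X0 @ [1.0, 0.5] + rng.normal(0, 0.5, m)[g] + rng.normal(size=n)
        f0 = fit0 = mep.fit_lme(y, X0, g, ["i", "x"])
        f1 = mep.fit_lme(y, Xe, g, ["i", "x", "z1", "z2"])
        lrt_hits += mep.likelihood_ratio_test(f0, f1)[2] < alpha
        L = np.zeros((2, 4))
        L[0, 2] = 1.0
        L[1, 3] = 1.0
        f_hits += mep.contrast_ftest(f1, L)[3] < alpha

    t_hits = w_hits = 0
    n_pair = 30
    for _ in range(reps):
        a, b = rng.normal(size=(2, n_pair))
        res = mep.paired_compare(a, b)
        t_hits += res["t_p"] < alpha
        w_hits += res["wilcoxon_p"] < alpha

    return {
        "lrt": lrt_hits / reps,
        "contrast_f": f_hits / reps,
        "paired_t": t_hits / reps,
        "wilcoxon": w_hits / reps,
        "reps": reps,
    }


def wilcoxon_exact_vs_enumeration(n: int = 8, seed: int = 5) -> float:
    """Absolute difference between the exact Wilcoxon p and brute-force
    enumeration over all sign patterns (zero for a correct implementation)."""
    from scipy import stats as sps

    rng = np.random.default_rng(seed)
    d = rng.normal(size=n)
    while len(np.unique(np.abs(d))) < n or np.any(d == 0):
        d = rng.normal(size=n)
    res = mep.paired_compare(d + 1.0, np.ones(n))
    ranks = sps.rankdata(np.abs(d))
    w_obs = ranks[d > 0].sum()
    total = ranks.sum()
    ws = np.array(
        [sum(ranks[i] for i in range(n) if mask >> i & 1) for mask in range(2**n)]
    )
    p_exact = float(np.mean(np.minimum(ws, total - ws) <= min(w_obs, total - w_obs)))
    return abs(res["wilcoxon_p"] - p_exact)
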