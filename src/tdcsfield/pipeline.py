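"""End-to-end orchestration: phantoms -> fields -> PLS -> mixed models.

`run_pipeline` executes the whole chain on a synthetic cohort with one
master seed: generate anatomically varied phantoms, solve the
volume-conductor problem per subject, extract cortical field maps on the
shared template, synthesize MEP responses from the extracted fields with
the known dose-response law, run the PLS region discovery over the r_E
ladder and both field types, locate the observation point, and fit the
mixed-effects dose-response models.  `serialize_results` writes the bundle
with a checksummed manifest so reruns can be verified byte-for-byte.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import fem, fields, mep, phantom, pls, synth
from .tissues import TissueTable

log = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Configuration of a full synthetic-cohort run.

    Defaults materialize the reference settings: 1 mA pads, 1e-6 solver
    residual, 1 mm sampling depth, the r_E ladder 1/2/3/10 %, 10-fold
    cross-validation.  ``cv_reps`` and cohort/grid sizes are scaled in tests
    for runtime.
    """

    n_subjects: int = 27
    voxel_size_mm: float = 2.0
    mesh_subdivisions: int = 3
    solver_tol: float = 1e-6
    sampling_depth_mm: float = 1.0
    sampling_method: str = "trilinear"
    r_e_ladder: tuple[float, ...] = (1.0, 2.0, 3.0, 10.0)
    n_pls_components: int = 3
    cv_folds: int = 10
    cv_reps: int = 1000
    seed: int = 7
    base_spec: phantom.AnatomySpec = field(default_factory=phantom.AnatomySpec)
    variability: phantom.CohortVariability = field(default_factory=phantom.CohortVariability)
    generative: synth.GenerativeParams = field(default_factory=synth.GenerativeParams)
    recovery_replicates: int = 0  # optional extra recovery experiment

    _known = None

    def __post_init__(self) -> None:
        if self.cv_folds > self.n_subjects:
            raise ValueError("cv_folds cannot exceed n_subjects")

    def to_config(self) -> dict:
        d = dataclasses.asdict(self)
        d["base_spec"] = self.base_spec.to_config()
        return d

    @classmethod
    def from_config(cls, d: dict) -> "RunConfig":
        d = dict(d)
        known = {f.name for f in dataclasses.fields(cls)}
        bad = set(d) - known
        if bad:
            raise ValueError(f"invalid config keys: {sorted(bad)}")
        if "base_spec" in d:
            d["base_spec"] = phantom.AnatomySpec.from_config(d["base_spec"])
        if "variability" in d and isinstance(d["variability"], dict):
            d["variability"] = phantom.CohortVariability(**d["variability"])
        if "generative" in d and isinstance(d["generative"], dict):
            gen = dict(d["generative"])
            if "e_n_range" in gen:
                gen["e_n_range"] = tuple(gen["e_n_range"])
            d["generative"] = synth.GenerativeParams(**gen)
        for key in ("r_e_ladder",):
            if key in d:
                d[key] = tuple(d[key])
        return cls(**d)


def _stage(name):
    log.info("stage: %s", name)
    return time.time()


def run_pipeline(config: RunConfig, tissues: TissueTable | None = None) -> dict:
    """Run all stages; returns the result bundle (plain dicts/frames/arrays)."""
    tissues = tissues or TissueTable()
    rng = np.random.default_rng(config.seed)
    seeds = {name: int(rng.integers(2**31)) for name in ("cohort", "mep", "pls", "recovery")}
    timings = {}

    t = _stage("phantom cohort")
    variability = dataclasses.replace(
        config.variability,
        min_thickness_mm=max(config.variability.min_thickness_mm, config.voxel_size_mm),
    )
    specs, manifest = phantom.draw_cohort_specs(
        config.n_subjects, variability, seeds["cohort"], config.base_spec
    )
    timings["phantom"] = time.time() - t

    t = _stage("solve + extract")
    mesh = fields.CorticalSurfaceMesh.icosphere_template(
        config.mesh_subdivisions, radius_mm=specs[0].grey_surface_radius
    )
    maps = []
    diagnostics = []
    for i, spec in enumerate(specs):
        model = phantom.build_layered_head(spec, config.voxel_size_mm, tissues)
        model = phantom.attach_electrodes(model)
        system = fem.assemble_system(model, tissues)
        pot = fem.solve(system, tol=config.solver_tol)
        E = fields.electric_field(pot, model)
        subj_mesh = fields.CorticalSurfaceMesh(
            vertices=mesh.vertices * (spec.grey_surface_radius / specs[0].grey_surface_radius),
            faces=mesh.faces,
            inner_normals=mesh.inner_normals,
        )
        fmap = fields.sample_cortical(
            E, subj_mesh, model, config.sampling_depth_mm, method=config.sampling_method
        )
        maps.append(fmap)
        diagnostics.append(pot.diagnostics())
        log.info("subject %d: residual %.2e", i, pot.relative_residual)
    mean_map, cohort_abs, cohort_n = fields.map_and_average(maps)
    timings["fields"] = time.time() - t

    t = _stage("mep synthesis")
    planted_vertex = int(np.argmax(np.abs(cohort_n).mean(axis=0)))
    e_n_values = cohort_n[:, planted_vertex]
    dataset = synth.generate_cohort_mep(
        config.generative,
        e_n_values=e_n_values,
        n_subjects=config.n_subjects,
        seed=seeds["mep"],
    )
    mn = mep.mean_normalized_mep(dataset)
    timings["mep"] = time.time() - t

    t = _stage("pls ladder")
    y_real = (
        mn[mn["session"] == "real"].sort_values("subject")["mean_norm_mep"].to_numpy()
    )
    y_sham = (
        mn[mn["session"] == "sham"].sort_values("subject")["mean_norm_mep"].to_numpy()
    )
    table_rows = []
    for field_type, matrix in (("e_abs", cohort_abs), ("e_n", cohort_n)):
        for r_e in config.r_e_ladder:
            for session, y in (("real", y_real), ("sham", y_sham)):
                block = pls.select_vertices(matrix, field_type, r_e)
                n = block.x.shape[0]
                n_train_min = n - int(np.ceil(n / config.cv_folds))
                a = max(1, min(config.n_pls_components, block.x.shape[1], n_train_min - 1))
                model_pls = pls.fit_pls1(block, y, a)
                q2, sig = pls.cross_validate_q2(
                    block, y, a, config.cv_folds, config.cv_reps, seeds["pls"]
                )
                row = {"field": field_type, "r_e": r_e, "session": session}
                for j in range(a):
                    row[f"r2_{j + 1}"] = float(model_pls.r2[j])
                    row[f"q2_{j + 1}"] = float(q2[j])
                    row[f"significant_{j + 1}"] = bool(sig[j])
                table_rows.append(row)
    pls_table = pd.DataFrame(table_rows)

    vip_block = pls.select_vertices(cohort_n, "e_n", 2.0)
    a = min(1, vip_block.x.shape[1])
    vip_model = pls.fit_pls1(vip_block, y_real, 1)
    vip = pls.vip_scores(vip_model)
    r0 = pls.observation_point(vip, vip_block.vertex_ids)
    timings["pls"] = time.time() - t

    t = _stage("mixed models")
    dataset.covariates["e_n_r0"] = cohort_n[:, r0]
    models = mep.fit_mep_models(dataset, covariate="e_n_r0")
    mn_cov = mn.merge(dataset.covariates, left_on="subject", right_index=True)
    real = mn_cov[mn_cov["session"] == "real"]
    regression = mep.simple_regression(real["e_n_r0"].to_numpy(), real["mean_norm_mep"].to_numpy())
    timings["lme"] = time.time() - t

    recovery = None
    if config.recovery_replicates:
        t = _stage("recovery")
        recovery = synth.recovery_experiment(
            config.generative,
            n_subjects=config.n_subjects,
            replicates=config.recovery_replicates,
            seed=seeds["recovery"],
        )
        timings["recovery"] = time.time() - t

    return {
        "config": config.to_config(),
        "cohort_manifest": manifest,
        "mesh": mesh,
        "mean_map": mean_map,
        "cohort_e_abs": cohort_abs,
        "cohort_e_n": cohort_n,
        "solver_diagnostics": diagnostics,
        "mep_dataset": dataset,
        "mean_normalized": mn,
        "pls_table": pls_table,
        "vip": vip,
        "vip_vertex_ids": vip_block.vertex_ids,
        "r0": r0,
        "planted_vertex": planted_vertex,
        "lme": {
            "lrt": models["lrt"],
            "coefficients": models["fit_with_covariate"].summary().to_dict(),
            "sigma2_intercept": models["fit_with_covariate"].sigma2_intercept,
            "sigma2_residual": models["fit_with_covariate"].sigma2_residual,
        },
        "regression": {
            "intercept": regression.intercept,
            "slope": regression.slope,
            "intercept_ci": regression.intercept_ci,
            "slope_ci": regression.slope_ci,
            "pearson_r": regression.pearson_r,
            "p_value": regression.p_value,
            "m": regression.e_n_mean,
        },
        "recovery": recovery,
        "timings": timings,
    }


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def serialize_results(bundle: dict, directory: str) -> dict:
    """Write the bundle's artefacts plus a checksummed manifest.

    Floating-point tables are written at full precision, so a rerun with the
    same config and seed reproduces every file byte-for-byte.
    """
    out = Path(directory)
    out.mkdir(parents=True, exist_ok=True)
    written: dict[str, str] = {}

    def save_json(name, obj):
        p = out / name
        p.write_text(json.dumps(obj, indent=2, sort_keys=True, default=_jsonable))
        written[name] = _sha256(p)

    def save_csv(name, frame):
        p = out / name
        frame.to_csv(p, index=False)  # default float repr round-trips exactly
        written[name] = _sha256(p)

    if not bundle:
        manifest = {"files": {}, "complete": True}
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
        return manifest

    complete = True
    try:
        save_json("config.json", bundle["config"])
        save_csv("cohort_manifest.csv", bundle["cohort_manifest"])
        save_csv("pls_table.csv", bundle["pls_table"])
        save_csv("mean_normalized_mep.csv", bundle["mean_normalized"])
        save_csv("mep_data.csv", bundle["mep_dataset"].data)
        save_csv(
            "vip.csv",
            pd.DataFrame({"vertex": bundle["vip_vertex_ids"], "vip": bundle["vip"]}),
        )
        save_json(
            "lme.json",
            {
                "lrt": bundle["lme"]["lrt"],
                "sigma2_intercept": bundle["lme"]["sigma2_intercept"],
                "sigma2_residual": bundle["lme"]["sigma2_residual"],
                "r0": bundle["r0"],
                "planted_vertex": bundle["planted_vertex"],
            },
        )
        save_json("regression.json", bundle["regression"])
        if bundle.get("recovery"):
            save_json("recovery.json", bundle["recovery"])
        save_csv("mean_field_map.csv", bundle["mean_map"].to_frame())
        bundle["mesh"].save_ply(str(out / "template_mesh.ply"))
        written["template_mesh.ply"] = _sha256(out / "template_mesh.ply")
    except Exception:
        complete = False
        raise
    finally:
        manifest = {"files": written, "complete": complete}
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest


def verify_manifest(directory: str) -> bool:
    """Re-hash the written artefacts against the manifest."""
    out = Path(directory)
    manifest = json.loads((out / "manifest.json").read_text())
    for name, digest in manifest["files"].items():
        if _sha256(out / name) != digest:
            return False
    return bool(manifest.get("complete", False))


def _jsonable(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON serializable: {type(obj)}")
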