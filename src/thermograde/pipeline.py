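"""Config-driven end-to-end runner: thermal solve → grading → structural
solve → probe report → mode comparison.

A run is fully described by a YAML/JSON config; all outputs land in one
directory together with a manifest (file list + SHA-256 checksums) and a log
that echoes the resolved config, so a run can be audited and repeated.
Every solver path is deterministic, so re-running a config reproduces the
CSV reports byte for byte.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field as dc_field
from pathlib import Path

import numpy as np
import yaml

from . import elasticity, grading, meshio, strain, thermal
from .grading import GPA, ModulusTemperatureMap, RegionTable
from .mesh import TetMesh

log = logging.getLogger("thermograde")

MODES = ("uniform_isotropic", "regional_isotropic", "thermally_graded")


class ConfigError(ValueError):
    """Raised when a run configuration is invalid."""


@dataclass
class RunConfig:
    """Validated run configuration with defaults resolved."""

    mesh: Path
    modes: list[str]
    loads: Path
    constraints: Path
    probes: Path | None = None
    material_table: Path | None = None
    seeds: Path | None = None
    anchor_modulus_pa: float = grading.DEFAULT_ANCHOR_MODULUS_PA
    anchor_temperature_c: float = grading.DEFAULT_ANCHOR_TEMPERATURE_C
    map_mode: str = "proportional"
    map_intercept_pa: float = 0.0
    conductivity: float = 1.0
    nu_policy: float | str = 0.28
    grade_trabecular: bool = False
    patch_radius: float = 0.0
    probe_mode: str = "containing_element"
    output_dir: Path = Path("thermograde_out")
    log_level: str = "INFO"

    def emap(self) -> ModulusTemperatureMap:
        return ModulusTemperatureMap(
            self.anchor_modulus_pa, self.anchor_temperature_c,
            self.map_mode, self.map_intercept_pa,
        )


def _load_config_dict(path: str | Path) -> dict:
    path = Path(path)
    text = path.read_text()
    try:
        if path.suffix.lower() == ".json":
            return json.loads(text)
        return yaml.safe_load(text)
    except (yaml.YAMLError, json.JSONDecodeError) as exc:
        mark = getattr(exc, "problem_mark", None)
        where = f" at line {mark.line + 1}, column {mark.column + 1}" if mark else ""
        raise ConfigError(f"{path}: cannot parse config{where}: {exc}") from exc


def validate_config(path: str | Path) -> tuple[RunConfig | None, list[str]]:
    """Parse and validate a config file.

    Returns ``(config, errors)``; ``config`` is None when errors prevent a
    run.  Moduli may be given in GPa (key ``anchor_modulus_gpa``) and are
    converted to Pa.
    """
    raw = _load_config_dict(path)
    if not isinstance(raw, dict):
        raise ConfigError(f"{path}: config must be a mapping")
    base = Path(path).parent
    errors: list[str] = []

    def resolve(key, required=False):
        v = raw.get(key)
        if v is None:
            if required:
                errors.append(f"missing required key {key!r}")
            return None
        p = Path(v)
        p = p if p.is_absolute() else base / p
        if not p.exists():
            errors.append(f"{key}: file not found: {p}")
        return p

    mesh_p = resolve("mesh", required=True)
    loads_p = resolve("loads", required=True)
    bc_p = resolve("constraints", required=True)
    probes_p = resolve("probes")
    table_p = resolve("material_table")
    seeds_p = resolve("seeds")

    modes = raw.get("modes") or [raw.get("mode", "uniform_isotropic")]
    if isinstance(modes, str):
        modes = [modes]
    for m in modes:
        if m not in MODES:
            errors.append(f"unknown mode {m!r}; choose from {MODES}")
    if "regional_isotropic" in modes and table_p is None:
        errors.append("regional_isotropic mode requires 'material_table'")
    if "thermally_graded" in modes and seeds_p is None:
        errors.append("thermally_graded mode requires 'seeds'")

    anchor_E = raw.get("anchor_modulus_pa")
    if anchor_E is None and "anchor_modulus_gpa" in raw:
        anchor_E = float(raw["anchor_modulus_gpa"]) * GPA
    if anchor_E is None:
        anchor_E = grading.DEFAULT_ANCHOR_MODULUS_PA
    intercept = raw.get("map_intercept_pa", 0.0)
    if "map_intercept_gpa" in raw:
        intercept = float(raw["map_intercept_gpa"]) * GPA

    conductivity = float(raw.get("conductivity", 1.0))
    if conductivity <= 0:
        errors.append(f"conductivity must be positive, got {conductivity}")
    nu_policy = raw.get("nu_policy", 0.28)
    if not isinstance(nu_policy, str):
        nu_policy = float(nu_policy)
        if not 0.0 <= nu_policy < 0.5:
            errors.append(
                f"nu_policy = {nu_policy} violates the invariant 0 <= nu < 0.5"
            )
    elif nu_policy != "regional":
        errors.append(f"nu_policy must be a number or 'regional', got {nu_policy!r}")

    probe_mode = raw.get("probe_mode", "containing_element")
    if probe_mode not in ("containing_element", "nodal_average"):
        errors.append(f"unknown probe_mode {probe_mode!r}")

    if errors:
        return None, errors
    out_dir = Path(raw.get("output_dir", "thermograde_out"))
    cfg = RunConfig(
        mesh=mesh_p, modes=list(modes), loads=loads_p, constraints=bc_p,
        probes=probes_p, material_table=table_p, seeds=seeds_p,
        anchor_modulus_pa=float(anchor_E),
        anchor_temperature_c=float(raw.get("anchor_temperature_c", 50.0)),
        map_mode=raw.get("map_mode", "proportional"),
        map_intercept_pa=float(intercept),
        conductivity=conductivity, nu_policy=nu_policy,
        grade_trabecular=bool(raw.get("grade_trabecular", False)),
        patch_radius=float(raw.get("patch_radius", 0.0)),
        probe_mode=probe_mode,
        output_dir=out_dir if out_dir.is_absolute() else base / out_dir,
        log_level=str(raw.get("log_level", "INFO")).upper(),
    )
    try:
        cfg.emap()
    except ValueError as exc:
        return None, [str(exc)]
    return cfg, []


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run(config: RunConfig) -> dict:
    """Execute the full workflow; returns the manifest dict.

    Stages: read inputs → (per mode) material solve → strain → probe report
    → cross-mode comparison.  Any stage failure aborts with the stage name.
    """
    logging.basicConfig(level=config.log_level)
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    outputs: list[Path] = []
    stage = "read-inputs"
    try:
        mesh = meshio.read_mesh(config.mesh)
        log.info("mesh: %d nodes, %d tets, regions %s",
                 mesh.n_nodes, mesh.n_tets, mesh.region_labels)
        loads = elasticity.read_loads_csv(config.loads, mesh).merged_with(
            elasticity.read_constraints_csv(config.constraints, mesh)
        )
        table = (
            RegionTable.from_csv(config.material_table)
            if config.material_table else None
        )
        seeds = (
            thermal.read_seeds_csv(config.seeds, mesh, config.patch_radius)
            if config.seeds else None
        )
        probes = strain.read_probes_csv(config.probes) if config.probes else None
        props = thermal.ThermalProps(default_conductivity=config.conductivity)

        reports: dict[str, object] = {}
        for mode in config.modes:
            stage = f"solve-{mode}"
            t0 = time.perf_counter()
            result = elasticity.run_material_mode(
                mesh, mode, loads, table=table, seeds=seeds, emap=config.emap(),
                thermal_props=props, nu_policy=config.nu_policy,
                grade_trabecular=config.grade_trabecular,
            )
            log.info("%s: solved %d dofs in %.2f s", mode, 3 * mesh.n_nodes,
                     time.perf_counter() - t0)
            tag = {"uniform_isotropic": "ui", "regional_isotropic": "ri",
                   "thermally_graded": "tg"}[mode]
            if result.temperature is not None:
                p = out / f"temperature_{tag}.vtu"
                meshio.write_point_field(mesh, result.temperature, p, "temperature_C")
                outputs.append(p)
                p = out / f"modulus_{tag}.vtu"
                meshio.write_vtu(
                    mesh, p,
                    point_data={"E_Pa": result.E_nodal},
                    cell_data={"E_element_Pa": result.E_per_element},
                )
                outputs.append(p)
            else:
                p = out / f"modulus_{tag}.vtu"
                meshio.write_vtu(mesh, p, cell_data={"E_element_Pa": result.E_per_element})
                outputs.append(p)
            p = out / f"displacement_{tag}.vtu"
            meshio.write_point_field(mesh, result.displacements, p, "displacement_m")
            outputs.append(p)

            stage = f"strain-{mode}"
            state = strain.element_strain(mesh, result.displacements)
            if probes is not None:
                rep = strain.probe_strains(mesh, state, probes, config.probe_mode)
                reports[tag] = rep
                p = out / f"strain_report_{tag}.csv"
                strain.write_probe_report(rep, p)
                outputs.append(p)

        if len(reports) >= 2:
            stage = "compare-modes"
            cmp = strain.compare_modes(reports)
            p = out / "comparison.csv"
            cmp.to_csv(p, float_format="%.10g")
            outputs.append(p)
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    manifest = {
        "config": {k: str(v) for k, v in vars(config).items()},
        "outputs": {p.name: _sha256(p) for p in outputs},
    }
    mpath = out / "manifest.json"
    mpath.write_text(json.dumps(manifest, indent=2, sort_keys=True))
    log.info("wrote %d outputs + manifest to %s", len(outputs), out)
    return manifest
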