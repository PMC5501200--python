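"""The numerical experiments, encoded as declarative presets.

Each preset fixes a geometry variant, the active species subset, the
initial collagen level, kinetic overrides (binding-term multipliers or a
constant MMP2 production), the vessel pressure set and the diffusivity
mode.  Presets live as YAML fixtures under ``zflymph/presets`` so the
experiment definitions are diffable; :func:`run_scenario` executes
geometry -> mesh -> flow -> transport -> diagnostics end to end.

Preset summary
--------------
``primary``             full network, C~_C1(0) = 1, symmetric pressures.
``tenfold_vegfc``       primary with the DA VEGFC influx x10.
``no_sequestration``    primary without any VEGFC-collagen interactions.
``constant_mmp2``       MMP2 produced at a constant rate 10 in the LEC
                        (activation cascade and TIMP2 dropped).
``reduced_c1``          C~_C1(0) = 0.1, VEGFC/collagen binding x10, no
                        collagenolysis.
``reduced_c1_nobind``   C~_C1 fixed at 0.1, VEGFC alone.
``asymmetric_pressure`` as reduced_c1_nobind with vessel pressures
                        {DA: 1, PCV: -0.5, DLAV: 0.8}.
``channelisation``      triply widened slice, constant MMP2 production,
                        collagenolysis on, asymmetric pressures, C~_C1(0)=0.1.
``low_c1``              C~_C1(0) = 0.01, binding x100, free diffusivity.
``low_c1_nobind``       C~_C1 fixed at 0.01, VEGFC alone, free diffusivity.
"""

from __future__ import annotations

import importlib.resources as resources
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import yaml

from .diagnostics import (CutLineProfile, extract_cutline, peclet_field,
                          write_cutline_csv, write_run_manifest, write_vtk)
from .flow import ASYMMETRIC_VESSEL_PRESSURES, DEFAULT_VESSEL_PRESSURES
from .geometry import TrunkGeometry, build_geometry
from .meshing import Mesh, generate_mesh
from .parameters import (DimensionlessGroups, ParameterSet, ScaleSet,
                         compute_groups, compute_scales)
from .transport import (Trajectory, TransportConfig, TransportSystem)

__all__ = ["ScenarioConfig", "ScenarioResult", "list_scenarios",
           "load_scenario", "run_scenario"]

_PRESSURE_SETS = {"symmetric": DEFAULT_VESSEL_PRESSURES,
                  "asymmetric": ASYMMETRIC_VESSEL_PRESSURES}

logger = logging.getLogger("zflymph")


@dataclass(frozen=True)
class ScenarioConfig:
    """Declarative description of one numerical experiment."""

    name: str
    description: str = ""
    geometry_variant: str = "standard"
    half_domain: bool = True
    species: Tuple[str, ...] = ()
    C1_initial: float = 1.0
    C1_constant: Optional[float] = None
    binding_multiplier: float = 1.0
    constant_m2_production: Optional[float] = None
    influx_scale: float = 1.0
    pressures: str = "symmetric"
    diffusivity_mode: str = "simplified"
    t_end: float = 1.0
    checkpoints: Tuple[float, ...] = (0.25, 0.5, 0.75, 1.0)
    rtol: float = 1e-5
    atol: float = 1e-9

    def transport_config(self) -> TransportConfig:
        return TransportConfig(
            species=self.species,
            C1_initial=self.C1_initial,
            C1_constant=self.C1_constant,
            binding_multiplier=self.binding_multiplier,
            constant_m2_production=self.constant_m2_production,
            influx_scale=self.influx_scale,
            vessel_pressures=dict(_PRESSURE_SETS[self.pressures]),
            diffusivity_mode=self.diffusivity_mode,
            rtol=self.rtol,
            atol_scale=self.atol,
        )


def _preset_dir():
    return resources.files("zflymph") / "presets"


def list_scenarios() -> List[str]:
    return sorted(p.name[:-5] for p in _preset_dir().iterdir()
                  if p.name.endswith(".yaml"))


def load_scenario(name: str) -> ScenarioConfig:
    path = _preset_dir() / f"{name}.yaml"
    try:
        data = yaml.safe_load(path.read_text())
    except FileNotFoundError:
        raise KeyError(f"no scenario preset named {name!r}; "
                       f"available: {list_scenarios()}")
    data.setdefault("name", name)
    data["species"] = tuple(data["species"])
    if "checkpoints" in data:
        data["checkpoints"] = tuple(data["checkpoints"])
    return ScenarioConfig(**data)


@dataclass
class ScenarioResult:
    """Everything a numerical experiment produced."""

    config: ScenarioConfig
    params: ParameterSet
    scales: ScaleSet
    groups: DimensionlessGroups
    mesh: Mesh
    trajectory: Trajectory

    # -- convenience ---------------------------------------------------------
    @property
    def system(self) -> TransportSystem:
        return self.trajectory.system

    def fields_at(self, t: float, clip: bool = True) -> Dict[str, np.ndarray]:
        """Full-length nodal arrays for every species at a checkpoint."""
        state = self.trajectory.state_at(t)
        raw = state.clipped() if clip else state.fields
        return {s: self.system.global_field(s, raw[s], fill=np.nan)
                for s in raw}

    def cutline(self, t: float, start, end, n_samples: int = 500
                ) -> CutLineProfile:
        return extract_cutline(self.mesh, self.fields_at(t), start, end,
                               n_samples=n_samples)

    def vertical_cutline(self, t: float, x: float = 0.0,
                         y_range=(-0.45, 0.45), n_samples: int = 500
                         ) -> CutLineProfile:
        return self.cutline(t, (x, y_range[0]), (x, y_range[1]), n_samples)

    def peclet_max(self, species: str = "VC", t: float = 1.0) -> float:
        state = self.trajectory.state_at(t)
        if state.flow is None:
            return 0.0
        return float(peclet_field(state.flow, species, self.groups).max())

    def report(self) -> Dict:
        last = self.trajectory.state_at(self.config.t_end)
        summary = {}
        for s, v in last.fields.items():
            summary[s] = dict(min=float(v.min()), max=float(v.max()))
        return dict(scenario=self.config.name,
                    n_elements=self.mesh.n_triangles,
                    n_nodes=self.mesh.n_points,
                    n_dof=self.system.n_dof,
                    n_flow_solves=self.trajectory.n_flow_solves,
                    solver=self.trajectory.solver_report,
                    final_fields=summary)


def run_scenario(scenario: str | ScenarioConfig,
                 params: Optional[ParameterSet] = None,
                 resolution: float = 1.0,
                 t_end: Optional[float] = None,
                 mesh: Optional[Mesh] = None,
                 seed: int = 0,
                 out_dir: Optional[str | Path] = None) -> ScenarioResult:
    """Execute a preset (or explicit config) end to end.

    ``resolution`` scales the mesh size knobs (>1 is coarser); a prebuilt
    ``mesh`` short-circuits meshing (used by convergence studies).  With
    ``out_dir`` the checkpoint fields (VTK), the reference cut-line profile
    (CSV) and a run manifest (JSON) are written there.
    """
    cfg = load_scenario(scenario) if isinstance(scenario, str) else scenario
    if t_end is not None:
        cfg = ScenarioConfig(**{**cfg.__dict__, "t_end": float(t_end)})
    params = params or ParameterSet()
    scales = compute_scales(params)
    groups = compute_groups(params, scales)
    if mesh is None:
        geo = build_geometry(variant=cfg.geometry_variant,
                             half_domain=cfg.half_domain)
        mesh = generate_mesh(geo, resolution=resolution, seed=seed)
    logger.info("scenario %s: %d elements, %d nodes, min angle %.1f deg",
                cfg.name, mesh.n_triangles, mesh.n_points,
                mesh.min_angle_deg())
    system = TransportSystem(mesh, groups, cfg.transport_config())
    traj = system.advance(t_end=cfg.t_end, checkpoints=cfg.checkpoints)
    logger.info("scenario %s: %s; %d flow solves",
                cfg.name, traj.solver_report, system.n_flow_solves)
    result = ScenarioResult(config=cfg, params=params, scales=scales,
                            groups=groups, mesh=mesh, trajectory=traj)
    if out_dir is not None:
        _write_outputs(result, Path(out_dir))
    return result


def _write_outputs(result: ScenarioResult, out: Path) -> None:
    out.mkdir(parents=True, exist_ok=True)
    cfg = result.config
    for state in result.trajectory.states:
        fields = result.fields_at(state.t)
        data = {k: np.nan_to_num(v, nan=0.0) for k, v in fields.items()}
        write_vtk(out / f"fields_t{state.t:.2f}.vtk", result.mesh, data)
    try:
        profile = result.vertical_cutline(cfg.t_end)
        write_cutline_csv(out / "cutline_x0.csv", profile)
    except Exception:
        pass
    write_run_manifest(out / "manifest.json",
                       dict(config=cfg.__dict__, report=result.report()))
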