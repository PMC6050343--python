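"""Configuration, file formats and run manifests.

Configuration is TOML with paper-friendly units carried in the key
names (um, mM, mV, V/mm); everything is converted to SI on load and
validated strictly (unknown keys are rejected, naming the key).  Field
states are written as legacy-ASCII VTK rectilinear-grid files with the
staggered velocity components preserved in FIELD arrays so a state can
be read back losslessly; tabular data is CSV; reports and manifests are
JSON.  Deterministic runs produce byte-identical CSV/JSON outputs
(manifest timestamps are opt-in).
"""

from __future__ import annotations

import hashlib
import json
import warnings
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from pydantic import BaseModel, ConfigDict, Field, ValidationError

from .constants import PhysicalConstants
from .geometry import DeviceGeometry, Mesh, build_mesh
from .solver import FieldState, SolverSettings
from .system import (
    DriveSpec,
    ElectrokineticSystem,
    ElectrolyteSpec,
    MembraneSpec,
    WallSpec,
)

try:
    import tomllib
except ModuleNotFoundError:  # pragma: no cover - python < 3.11
    import tomli as tomllib  # type: ignore


class ConfigError(ValueError):
    pass


class _Table(BaseModel):
    model_config = ConfigDict(extra="forbid")


class GeometryTable(_Table):
    channel_length_um: float = 10000.0
    channel_height_um: float = 17.0
    membrane_length_um: float = 400.0
    membrane_thickness_um: float = 6.0
    membrane_x_center_um: float | None = None


class ElectrolyteTable(_Table):
    c0_mM: float = 10.0
    z_plus: int = 1
    z_minus: int = -1
    D_plus_m2_s: float = 1.33e-9
    D_minus_m2_s: float = 2.03e-9


class MembraneTable(_Table):
    fixed_charge_mM: float = -100.0
    cation_only: bool = True
    diffusivity_factor: float = 0.01


class WallsTable(_Table):
    zeta_bottom_mV: float = -60.0
    zeta_top_mV: float = -40.0


class DriveTable(_Table):
    field_V_per_mm: float | None = None
    total_voltage_V: float | None = None


class MeshTable(_Table):
    nx: int = 200
    ny: int = 40
    grading: float = 1.0


class SolverTable(_Table):
    newton_tolerance: float = 1.0e-9
    debye_scale: float | None = None
    include_flow: bool = True
    linear_solver: str = "direct"
    continuation: list[float] | None = None


class TracerTable(_Table):
    valence: float = -10.0
    diffusivity_m2_s: float = 1.0e-10
    c_init_mM: float = 1.0
    t_end_s: float = 60.0
    dt_s: float = 0.5


class SynthTable(_Table):
    n_devices: int = 12
    n_replicates: int = 3
    quench: float = 0.85
    intra_cv: float = 9.80
    inter_cv: float = 9.45


class RunConfig(_Table):
    """Merged, validated configuration for one run (SI on conversion)."""

    geometry: GeometryTable = Field(default_factory=GeometryTable)
    electrolyte: ElectrolyteTable = Field(default_factory=ElectrolyteTable)
    membrane: MembraneTable = Field(default_factory=MembraneTable)
    walls: WallsTable = Field(default_factory=WallsTable)
    drive: DriveTable = Field(default_factory=DriveTable)
    mesh: MeshTable = Field(default_factory=MeshTable)
    solver: SolverTable = Field(default_factory=SolverTable)
    tracer: TracerTable = Field(default_factory=TracerTable)
    synth: SynthTable = Field(default_factory=SynthTable)
    seed: int = 0

    def to_geometry(self) -> DeviceGeometry:
        g = self.geometry
        length = g.channel_length_um * 1e-6
        center = (g.membrane_x_center_um * 1e-6) if g.membrane_x_center_um is not None else 0.5 * length
        return DeviceGeometry(
            channel_length=length,
            channel_height=g.channel_height_um * 1e-6,
            membrane_length=g.membrane_length_um * 1e-6,
            membrane_thickness=g.membrane_thickness_um * 1e-6,
            membrane_x_center=center,
        )

    def to_drive(self) -> DriveSpec:
        d = self.drive
        length = self.geometry.channel_length_um * 1e-6
        if d.field_V_per_mm is not None:
            axial = d.field_V_per_mm * 1e3
            if d.total_voltage_V is not None and not np.isclose(d.total_voltage_V, axial * length):
                warnings.warn(
                    f"drive.total_voltage_V={d.total_voltage_V:g} V is inconsistent with "
                    f"field {d.field_V_per_mm:g} V/mm over {length * 1e3:g} mm; "
                    "the field value wins",
                    stacklevel=2,
                )
            return DriveSpec(axial_field=axial)
        if d.total_voltage_V is not None:
            return DriveSpec(axial_field=d.total_voltage_V / length)
        return DriveSpec(axial_field=3.6e3)

    def to_system(self) -> ElectrokineticSystem:
        e = self.electrolyte
        return ElectrokineticSystem(
            constants=PhysicalConstants(),
            electrolyte=ElectrolyteSpec(
                z_plus=e.z_plus, z_minus=e.z_minus,
                D_plus=e.D_plus_m2_s, D_minus=e.D_minus_m2_s, c0=e.c0_mM,
            ),
            geometry=self.to_geometry(),
            membrane=MembraneSpec(
                fixed_charge_concentration=self.membrane.fixed_charge_mM,
                cation_only=self.membrane.cation_only,
                diffusivity_factor=self.membrane.diffusivity_factor,
            ),
            walls=WallSpec(
                zeta_bottom=self.walls.zeta_bottom_mV * 1e-3,
                zeta_top=self.walls.zeta_top_mV * 1e-3,
            ),
            drive=self.to_drive(),
        )

    def to_mesh(self) -> Mesh:
        return build_mesh(self.to_geometry(), nx=self.mesh.nx, ny=self.mesh.ny,
                          grading=self.mesh.grading)

    def to_solver_settings(self) -> SolverSettings:
        s = self.solver
        return SolverSettings(
            newton_tolerance=s.newton_tolerance,
            debye_scale=s.debye_scale,
            include_flow=s.include_flow,
            linear_solver=s.linear_solver,
            continuation=tuple(s.continuation) if s.continuation else None,
        )

    def config_hash(self) -> str:
        return hashlib.sha256(
            json.dumps(self.model_dump(), sort_keys=True).encode()
        ).hexdigest()


def load_config(path: str | Path | None = None) -> RunConfig:
    """Load and validate a TOML config; missing tables take the
    reference-device defaults (1 cm x 17 um channel, 10 mM NaCl,
    zeta -60/-40 mV, E = 3.6 V/mm)."""
    data = {}
    if path is not None:
        with open(path, "rb") as fh:
            data = tomllib.load(fh)
    try:
        return RunConfig(**data)
    except ValidationError as exc:
        first = exc.errors()[0]
        loc = ".".join(str(p) for p in first["loc"])
        raise ConfigError(f"invalid config key '{loc}': {first['msg']}") from exc


# ---------------------------------------------------------------------------
# VTK rectilinear grid (legacy ASCII)
# ---------------------------------------------------------------------------


def write_vtk_rectilinear(path: str | Path, mesh: Mesh, cell_data: dict[str, np.ndarray],
                          field_data: dict[str, np.ndarray] | None = None) -> None:
    """Write cell-centred scalars (and optional free-form FIELD arrays)
    on a rectilinear grid in the legacy ASCII VTK format."""
    lines = [
        "# vtk DataFile Version 3.0",
        "icpkit fields",
        "ASCII",
        "DATASET RECTILINEAR_GRID",
        f"DIMENSIONS {mesh.nx + 1} {mesh.ny + 1} 1",
        f"X_COORDINATES {mesh.nx + 1} double",
        " ".join(repr(float(v)) for v in mesh.x_faces),
        f"Y_COORDINATES {mesh.ny + 1} double",
        " ".join(repr(float(v)) for v in mesh.y_faces),
        "Z_COORDINATES 1 double",
        "0.0",
        f"CELL_DATA {mesh.n_cells}",
    ]
    for name, arr in cell_data.items():
        flat = np.asarray(arr, float).reshape(mesh.ny, mesh.nx).ravel()
        lines.append(f"SCALARS {name} double 1")
        lines.append("LOOKUP_TABLE default")
        lines.append(" ".join(repr(float(v)) for v in flat))
    if field_data:
        lines.append(f"FIELD extra {len(field_data)}")
        for name, arr in field_data.items():
            flat = np.asarray(arr, float).ravel()
            lines.append(f"{name} 1 {flat.size} double")
            lines.append(" ".join(repr(float(v)) for v in flat))
    Path(path).write_text("\n".join(lines) + "\n")


def read_vtk_rectilinear(path: str | Path):
    """Read back a file produced by :func:`write_vtk_rectilinear`.

    Returns (x_faces, y_faces, cell_data, field_data).
    """
    tokens = Path(path).read_text().split("\n")
    it = iter(tokens)
    x_faces = y_faces = None
    cell_data: dict[str, np.ndarray] = {}
    field_data: dict[str, np.ndarray] = {}
    line = next(it, None)
    while line is not None:
        if line.startswith("X_COORDINATES"):
            x_faces = np.fromstring(next(it), sep=" ")
        elif line.startswith("Y_COORDINATES"):
            y_faces = np.fromstring(next(it), sep=" ")
        elif line.startswith("SCALARS"):
            name = line.split()[1]
            next(it)  # LOOKUP_TABLE
            cell_data[name] = np.fromstring(next(it), sep=" ")
        elif line.startswith("FIELD"):
            n = int(line.split()[-1])
            for _ in range(n):
                header = next(it).split()
                field_data[header[0]] = np.fromstring(next(it), sep=" ")
        line = next(it, None)
    if x_faces is None or y_faces is None:
        raise ValueError(f"{path} is not a rectilinear-grid VTK file")
    return x_faces, y_faces, cell_data, field_data


def write_state(path: str | Path, state: FieldState) -> None:
    """Serialize a converged field state (VTK + staggered velocities)."""
    mesh = state.mesh
    write_vtk_rectilinear(
        path,
        mesh,
        cell_data={
            "c_plus": state.C_plus,
            "c_minus": state.C_minus,
            "phi": state.phi,
            "pressure": state.P,
            "rho_e": state.rho_e,
            "speed": state.speed,
            "membrane": mesh.membrane_mask.astype(float),
        },
        field_data={"ux_mac": state.ux, "uy_mac": state.uy},
    )


def read_state(path: str | Path, system: ElectrokineticSystem) -> FieldState:
    """Read a state written by :func:`write_state`."""
    xf, yf, cell, fdata = read_vtk_rectilinear(path)
    nx, ny = len(xf) - 1, len(yf) - 1
    mask = cell["membrane"].reshape(ny, nx).astype(bool)
    mesh = Mesh(x_faces=xf, y_faces=yf, membrane_mask=mask, geometry=system.geometry)
    return FieldState(
        C_plus=cell["c_plus"].reshape(ny, nx),
        C_minus=cell["c_minus"].reshape(ny, nx),
        phi=cell["phi"].reshape(ny, nx),
        ux=fdata["ux_mac"].reshape(ny, nx + 1),
        uy=fdata["uy_mac"].reshape(ny + 1, nx),
        P=cell["pressure"].reshape(ny, nx),
        mesh=mesh,
        system=system,
    )


# ---------------------------------------------------------------------------
# Tabular outputs and manifest
# ---------------------------------------------------------------------------


def write_profile_csv(path: str | Path, profile) -> None:
    pd.DataFrame(
        {"x_m": profile.x, "c_plus_mM": profile.C_plus, "c_minus_mM": profile.C_minus}
    ).to_csv(path, index=False)


def write_pcf_csv(path: str | Path, tracer_field) -> None:
    pd.DataFrame({"t_s": tracer_field.times, "pcf": tracer_field.pcf}).to_csv(path, index=False)


@dataclass
class RunManifest:
    """Provenance record of one run."""

    tool: str
    version: str
    config_hash: str
    seed: int
    files: dict[str, str] = field(default_factory=dict)
    timestamp: str | None = None

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2, sort_keys=True)


def write_outputs(
    out_dir: str | Path,
    config: RunConfig,
    artifacts: dict[str, object],
    include_timestamp: bool = False,
) -> RunManifest:
    """Write a set of artifacts and a manifest to ``out_dir``.

    Artifact values are dispatched on type: FieldState -> VTK, Profile /
    TracerField / PlateData -> CSV, everything else -> JSON.  Returns
    the manifest (also written as ``manifest.json``).
    """
    from .analysis import Profile  # local import to avoid cycle at module load
    from .kinetics import PlateData
    from .tracer import TracerField

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    files: dict[str, str] = {}
    for name, obj in artifacts.items():
        if isinstance(obj, FieldState):
            fname = f"{name}.vtk"
            write_state(out / fname, obj)
        elif isinstance(obj, Profile):
            fname = f"{name}.csv"
            write_profile_csv(out / fname, obj)
        elif isinstance(obj, TracerField):
            fname = f"{name}.csv"
            write_pcf_csv(out / fname, obj)
        elif isinstance(obj, PlateData):
            fname = f"{name}.csv"
            obj.to_csv(out / fname)
        else:
            fname = f"{name}.json"
            (out / fname).write_text(json.dumps(obj, indent=2, sort_keys=True, default=_json_default))
        files[fname] = hashlib.sha256((out / fname).read_bytes()).hexdigest()
    manifest = RunManifest(
        tool="icpkit",
        version=_package_version(),
        config_hash=config.config_hash(),
        seed=config.seed,
        files=files,
        timestamp=_now() if include_timestamp else None,
    )
    (out / "manifest.json").write_text(manifest.to_json())
    return manifest


def _json_default(obj):
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if hasattr(obj, "__dataclass_fields__"):
        return asdict(obj)
    raise TypeError(f"cannot serialize {type(obj)!r}")


def _package_version() -> str:
    from importlib.metadata import PackageNotFoundError, version

    try:
        return version("icpkit")
    except PackageNotFoundError:  # pragma: no cover
        return "unknown"


def _now() -> str:
    from datetime import datetime, timezone

    return datetime.now(timezone.utc).isoformat()
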