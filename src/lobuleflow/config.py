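"""Run configuration: YAML schema with explicit physical units.

Pressures and conductances are conventionally reported in mmHg-based
units in the physiology literature while the solver works in SI, so every
dimensional entry in a config file is a string ``"<value> <unit>"`` (or a
bare number, interpreted as SI).  Unknown keys and unknown units are
rejected with field-level messages.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from pathlib import Path

import yaml

from .parameters import CMH2O, MMHG, PhysiologicalParameters
from .geometry import SurfaceKind
from .solver import ModelOptions, ModelVariant, SurfaceModel


class ConfigError(ValueError):
    pass


# unit-name -> factor to SI, per dimension
_UNIT_TABLES: dict[str, dict[str, float]] = {
    "length": {"m": 1.0, "mm": 1e-3, "cm": 1e-2, "um": 1e-6, "µm": 1e-6},
    "area": {"m^2": 1.0, "cm^2": 1e-4, "mm^2": 1e-6},
    "volume": {"m^3": 1.0, "cm^3": 1e-6, "ml": 1e-6, "l": 1e-3},
    "permeability": {"m^2": 1.0},
    "viscosity": {"Pa s": 1.0, "Pa.s": 1.0, "mPa s": 1e-3},
    "pressure": {"Pa": 1.0, "kPa": 1e3, "mmHg": MMHG, "cmH2O": CMH2O},
    "exchange": {"1/(Pa s)": 1.0, "1/(mmHg s)": 1.0 / MMHG},
    "conductance": {
        "m/(s Pa)": 1.0,
        "m/(s mmHg)": 1.0 / MMHG,
        # conventional membrane filtration unit: ml per hour per cmH2O per cm^2
        "ml/h/cmH2O/cm^2": 1e-6 / 3600.0 / CMH2O / 1e-4,
    },
    "dimensionless": {"": 1.0, "1": 1.0},
}

_FIELD_DIMENSIONS: dict[str, str] = {
    "L_lob": "length", "D_PT": "length", "D_CV": "length",
    "V_liv": "volume", "A_liv": "area", "chi": "dimensionless",
    "k_S": "permeability", "k_I": "permeability",
    "mu_S": "viscosity", "mu_I": "viscosity",
    "C_f": "exchange", "C_l": "exchange",
    "p_0": "pressure", "p_S_PT": "pressure", "p_S_CV": "pressure",
    "M_BA": "conductance", "M_GP": "conductance",
    "p_DS": "pressure", "p_PC": "pressure",
}

# units used when serializing a config back to text
_PRESENT_UNITS: dict[str, str] = {
    "length": "um", "area": "cm^2", "volume": "cm^3", "permeability": "m^2",
    "viscosity": "Pa s", "pressure": "mmHg", "exchange": "1/(mmHg s)",
    "conductance": "m/(s mmHg)", "dimensionless": "",
}


def parse_quantity(value, dimension: str, field_name: str = "?") -> float:
    """Parse ``"4.4 mmHg"`` (or a bare SI number) into an SI float."""
    table = _UNIT_TABLES[dimension]
    if isinstance(value, (int, float)):
        return float(value)
    if not isinstance(value, str):
        raise ConfigError(f"{field_name}: expected a number or 'value unit' "
                          f"string, got {value!r}")
    s = value.strip()
    if s.lower() in ("inf", "infinite", "infinity"):
        return math.inf
    parts = s.split(None, 1)
    try:
        num = float(parts[0])
    except ValueError as exc:
        raise ConfigError(f"{field_name}: cannot parse number in {value!r}") from exc
    unit = parts[1].strip() if len(parts) > 1 else ""
    if unit not in table:
        raise ConfigError(
            f"{field_name}: unknown unit {unit!r} for dimension {dimension} "
            f"(accepted: {sorted(u for u in table if u)})")
    return num * table[unit]


def format_quantity(si_value: float, dimension: str) -> str:
    if math.isinf(si_value):
        return "inf"
    unit = _PRESENT_UNITS[dimension]
    factor = _UNIT_TABLES[dimension][unit]
    return f"{si_value / factor:.17g} {unit}".strip()


@dataclass
class GeometryConfig:
    kind: str = "lobule"                 # lobule | square | slab
    surface: str = "glisson_peritoneal"  # for slabs
    n_rows: int | None = None
    mesh_size: float | None = None       # [m]; default L_lob/50

    def surface_kind(self) -> SurfaceKind:
        return SurfaceKind(self.surface)


@dataclass
class OutputConfig:
    directory: str = "lobuleflow_out"
    formats: list[str] = field(default_factory=lambda: ["csv", "vtk", "png"])


@dataclass
class RunConfig:
    params: PhysiologicalParameters = field(default_factory=PhysiologicalParameters)
    geometry: GeometryConfig = field(default_factory=GeometryConfig)
    options: ModelOptions = field(default_factory=ModelOptions)
    output: OutputConfig = field(default_factory=OutputConfig)
    overrides: dict = field(default_factory=dict)   # logged raw overrides


def _check_keys(block: dict, allowed: set[str], where: str) -> None:
    unknown = set(block) - allowed
    if unknown:
        raise ConfigError(f"unknown key(s) {sorted(unknown)} in {where!r} "
                          f"(accepted: {sorted(allowed)})")


def load_config(path: str | Path | None) -> RunConfig:
    """Load and validate a YAML run configuration.

    An empty (or missing) file yields the full physiological defaults.
    ``k_I`` keeps its proportionality to ``k_S`` (0.002 k_S) when ``k_S``
    is overridden without an explicit ``k_I``.
    """
    raw = {}
    if path is not None:
        text = Path(path).read_text()
        raw = yaml.safe_load(text) or {}
    if not isinstance(raw, dict):
        raise ConfigError("top level of the config must be a mapping")
    _check_keys(raw, {"parameters", "geometry", "model", "output"}, "config")

    pblock = raw.get("parameters") or {}
    _check_keys(pblock, set(_FIELD_DIMENSIONS), "parameters")
    overrides = {}
    for name, value in pblock.items():
        overrides[name] = parse_quantity(value, _FIELD_DIMENSIONS[name], name)
    base = PhysiologicalParameters()
    params = base.with_(**overrides) if overrides else base

    gblock = raw.get("geometry") or {}
    _check_keys(gblock, {"kind", "surface", "n_rows", "mesh_size"}, "geometry")
    geometry = GeometryConfig(
        kind=gblock.get("kind", "lobule"),
        surface=gblock.get("surface", "glisson_peritoneal"),
        n_rows=gblock.get("n_rows"),
        mesh_size=(parse_quantity(gblock["mesh_size"], "length", "mesh_size")
                   if "mesh_size" in gblock else None),
    )
    if geometry.kind not in ("lobule", "square", "slab"):
        raise ConfigError(f"geometry.kind must be lobule|square|slab, "
                          f"got {geometry.kind!r}")
    if geometry.surface not in [s.value for s in SurfaceKind]:
        raise ConfigError(f"geometry.surface must be one of "
                          f"{[s.value for s in SurfaceKind]}")

    mblock = raw.get("model") or {}
    _check_keys(mblock, {"variant", "surface_model", "active_set_tol",
                         "max_active_set_iters"}, "model")
    try:
        options = ModelOptions(
            variant=ModelVariant(mblock.get("variant", "standard")),
            surface_model=SurfaceModel(mblock.get("surface_model", "robin")),
            active_set_tol=float(mblock.get("active_set_tol", 1e-10)),
            max_active_set_iters=int(mblock.get("max_active_set_iters", 30)),
        )
    except ValueError as exc:
        raise ConfigError(f"model block: {exc}") from exc

    oblock = raw.get("output") or {}
    _check_keys(oblock, {"directory", "formats"}, "output")
    output = OutputConfig(directory=oblock.get("directory", "lobuleflow_out"),
                          formats=list(oblock.get("formats", ["csv", "vtk", "png"])))

    return RunConfig(params=params, geometry=geometry, options=options,
                     output=output, overrides=overrides)


def save_config(config: RunConfig, path: str | Path) -> None:
    """Serialize a config with explicit units; round-trips through load_config."""
    pblock = {name: format_quantity(getattr(config.params, name),
                                    _FIELD_DIMENSIONS[name])
              for name in _FIELD_DIMENSIONS}
    doc = {
        "parameters": pblock,
        "geometry": {
            "kind": config.geometry.kind,
            "surface": config.geometry.surface,
            **({"n_rows": config.geometry.n_rows}
               if config.geometry.n_rows is not None else {}),
            **({"mesh_size": format_quantity(config.geometry.mesh_size, "length")}
               if config.geometry.mesh_size is not None else {}),
        },
        "model": {
            "variant": config.options.variant.value,
            "surface_model": config.options.surface_model.value,
            "active_set_tol": config.options.active_set_tol,
            "max_active_set_iters": config.options.max_active_set_iters,
        },
        "output": {"directory": config.output.directory,
                   "formats": config.output.formats},
    }
    Path(path).write_text(yaml.safe_dump(doc, sort_keys=False))
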