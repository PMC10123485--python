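"""Model parameters, presets, and whole-cell-to-box count scaling.

The simulation box is a 1.5 x 1.5 x 0.5 μm rectangular cuboid standing in
for a patch of pre-B cell membrane plus the cytosol beneath it.  Whole-cell
molecule counts (receptors, Syk) are scaled to the box by area or volume
ratio against the morphometric cell estimates (membrane area 315.7 μm²,
cytosolic volume 321.8 μm³), rounding to the nearest integer.  The Lyn pool
available to receptors is a fixed fraction (10%) of the receptor count.

Two presets are shipped: ``"697"`` and ``"nalm6"``, the two B-ALL cell-line
parameterizations.  They differ in the receptor dimer off-rate (1.14 vs
0.159 /s) and Syk abundance (48290 vs 274302 per cell); everything else is
shared.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Any, Mapping, Union

import yaml

from . import molecules as mol


class ConfigError(ValueError):
    """A configuration document failed validation; names the offending field."""


def _nested_tuple(x):
    if isinstance(x, (list, tuple)):
        return tuple(_nested_tuple(v) for v in x)
    return x


def default_rate_tables() -> dict[str, Any]:
    """Tables of kinase binding, phosphorylation and dephosphorylation rates.

    Keys use ITAM kind names 'iga'/'igb' and statuses as strings so the
    structure round-trips through YAML.
    """
    return {
        "lyn_table": {
            "iga": {
                "0": {"radius": 2.29e-4, "off_rate": 20.0, "mode": "unique"},
                "1": {"radius": 2.29e-4, "off_rate": 0.12, "mode": "sh2"},
                "2": {"radius": 2.29e-4, "off_rate": 0.12, "mode": "sh2"},
            },
            "igb": {
                "1": {"radius": 1.14e-4, "off_rate": 0.12, "mode": "sh2"},
                "2": {"radius": 1.14e-4, "off_rate": 0.12, "mode": "sh2"},
            },
        },
        "syk_table": {
            "iga": {
                "1": {"radius": 1.31e-4, "off_rate": 2.6},
                "2": {"radius": 1.57e-3, "off_rate": 0.3},
            },
            "igb": {
                "1": {"radius": 4.37e-5, "off_rate": 2.6},
                "2": {"radius": 5.25e-4, "off_rate": 0.3},
            },
        },
        "phospho_table": {
            "itam": [list(r) for r in mol.PHOSPHO_ITAM],
            "lyn_y397": list(mol.PHOSPHO_LYN_Y397),
            "syk_linker": list(mol.PHOSPHO_SYK_LINKER),
            "syk_catalytic": list(mol.PHOSPHO_SYK_CATALYTIC),
        },
        "dephospho_table": {
            "itam": {"1": mol.DEPHOSPHO_ITAM[1], "2": mol.DEPHOSPHO_ITAM[2]},
            "lyn_y397": mol.DEPHOSPHO_LYN_Y397,
            "syk": mol.DEPHOSPHO_SYK,
        },
    }


@dataclass
class ModelParameters:
    """All constants of a simulation condition, in μm / s units.

    ``n_receptors_cell`` and ``n_syk_cell`` are whole-cell counts; box-level
    counts are derived via :func:`scale_membrane_count` and
    :func:`scale_cytosol_count`.
    """

    cell_line_label: str = "697"
    n_receptors_cell: int = 10000
    n_syk_cell: int = 48290
    lyn_fraction: float = 0.10
    d_rec: float = 0.16      # μm²/s, monomeric receptor
    d_lyn: float = 0.4       # μm²/s
    d_syk: float = 17.0      # μm²/s
    sigma_rec: float = 1.0e-4  # μm, receptor-receptor binding radius
    k_off_dimer: float = 1.14  # /s per receptor-receptor bond
    cell_area: float = 315.7   # μm²
    cell_volume: float = 321.8  # μm³
    box_x: float = 1.5       # μm
    box_y: float = 1.5       # μm
    box_z: float = 0.5       # μm
    dt: float = 1e-5         # s
    t_total: float = 600.0   # s
    t_ini: float = 50.0      # s, equilibration window excluded from averages
    exit_probability: float = 0.2
    sample_interval: float = 0.1  # s
    seed: int = 0
    lyn_table: dict = field(default_factory=lambda: default_rate_tables()["lyn_table"])
    syk_table: dict = field(default_factory=lambda: default_rate_tables()["syk_table"])
    phospho_table: dict = field(
        default_factory=lambda: default_rate_tables()["phospho_table"]
    )
    dephospho_table: dict = field(
        default_factory=lambda: default_rate_tables()["dephospho_table"]
    )

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        nonneg = [
            "n_receptors_cell", "n_syk_cell", "d_rec", "d_lyn", "d_syk",
            "sigma_rec", "k_off_dimer",
        ]
        for name in nonneg:
            if getattr(self, name) < 0:
                raise ConfigError(f"{name} must be >= 0, got {getattr(self, name)}")
        for name in ("cell_area", "cell_volume", "box_x", "box_y", "box_z",
                     "t_total", "sample_interval"):
            if getattr(self, name) <= 0:
                raise ConfigError(f"{name} must be > 0, got {getattr(self, name)}")
        if self.dt <= 0:
            raise ConfigError(f"dt must be > 0, got {self.dt}")
        if not self.t_ini < self.t_total:
            raise ConfigError(
                f"t_ini must be < t_total ({self.t_ini} >= {self.t_total})"
            )
        if self.t_ini < 0:
            raise ConfigError(f"t_ini must be >= 0, got {self.t_ini}")
        if not 0.0 <= self.exit_probability <= 1.0:
            raise ConfigError(
                f"exit_probability must be in [0, 1], got {self.exit_probability}"
            )
        if not 0.0 <= self.lyn_fraction <= 1.0:
            raise ConfigError(
                f"lyn_fraction must be in [0, 1], got {self.lyn_fraction}"
            )
        if self.sigma_rec >= min(self.box_x, self.box_y):
            raise ConfigError("sigma_rec must be smaller than the box")

    # -- derived geometry and counts ---------------------------------------

    @property
    def box_area(self) -> float:
        return self.box_x * self.box_y

    @property
    def box_volume(self) -> float:
        """Geometric box volume box_x * box_y * box_z (1.125 μm³ by default)."""
        return self.box_x * self.box_y * self.box_z

    @property
    def n_receptors_box(self) -> int:
        return scale_membrane_count(self.n_receptors_cell, self.cell_area,
                                    self.box_area)

    @property
    def n_syk_box(self) -> int:
        return scale_cytosol_count(self.n_syk_cell, self.cell_volume,
                                   self.box_volume)

    @property
    def n_lyn_box(self) -> int:
        return lyn_pool_count(self.n_receptors_box, self.lyn_fraction)

    @property
    def receptor_density(self) -> float:
        """Receptors per μm² of membrane (whole cell)."""
        return self.n_receptors_cell / self.cell_area

    def replace(self, **changes) -> "ModelParameters":
        return dataclasses.replace(self, **changes)

    def to_dict(self) -> dict[str, Any]:
        return dataclasses.asdict(self)


def scale_membrane_count(n_cell: int, cell_area: float, box_area: float) -> int:
    """Scale a whole-cell membrane count to the box by area ratio.

    Nearest-integer rounding: 10000 receptors on 315.7 μm² map to 71 in a
    2.25 μm² box.
    """
    if cell_area <= 0 or box_area <= 0:
        raise ConfigError("areas must be positive")
    if n_cell < 0:
        raise ConfigError("n_cell must be >= 0")
    return round(n_cell * box_area / cell_area)


def scale_cytosol_count(n_cell: int, cell_volume: float, box_volume: float) -> int:
    """Scale a whole-cell cytosolic count to the box by volume ratio."""
    if cell_volume <= 0 or box_volume <= 0:
        raise ConfigError("volumes must be positive")
    if n_cell < 0:
        raise ConfigError("n_cell must be >= 0")
    return round(n_cell * box_volume / cell_volume)


def lyn_pool_count(n_receptors_box: int, lyn_fraction: float) -> int:
    """Lyn molecules available to receptors: a fixed fraction of receptors."""
    if not 0.0 <= lyn_fraction <= 1.0:
        raise ConfigError(f"lyn_fraction must be in [0, 1], got {lyn_fraction}")
    if n_receptors_box < 0:
        raise ConfigError("n_receptors_box must be >= 0")
    return round(lyn_fraction * n_receptors_box)


_SCALAR_FIELDS = {
    f.name for f in dataclasses.fields(ModelParameters)
    if f.name not in ("lyn_table", "syk_table", "phospho_table", "dephospho_table")
}
_TABLE_FIELDS = {"lyn_table", "syk_table", "phospho_table", "dephospho_table"}
_REQUIRED_KEYS = {
    "cell_line_label", "n_receptors_cell", "n_syk_cell", "k_off_dimer",
}


def load_config(source: Union[str, Path, Mapping[str, Any]]) -> ModelParameters:
    """Build validated :class:`ModelParameters` from YAML or a mapping.

    Unknown keys are rejected; missing required keys and out-of-range values
    raise :class:`ConfigError` naming the field.
    """
    if isinstance(source, Mapping):
        doc = dict(source)
    else:
        text = Path(source).read_text()
        doc = yaml.safe_load(text)
        if not isinstance(doc, Mapping):
            raise ConfigError(f"configuration {source} did not parse to a mapping")
        doc = dict(doc)

    unknown = set(doc) - _SCALAR_FIELDS - _TABLE_FIELDS
    if unknown:
        raise ConfigError(f"unknown configuration keys: {sorted(unknown)}")
    missing = _REQUIRED_KEYS - set(doc)
    if missing:
        raise ConfigError(f"missing required keys: {sorted(missing)}")
    try:
        return ModelParameters(**doc)
    except TypeError as exc:  # pragma: no cover - defensive
        raise ConfigError(str(exc)) from exc


def preset_path(name: str) -> Path:
    pkg_dir = resources.files("prebcr") / "presets"
    p = Path(str(pkg_dir)) / f"{name}.yaml"
    if not p.exists():
        raise ConfigError(
            f"unknown preset {name!r}; available: 697, nalm6"
        )
    return p


def get_preset(name: str) -> ModelParameters:
    """Load a named cell-line preset ('697' or 'nalm6')."""
    name = name.lower()
    base = yaml.safe_load(preset_path("base").read_text())
    over = yaml.safe_load(preset_path(name).read_text())
    base.update(over)
    return load_config(base)
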