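"""Temperature ↔ Young's-modulus surrogate map and modulus-field grading.

The grading trick represents each measured modulus as a "temperature":
a strictly increasing linear map sends moduli to temperatures, seed nodes
are held at the mapped temperatures, the steady-state conduction solve
interpolates them through the structure, and the inverse map turns the
temperature field back into a spatially graded modulus field.

The default map is proportional through the origin, anchored so that the
mid-range cortical modulus of 17.3 GPa corresponds to 50 °C.  An affine
variant (nonzero intercept) is available; it must remain strictly
increasing and positive over its range of use.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

from .mesh import TetMesh

GPA = 1e9

#: the anchor pairing used for all defaults: mid-range cortical modulus at 50 degC
DEFAULT_ANCHOR_MODULUS_PA = 17.3 * GPA
DEFAULT_ANCHOR_TEMPERATURE_C = 50.0


@dataclass(frozen=True)
class ModulusTemperatureMap:
    """Affine surrogate map E(T) = slope * T + intercept (Pa, °C).

    ``proportional`` mode fixes intercept = 0 so E(T) = (E_a / T_a) T.
    """

    anchor_modulus: float = DEFAULT_ANCHOR_MODULUS_PA
    anchor_temperature: float = DEFAULT_ANCHOR_TEMPERATURE_C
    mode: str = "proportional"
    intercept: float = 0.0

    def __post_init__(self) -> None:
        if self.mode not in ("proportional", "affine"):
            raise ValueError(f"unknown map mode {self.mode!r}")
        if not self.anchor_modulus > 0:
            raise ValueError("anchor modulus must be positive")
        if self.mode == "proportional":
            if self.anchor_temperature == 0:
                raise ValueError("proportional map undefined for anchor temperature 0")
            object.__setattr__(self, "intercept", 0.0)
        if self.slope <= 0:
            raise ValueError("map must be strictly increasing in temperature")

    @property
    def slope(self) -> float:
        """Pa per °C."""
        return (self.anchor_modulus - self.intercept) / self.anchor_temperature

    def modulus_of(self, temperature):
        """E(T) in Pa."""
        return self.slope * np.asarray(temperature, dtype=float) + self.intercept

    def temperature_of(self, modulus):
        """Inverse map T(E) in °C."""
        return (np.asarray(modulus, dtype=float) - self.intercept) / self.slope


def build_map(
    anchor_modulus: float = DEFAULT_ANCHOR_MODULUS_PA,
    anchor_temperature: float = DEFAULT_ANCHOR_TEMPERATURE_C,
    mode: str = "proportional",
    intercept: float = 0.0,
) -> ModulusTemperatureMap:
    """Construct the linear modulus↔temperature surrogate map."""
    return ModulusTemperatureMap(anchor_modulus, anchor_temperature, mode, intercept)


@dataclass
class RegionTable:
    """Region label → (Young's modulus Pa, Poisson's ratio).

    The packaged fixture ``table1_strait2005.csv`` holds the 17 regional
    isotropic property records for the macaque cranium (E in GPa from 0.64
    trabecular to 20.8 anterior zygomatic arch).
    """

    table: pd.DataFrame  # columns: region (index), E (Pa), nu
    provenance: str = ""

    def __post_init__(self) -> None:
        if self.table["E"].le(0).any():
            bad = self.table.index[self.table["E"] <= 0][0]
            raise ValueError(f"region {bad!r}: Young's modulus must be positive")
        if (self.table["nu"].lt(0) | self.table["nu"].ge(0.5)).any():
            bad = self.table.index[(self.table["nu"] < 0) | (self.table["nu"] >= 0.5)][0]
            raise ValueError(f"region {bad!r}: Poisson's ratio must satisfy 0 <= nu < 0.5")
        if not self.table.index.is_unique:
            raise ValueError("region labels must be unique")

    @classmethod
    def from_csv(cls, path: str | Path, provenance: str = "") -> "RegionTable":
        """Read a CSV with columns (region, E_GPa, nu); moduli converted to Pa."""
        df = pd.read_csv(path)
        cols = {c.lower().strip(): c for c in df.columns}
        if "region" not in cols:
            raise ValueError(f"{path}: material table needs a 'region' column")
        if "e_gpa" in cols:
            E = df[cols["e_gpa"]].to_numpy(dtype=float) * GPA
        elif "e_pa" in cols:
            E = df[cols["e_pa"]].to_numpy(dtype=float)
        else:
            raise ValueError(f"{path}: material table needs an 'E_GPa' (or 'E_Pa') column")
        if "nu" not in cols:
            raise ValueError(f"{path}: material table needs a 'nu' column")
        out = pd.DataFrame(
            {"E": E, "nu": df[cols["nu"]].to_numpy(dtype=float)},
            index=pd.Index(df[cols["region"]].astype(str).str.strip(), name="region"),
        )
        return cls(out, provenance=provenance or str(path))

    @classmethod
    def packaged_table1(cls) -> "RegionTable":
        """The bundled 17-region macaque cranial property table."""
        ref = resources.files("thermograde") / "data" / "table1_strait2005.csv"
        with resources.as_file(ref) as p:
            return cls.from_csv(p, provenance="regional isotropic macaque cranial properties")

    def __len__(self) -> int:
        return len(self.table)

    @property
    def regions(self) -> list[str]:
        return list(self.table.index)

    def modulus(self, region: str) -> float:
        self._require(region)
        return float(self.table.loc[region, "E"])

    def poisson(self, region: str) -> float:
        self._require(region)
        return float(self.table.loc[region, "nu"])

    def _require(self, region: str) -> None:
        if region not in self.table.index:
            raise KeyError(f"region {region!r} not in material table; known: {self.regions}")


@dataclass(frozen=True)
class MaterialPoint:
    """Isotropic material state at a point; shear modulus is always derived."""

    E: float
    nu: float

    @property
    def G(self) -> float:
        """Isotropic shear modulus E / (2 (1 + nu)) — never an independent input."""
        return self.E / (2.0 * (1.0 + self.nu))


def table_to_seed_temperatures(
    table: RegionTable,
    seed_nodes: dict[str, int | list[int]],
    emap: ModulusTemperatureMap | None = None,
):
    """Map each seed region's modulus to a seed temperature.

    ``seed_nodes`` maps region label → node index (or list of node indices).
    Returns parallel arrays (node_ids, temperatures) ready for a
    :class:`~thermograde.thermal.SeedSet`.
    """
    emap = emap or ModulusTemperatureMap()
    unknown = [r for r in seed_nodes if r not in table.table.index]
    if unknown:
        raise KeyError(f"regions not in material table: {unknown}")
    ids, temps = [], []
    for region, nodes in seed_nodes.items():
        t = float(emap.temperature_of(table.modulus(region)))
        for nid in np.atleast_1d(nodes):
            ids.append(int(nid))
            temps.append(t)
    return np.array(ids, dtype=np.intp), np.array(temps)


def temperature_to_modulus_field(
    temperature: np.ndarray, emap: ModulusTemperatureMap | None = None
) -> np.ndarray:
    """Pointwise application of the map to a nodal temperature field (Pa out)."""
    emap = emap or ModulusTemperatureMap()
    E = emap.modulus_of(temperature)
    if np.any(E <= 0):
        bad = int(np.nonzero(E <= 0)[0][0])
        raise ValueError(
            f"node {bad}: temperature {temperature[bad]:g} maps to non-positive "
            f"modulus {E[bad]:g} Pa"
        )
    return E


#: standard 4-point tet quadrature in barycentric coordinates (degree 2)
_TET4_QUAD_A = 0.5854101966249685  # (5 + 3 sqrt 5) / 20
_TET4_QUAD_B = 0.1381966011250105  # (5 - sqrt 5) / 20
TET4_QUADRATURE_BARY = np.full((4, 4), _TET4_QUAD_B) + np.eye(4) * (
    _TET4_QUAD_A - _TET4_QUAD_B
)


def element_modulus(mesh: TetMesh, E_field: np.ndarray, rule: str = "centroid") -> np.ndarray:
    """Evaluate a nodal modulus field at element quadrature points.

    ``centroid`` (default): one value per element, the mean of its four nodal
    values — the linear interpolant at the barycenter, which integrates the
    linearly varying stiffness exactly against the constant strain of a
    linear tet.  ``four_point``: (n_tets, 4) values at the standard degree-2
    quadrature locations.
    """
    E_field = np.asarray(E_field, dtype=float)
    if len(E_field) != mesh.n_nodes:
        raise ValueError("modulus field must have one value per node")
    nodal = E_field[mesh.tets]  # (n_tets, 4)
    if rule == "centroid":
        return nodal.mean(axis=1)
    if rule == "four_point":
        return nodal @ TET4_QUADRATURE_BARY.T
    raise ValueError(f"unknown quadrature rule {rule!r}")
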