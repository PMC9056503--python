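"""Proton stopping power, CSDA range and energy degradation through layers.

The package bundles mass stopping-power tables for water, air and kapton
(polyimide), computed from the Bethe formula with ICRU-49 mean excitation
energies — see the ``# provenance`` header of each CSV and
``scripts/make_stopping_tables.py``.  Interpolation is log-log linear;
below the tabulated grid a power law S ∝ E^{-q} is assumed, with q taken
from the slope of the two lowest grid points.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "StoppingPowerTable",
    "BeamlineGeometry",
    "load_table",
    "interpolate_sp",
    "csda_range",
    "energy_after_layers",
    "BeamStoppedError",
    "MEV_PER_G_TO_GY",
]

#: Gy per (MeV/g): 1 MeV = 1.602176634e-13 J and 1 g = 1e-3 kg.
MEV_PER_G_TO_GY = 1.602176634e-10

#: Elementary charge in coulomb, for converting beam current to protons/s.
ELEMENTARY_CHARGE_C = 1.602176634e-19


class BeamStoppedError(ValueError):
    """Raised when a proton stops inside a beamline layer."""

    def __init__(self, layer_index: int, material: str, residual_range_cm: float):
        self.layer_index = layer_index
        self.material = material
        self.residual_range_cm = residual_range_cm
        super().__init__(
            f"beam stopped in layer {layer_index} ({material}); "
            f"residual range on entering the layer was "
            f"{residual_range_cm:.4g} cm"
        )


@dataclass(frozen=True)
class StoppingPowerTable:
    """Tabulated proton mass stopping power for one material.

    ``energies_MeV`` must be strictly increasing, stopping powers and
    density strictly positive.  Queries outside the grid are rejected.
    """

    material: str
    density_g_cm3: float
    energies_MeV: np.ndarray
    mass_sp_MeV_cm2_per_g: np.ndarray
    provenance: str = ""
    _log_e: np.ndarray = field(init=False, repr=False)
    _log_s: np.ndarray = field(init=False, repr=False)

    def __post_init__(self) -> None:
        e = np.asarray(self.energies_MeV, dtype=float)
        s = np.asarray(self.mass_sp_MeV_cm2_per_g, dtype=float)
        if e.ndim != 1 or e.size < 2:
            raise ValueError("need at least two grid energies")
        if np.any(np.diff(e) <= 0):
            raise ValueError("energy grid must be strictly increasing")
        if np.any(s <= 0):
            raise ValueError("stopping powers must be positive")
        if self.density_g_cm3 <= 0:
            raise ValueError("density must be positive")
        object.__setattr__(self, "energies_MeV", e)
        object.__setattr__(self, "mass_sp_MeV_cm2_per_g", s)
        object.__setattr__(self, "_log_e", np.log(e))
        object.__setattr__(self, "_log_s", np.log(s))

    @property
    def e_min(self) -> float:
        return float(self.energies_MeV[0])

    @property
    def e_max(self) -> float:
        return float(self.energies_MeV[-1])

    def __call__(self, E_MeV) -> np.ndarray | float:
        return interpolate_sp(self, E_MeV)

    @property
    def low_energy_exponent(self) -> float:
        """Power-law exponent q of S ∝ E^{-q} at the bottom of the grid."""
        return float(-(self._log_s[1] - self._log_s[0]) / (self._log_e[1] - self._log_e[0]))


def load_table(source: str | Path) -> StoppingPowerTable:
    """Load a stopping-power table from a bundled material name or CSV path.

    Bundled materials: ``"water"``, ``"air"``, ``"kapton"``.  The CSV
    dialect is two columns ``energy_MeV,mass_sp_MeV_cm2_per_g`` preceded by
    ``#``-prefixed header lines carrying material, density and provenance.
    """
    name = str(source)
    if name in ("water", "air", "kapton"):
        text = resources.files("actipet.data").joinpath(f"{name}_bethe.csv").read_text()
    else:
        text = Path(source).read_text()
    meta: dict[str, str] = {}
    body_lines = []
    for line in text.splitlines():
        if line.startswith("#"):
            key, _, value = line.lstrip("# ").partition(":")
            meta[key.strip()] = value.strip()
        else:
            body_lines.append(line)
    df = pd.read_csv(io.StringIO("\n".join(body_lines)))
    return StoppingPowerTable(
        material=meta.get("material", name),
        density_g_cm3=float(meta["density_g_cm3"]),
        energies_MeV=df["energy_MeV"].to_numpy(),
        mass_sp_MeV_cm2_per_g=df["mass_sp_MeV_cm2_per_g"].to_numpy(),
        provenance=meta.get("provenance", ""),
    )


def interpolate_sp(table: StoppingPowerTable, E_MeV) -> np.ndarray | float:
    """Mass stopping power at ``E_MeV`` by log-log linear interpolation.

    Exact at grid nodes; raises for queries outside the grid.
    """
    e = np.asarray(E_MeV, dtype=float)
    if np.any(e < table.e_min) or np.any(e > table.e_max):
        raise ValueError(
            f"energy outside {table.material} grid "
            f"[{table.e_min:.4g}, {table.e_max:.4g}] MeV"
        )
    out = np.exp(np.interp(np.log(e), table._log_e, table._log_s))
    return float(out) if np.isscalar(E_MeV) else out


def _range_below_grid(table: StoppingPowerTable, E_MeV: float) -> float:
    # power-law tail: S = S(E0) (E/E0)^-q  =>  ∫0^E dE'/S = E^{1+q}/(S0 E0^q (1+q))
    q = table.low_energy_exponent
    e0 = table.e_min
    s0 = float(table.mass_sp_MeV_cm2_per_g[0])
    return (E_MeV ** (1.0 + q)) / (s0 * e0**q * (1.0 + q)) / table.density_g_cm3


def csda_range(table: StoppingPowerTable, E_MeV: float, rtol: float = 1e-4) -> float:
    """CSDA range in cm: ∫₀^E dE'/(ρ·S(E')), adaptive trapezoid quadrature.

    The integral over the tabulated grid uses a log-spaced sub-grid whose
    density is doubled until the result changes by less than ``rtol``;
    the tail below the grid uses the declared power-law extrapolation.
    """
    if E_MeV <= table.e_min:
        if E_MeV <= 0:
            raise ValueError("energy must be positive")
        return _range_below_grid(table, E_MeV)
    if E_MeV > table.e_max:
        raise ValueError(
            f"energy above {table.material} grid maximum {table.e_max:.4g} MeV"
        )

    tail = _range_below_grid(table, table.e_min)
    n = 64
    prev = None
    while True:
        grid = np.geomspace(table.e_min, E_MeV, n)
        integral = np.trapezoid(1.0 / interpolate_sp(table, grid), grid)
        if prev is not None and abs(integral - prev) <= rtol * abs(integral):
            break
        prev = integral
        n *= 2
        if n > 1 << 18:  # pragma: no cover - safety stop
            break
    return integral / table.density_g_cm3 + tail


@dataclass(frozen=True)
class BeamlineGeometry:
    """Ordered material layers a beam traverses before reaching the target.

    ``layers`` is a list of ``(table, thickness_cm)`` pairs; thicknesses
    must be non-negative.
    """

    layers: tuple
    entry_energy_MeV: float

    def __post_init__(self) -> None:
        layers = tuple(self.layers)
        for table, t in layers:
            if not isinstance(table, StoppingPowerTable):
                raise TypeError("each layer needs a StoppingPowerTable")
            if t < 0:
                raise ValueError("layer thickness must be >= 0")
        if self.entry_energy_MeV <= 0:
            raise ValueError("entry energy must be positive")
        object.__setattr__(self, "layers", layers)

    @classmethod
    def from_names(cls, layers, entry_energy_MeV):
        """Build from ``(material_name, thickness_cm)`` pairs."""
        return cls(
            tuple((load_table(n), t) for n, t in layers),
            entry_energy_MeV,
        )


def _degrade_through(table: StoppingPowerTable, E0: float, thickness_cm: float,
                     max_step_MeV: float = 0.002) -> float:
    """Slow a proton through one homogeneous layer; midpoint stepping in
    areal density with steps bounded by ``max_step_MeV`` energy loss."""
    areal = thickness_cm * table.density_g_cm3  # g/cm^2
    if areal == 0.0:
        return E0
    E = E0
    remaining = areal
    while remaining > 0.0:
        s1 = interpolate_sp(table, E)
        dx = min(remaining, max_step_MeV / s1)
        e_mid = E - 0.5 * s1 * dx
        if e_mid <= table.e_min:
            return -1.0
        dE = interpolate_sp(table, e_mid) * dx
        E -= dE
        if E <= table.e_min:
            return -1.0
        remaining -= dx
    return E


def energy_after_layers(geom: BeamlineGeometry) -> tuple[float, float]:
    """Exit energy and total energy loss after traversing all layers.

    Raises :class:`BeamStoppedError` if the proton's energy falls to the
    usable bottom of a layer's table before the stack is exhausted.
    """
    E = geom.entry_energy_MeV
    for k, (table, t) in enumerate(geom.layers):
        E_next = _degrade_through(table, E, t)
        if E_next < 0.0:
            raise BeamStoppedError(k, table.material, csda_range(table, E))
        E = E_next
    return E, geom.entry_energy_MeV - E
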