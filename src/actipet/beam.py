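"""Gaussian pencil-beam spot model, fluence maps and surface-dose maps.

A low-energy proton spot is modelled as a single 2-D Gaussian whose lateral
spreads σx, σy grow with distance from the exit window; their longitudinal
variation is described by a second-degree polynomial per axis.  An
irradiation plan is a list of spots (position, dwell time, beam current);
the fluence it delivers is the sum of the per-spot Gaussians, and the
surface dose follows from the fluence and the mean mass stopping power over
a thin slab.

Coordinates are beam's-eye-view millimetres on a regular grid of cell
centres, origin at the plan centroid by default.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import optimize

from .stopping import (
    ELEMENTARY_CHARGE_C,
    MEV_PER_G_TO_GY,
    StoppingPowerTable,
    csda_range,
    interpolate_sp,
)

__all__ = [
    "SpotShapeModel",
    "Spot",
    "SpotPlan",
    "reference_plan",
    "FluenceMap",
    "DoseMap",
    "sigma_at",
    "fit_sigma_polynomial",
    "fit_gaussian_spot",
    "fluence_at",
    "fluence_map",
    "surface_dose",
    "dose_map",
]


@dataclass(frozen=True)
class SpotShapeModel:
    """σx(z), σy(z) in mm as degree-2 polynomials of distance z in cm.

    Coefficients are stored lowest order first: σ(z) = c0 + c1·z + c2·z².
    """

    coeffs_x: tuple[float, float, float]
    coeffs_y: tuple[float, float, float]
    z_domain_cm: tuple[float, float] = (0.0, 10.0)
    residuals_x: tuple = ()
    residuals_y: tuple = ()

    @classmethod
    def constant(cls, sigma_x_mm: float, sigma_y_mm: float) -> "SpotShapeModel":
        return cls((sigma_x_mm, 0.0, 0.0), (sigma_y_mm, 0.0, 0.0))


def sigma_at(model: SpotShapeModel, z_cm: float) -> tuple[float, float]:
    """Evaluate the spot spreads (σx, σy) in mm at distance ``z_cm``."""
    lo, hi = model.z_domain_cm
    if not lo <= z_cm <= hi:
        raise ValueError(f"z = {z_cm} cm outside declared domain [{lo}, {hi}]")
    sx = float(np.polyval(model.coeffs_x[::-1], z_cm))
    sy = float(np.polyval(model.coeffs_y[::-1], z_cm))
    if sx <= 0 or sy <= 0:
        raise ValueError(f"non-positive spot spread at z = {z_cm} cm")
    return sx, sy


def fit_sigma_polynomial(obs_x, obs_y=None, z_domain_cm=None) -> SpotShapeModel:
    """Least-squares degree-2 fit of σ(z) per axis.

    ``obs_x`` (and optionally ``obs_y``) are sequences of ``(z_cm,
    sigma_mm)`` pairs; at least three distinct z values are required per
    axis.  If ``obs_y`` is omitted the x observations are reused for y.
    """
    if obs_y is None:
        obs_y = obs_x

    def _fit(obs):
        z = np.asarray([p[0] for p in obs], dtype=float)
        s = np.asarray([p[1] for p in obs], dtype=float)
        if np.unique(z).size < 3:
            raise ValueError("need >= 3 distinct z values for a degree-2 fit")
        design = np.vander(z, 3, increasing=True)
        coeffs, res, rank, _ = np.linalg.lstsq(design, s, rcond=None)
        if rank < 3:
            raise ValueError("degenerate design matrix in sigma polynomial fit")
        residuals = s - design @ coeffs
        return tuple(coeffs), tuple(residuals)

    cx, rx = _fit(obs_x)
    cy, ry = _fit(obs_y)
    if z_domain_cm is None:
        z_all = [p[0] for p in obs_x] + [p[0] for p in obs_y]
        z_domain_cm = (min(z_all), max(z_all))
    return SpotShapeModel(cx, cy, z_domain_cm, rx, ry)


def fit_gaussian_spot(image, pitch_mm: float):
    """Fit a single 2-D Gaussian to a spot image.

    Initial centre and spreads come from image moments; they are refined
    by least squares on a Gaussian with free amplitude, centre, spreads
    and constant baseline.  Returns ``(sigma_x_mm, sigma_y_mm, (x0_mm,
    y0_mm))`` with coordinates relative to the image's lower-left cell
    centre.
    """
    img = np.asarray(image, dtype=float)
    if img.ndim != 2:
        raise ValueError("image must be 2-D")
    if np.any(img < 0):
        raise ValueError("image must be non-negative")
    if img.max() <= 0 or np.ptp(img) == 0:
        raise ValueError("flat or empty image: no spot to fit")

    ny, nx = img.shape
    x = np.arange(nx) * pitch_mm
    y = np.arange(ny) * pitch_mm
    xx, yy = np.meshgrid(x, y)

    w = img - img.min()
    tot = w.sum()
    x0 = float((w * xx).sum() / tot)
    y0 = float((w * yy).sum() / tot)
    sx0 = float(np.sqrt((w * (xx - x0) ** 2).sum() / tot)) or pitch_mm
    sy0 = float(np.sqrt((w * (yy - y0) ** 2).sum() / tot)) or pitch_mm

    def model(p):
        amp, cx, cy, sx, sy, base = p
        return amp * np.exp(
            -((xx - cx) ** 2) / (2 * sx**2) - ((yy - cy) ** 2) / (2 * sy**2)
        ) + base

    def resid(p):
        return (model(p) - img).ravel()

    p0 = [float(img.max() - img.min()), x0, y0, sx0, sy0, float(img.min())]
    sol = optimize.least_squares(
        resid, p0,
        bounds=([0, x[0] - pitch_mm, y[0] - pitch_mm, pitch_mm / 10, pitch_mm / 10, -np.inf],
                [np.inf, x[-1] + pitch_mm, y[-1] + pitch_mm, np.inf, np.inf, np.inf]),
    )
    if not sol.success:
        raise RuntimeError(f"gaussian spot fit failed: {sol.message}")
    _, cx, cy, sx, sy, _ = sol.x
    return float(sx), float(sy), (float(cx), float(cy))


@dataclass(frozen=True)
class Spot:
    x_mm: float
    y_mm: float
    dwell_time_s: float
    beam_current_nA: float

    def __post_init__(self) -> None:
        if self.dwell_time_s <= 0:
            raise ValueError("dwell time must be positive")
        if self.beam_current_nA <= 0:
            raise ValueError("beam current must be positive")

    @property
    def protons(self) -> float:
        """Protons delivered: N = I·t/e."""
        return self.beam_current_nA * 1e-9 * self.dwell_time_s / ELEMENTARY_CHARGE_C


@dataclass(frozen=True)
class SpotPlan:
    """An irradiation plan: spots plus the beam energy entering the target."""

    spots: tuple[Spot, ...]
    entry_energy_MeV: float

    def __post_init__(self) -> None:
        object.__setattr__(self, "spots", tuple(self.spots))

    @property
    def total_protons(self) -> float:
        return sum(s.protons for s in self.spots)

    @property
    def centroid_mm(self) -> tuple[float, float]:
        if not self.spots:
            return (0.0, 0.0)
        return (
            float(np.mean([s.x_mm for s in self.spots])),
            float(np.mean([s.y_mm for s in self.spots])),
        )

    @classmethod
    def grid(cls, n: int, pitch_mm: float, dwell_time_s: float,
             beam_current_nA: float, entry_energy_MeV: float) -> "SpotPlan":
        """A centred n×n square grid of identical spots."""
        offs = (np.arange(n) - (n - 1) / 2.0) * pitch_mm
        spots = [
            Spot(float(x), float(y), dwell_time_s, beam_current_nA)
            for y in offs for x in offs
        ]
        return cls(tuple(spots), entry_energy_MeV)


def reference_plan() -> SpotPlan:
    """The 3×3 study plan: 1.2-mm pitch, 10 s per spot at 6.0 nA, 7.5 MeV
    entering the target."""
    return SpotPlan.grid(3, 1.2, 10.0, 6.0, 7.5)


@dataclass(frozen=True)
class _GridMap:
    origin_mm: tuple[float, float]  # coordinates of cell centre [0, 0]
    pitch_mm: float
    values: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if np.any(v < 0):
            raise ValueError("map values must be non-negative")
        object.__setattr__(self, "values", v)

    @property
    def x_mm(self) -> np.ndarray:
        return self.origin_mm[0] + np.arange(self.values.shape[1]) * self.pitch_mm

    @property
    def y_mm(self) -> np.ndarray:
        return self.origin_mm[1] + np.arange(self.values.shape[0]) * self.pitch_mm

    def value_at_centre(self) -> float:
        """Value of the cell nearest the (0, 0) coordinate."""
        ix = int(np.argmin(np.abs(self.x_mm)))
        iy = int(np.argmin(np.abs(self.y_mm)))
        return float(self.values[iy, ix])

    def export(self, path_prefix: str | Path, units: str) -> None:
        """Write the grid as delimited text plus a JSON geometry sidecar."""
        prefix = Path(path_prefix)
        np.savetxt(prefix.with_suffix(".txt"), self.values, fmt="%.6e")
        sidecar = {
            "origin_mm": list(self.origin_mm),
            "pitch_mm": self.pitch_mm,
            "shape": list(self.values.shape),
            "units": units,
        }
        prefix.with_suffix(".json").write_text(json.dumps(sidecar, indent=2))


@dataclass(frozen=True)
class FluenceMap(_GridMap):
    """2-D proton fluence in protons/cm² on a regular grid."""

    total_protons: float = 0.0

    def integral_protons(self) -> float:
        """Grid integral (values × cell area) in protons."""
        cell_cm2 = (self.pitch_mm / 10.0) ** 2
        return float(self.values.sum() * cell_cm2)


@dataclass(frozen=True)
class DoseMap(_GridMap):
    """2-D surface dose in Gy, averaged over ``averaging_depth_um``."""

    averaging_depth_um: float = 100.0

    def isodose_contours(self, levels_gy) -> dict[float, list]:
        """Contour polygons (lists of [x_mm, y_mm] vertices) per level."""
        from skimage import measure

        out: dict[float, list] = {}
        for level in levels_gy:
            polys = []
            for contour in measure.find_contours(self.values, level):
                xy = np.column_stack([
                    self.origin_mm[0] + contour[:, 1] * self.pitch_mm,
                    self.origin_mm[1] + contour[:, 0] * self.pitch_mm,
                ])
                polys.append(xy.tolist())
            out[float(level)] = polys
        return out


def fluence_at(plan: SpotPlan, sigma_x_mm: float, sigma_y_mm: float,
               x_mm, y_mm) -> np.ndarray | float:
    """Point fluence in protons/cm² at beam's-eye-view coordinates.

    Each spot contributes N/(2π σx σy)·exp(−Δx²/2σx² − Δy²/2σy²); the
    1/mm² density is converted to 1/cm².
    """
    x = np.asarray(x_mm, dtype=float)
    y = np.asarray(y_mm, dtype=float)
    per_mm2 = np.zeros(np.broadcast(x, y).shape)
    norm = 2.0 * np.pi * sigma_x_mm * sigma_y_mm
    for s in plan.spots:
        per_mm2 = per_mm2 + (s.protons / norm) * np.exp(
            -((x - s.x_mm) ** 2) / (2 * sigma_x_mm**2)
            - ((y - s.y_mm) ** 2) / (2 * sigma_y_mm**2)
        )
    out = per_mm2 * 100.0  # 1/mm² -> 1/cm²
    return float(out) if out.ndim == 0 else out


def fluence_map(plan: SpotPlan, sigma_x_mm: float, sigma_y_mm: float,
                pitch_mm: float = 0.05, half_extent_mm: float = 5.0,
                edge_action: str = "warn") -> FluenceMap:
    """Grid the plan's fluence around its centroid.

    The grid must cover ≥ 4σ beyond the outermost spot; if the edge value
    exceeds 10⁻³ of the maximum the map is incomplete and, depending on
    ``edge_action`` (``"warn"`` | ``"error"`` | ``"ignore"``), a warning
    or error is raised.
    """
    cx, cy = plan.centroid_mm
    n = int(round(2 * half_extent_mm / pitch_mm)) + 1
    x = cx - half_extent_mm + np.arange(n) * pitch_mm
    y = cy - half_extent_mm + np.arange(n) * pitch_mm
    xx, yy = np.meshgrid(x, y)
    values = (
        fluence_at(plan, sigma_x_mm, sigma_y_mm, xx, yy)
        if plan.spots else np.zeros_like(xx)
    )
    if plan.spots:
        edge_max = max(values[0].max(), values[-1].max(),
                       values[:, 0].max(), values[:, -1].max())
        if edge_max > 1e-3 * values.max():
            msg = (f"grid edge fluence {edge_max:.3g} exceeds 1e-3 of the "
                   f"maximum; enlarge half_extent_mm")
            if edge_action == "error":
                raise ValueError(msg)
            if edge_action == "warn":
                warnings.warn(msg, stacklevel=2)
    return FluenceMap((float(x[0]), float(y[0])), pitch_mm, values,
                      total_protons=plan.total_protons)


def mean_stopping_power(table: StoppingPowerTable, E_MeV: float,
                        slab_um: float, n_steps: int = 200) -> float:
    """Mean mass stopping power (MeV·cm²/g) over a thin slab, computed by
    slowing the proton across the slab in equal areal-density steps."""
    areal = slab_um * 1e-4 * table.density_g_cm3  # g/cm^2
    if areal <= 0:
        raise ValueError("slab thickness must be positive")
    dx = areal / n_steps
    E = E_MeV
    deposited = 0.0
    for _ in range(n_steps):
        s = interpolate_sp(table, E)
        dE = s * dx
        if E - dE <= table.e_min:
            raise ValueError(
                f"slab of {slab_um} µm exceeds the residual range at "
                f"{E_MeV} MeV in {table.material}"
            )
        deposited += dE
        E -= dE
    return deposited / areal


def surface_dose(fluence_p_cm2: float, E_MeV: float, slab_um: float,
                 table: StoppingPowerTable) -> float:
    """Surface dose in Gy: fluence × mean mass stopping power over the slab.

    The slab must be much thinner than the CSDA range at ``E_MeV``.
    """
    if fluence_p_cm2 < 0:
        raise ValueError("fluence must be >= 0")
    if fluence_p_cm2 == 0.0:
        return 0.0
    if slab_um * 1e-4 >= csda_range(table, E_MeV):
        raise ValueError("slab exceeds the CSDA range; not a surface dose")
    s_mean = mean_stopping_power(table, E_MeV, slab_um)
    return fluence_p_cm2 * s_mean * MEV_PER_G_TO_GY


def dose_map(plan: SpotPlan, sigma_x_mm: float, sigma_y_mm: float,
             table: StoppingPowerTable, slab_um: float = 100.0,
             pitch_mm: float = 0.05, half_extent_mm: float = 5.0,
             edge_action: str = "warn") -> DoseMap:
    """Surface-dose map: per-cell fluence × the slab-mean stopping power."""
    fmap = fluence_map(plan, sigma_x_mm, sigma_y_mm, pitch_mm,
                       half_extent_mm, edge_action)
    if plan.spots:
        if slab_um * 1e-4 >= csda_range(table, plan.entry_energy_MeV):
            raise ValueError("slab exceeds the CSDA range; not a surface dose")
        factor = mean_stopping_power(table, plan.entry_energy_MeV, slab_um) \
            * MEV_PER_G_TO_GY
    else:
        factor = 0.0
    return DoseMap(fmap.origin_mm, fmap.pitch_mm, fmap.values * factor,
                   averaging_depth_um=slab_um)
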