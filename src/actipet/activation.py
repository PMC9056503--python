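"""Isotope-production yields in ¹⁸O-enriched tissue and ¹⁸O-enrichment inference.

For a thick target irradiated with protons of energy Ep, the number of
nuclei of each isotope produced is proportional to the target atom density
and the integrated production cross section:

    A(¹⁸F) = A₀ · N_O · f(¹⁸O)     · ∫₀^Ep σ_{¹⁸O(p,n)¹⁸F}(E) dE
    A(¹³N) = A₀ · N_O · (1−f(¹⁸O)) · ∫₀^Ep σ_{¹⁶O(p,X)¹³N}(E) dE
    A(¹¹C) = A₀ · N_N               · ∫₀^Ep σ_{¹⁴N(p,X)¹¹C}(E) dE

where N_O, N_N are oxygen and nitrogen atoms per gram, f(¹⁸O) is the
fraction of oxygen atoms replaced by ¹⁸O, and A₀ collects everything
isotope-independent (dose, mass, detector efficiency).  Inverting the
¹⁸F/¹¹C ratio yields f(¹⁸O) from measured, decay-corrected amplitudes.

The expected ¹³N/¹¹C ratio exists in two conventions: ``mc_constant`` uses
the Monte-Carlo-calibrated constant 0.394·(1−f) that the study's fitting
constraint employed, while ``xs_integral`` evaluates the transparent
ratio of the yield expressions above.  The two disagree by a factor of
about 21 — the calibrated constant embeds the simulation's full σ(E) and
transport weighting, which the single packaged integrals cannot carry —
so the opaque constant is kept as the default for fitting constraints and
the transparent ratio as a documented alternative.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .isotopes import EP_GUARD_MEV, EP_REFERENCE_MEV, ISOTOPES
from .stopping import StoppingPowerTable, csda_range, interpolate_sp

__all__ = [
    "AVOGADRO",
    "MC_RATIO_13N_11C",
    "TissueComposition",
    "ActivationYields",
    "atoms_per_gram",
    "relative_yields",
    "expected_ratio_13N_11C",
    "infer_f18O",
    "predict_bp_activity",
]

AVOGADRO = 6.02214076e23

#: Monte-Carlo-calibrated A(¹³N)/A(¹¹C) ratio at f(¹⁸O)=0 (opaque constant).
MC_RATIO_13N_11C = 0.394

#: Nominal atomic masses used to convert mass fractions to atom counts.
ATOMIC_MASS = {"H": 1.0, "C": 12.0, "N": 14.0, "O": 16.0}


@dataclass(frozen=True)
class TissueComposition:
    """Elemental mass fractions of the target plus its ¹⁸O enrichment.

    ``f18O`` is the fraction of oxygen atoms that are ¹⁸O (0-1).  Mass
    fractions may sum to slightly less than 1 (trace elements ignored);
    sums outside [0.95, 1.05] are rejected.
    """

    mass_fractions: dict
    f18O: float = 0.0

    def __post_init__(self) -> None:
        for el, frac in self.mass_fractions.items():
            if not 0.0 <= frac <= 1.0:
                raise ValueError(f"mass fraction of {el} outside [0, 1]")
        total = sum(self.mass_fractions.values())
        if not 0.95 <= total <= 1.05:
            raise ValueError(f"mass fractions sum to {total:.3f}, not ~1")
        if not 0.0 <= self.f18O <= 1.0:
            raise ValueError("f18O must be in [0, 1]")
        object.__setattr__(self, "mass_fractions", dict(self.mass_fractions))

    @classmethod
    def squamous_cell_carcinoma(cls, f18O: float = 0.0) -> "TissueComposition":
        """H 9.8 %, C 19.5 %, N 4.8 %, O 65.0 % by mass (sum 99.1 %)."""
        return cls({"H": 0.098, "C": 0.195, "N": 0.048, "O": 0.650}, f18O)

    @classmethod
    def water(cls, f18O: float = 0.0) -> "TissueComposition":
        return cls({"H": 0.1119, "O": 0.8881}, f18O)


def atoms_per_gram(comp: TissueComposition) -> tuple[float, float]:
    """Oxygen and nitrogen atoms per gram: N_X = w_X · N_A / A_X."""
    n_o = comp.mass_fractions.get("O", 0.0) * AVOGADRO / ATOMIC_MASS["O"]
    n_n = comp.mass_fractions.get("N", 0.0) * AVOGADRO / ATOMIC_MASS["N"]
    return n_o, n_n


@dataclass(frozen=True)
class ActivationYields:
    """Per-isotope production yields in units of the normalisation A₀,
    referenced to the end of irradiation."""

    A_18F: float
    A_13N: float
    A_11C: float
    Ep_MeV: float = EP_REFERENCE_MEV

    def __post_init__(self) -> None:
        if min(self.A_18F, self.A_13N, self.A_11C) < 0:
            raise ValueError("yields must be >= 0")

    def as_dict(self) -> dict[str, float]:
        return {"18F": self.A_18F, "13N": self.A_13N, "11C": self.A_11C}


def _check_ep(Ep_MeV: float, user_integrals) -> None:
    if Ep_MeV >= EP_GUARD_MEV:
        raise ValueError(
            f"Ep = {Ep_MeV} MeV >= {EP_GUARD_MEV} MeV: the three-isotope "
            "model is invalid once 15O production opens"
        )
    if user_integrals is None and Ep_MeV != EP_REFERENCE_MEV:
        raise ValueError(
            f"packaged cross-section integrals are valid only at "
            f"Ep = {EP_REFERENCE_MEV} MeV; supply user integrals for "
            f"Ep = {Ep_MeV} MeV"
        )


def relative_yields(comp: TissueComposition, Ep_MeV: float = EP_REFERENCE_MEV,
                    A0: float = 1.0, user_integrals: dict | None = None
                    ) -> ActivationYields:
    """Per-isotope yields in units of A₀ for the given composition.

    ``user_integrals`` maps isotope name to ∫₀^Ep σ dE (mb·MeV) and is
    required for any Ep other than the packaged 7.5 MeV reference.
    """
    _check_ep(Ep_MeV, user_integrals)
    integrals = user_integrals or {
        k: v.integrated_xs_mb_MeV for k, v in ISOTOPES.items()
    }
    n_o, n_n = atoms_per_gram(comp)
    return ActivationYields(
        A_18F=A0 * n_o * comp.f18O * integrals["18F"],
        A_13N=A0 * n_o * (1.0 - comp.f18O) * integrals["13N"],
        A_11C=A0 * n_n * integrals["11C"],
        Ep_MeV=Ep_MeV,
    )


def expected_ratio_13N_11C(f18O: float, mode: str = "mc_constant",
                           comp: TissueComposition | None = None,
                           constant: float = MC_RATIO_13N_11C) -> float:
    """Expected A(¹³N)/A(¹¹C) for enrichment ``f18O``.

    ``mc_constant`` (default, used by the fitting constraint) returns
    (1−f)·0.394; ``xs_integral`` evaluates the transparent yield ratio
    for ``comp`` (default squamous-cell-carcinoma composition).
    """
    if not 0.0 <= f18O <= 1.0:
        raise ValueError("f18O must be in [0, 1]")
    if mode == "mc_constant":
        return (1.0 - f18O) * constant
    if mode == "xs_integral":
        comp = comp or TissueComposition.squamous_cell_carcinoma()
        n_o, n_n = atoms_per_gram(comp)
        if n_n == 0:
            raise ValueError("composition has no nitrogen; ratio undefined")
        return (
            n_o * (1.0 - f18O) * ISOTOPES["13N"].integrated_xs_mb_MeV
            / (n_n * ISOTOPES["11C"].integrated_xs_mb_MeV)
        )
    raise ValueError(f"unknown mode {mode!r}")


def infer_f18O(A_18F: float, A_11C: float, comp: TissueComposition,
               rel_err_18F: float = 0.0, rel_err_11C: float = 0.0
               ) -> tuple[float, float, bool]:
    """¹⁸O enrichment from decay-corrected ¹⁸F and ¹¹C amplitudes.

    Inverts the yield ratio:  f = (A¹⁸F/A¹¹C)·(N_N/N_O)·(I¹¹C/I¹⁸F).
    Relative uncertainties combine in quadrature.  Returns ``(f, sigma_f,
    clipped)``; ``clipped`` flags a result outside [0, 1] that was clipped.
    A_18F = 0 is allowed and maps to f = 0.
    """
    if A_18F < 0 or A_11C <= 0:
        raise ValueError("need A_18F >= 0 and A_11C > 0")
    n_o, n_n = atoms_per_gram(comp)
    if n_o == 0 or n_n == 0:
        raise ValueError("composition must contain both oxygen and nitrogen")
    f = (A_18F / A_11C) * (n_n / n_o) * (
        ISOTOPES["11C"].integrated_xs_mb_MeV
        / ISOTOPES["18F"].integrated_xs_mb_MeV
    )
    sigma = f * math.hypot(rel_err_18F, rel_err_11C)
    clipped = not 0.0 <= f <= 1.0
    return min(max(f, 0.0), 1.0), sigma, clipped


def predict_bp_activity(dose_gy: float, enrichment: float,
                        comp: TissueComposition | None = None,
                        table: StoppingPowerTable | None = None,
                        Ep_MeV: float = EP_REFERENCE_MEV) -> float:
    """Order-of-magnitude ¹⁸F activity (Bq/mm³) from a Bragg-peak dose.

    A deliberately transparent estimate:

    * fluence from dose via the energy-averaged mass stopping power S̄
      over the activation window [E_thr, Ep];
    * ¹⁸F nuclei per proton from the packaged ∫σdE divided by ρ·S̄;
    * nuclei spread uniformly over the activation path length
      R(Ep) − R(E_thr);
    * activity via λ(¹⁸F).

    The result is an order-of-magnitude figure only: the single packaged
    cross-section integral cannot reproduce a transport simulation's full
    σ(E) weighting (see the module docstring), and this estimator comes
    out roughly an order of magnitude below published Monte-Carlo values
    for comparable scenarios.
    """
    if dose_gy < 0:
        raise ValueError("dose must be >= 0")
    if not 0.0 <= enrichment <= 1.0:
        raise ValueError("enrichment must be in [0, 1]")
    if dose_gy == 0.0 or enrichment == 0.0:
        return 0.0
    from .stopping import MEV_PER_G_TO_GY  # local to avoid cycle at import

    comp = comp or TissueComposition.water()
    table = table if table is not None else _default_water()
    spec = ISOTOPES["18F"]
    _check_ep(Ep_MeV, user_integrals=None if Ep_MeV != EP_REFERENCE_MEV else {})

    import numpy as np

    e_grid = np.linspace(spec.threshold_MeV, Ep_MeV, 200)
    s_bar = float(np.trapezoid(interpolate_sp(table, e_grid), e_grid)
                  / (Ep_MeV - spec.threshold_MeV))
    fluence = dose_gy / (s_bar * MEV_PER_G_TO_GY)  # protons/cm^2
    n_o, _ = atoms_per_gram(comp)
    n_18o = n_o * enrichment * table.density_g_cm3  # atoms/cm^3
    xs_cm2_mev = spec.integrated_xs_mb_MeV * 1e-27  # mb·MeV -> cm²·MeV
    per_proton = n_18o * xs_cm2_mev / (table.density_g_cm3 * s_bar)
    L_act_cm = csda_range(table, Ep_MeV) - csda_range(table, spec.threshold_MeV)
    nuclei_per_cm3 = fluence * per_proton / L_act_cm
    activity_bq_cm3 = nuclei_per_cm3 * spec.decay_constant_per_s
    return activity_bq_cm3 / 1000.0  # Bq/cm³ -> Bq/mm³


def _default_water() -> StoppingPowerTable:
    from .stopping import load_table

    return load_table("water")
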