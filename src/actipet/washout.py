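"""Biological washout of ¹⁸F: combined-half-life fitting and algebra.

A dynamic PET time-activity curve (TAC) of an irradiated, ¹⁸O-enriched
target decays as the product of the physical decay of ¹⁸F and a biological
clearance exponential:

    A(t) = A₀ · e^(−(λ_phys + λ_bio)·t),      λ_bio ≥ 0.

Reciprocal half-lives add: 1/T_comb = 1/T_phys + 1/T_bio, so a combined
half-life slightly below T_phys(¹⁸F) = 109.77 min implies a long biological
washout half-life.  The retained fraction at time t due to biology alone is
2^(−t/T_bio).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .isotopes import ISOTOPES, IsotopeSpec

__all__ = [
    "WashoutFitResult",
    "fit_washout",
    "combined_half_life",
    "washout_half_life",
    "biological_retention",
]


def combined_half_life(T_phys_min: float, T_bio_min: float) -> float:
    """T_comb from physical and biological half-lives: rates add.

    ``T_bio_min = inf`` (no washout) returns T_phys.
    """
    if T_phys_min <= 0 or T_bio_min <= 0:
        raise ValueError("half-lives must be positive")
    if math.isinf(T_bio_min):
        return T_phys_min
    return T_phys_min * T_bio_min / (T_phys_min + T_bio_min)


def washout_half_life(T_comb_min: float, T_phys_min: float) -> float:
    """Biological half-life from the combined and physical ones.

    Inverse of :func:`combined_half_life`; requires T_comb < T_phys.
    """
    if T_comb_min <= 0 or T_phys_min <= 0:
        raise ValueError("half-lives must be positive")
    if T_comb_min >= T_phys_min:
        raise ValueError(
            f"no positive washout: T_comb = {T_comb_min} min is not below "
            f"T_phys = {T_phys_min} min"
        )
    return T_comb_min * T_phys_min / (T_phys_min - T_comb_min)


def biological_retention(t_h: float, T_bio_h: float) -> float:
    """Fraction of activity retained at ``t_h`` by biology alone: 2^(−t/T_bio)."""
    if T_bio_h <= 0:
        raise ValueError("biological half-life must be positive")
    return 2.0 ** (-t_h / T_bio_h)


@dataclass(frozen=True)
class WashoutFitResult:
    """Result of the physical×biological exponential fit to a TAC.

    ``lambda_bio_per_min`` ≥ 0; ``T_bio_h`` is infinite when the fit pins
    λ_bio at zero (``no_washout``).  The identity
    1/T_comb = 1/T_phys + 1/T_bio holds exactly by construction.
    95 % confidence intervals use a t quantile with the fit's degrees of
    freedom on the covariance of (A₀, λ_bio).
    """

    A0: float
    lambda_bio_per_min: float
    T_phys_min: float
    cov: np.ndarray
    dof: int
    chi2: float
    no_washout: bool
    known_sd: bool = True

    @property
    def lambda_comb_per_min(self) -> float:
        return math.log(2.0) / self.T_phys_min + self.lambda_bio_per_min

    @property
    def T_comb_min(self) -> float:
        return math.log(2.0) / self.lambda_comb_per_min

    @property
    def T_bio_min(self) -> float:
        if self.no_washout or self.lambda_bio_per_min <= 0:
            return math.inf
        return math.log(2.0) / self.lambda_bio_per_min

    @property
    def T_bio_h(self) -> float:
        return self.T_bio_min / 60.0

    def _tq(self) -> float:
        """CI multiplier: normal when frame variances are known, Student-t
        when the noise scale was estimated from the residuals."""
        if self.known_sd:
            return float(stats.norm.ppf(0.975))
        return float(stats.t.ppf(0.975, self.dof)) if self.dof > 0 else math.inf

    @property
    def lambda_bio_ci95(self) -> tuple[float, float]:
        sd = math.sqrt(max(self.cov[1, 1], 0.0))
        half = self._tq() * sd
        return (self.lambda_bio_per_min - half, self.lambda_bio_per_min + half)

    @property
    def T_comb_ci95_min(self) -> tuple[float, float]:
        """CI on T_comb mapped from the λ_bio interval (clipped at λ_bio ≥ 0)."""
        lo, hi = self.lambda_bio_ci95
        lam_p = math.log(2.0) / self.T_phys_min
        return (math.log(2.0) / (lam_p + hi),
                math.log(2.0) / (lam_p + max(lo, 0.0)))

    @property
    def T_bio_ci95_h(self) -> tuple[float, float]:
        """CI on T_bio mapped from the λ_bio interval (lower λ → longer T)."""
        lo, hi = self.lambda_bio_ci95
        upper = math.inf if lo <= 0 else math.log(2.0) / lo / 60.0
        lower = math.inf if hi <= 0 else math.log(2.0) / hi / 60.0
        return (lower, upper)

    def as_dict(self) -> dict:
        return {
            "A0": self.A0,
            "lambda_bio_per_min": self.lambda_bio_per_min,
            "T_comb_min": self.T_comb_min,
            "T_bio_h": self.T_bio_h,
            "T_bio_ci95_h": list(self.T_bio_ci95_h),
            "lambda_bio_ci95_per_min": list(self.lambda_bio_ci95),
            "chi2": self.chi2,
            "dof": self.dof,
            "no_washout": self.no_washout,
        }


def _frame_model(t0, t1, lam, averaging: str):
    if averaging == "integral":
        return (np.exp(-lam * t0) - np.exp(-lam * t1)) / (lam * (t1 - t0))
    if averaging == "midpoint":
        return np.exp(-lam * 0.5 * (t0 + t1))
    raise ValueError(f"unknown frame averaging {averaging!r}")


def fit_washout(tac: pd.DataFrame, isotope: IsotopeSpec | None = None,
                frame_averaging: str = "integral") -> WashoutFitResult:
    """Fit A(t) = A₀·e^(−(λ_phys+λ_bio)t) to a frame-averaged TAC.

    ``tac`` needs columns ``frame_start_min``, ``frame_end_min``,
    ``mean_activity`` and optionally ``sd`` (used as weights when
    present and positive).  λ_phys is fixed at the isotope's (default
    ¹⁸F); λ_bio is bounded below by 0.  ``frame_averaging`` selects
    whether the model value for a frame is the decay integral over the
    frame (default) or the midpoint evaluation.
    """
    isotope = isotope or ISOTOPES["18F"]
    lam_p = isotope.decay_constant_per_min
    t0 = tac["frame_start_min"].to_numpy(dtype=float)
    t1 = tac["frame_end_min"].to_numpy(dtype=float)
    y = tac["mean_activity"].to_numpy(dtype=float)
    if len(y) < 3:
        raise ValueError("need at least 3 frames to fit washout")
    if "sd" in tac.columns and np.all(tac["sd"].to_numpy(dtype=float) > 0):
        sd = tac["sd"].to_numpy(dtype=float)
        known_sd = True
    else:
        sd = np.ones_like(y)
        known_sd = False

    # starting values from a log-linear regression on frame midpoints
    mid = 0.5 * (t0 + t1)
    pos = y > 0
    slope, intercept = np.polyfit(mid[pos], np.log(y[pos]), 1)
    lam_b0 = max(-slope - lam_p, 1e-8)
    a00 = float(np.exp(intercept))

    def resid(p):
        a0, lam_b = p
        lam = lam_p + lam_b
        return (a0 * _frame_model(t0, t1, lam, frame_averaging) - y) / sd

    sol = optimize.least_squares(resid, [a00, lam_b0],
                                 bounds=([0.0, 0.0], [np.inf, np.inf]),
                                 xtol=1e-14, ftol=1e-14, gtol=1e-14)
    if not sol.success:
        raise RuntimeError(f"washout fit failed: {sol.message}")
    a0, lam_b = sol.x
    dof = len(y) - 2
    chi2 = float(2 * sol.cost)
    # covariance from the Jacobian; sd column treated as known variances
    jtj = sol.jac.T @ sol.jac
    try:
        cov = np.linalg.inv(jtj)
    except np.linalg.LinAlgError:
        cov = np.full((2, 2), np.nan)
    # if no sd provided, scale by reduced chi-square (unknown noise level)
    if not known_sd and dof > 0:
        cov = cov * chi2 / dof
    no_washout = bool(lam_b <= 1e-12)
    return WashoutFitResult(float(a0), float(lam_b), isotope.half_life_min,
                            cov, dof, chi2, no_washout, known_sd)
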