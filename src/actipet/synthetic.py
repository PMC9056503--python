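"""Synthetic counting data with known ground truth.

Generates every input the analysis consumes, emulating the study's
measurement conditions: list-mode gamma events from a three-isotope decay
mixture plus flat background (inhomogeneous Poisson, sampled by per-isotope
inverse-CDF of the truncated exponential), dynamic PET time-activity curves
with physical×biological decay in hour-long frames, and Gaussian beam-spot
images for σ calibration.  Every generator is a pure function of
(spec, seed).

What the generators do *not* emulate: detector dead time, pile-up, the
Compton continuum below the photopeak, scatter/randoms in PET, and spatial
response — tests that pass on these data validate the inverse analyses
under ideal counting statistics, not full detector physics.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .activation import (
    TissueComposition,
    expected_ratio_13N_11C,
    relative_yields,
)
from .decay import CountTimeSeries, GammaEventList
from .isotopes import ISOTOPES, default_isotopes

__all__ = [
    "ScenarioSpec",
    "scenario_preset",
    "simulate_event_stream",
    "simulate_count_series",
    "simulate_tac",
    "simulate_spot_image",
]

#: Fractional FWHM energy resolution at the reference energy.
ENERGY_RESOLUTION_FWHM = 0.06
ENERGY_RESOLUTION_REF_KEV = 662.0
FWHM_TO_SIGMA = 1.0 / (2.0 * math.sqrt(2.0 * math.log(2.0)))

#: Band over which flat background energies are drawn.
BACKGROUND_BAND_KEV = (300.0, 700.0)


def photopeak_sigma_keV(energy_keV: float) -> float:
    """Photopeak σ assuming fractional FWHM scales as 1/√E."""
    frac_fwhm = ENERGY_RESOLUTION_FWHM * math.sqrt(
        ENERGY_RESOLUTION_REF_KEV / energy_keV)
    return frac_fwhm * energy_keV * FWHM_TO_SIGMA


@dataclass(frozen=True)
class ScenarioSpec:
    """Ground truth for one synthetic measurement scenario.

    Amplitudes are detected count rates (cps) at the end of irradiation;
    ``background_cps`` is the flat background rate inside the analysis
    energy window.  The pre/post windows are (start delay, duration) in
    minutes since end of irradiation; ``retention`` scales the post-wash
    amplitudes per isotope.  ``gaps_min`` are acquisition-local
    (start, end) dead intervals of the pre-wash measurement.
    """

    name: str
    amplitudes_cps: dict
    f18O: float
    background_cps: float = 1.0
    pre_window_min: tuple[float, float] = (10.0, 29.0)
    post_window_min: tuple[float, float] = (55.0, 22.0)
    retention: dict = field(default_factory=lambda: {"18F": 0.59,
                                                     "11C": 0.14,
                                                     "13N": 0.14})
    tac_frames: int = 9
    tac_frame_min: float = 60.0
    tac_start_min: float = 225.0
    tac_noise_cv: float = 0.03
    tac_A0: float = 1000.0
    T_bio_h: float = 14.7
    gaps_min: tuple = ()
    seed: int = 0

    def __post_init__(self) -> None:
        if any(a < 0 for a in self.amplitudes_cps.values()):
            raise ValueError("amplitudes must be >= 0")
        if self.background_cps < 0:
            raise ValueError("background must be >= 0")
        for w in (self.pre_window_min, self.post_window_min):
            if w[1] <= 0:
                raise ValueError("window durations must be positive")
        for r in self.retention.values():
            if not 0.0 <= r <= 1.0:
                raise ValueError("retention must be in [0, 1]")
        if not 0.0 <= self.f18O <= 1.0:
            raise ValueError("f18O must be in [0, 1]")


def _preset_amplitudes(f18O: float, a_11c_cps: float) -> dict:
    """Amplitudes consistent with the study's two ratio conventions: the
    ¹⁸F/¹¹C ratio follows the transparent yield model (it is what the
    enrichment inference inverts), while the ¹³N/¹¹C ratio follows the
    Monte-Carlo-calibrated constant (it is what the fitting constraint
    assumes)."""
    comp = TissueComposition.squamous_cell_carcinoma(f18O)
    y = relative_yields(comp)
    return {
        "18F": a_11c_cps * y.A_18F / y.A_11C,
        "13N": a_11c_cps * expected_ratio_13N_11C(f18O, "mc_constant"),
        "11C": a_11c_cps,
    }


def scenario_preset(name: str, seed: int = 0) -> ScenarioSpec:
    """Presets emulating the study's seven measurements.

    T1-T4 are ex-vivo spectrometer scenarios (29-min pre-wash starting
    10 min after irradiation; 22-min post-wash; ¹⁸O enrichment from 0.61 %
    in T1 to 3.0 % in T4; T3 includes the 10-min acquisition gap).  E1/E2
    are dynamic-PET scenarios: nine 60-min frames starting 3.75 h after
    irradiation, with biological half-lives of 14.7 h and 21 h.

    Absolute count rates are not printed in the study; the presets use
    hundreds of cps pre-wash, a deliberate calibration that makes the fit
    uncertainties resemble the published ±9 % / ±26 % retention errors.
    The ¹⁸F and ¹³N amplitudes follow from the ¹¹C rate through the
    activation yield model, so each preset is internally consistent with
    its f(¹⁸O) truth.
    """
    f18O_by_tumour = {"T1": 0.0061, "T2": 0.015, "T3": 0.022, "T4": 0.030}
    if name in f18O_by_tumour:
        f = f18O_by_tumour[name]
        spec = ScenarioSpec(
            name=name,
            amplitudes_cps=_preset_amplitudes(f, a_11c_cps=150.0),
            f18O=f,
            seed=seed,
        )
        if name == "T3":
            # acquisition stopped for 10 min mid-measurement, then resumed
            spec = replace(spec, gaps_min=((12.0, 22.0),),
                           pre_window_min=(10.0, 39.0))
        return spec
    if name in ("E1", "E2"):
        return ScenarioSpec(
            name=name,
            amplitudes_cps={"18F": 0.0, "11C": 0.0, "13N": 0.0},
            f18O=0.03,
            T_bio_h=14.7 if name == "E1" else 21.0,
            seed=seed,
        )
    raise ValueError(f"unknown scenario {name!r}; use T1..T4, E1 or E2")


def _window_amplitudes(spec: ScenarioSpec, phase: str) -> tuple[dict, tuple]:
    if phase == "pre":
        return dict(spec.amplitudes_cps), spec.pre_window_min
    if phase == "post":
        amps = {k: a * spec.retention.get(k, 1.0)
                for k, a in spec.amplitudes_cps.items()}
        return amps, spec.post_window_min
    raise ValueError(f"phase must be 'pre' or 'post', not {phase!r}")


def _live_intervals(duration_s: float, gaps_s) -> list[tuple[float, float]]:
    """Acquisition-local live intervals after removing gaps."""
    intervals = []
    cursor = 0.0
    for a, b in gaps_s:
        if a > cursor:
            intervals.append((cursor, min(a, duration_s)))
        cursor = max(cursor, b)
    if cursor < duration_s:
        intervals.append((cursor, duration_s))
    return [iv for iv in intervals if iv[1] > iv[0]]


def simulate_event_stream(spec: ScenarioSpec, phase: str = "pre",
                          rng: np.random.Generator | None = None
                          ) -> GammaEventList:
    """List-mode (time, energy) events for one measurement window.

    Per isotope the event times follow an inhomogeneous Poisson process
    with intensity A·e^(−λt) (t on the common clock): the event count is
    Poisson with mean equal to the intensity integral over each live
    interval, and times are drawn by inverse-CDF sampling of the
    truncated exponential.  Energies are Gaussian around 511 keV with the
    detector's 6 %-at-662-keV resolution scaled as 1/√E.  Background
    events are uniform in time and uniform in energy over 300-700 keV,
    with the rate scaled so the in-window rate matches the spec.
    """
    rng = rng if rng is not None else np.random.default_rng(spec.seed)
    amps, (delay_min, duration_min) = _window_amplitudes(spec, phase)
    duration_s = duration_min * 60.0
    gaps_s = tuple((a * 60.0, b * 60.0) for a, b in
                   (spec.gaps_min if phase == "pre" else ()))
    live = _live_intervals(duration_s, gaps_s)
    t_offset_s = delay_min * 60.0

    times = []
    energies = []
    sigma_e = photopeak_sigma_keV(511.0)
    for name, a0 in amps.items():
        if a0 == 0.0:
            continue
        lam = ISOTOPES[name].decay_constant_per_s
        for (ta, tb) in live:
            # expected counts over [ta, tb] on the common clock
            mu = (a0 / lam) * (math.exp(-lam * (ta + t_offset_s))
                               - math.exp(-lam * (tb + t_offset_s)))
            n = rng.poisson(mu)
            if n == 0:
                continue
            u = rng.random(n)
            ea = math.exp(-lam * (ta + t_offset_s))
            eb = math.exp(-lam * (tb + t_offset_s))
            t_abs = -np.log(ea - u * (ea - eb)) / lam
            times.append(t_abs - t_offset_s)
            energies.append(rng.normal(511.0, sigma_e, n))

    if spec.background_cps > 0:
        window_width = 511.0 * 0.2  # default ±10 % analysis window
        band_lo, band_hi = BACKGROUND_BAND_KEV
        total_rate = spec.background_cps * (band_hi - band_lo) / window_width
        live_time = sum(b - a for a, b in live)
        n_bg = rng.poisson(total_rate * live_time)
        if n_bg:
            # uniform over the union of live intervals
            u = rng.random(n_bg) * live_time
            t_bg = np.empty(n_bg)
            edges = np.cumsum([0.0] + [b - a for a, b in live])
            for i, (a, b) in enumerate(live):
                sel = (u >= edges[i]) & (u < edges[i + 1])
                t_bg[sel] = a + (u[sel] - edges[i])
            times.append(t_bg)
            energies.append(rng.uniform(band_lo, band_hi, n_bg))

    if times:
        t_all = np.concatenate(times)
        e_all = np.concatenate(energies)
        order = np.argsort(t_all, kind="stable")
        t_all, e_all = t_all[order], e_all[order]
    else:
        t_all = np.empty(0)
        e_all = np.empty(0)
    truth = {"phase": phase, "amplitudes_cps": amps, "f18O": spec.f18O,
             "background_cps": spec.background_cps,
             "retention": dict(spec.retention), "seed": spec.seed}
    return GammaEventList(t_all, e_all, t_start_min=delay_min,
                          gaps_s=gaps_s, truth=truth)


def simulate_count_series(spec: ScenarioSpec, phase: str = "pre",
                          bin_width_s: float = 10.0,
                          rng: np.random.Generator | None = None
                          ) -> CountTimeSeries:
    """Poisson-binned 511-keV counts for one window, bypassing the
    event-level and energy stages (assumes a perfect photopeak window).

    Useful for replicate studies where simulating every event would be
    wasteful; statistically equivalent to event simulation followed by
    binning for the in-window counts.
    """
    rng = rng if rng is not None else np.random.default_rng(spec.seed)
    amps, (delay_min, duration_min) = _window_amplitudes(spec, phase)
    n_bins = int(round(duration_min * 60.0 / bin_width_s))
    local_edges = np.arange(n_bins + 1) * bin_width_s
    edges = local_edges + delay_min * 60.0
    t0, t1 = edges[:-1], edges[1:]
    mu = np.zeros(n_bins)
    for name, a0 in amps.items():
        lam = ISOTOPES[name].decay_constant_per_s
        mu += (a0 / lam) * (np.exp(-lam * t0) - np.exp(-lam * t1))
    mu += spec.background_cps * bin_width_s
    counts = rng.poisson(mu)
    mask = np.zeros(n_bins, dtype=bool)
    gaps = spec.gaps_min if phase == "pre" else ()
    for a, b in gaps:
        mask |= (local_edges[:-1] < b * 60.0) & (local_edges[1:] > a * 60.0)
    counts = np.where(mask, 0, counts)
    truth = {"phase": phase, "amplitudes_cps": amps, "f18O": spec.f18O,
             "retention": dict(spec.retention), "seed": spec.seed}
    return CountTimeSeries(edges, counts,
                           background_rate_cps=spec.background_cps,
                           background_rate_sd_cps=0.0, mask=mask, truth=truth)


def simulate_tac(spec: ScenarioSpec,
                 rng: np.random.Generator | None = None) -> pd.DataFrame:
    """Frame-averaged PET time-activity curve with multiplicative Gaussian
    noise at the spec's coefficient of variation.

    Columns: ``frame_start_min``, ``frame_end_min``, ``mean_activity``,
    ``sd``.  The noiseless frame value is the exact decay integral of
    A₀·e^(−(λ_phys+λ_bio)t) over the frame, divided by its length.
    """
    rng = rng if rng is not None else np.random.default_rng(spec.seed)
    lam_p = ISOTOPES["18F"].decay_constant_per_min
    lam_b = 0.0 if math.isinf(spec.T_bio_h) else math.log(2.0) / (spec.T_bio_h * 60.0)
    lam = lam_p + lam_b
    starts = spec.tac_start_min + np.arange(spec.tac_frames) * spec.tac_frame_min
    ends = starts + spec.tac_frame_min
    ideal = spec.tac_A0 * (np.exp(-lam * starts) - np.exp(-lam * ends)) \
        / (lam * (ends - starts))
    noisy = ideal * (1.0 + spec.tac_noise_cv * rng.standard_normal(ideal.size)) \
        if spec.tac_noise_cv > 0 else ideal.copy()
    sd = spec.tac_noise_cv * ideal if spec.tac_noise_cv > 0 else np.zeros_like(ideal)
    return pd.DataFrame({
        "frame_start_min": starts,
        "frame_end_min": ends,
        "mean_activity": noisy,
        "sd": sd,
    })


def simulate_spot_image(sigma_x_mm: float, sigma_y_mm: float,
                        pitch_mm: float = 0.05, half_extent_mm: float = 4.0,
                        snr: float = math.inf, amplitude: float = 1.0,
                        seed: int = 0) -> np.ndarray:
    """A film-like 2-D Gaussian spot image, optionally with additive
    Gaussian noise at peak-amplitude/noise-σ ratio ``snr``."""
    rng = np.random.default_rng(seed)
    n = int(round(2 * half_extent_mm / pitch_mm)) + 1
    ax = (np.arange(n) - (n - 1) / 2.0) * pitch_mm
    xx, yy = np.meshgrid(ax, ax)
    img = amplitude * np.exp(-xx**2 / (2 * sigma_x_mm**2)
                             - yy**2 / (2 * sigma_y_mm**2))
    if math.isfinite(snr):
        img = img + rng.normal(0.0, amplitude / snr, img.shape)
        img = np.clip(img, 0.0, None)
    return img
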