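"""Physical constants for the positron emitters produced by low-energy protons.

Three isotopes dominate activation of soft tissue below 8 MeV: ¹⁸F from
¹⁸O(p,n), ¹³N from ¹⁶O(p,X) and ¹¹C from ¹⁴N(p,X).  ¹⁵O and ¹¹C-from-¹²C
are excluded because their production thresholds (16.79 and 17.9 MeV) lie
above the beam energies this package models; :data:`EP_GUARD_MEV` enforces
that.  The packaged integrated cross sections ∫₀^Ep σ(E) dE are valid only
at Ep = 7.5 MeV.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from importlib import resources

__all__ = [
    "IsotopeSpec",
    "ISOTOPES",
    "default_isotopes",
    "EP_REFERENCE_MEV",
    "EP_GUARD_MEV",
]

#: Proton energy at which the packaged cross-section integrals are valid.
EP_REFERENCE_MEV = 7.5

#: ¹⁵O production cut-off; proton energies at or above this are refused
#: because the three-isotope model would be incomplete.
EP_GUARD_MEV = 16.79


@dataclass(frozen=True)
class IsotopeSpec:
    """Constants for one PET isotope and its production channel.

    ``integrated_xs_mb_MeV`` is the value of ∫₀^Ep σ(E) dE at
    Ep = 7.5 MeV, in mb·MeV.  ``decay_constant_per_min`` is derived as
    ln 2 / T½ so that λ·T½ = ln 2 holds exactly.
    """

    name: str
    half_life_min: float
    reaction_channel: str
    threshold_MeV: float
    integrated_xs_mb_MeV: float
    target_element: str
    decay_constant_per_min: float = field(init=False)

    def __post_init__(self) -> None:
        if self.half_life_min <= 0:
            raise ValueError("half-life must be positive")
        object.__setattr__(
            self, "decay_constant_per_min", math.log(2.0) / self.half_life_min
        )

    @property
    def decay_constant_per_s(self) -> float:
        return self.decay_constant_per_min / 60.0

    def to_dict(self) -> dict:
        return {
            "name": self.name,
            "half_life_min": self.half_life_min,
            "reaction_channel": self.reaction_channel,
            "threshold_MeV": self.threshold_MeV,
            "integrated_xs_mb_MeV": self.integrated_xs_mb_MeV,
            "target_element": self.target_element,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "IsotopeSpec":
        return cls(
            name=d["name"],
            half_life_min=d["half_life_min"],
            reaction_channel=d["reaction_channel"],
            threshold_MeV=d["threshold_MeV"],
            integrated_xs_mb_MeV=d["integrated_xs_mb_MeV"],
            target_element=d["target_element"],
        )


def _load_registry() -> dict[str, IsotopeSpec]:
    raw = json.loads(
        resources.files("actipet.data").joinpath("isotopes.json").read_text()
    )
    return {k: IsotopeSpec.from_dict(v) for k, v in raw.items()}


#: The packaged isotope registry, keyed by isotope name.
ISOTOPES: dict[str, IsotopeSpec] = _load_registry()


def default_isotopes() -> tuple[IsotopeSpec, IsotopeSpec, IsotopeSpec]:
    """The (¹⁸F, ¹¹C, ¹³N) triple used throughout the decay analyses."""
    return ISOTOPES["18F"], ISOTOPES["11C"], ISOTOPES["13N"]
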