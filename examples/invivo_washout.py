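"""Biological-washout fitting of a dynamic PET time-activity curve.

Simulates a nine-frame, 9-hour PET acquisition starting 3.75 h after
irradiation (biological half-life truth 14.7 h, 3 % frame noise), fits the
physical×biological decay model and prints the combined and washout
half-lives and the retained fraction at 8 h.
"""

import numpy as np

from actipet import biological_retention, fit_washout, scenario_preset, simulate_tac

spec = scenario_preset("E1", seed=1)
tac = simulate_tac(spec, rng=np.random.default_rng(spec.seed))

fit = fit_washout(tac)
lo, hi = fit.T_bio_ci95_h
print(f"combined half-life  : {fit.T_comb_min:.1f} min "
      f"(pure 18F physics would give {fit.T_phys_min:.2f} min)")
print(f"washout half-life   : {fit.T_bio_h:.1f} h  (95% CI {lo:.1f}-{hi:.1f} h)")
print(f"retained at 8 h     : {100*biological_retention(8.0, fit.T_bio_h):.0f} % "
      "of the decay-corrected signal")
# A combined half-life just below the 109.77-min physical value means the
# signal is dominated by physical decay: the produced 18F stays trapped in
# the cells instead of washing out.
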