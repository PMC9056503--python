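"""Ex-vivo analysis on synthetic counting data with known ground truth.

Simulates the strongest-enrichment tumour scenario (3.0 % of oxygen atoms
replaced by ¹⁸O, ¹⁸F retention 0.59 after washing), runs the full chain —
Poisson counting, constrained triple-exponential fits of the pre- and
post-wash windows, decay correction — and prints the recovered enrichment
and retention next to the truth.
"""

import numpy as np

from actipet import scenario_preset, simulate_count_series
from actipet.pipelines import fit_exvivo_series

spec = scenario_preset("T4", seed=1)
rng = np.random.default_rng(spec.seed)
pre = simulate_count_series(spec, "pre", rng=rng)    # 10-39 min post-irr.
post = simulate_count_series(spec, "post", rng=rng)  # 55-77 min post-irr.

report = fit_exvivo_series(pre, post)

print(f"true f(18O)       : {100*spec.f18O:.2f} %")
print(f"recovered f(18O)  : {report['f18O_percent']:.2f} "
      f"+/- {100*report['f18O_sd']:.2f} %")
amp = report["pre_fit"]["amplitudes_cps"]
print("pre-wash amplitudes at end of irradiation (cps): "
      + ", ".join(f"{k}={v:.0f}" for k, v in amp.items()))
for name in ("18F", "11C+13N"):
    r = report["retention"][name]
    truth = spec.retention["18F"] if name == "18F" else spec.retention["11C"]
    print(f"retention {name:7s}: {r['value']:.3f} +/- {r['sd']:.3f} "
          f"(truth {truth:.2f})")
# The 18F retention is tightly determined; the pooled short-lived channel
# is weakly constrained because most of its activity has decayed before
# the post-wash measurement starts.
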