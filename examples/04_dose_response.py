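"""Fit three-parameter logistics and build a potency table.

The model is Y = Bottom + (Top - Bottom) / (10^(LogEC50 - X) + 1) with X in
log10 molar; pEC50 = -LogEC50 and span = Top - Bottom.
"""

import numpy as np
import pandas as pd

from qpihuvec import (derive_potency_table, fit_3pl, fit_by_experiment,
                      simulate_dose_response)

concs = list(np.linspace(-13.0, np.log10(3e-9), 8))  # 100 fM - 3 nM

# --- noiseless sanity check: the fit recovers the generator exactly ---------
table, truth = simulate_dose_response(top=1.87, bottom=1.70, log_ec50=-10.34,
                                      concentrations=concs, n_replicates=2,
                                      noise_sd=0.0)
fit = fit_3pl(table)
print(f"noiseless: pEC50 {fit.pec50:.4f} (truth {truth.dose_response.pec50}), "
      f"span {fit.span:.4f} (truth {truth.dose_response.span:.2f})")

# --- a realistic multi-experiment campaign for two agonists -----------------
rng = np.random.default_rng(0)
campaign = {}
for name, (top, bottom, lec, n_exp) in {
        "agonist-A": (1.87, 1.70, -10.34, 7),
        "agonist-B": (1.90, 1.70, -11.82, 6)}.items():
    parts = []
    for e in range(n_exp):
        t, _ = simulate_dose_response(top, bottom, lec, concs, n_replicates=2,
                                      noise_sd=0.15 * (top - bottom),
                                      seed=int(rng.integers(2 ** 31)),
                                      experiment_id=e)
        parts.append(t)
    campaign[name] = fit_by_experiment(pd.concat(parts, ignore_index=True))

potency = derive_potency_table(campaign)
print(potency.to_string(index=False))
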