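"""Simulate rosette growth for the default screen design.

48 plants per treatment (unprimed control; DAP, Orn, Put at 0.1 and
1 mM) in each of three growth conditions (optimal, 100 mM mannitol,
100 mM NaCl), imaged twice daily for 7 days.
"""
import numpy as np

from phenoprime import GrowthScenario, simulate_growth

scenario = GrowthScenario(seed=1)
series = simulate_growth(scenario)
print(f"simulated {len(series)} plants "
      f"({scenario.n_plants_per_group}/group x {len(scenario.treatments)} "
      f"treatments x {len(scenario.conditions)} conditions)")

for condition in scenario.conditions:
    finals = [s.areas[-1] for s in series
              if s.treatment == "control" and s.condition == condition]
    print(f"  control final area, {condition:8s}: {np.mean(finals):7.1f} px")

# The stress multipliers on the carrying capacity (0.30 osmotic, 0.22 salt)
# reduce the unprimed final rosette size by ~70% and ~78% versus optimal.
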