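"""Compute the five phenotyping traits and score treatments with the PBCI.

The PBCI of a treatment is the sum over GC-slope, AUC, RGR, FG and GLI
of log2(treatment mean / control mean) within one growth condition:
positive = growth promoter (optimal) or stress alleviator (stress),
negative = stress inductor.
"""
from phenoprime import (
    GrowthScenario, compute_trait_table, score_all, simulate_growth,
)
from phenoprime.pbci import records_to_frame

scenario = GrowthScenario(n_plants_per_group=48, seed=1)
table = compute_trait_table(simulate_growth(scenario))
print(f"trait table: {table.shape[0]} plants x {table.shape[1]} columns")

records = score_all(table)
frame = records_to_frame(records)
for condition in ("optimal", "osmotic", "salt"):
    print(f"\ncondition: {condition}")
    sub = frame[frame["condition"] == condition]
    for _, r in sub.iterrows():
        if r["treatment"] == "control":
            continue
        print(f"  {r['concentration']:>4g} mM {r['treatment']:<4s} "
              f"PBCI {r['pbci']:+6.3f}  {r['label']}")

# Under the default emulation the strongest salt alleviator is 1 mM DAP
# and 1 mM Orn is a stress inductor, while effects under optimal growth
# stay small -- the qualitative pattern of a polyamine priming screen.
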