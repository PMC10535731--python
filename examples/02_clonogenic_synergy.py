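"""Per-dose Bliss synergy verdicts from a simulated clonogenic assay.

The generator is configured with interaction = 0.5: the combination kills
twice as many clonogenic cells as independent action predicts, so every
radiation dose should be classified as synergism.
"""

from radsyn import classify_bliss, plating_efficiency, survival_points
from radsyn.simulate import SimulationConfig, simulate_clonogenic

config = SimulationConfig(seed=1, interaction=0.5)
records = simulate_clonogenic(config)

pe = plating_efficiency(records)
points = survival_points(records, pe)
sf_c = next(p for p in points if p.condition == "drug_only").sf
print(f"plating efficiency {pe:.3f}; drug-only SF {sf_c:.3f}")

print("dose (Gy)   SF_R     SF_R*SF_C   SF_R+C   verdict")
for p in points:
    if p.condition != "radiation_only" or p.radiation_dose == 0:
        continue
    combo = next(
        q for q in points
        if q.condition == "combination" and q.radiation_dose == p.radiation_dose
    )
    row = classify_bliss(p.sf, sf_c, combo.sf, radiation_dose=p.radiation_dose)
    print(
        f"{row.radiation_dose:8.0f}   {row.sf_r:.3f}   {row.bliss_product:9.4f}"
        f"   {row.sf_observed:.4f}   {row.verdict}"
    )

# An observed combination SF below the product SF_R × SF_C means the agents
# kill more than independent action predicts (Bliss synergy).
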