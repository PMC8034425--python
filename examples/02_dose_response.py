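"""Five-dose screen analysis: percent growth to GI50/TGI/LC50.

Generates a small synthetic NCI60-style screen (Hill-shaped growth curves
with 3% signal noise over 0.01-100 uM), recovers the three endpoint
concentrations per cell line, and summarizes potency ranges per panel.
"""

from screenkit.dose_response import analyze_plate, summarize_screen
from screenkit.synthetic_data import gen_dose_plates

plates, truth = gen_dose_plates(n_lines=12, seed=7)

first = analyze_plate(plates[0])
print(f"{first.cell_line} ({first.panel}):")
print(f"  GI50 = {first.gi50.as_uM_string()} uM   (50% growth inhibition)")
print(f"  TGI  = {first.tgi.as_uM_string()} uM   (total growth inhibition)")
print(f"  LC50 = {first.lc50.as_uM_string()} uM   (50% net cell loss)")
true_gi50 = truth.gi50_M.iloc[0] * 1e6
print(f"  generating-curve GI50 was {true_gi50:.3g} uM")

params, ranges = summarize_screen(plates)
print("\nper-panel GI50 ranges (uM; censored lines counted separately):")
gi = ranges[ranges.endpoint == "GI50"]
print(gi[["panel", "min_uM", "max_uM", "n_exact", "n_censored"]].to_string(index=False))

# Censored endpoints print as "> 100" / "< 0.01": the curve never crossed
# the level inside the tested concentration window.
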