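"""Synthetic normalized drug-crossing time courses.

Emulates the saturating, plateau-reaching shape of drug passage across the
barrier for a brain-penetrant drug (plateau ~96%) and a poorly penetrant
one (plateau ~33%), each sampled at 15/30/60 min.  The curves are a
phenomenological saturating exponential, not a mechanistic transport model.
"""

import math

from barrierkit.synthetic import generate_drug_timecourse

timepoints = [15.0, 30.0, 60.0]

# rate chosen so the penetrant drug reaches 78% of normalized crossing at
# 15 min given a 96% plateau: r = ln(1/(1 - 78/96)) / 15
rate = math.log(1.0 / (1.0 - 78.0 / 96.0)) / 15.0
print(f"saturation rate: {rate:.4f} 1/min")

penetrant = generate_drug_timecourse(96.0, rate, timepoints)
blocked = generate_drug_timecourse(33.0, rate, timepoints)

print("time (min) | penetrant (%) | poorly penetrant (%)")
for t, a, b in zip(timepoints, penetrant, blocked):
    print(f"{t:10.0f} | {a:13.1f} | {b:20.1f}")
print("\nBoth curves plateau after ~60 min; the contrast between them is "
      "what a barrier model must resolve to rank drug penetration.")
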