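"""Map predicted death rates to the three clinical cell states.

Evaluates the PDT reference surface over the feasible (duration, intensity)
box and labels each setting dead (> 60% predicted kill), affected (30-60%)
or unaffected (< 30%), printing a compact character map.
"""

import numpy as np

from photoplan import StateThresholds, reference_surfaces, state_map_from_surface

pdt, _ = reference_surfaces()
taus = np.arange(1.0, 8.5, 0.5)
intensities = np.arange(1.0, 31.0, 1.0)
table = state_map_from_surface(pdt, taus, intensities, StateThresholds(d_th=0.6, h_th=0.3))

glyph = {"dead": "#", "affected": "+", "unaffected": "."}
print("rows: duration 1..8 min (top to bottom); cols: intensity 1..30 mW/cm^2")
for tau in taus:
    row = table[table.tau == tau].sort_values("intensity")
    print(f"{tau:4.1f} | " + "".join(glyph[s] for s in row.state))
counts = table.state.value_counts()
print("\nsettings per state:", {k: int(v) for k, v in counts.items()})

# '#' marks settings predicted to kill most of the population, '+' partial
# damage, '.' little effect; the dead region grows with both dose axes.
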