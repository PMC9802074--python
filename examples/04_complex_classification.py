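"""Alone / binary / ternary complex classification.

Each chloroplast, peroxisome and mitochondrion is categorized by the set
of other organelle classes it touches: Alone, one binary category per
partner class, or the ternary category. Percentages are pooled over the
organelles of each condition.
"""

from organelle3d import classify, cell_contactome, population_fractions
from organelle3d.synthetic import generate_condition_panel

assignments = []
for cond in ("dark", "light"):
    for vol, _ in generate_condition_panel(2, cond, seed=1):
        assignments.extend(classify(cell_contactome(vol)))

fractions = population_fractions(assignments)
for cls in ("chloroplast", "peroxisome", "mitochondrion"):
    sub = fractions[fractions.organelle_class == cls]
    print(f"\n{cls} (n dark = {sub[sub.condition == 'dark'].n_total.iloc[0]},"
          f" n light = {sub[sub.condition == 'light'].n_total.iloc[0]})")
    wide = sub.pivot(index="category", columns="condition", values="percent")
    print(wide.round(1).to_string())

print("\nReading: light-grown cells have fewer free ('Alone') organelles "
      "and more chloroplast-centered ternary complexes.")
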