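"""Classify component triples into the 13 somatotype categories and draw
a somatochart.

The somatochart projects (endo, meso, ecto) onto the plane with
x = ecto - endo and y = 2*meso - (endo + ecto); the 13 categories label a
triple by which components dominate and by how much.
"""

from somascan import classify_13, generate_manual_cohort, CohortConfig
from somascan import plot_somatochart, somatochart_coordinates, somatotype_manual

for triple in [(3, 3, 3), (5, 3, 1.5), (4, 4, 1), (1.5, 2.2, 5.5)]:
    x, y = somatochart_coordinates(*triple)
    print(f"{triple} -> {classify_13(*triple).label:<24} chart ({x:+.1f}, {y:+.1f})")

cohort = generate_manual_cohort(CohortConfig(n=60, seed=11))
results = [somatotype_manual(r) for r in cohort.subjects]
plot_somatochart([r.components for r in results], path="somatochart.png")
print(f"\nplotted {len(results)} synthetic subjects -> somatochart.png")

# Points left of the vertical axis are endomorph-dominated, right
# ectomorph-dominated, and high points mesomorph-dominated; the printed
# labels are the deterministic rule-table categories for each triple.
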