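"""Decomposing rate variation into structural and functional parts.

Fits the seven per-protein linear models of rate (distance d, packing WCN,
exposure RSA, and their combinations) over a small synthetic dataset and
reports mean variance explained, plus the gain from adding distance to the
best purely structural model.
"""

from enzgrad import FORMULAS, aggregate_fits, fit_all_models
from enzgrad.pipeline import simulate_study

proteins = simulate_study(10, seed=7, catalytic_mode="random")
fits = [fit_all_models(p.site_table) for p in proteins]
agg = aggregate_fits(fits)

print(f"mean R^2 across {len(proteins)} synthetic proteins (one protein, one vote):")
for formula in FORMULAS:
    print(f"  {formula:<14s} {100 * agg.mean_r_squared[formula]:5.1f}%")

gain = 100 * agg.delta_r_squared["K~WCN+RSA"].mean()
print(f"\nadding d to K~WCN+RSA gains {gain:.1f} percentage points of R^2.")
print("Distance to the catalytic site explains rate variation that packing")
print("and solvent exposure alone cannot: the functional constraint is")
print("distinct from the structural one.")
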