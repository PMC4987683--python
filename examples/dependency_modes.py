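"""Classify Wnt3-dependency modes under CHIR perturbations.

CHIR activates canonical Wnt signaling downstream of Wnt3 while repressing
Wnt3 itself, so genes correlated with Wnt3 on control EBs split into four
modes when CHIR is applied: canonical regulation (off-trend response),
trend continuation (follows the realized Wnt3 level), decoupled/parallel
(expression unmoved), and indirect long-term-only effects.
"""

from collections import Counter

from ebclock.perturbmodes import classify_dependency_modes, group_shift, pca_groups
from ebclock.synthgen import gen_mode_panel

neg, meta, truth = gen_mode_panel(genes_per_mode=5, n_per_group=12, rng=1)

shifts = {s.gene: s for s in group_shift(neg, "chir_long", groups=meta["group"])}
print(f"Wnt3 shift under long CHIR: {shifts['Wnt3'].delta:+.2f} −ΔΔCT "
      f"(significant: {shifts['Wnt3'].significant})")

res = pca_groups(neg, groups=meta["group"])
print("PC1/PC2 explained variance: "
      f"{res['percent_variance'][0]:.0f}% / {res['percent_variance'][1]:.0f}%")
print("group centroids on PC1:", res["centroids"]["PC1"].round(2).to_dict())

calls = classify_dependency_modes(neg, groups=meta["group"])
acc = sum(c.mode == truth[c.gene] for c in calls) / len(calls)
print("mode calls:", dict(Counter(c.mode for c in calls)))
print(f"agreement with designed modes: {acc:.0%}")
# Wnt3 drops several cycles under CHIR; group centroids order control →
# short → long along PC1 (graded treatment effect); the decision tree
# recovers the designed mode for nearly every gene
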