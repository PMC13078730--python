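"""Screen all 780 per-minute features for a strong exposure effect.

Each of the 13 parameters x 60 minutes is compared between groups with a
two-sided Mann-Whitney U test; Bonferroni adjustment over all 780 tests
controls the family-wise error rate.  NSUP (the number of significant
univariate parameters) is the headline per-comparison statistic.
"""

import zebraldt as z
from zebraldt.screen import screen_features

strong = z.GeneratorConfig(
    seed=7, effect=z.EffectSpec(affected_params=("dur", "dist"), multiplier=3.0)
)
matrix = z.assemble_matrix(z.generate_cohort(strong))
results, nsup = screen_features(matrix, alpha=0.05)

print(f"features tested: {matrix.n_features}, NSUP (adjusted p < 0.05): {nsup}")
top = sorted(results, key=lambda r: r.p_adjusted)[:5]
for r in top:
    print(f"  {r.feature_name:16s} U={r.U_statistic:6.1f} p_adj={r.p_adjusted:.2e}")

none = z.GeneratorConfig(seed=7, effect=z.EffectSpec(multiplier=1.0))
_, nsup0 = screen_features(z.assemble_matrix(z.generate_cohort(none)))
print(f"same cohort with no effect: NSUP = {nsup0}")
print("-> significant features concentrate in dark-phase activity minutes;")
print("   without an effect the Bonferroni screen stays silent.")
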