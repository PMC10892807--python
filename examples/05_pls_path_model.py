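"""PLS path model: warming -> trait blocks -> comprehensive score.

Builds per-plant indicator data (traits + AHP score + a binary warming
indicator), fits the structural model in which each trait block is a latent
variable proxied by its indicators, and bootstraps the path coefficients.
"""

import ornaval as ov
from ornaval.multivariate import bootstrap_paths, default_path_model, fit_pls_sem

table = ov.generate_traits(ov.default_params(), seed=1)
hierarchy = ov.default_hierarchy()
crit_m, idx_m = ov.default_matrices()
weights = ov.synthesize_weights(hierarchy, crit_m, idx_m)
rubric = ov.GradingRubric.from_quantiles(table, hierarchy.indices)
scores = ov.comprehensive_score(ov.grade_traits(table, rubric, hierarchy.indices), weights)

merged = table.df.merge(
    scores.scores[["plant_id", "treatment", "year", "score"]],
    on=["plant_id", "treatment", "year"],
)
merged["warming"] = (merged["treatment"] == "warming").astype(float)

model = default_path_model("two-flowering-blocks")
for year in (2017, 2018):
    cols = [c for b in model.blocks.values() for c in b]
    data = merged[merged["year"] == year][cols].dropna()
    fit = fit_pls_sem(data, model)
    boot = bootstrap_paths(data, model, replicates=200, seed=7)
    print(f"\n{year}  (n = {len(data)} plants)")
    for _, r in boot.iterrows():
        star = "*" if r["significant"] else " "
        print(f"  {r['source']:>26} -> {r['target']:<26} "
              f"{r['estimate']:+.3f}{star}  CI [{r['ci_low']:+.3f}, {r['ci_high']:+.3f}]")
    print("  R2:", {k: round(v, 3) for k, v in fit.r_squared.items()})
# Standardized coefficients: warming depresses the flowering blocks, and the
# flowering blocks carry the score - the indirect route by which warming
# lowers ornamental value. Asterisks mark bootstrap CIs that exclude zero.
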