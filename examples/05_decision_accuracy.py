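"""Decision accuracy: population benefit of treating per the model.

Out-of-sample predicted benefit above the threshold (here 0) recommends
treatment.  PB contrasts survival of participants treated according to the
model against those treated opposite to it; PBvC and PBvT compare against
treating no-one and everyone.
"""

from survbenefit import (
    TimeGrid,
    WeibullSLearner,
    assign_groups,
    cv_predict,
    make_folds,
    make_scenario,
    population_benefit,
    predict_benefit,
)

sim = make_scenario("paper_default", seed=1)
d = sim.data
grid = TimeGrid.default(float(d.time.max()))
oos = cv_predict(d, WeibullSLearner, make_folds(d, 10, seed=2), grid)
pred = predict_benefit(oos.curves, "SP", 2.0).values

groups = assign_groups(d, pred, b_th=0.0)
print(f"model recommends treatment for {100 * groups.recommend_rate:.0f}% of participants")

res = population_benefit(groups, d, "SP", 2.0, ci="bootstrap", n_boot=500, seed=3)
fmt = lambda v, ci: f"{100 * v:+.0f}% [{100 * ci[0]:+.0f}%; {100 * ci[1]:+.0f}%]"
print(f"PB   (model vs opposite):   {fmt(res.pb, res.pb_ci)}")
print(f"PBvC (model vs treat none): {fmt(res.pb_vc, res.pb_vc_ci)}")
print(f"PBvT (model vs treat all):  {fmt(res.pb_vt, res.pb_vt_ci)}")
print(f"effect in predicted-harm subgroup: {fmt(res.subgroup_neg_effect, res.subgroup_neg_effect_ci)}")
# PBvT near 0 means personalizing adds little over treating everyone; a
# negative subgroup effect shows the model does find participants whom
# treatment would harm.
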