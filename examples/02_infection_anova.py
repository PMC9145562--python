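"""Quantify how infection shifts morphology, per trait and species.

Pipeline: z-scale traits within species (removing species body-size
scale), fit the global trait x infection x species sequential ANOVA,
then per-trait species x infection models, and extract uninfected-
minus-infected marginal-mean contrasts with Bonferroni adjustment.
"""

import antmorph as am

table = am.generate(am.default_study_scenario(seed=1))

long = am.scale_by_species(table).to_long()
res = am.fit_global_model(long)
print(res.to_frame().to_string(index=False, float_format="%.3f"))
# The df column is forced by the design (81 specimens x 21 traits):
# 20/1/2/20/40/2/40 and 1575 residual df.  A significant
# infected:species term means the infection effect differs by species.

model_set = am.fit_trait_models(am.scale_by_species(table))
raw = (model_set.interaction_p["p_raw"] < 0.05).sum()
adj = (model_set.interaction_p["p_adjusted"] < 0.05).sum()
print(f"\ntraits with species:infected interaction p < 0.05: "
      f"{raw} / 21 raw, {adj} / 21 after Bonferroni")
# With the default scenario's moderate simulated shifts (0.5-0.8 SD)
# and 81 specimens, single-trait interaction tests have limited power;
# the global infected:species term above carries the pooled signal.

contrasts = am.estimate_contrasts(model_set)
print("\nmean uninfected-minus-infected contrast per species "
      "(within-species SD units):")
print(contrasts.groupby("species")["estimate"].mean().round(3).to_string())
# Positive = infected workers are smaller; the third species is
# negative, i.e. its infected workers are larger.
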