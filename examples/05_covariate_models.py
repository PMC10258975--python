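"""Fit a per-category covariate model and recover a planted effect.

One AMPDS category, ~5,000 dispatches, a planted night effect of
OR 0.6 on patient contact and no other effects.  Backward elimination
should retain the shift term alone, with the planted odds ratio inside
the fitted confidence interval.
"""

import math

import hemsdispatch as hd

code = hd.parse_code("09-E-01")
profile = hd.CodeProfile(
    code=code, ems_annual_rate=5000.0, hems_dispatch_prob=0.25,
    contact_prob=0.6, hlidd_prob=0.6,
)
config = hd.GeneratorConfig(
    n_codes=2, hems_rate_per_year=1270.0, study_days=1461,
    missing_code_prob=0.0, seed=8,
)
effects = hd.EffectConfig(
    night_contact=math.log(0.6), rrv_contact=0.0, ccp_contact=0.0,
    night_hlidd=0.0, rrv_hlidd=0.0, male_hlidd=0.0,
    age_lt16_hlidd=0.0, age_gt55_hlidd=0.0,
)
universe = hd.build_code_universe(config, [profile])
records = hd.simulate_hems_dispatches(universe, effects, config)

dataset = hd.prepare_category_dataset(records, "09", "contact")
print(f"category 09 contact model, n = {dataset.n_rows}")
result = hd.fit_reduced_model(dataset)
for t in result.retained_terms:
    print(f"  retained {t.level}: adjusted OR {t.odds_ratio:.2f} "
          f"({t.ci95[0]:.2f}-{t.ci95[1]:.2f}), p = {t.p_value:.2e}")
for term, stage, p in result.eliminated_terms:
    print(f"  eliminated {term} at the {stage} stage (p = {p:.2f})")
diag = result.diagnostics
print(f"  diagnostics: {len(diag.influence_flags)} influential rows "
      f"(Cook's d > {diag.cooks_cutoff:.1e}), VIF {diag.vif_by_term}, "
      f"logit linearity: {diag.logit_linearity}")
print("\nThe planted truth was OR 0.6 for night with null platform and")
print("desk effects; the fitted CI should cover 0.6 and the nulls drop.")
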