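"""Associate walkability with daily walking minutes via Tobit regression.

Runs the full chain: landscape -> components -> index -> synthetic travel
survey -> censored regression.  More than half of the respondents report
zero walking minutes, so effects are estimated with a left-censored
Gaussian (Tobit) likelihood and reported per 10 points of the 0-100 index,
unadjusted (Model 1) and fully adjusted for individual, household and
survey covariates (Model 2).
"""

from walkability import (MODEL2_CONFOUNDERS, apply_exclusions,
                         build_index_table, compute_components, fit_and_report,
                         generate_landscape, generate_survey)
from walkability.synthetic import SyntheticScenario

scenario = SyntheticScenario(seed=1)
landscape = generate_landscape(scenario)
index = build_index_table(compute_components(landscape, 150.0))
respondents, trips = generate_survey(scenario, index)
included, exclusion_log = apply_exclusions(respondents)

zero_share = (included["walk_minutes_total"] == 0).mean()
print(f"{len(included)} of {len(respondents)} respondents included; "
      f"{zero_share:.1%} report zero walking minutes\n")
print(f"true latent effect: {scenario.true_beta_walkability * 10:.2f} "
      f"minutes per 10 index points\n")

for label, conf in (("Model 1 (unadjusted)", None),
                    ("Model 2 (fully adjusted)", MODEL2_CONFOUNDERS)):
    fit, eff = fit_and_report(included, "walk_minutes_total",
                              confounders=conf, model_label=label)
    print(f"{label}: {eff.estimate:5.2f} min per 10 points "
          f"(95% CI {eff.ci_low:.2f} to {eff.ci_high:.2f}); "
          f"sigma = {fit.sigma:.1f}, censored {fit.n_censored}/{fit.n_total}")

print("\nBoth Wald intervals should cover the true latent effect; Model 2 "
      "additionally adjusts for the covariates that shift walking minutes.")
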