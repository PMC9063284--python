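"""Find the component driving an association via leave-one-out attenuation.

Builds a world in which *only* public-transport density moves the latent
walking outcome, then refits the fully adjusted Tobit model with each
six-component partial index in place of the full one.  The partial that
attenuates the effect most marks its omitted component as the driver.
"""

from walkability import (attenuation_analysis, build_index_table,
                         compute_components, generate_landscape,
                         generate_survey)
from walkability.synthetic import SyntheticScenario

scenario = SyntheticScenario(
    seed=1, n_respondents=1500,
    true_beta_walkability=0.0,
    true_component_betas={"public_transport_density": 18.0},
)
landscape = generate_landscape(scenario)
index = build_index_table(compute_components(landscape, 150.0))
respondents, _ = generate_survey(scenario, index)
partials = [c for c in index.columns if c.startswith("partial_")]
data = respondents.merge(index[["unit_id", *partials]], on="unit_id")

table = attenuation_analysis(data, "walk_minutes_total", partials)
print("effect per 10 index points (full index, then each partial index):\n")
for _, row in table.iterrows():
    flag = "  <- driver" if row["drives_association"] else ""
    print(f"  omit {str(row['omitted_component'] or '-'):<26} "
          f"{row['estimate_per_10']:6.2f} "
          f"({row['ci_low']:.2f}, {row['ci_high']:.2f}){flag}")

print("\nOmitting the truly causal component collapses the estimate; the "
      "other partials stay near the full-index effect.")
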