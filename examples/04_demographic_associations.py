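"""Screen every assessment for demographic associations.

Spearman rank correlations against age and years of education, Wilcoxon
rank-sum tests for gender (male vs female) and race (White vs people of
color), at alpha = .05 with no multiplicity correction.  In the synthetic
world only age effects are planted (on 21 of 29 tasks), so the age screen
should light up heavily while the other screens stay near the 5% false-
positive floor.
"""

import cogbattery as cb

registry = cb.load_registry()
dataset = cb.generate_study_dataset(cb.CohortConfig(seed=42))

frame = cb.association_screen(dataset, registry=registry)
for covariate in ("age", "education_years", "gender", "race"):
    sub = frame[(frame["covariate"] == covariate) & frame["evaluable"]]
    sig = sub[sub["significant"]]
    print(f"{covariate:<16} {len(sig):>2}/{len(sub)} significant")

age_sig = set(frame[(frame["covariate"] == "age") & frame["significant"]]["assessment"])
planted = {s.name for s in registry if s.age_sensitive}
print(f"planted age-sensitive tasks recovered: {len(age_sig & planted)}/21")
print(f"false alarms on age-insensitive tasks: {len(age_sig - planted)}/8")
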