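"""Generate a full synthetic study and summarize who took part.

The default configuration reproduces the reference deployment's stated
world: 414 registrants with its demographic marginals, a 4-factor latent
ability structure, and an engagement mixture in which ~11% never start
and ~25% finish all 29 assessments.
"""

import cogbattery as cb

config = cb.CohortConfig(seed=42)
dataset = cb.generate_study_dataset(config)
registry = cb.load_registry()

completion = cb.completion_summary(dataset, registry, n_contacted=365_782)
print(f"registered:        {completion.n_registered}")
print(f"completed >= 1:    {completion.n_completed_any} ({completion.pct_completed_any:.1f}%)")
print(f"completed all 29:  {completion.n_completed_all} ({completion.pct_completed_all:.1f}%)")
for (lo, hi), n, pct in zip(completion.bins, completion.bin_counts, completion.bin_pcts):
    print(f"  {lo:>2}-{hi:<2} assessments: {n:>3} ({pct:.1f}% of starters)")

demo = cb.demographics_summary(dataset.participants)
print(f"age: mean {demo['age']['mean']:.1f} (SD {demo['age']['sd']:.1f}), "
      f"range {demo['age']['range'][0]:.0f}-{demo['age']['range'][1]:.0f}")
print(f"degree holders:  {demo['degree_holders']['n']} ({demo['degree_holders']['pct']:.1f}%)")
print(f"people of color: {demo['people_of_color']['n']} ({demo['people_of_color']['pct']:.1f}%)")
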