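"""z-scores, composite scores and the four a-priori cognitive profiles.

Completers' raw scores are standardized per assessment (lower-is-better
columns sign-flipped so positive z always means better performance),
averaged into a composite, and each completer is labeled: high performer
(composite > 0.40), low performer (< -0.40), auditory- or visual-strong
(modality means differing by >= half an SD), else unclassified.
"""

import cogbattery as cb

registry = cb.load_registry()
dataset = cb.generate_study_dataset(cb.CohortConfig(seed=42))

wide = cb.completer_score_matrix(dataset, registry)
ztable = cb.zscore_transform(wide, registry, "aligned_higher_better")
composites, summary = cb.composite_scores(ztable)
print(f"completers: {ztable.n}")
print(f"composite z: mean {summary.mean:.3f} (exactly 0 by construction), "
      f"SD {summary.sd:.2f}, range {summary.range[0]:.2f} to {summary.range[1]:.2f}")

profiles = cb.profile_table(ztable, registry)
for label, count in profiles["label"].value_counts().items():
    print(f"  {label:<16} {count}")

example = profiles.iloc[0]
print(f"first completer: composite {example.composite_z:+.2f}, "
      f"auditory {example.auditory_mean_z:+.2f}, visual {example.visual_mean_z:+.2f} "
      f"-> {example.label}")
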