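"""CASCADE array analysis: Δz motifs, significance, recruitment contrast.

Generates a synthetic cofactor-recruitment array in which one TF family
(FAM00) has a 50% stronger binding-energy amplitude in the exhausted
condition, then runs the full chain: background z-transform, Δz motifs,
PWM/IC significance filtering, top-15% motif strength, family aggregation,
2-replicate consensus, and the exhausted-minus-acute contrast.
"""

import numpy as np

from exhaustnet import (
    ArrayScenario,
    analyze_replicate,
    build_delta_z_motif,
    condition_contrast,
    family_aggregate,
    gen_probe_array,
    replicate_consensus,
    z_transform,
)

sc = ArrayScenario(seed=0, condition_effects={"FAM00": 0.5})
design, models, measurements, planted = gen_probe_array(sc)
print(f"{len(models)} TF-binding models, {len(design)} probes "
      f"({sum(p.probe_class == 'background' for p in design)} background)")

# Motif recovery on one replicate array
one = measurements[(measurements.condition == "acute") & (measurements.replicate == "r1")]
zs = z_transform(one, design)
rs = [
    np.corrcoef(planted[m.model_id]["delta"].ravel(),
                build_delta_z_motif(m, zs, design).delta_z.ravel())[0, 1]
    for m in models
]
print(f"median Pearson r (planted energies vs recovered Δz): {np.median(rs):.3f}")

# Full replicate-consensus recruitment profiles per condition
profiles = {}
for condition, grp in measurements.groupby("condition"):
    reps = [family_aggregate(analyze_replicate(rep_grp, design, models))
            for _, rep_grp in grp.groupby("replicate")]
    profiles[condition] = replicate_consensus(reps, min_reps=2)

contrast = condition_contrast(profiles["acute"], profiles["exhausted"])
print("\ncofactor  family  acute  exhausted  contrast  status")
for _, row in contrast.iterrows():
    print(f"{row.cofactor:<8} {row.family:<7} {row.acute:6.2f} {row.exhausted:9.2f} "
          f"{row.contrast:+9.2f}  {row.status}")
print(
    "\nThe boosted family (FAM00) shows a positive exhausted-minus-acute"
    " contrast; unshifted families sit near zero. Strengths are mean Δz of"
    " each model's top 15% probes, averaged over significant family members"
    " and over the replicates in which the interaction recurs."
)
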