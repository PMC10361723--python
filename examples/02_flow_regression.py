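"""Mixed-effects regression of angular velocity across the organizer.

Simulates a fluid-extraction experiment (Sham / NoDefects / Defects groups,
stages 6-8), reduces tracks to per-track observations, and fits
AAV ~ 1 + Group*LR + Group*PA + Group*Time + (1 + Group | embryo).
The printed coefficients recover the generating effects: an anterior
gradient of 0.16 rad/s per unit PA and a -0.13 rad/s offset in embryos
that later develop laterality defects.
"""

import kupfferflow as kf
from kupfferflow.kinematics import observations_from_frames

groups = {
    "Sham": kf.GroupEffects(),
    "NoDefects": kf.GroupEffects(intercept=-0.03, lr=0.027, pa=0.034, time=0.027),
    "Defects": kf.GroupEffects(intercept=-0.13, lr=-0.003, pa=-0.041, time=0.013),
}
cfg = kf.SyntheticFlowConfig(seed=42, n_tracks=40)
tracks, meta, _ = kf.generate_tracks(cfg, groups, n_embryos=20)
obs = observations_from_frames(tracks, meta)
print(f"{obs['embryo_id'].nunique()} embryos, {len(obs)} track observations")

fit = kf.fit_mixed_model(kf.build_design(obs, design="suction", time_origin=6.0))
table = kf.report_effects(fit)
print(table.to_string(index=False, float_format=lambda v: f"{v:.4f}"))
print(
    "\nThe 'pa' row is the anterior-dominance gradient (true 0.16); the\n"
    "'group[Defects]' row is the flow deficit of defect-fated embryos\n"
    "(true -0.13). Stars mark Wald p-value thresholds 0.05 / 0.01 / 0.001."
)
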