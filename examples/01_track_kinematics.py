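"""Particle-track kinematics: from raw positions to a polar flow field.

Generates a small synthetic cohort of tracked LRO particles, converts the
tracks to polar kinematic samples about the organizer center, applies the
half-radius core exclusion, and summarizes the angular-velocity field in
eight sectors around the vesicle.
"""

import numpy as np

import kupfferflow as kf
from kupfferflow.kinematics import samples_from_frame, sector_summary

cfg = kf.SyntheticFlowConfig(seed=1, n_tracks=120, stages=(6,))
tracks, meta, _ = kf.generate_tracks(cfg, n_embryos=4)
samples = samples_from_frame(tracks, meta)
kept = samples[(samples["r"] >= samples["radius"] / 2)
               & (samples["r_next"] >= samples["radius"] / 2)]

print(f"{len(tracks)} track points -> {len(samples)} steps "
      f"({len(samples) - len(kept)} removed by core exclusion)")
print(f"median angular velocity: {kept['aav'].median():.3f} rad/s "
      "(positive = counterclockwise)")

summary = sector_summary(kept, n_sectors=8)
print("\nsector  n      median aav (rad/s)   [sector 0 starts at anterior]")
for _, row in summary.iterrows():
    print(f"  {int(row['sector'])}    {int(row['n']):5d}   {row['median']:.3f}")

print(
    "\nAnterior sectors (0 and 7) rotate faster than posterior ones (3 and 4):"
    " the anterior-dominant gradient that drives left-right symmetry breaking."
)
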