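"""Anterior-angular-velocity stage models under sham and interventions.

Evaluates the fitted population curves (sham linear model, post-extraction
sigmoidal recovery) and samples per-embryo trajectories with random
effects for several intervention scenarios.
"""

import numpy as np

import kupfferflow as kf

print("population means (rad/s):")
print("  stage :", "  ".join(f"{t}ss" for t in kf.STAGES))
sham6 = kf.sham_mean(6)
sham = [kf.rescale_early(sham6, t=t) if t <= 5 else kf.sham_mean(t) for t in kf.STAGES]
print("  sham  :", "  ".join(f"{v:.3f}" for v in sham))
print("  5ss intervention curve: AAV(5) = "
      f"{kf.intervention_mean(5):.5f}, AAV(8) = {kf.intervention_mean(8):.3f}")

for label, stages in [("sham", ()), ("3ss", (3,)), ("5ss", (5,)), ("5ss+7ss", (5, 7))]:
    scen = kf.InterventionScenario(label, stages)
    traj = kf.sample_trajectories(scen, 2000, np.random.default_rng(5))
    mean = traj.mean(axis=0)
    print(f"  {label:8s}: " + "  ".join(f"{v:.3f}" for v in mean))

print(
    "\nExtraction collapses flow to ~0 at the intervention stage; the\n"
    "sigmoidal recovery then restores (and overshoots) the sham level.\n"
    "Stages 3-5 are rescaled by the motile-cilia fractions (5.57%, 42.9%,\n"
    "62.1% of the 76.3% reached at 6 ss)."
)
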