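"""Generate a synthetic age-stratified skill panel with known structure.

The generator mimics a TGMD-3 assessment campaign: 13 skills in two
communities (6 locomotor, 7 ball skills), bounded integer scores, three
age strata whose network connectivity weakens with age, and a 51% female
sample.  The underlying truth — a sparse precision matrix with two hub
skills bridging the communities — is known exactly, which is what makes
every later stage checkable.
"""
import numpy as np

import skillnet as sn

spec = sn.default_skill_spec()
print(f"{spec.p} skills; hubs: {spec.hub_nodes}")
P = spec.true_pcor.copy()
np.fill_diagonal(P, 0.0)
print(f"true edges: {int((np.triu(P) != 0).sum())}, "
      f"|pcor| range {np.abs(P[P != 0]).min():.2f}-{np.abs(P[P != 0]).max():.2f}")

panels = sn.make_study_panels(
    spec, group_sizes={"3-5": 400, "6-8": 500, "9-11": 450}, seed=1
)
for g, panel in panels.items():
    female = (panel.sex == "F").mean()
    print(f"age {g}: n={panel.n}, {female:.0%} female, "
          f"score range {panel.scores.min()}-{panel.scores.max()}")

# Each column j is bounded by its per-skill maximum; subscale maxima sum
# to the instrument's 46 (locomotor) and 54 (ball skills).
ls = sum(panels['3-5'].score_max[s] for s in sn.LOCOMOTOR_SKILLS)
bs = sum(panels['3-5'].score_max[s] for s in sn.BALL_SKILLS)
print(f"subscale maxima: locomotor {ls}, ball {bs}")
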