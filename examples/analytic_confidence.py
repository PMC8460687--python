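"""Behaviour of the confidence score over the space of local correlations.

S_conf = 1/2 min(1, PCC_sharp/0.85) + 1/2 min(1, PCC_str/0.85), with each
term clamped to [0, 1].  A local correlation of 0.85 in both the sharpening
and structure representations already counts as full confidence, because a
perfect correlation is unlikely even for faithful reconstructions (the
reference image has slightly degraded precision and the skeletons are
blurred).
"""

import numpy as np

from hawkman import confidence_score

grid = np.linspace(-1.0, 1.0, 401)
ps, pstr = np.meshgrid(grid, grid)
surface = confidence_score(ps, pstr)
print(f"score range over [-1,1]^2 : [{surface.min():.3f}, {surface.max():.3f}]")

diag = confidence_score(grid, grid)
c_star = grid[diag >= 1.0 - 1e-12].min()
print(f"full confidence first reached at equal correlations of {c_star:.3f}")

for ps_v, pstr_v in [(0.9, 0.9), (0.85, 0.85), (0.425, 0.425), (-0.3, 1.0), (0.0, 0.0)]:
    print(f"S_conf(PCC_sharp={ps_v:+.3f}, PCC_str={pstr_v:+.3f}) = "
          f"{confidence_score(ps_v, pstr_v):.3f}")

# Values at or above 0.85 saturate; negative correlations carry no
# positive evidence and clamp to zero rather than subtracting.
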