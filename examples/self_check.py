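"""Self-comparison sanity check: an image agrees with itself at every scale.

Renders a synthetic crossing-line structure and compares it against
itself.  All global correlations must be exactly 1 and the confidence
score 1 wherever it is defined — the method has no stochastic steps.
"""

import numpy as np

from hawkman import SimulationConfig, generate_fixture, run_hawkman

config = SimulationConfig(structure="crossing", field_size_nm=2560.0, seed=7)
image = generate_fixture(config).test
print(f"rendered crossing-lines image: {image.shape}, pixel {image.pixel_size_nm} nm")

run = run_hawkman(image, image, psf_fwhm_nm=270.0, max_scale_no=27, render=False)
worst_sharp = min(r.pcc_sharp_global for r in run.scales)
worst_str = min(r.pcc_str_global for r in run.scales)
worst_conf = min(
    float(r.s_conf[r.conf_defined].min()) for r in run.scales if r.conf_defined.any()
)
print(f"minimum global PCC (sharpening) over 27 scales: {worst_sharp:.12f}")
print(f"minimum global PCC (structure)  over 27 scales: {worst_str:.12f}")
print(f"minimum defined confidence score:               {worst_conf:.12f}")
print("all three are 1 (to machine precision): the image is in full "
      "agreement with itself, as required of a deterministic comparison.")
assert np.isclose(worst_sharp, 1.0) and np.isclose(worst_str, 1.0)
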