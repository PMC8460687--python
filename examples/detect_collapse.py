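"""Detect bias-induced collapse of a line pair and read off the artefact scale.

Simulates a pair of labelled lines 100 nm apart imaged at high emitter
density: in the test reconstruction 80% of overlapping appearances are
pulled towards their mutual centre (artificial sharpening), while the
reference reconstruction is unbiased.  The comparison should report low
confidence at scales below the collapse artefact and recover above it.
"""

from hawkman import SimulationConfig, generate_fixture, run_hawkman

config = SimulationConfig(
    structure="line_pair",
    separation_nm=100.0,
    bias_fraction=0.8,
    precision_test_nm=5.0,
    precision_ref_nm=5.0,   # ground-truth-proxy reference
    seed=0,
)
pair = generate_fixture(config)
print(f"simulated {pair.manifest['n_emitters']} emitters, "
      f"{pair.manifest['n_appearances_test']} test appearances")

run = run_hawkman(pair.test, pair.reference, psf_fwhm_nm=config.psf_fwhm_nm,
                  max_scale_no=27, render=False)

print("scale  fwhm_nm  pcc_sharp  pcc_str  mean_conf")
for res in run.scales[::3]:
    print(f"{res.scale.scale_no:5d}  {res.scale.fwhm_nm:7.0f}  "
          f"{res.pcc_sharp_global:9.3f}  {res.pcc_str_global:7.3f}  {res.mean_conf:9.3f}")

first = next((r.scale.scale_no for r in run.scales if r.mean_conf >= 0.9), None)
print(f"\nconfidence first exceeds 0.9 at scale {first} "
      f"({first * 10 if first else '-'} nm): structure below this length "
      "scale is unreliable in the test image — the collapse artefact.")
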