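# hawkman

Multi-length-scale structural error mapping for single-molecule
localisation microscopy (SMLM) reconstructions.

## The problem

SMLM images are computed, not recorded: a localisation algorithm fits
blinking emitters frame by frame and the fitted positions are rendered at
sub-diffraction pixel sizes.  When emitter fluorescence profiles overlap —
the normal situation at the densities needed for live-cell imaging —
algorithms localise overlapping emitters towards their mutual centre.
The biased localisations show *reduced* scatter, so the artefact
("artificial sharpening") masquerades as extra resolution: adjacent
structures collapse into one, crossings pinch together, and intensity-
or self-consistency-based quality metrics (FRC, widefield comparison)
reward the error instead of flagging it.

`hawkman` maps this bias by comparing a **test** reconstruction against a
**reference** reconstruction produced from the same raw data with HAWK
preprocessing (a Haar-wavelet temporal splitting that removes
density-induced bias at the cost of some localisation precision) — or any
ground-truth-proxy image such as a low-density acquisition.  Because both
inputs are binarised, the comparison depends only on *structure*, not on
the non-linear relationship between reconstruction intensity and
labelling density.

## The method

For each length scale *n* (a Gaussian FWHM of *n* reconstruction pixels,
from 1 up to typically the instrument PSF):

1. cap intensities at the 98th percentile of the nonzero histogram,
   blur both images at the scale, normalise to maximum 1;
2. binarise with a Wellner-style adaptive threshold
   `P_thr = C_b · mean_r(P) + 0.1 · mean_r'(P) + C_a` where `(2r+1)` is
   the largest odd window not exceeding the scale and `r'` is the
   half-PSF window; `C_b = 0.7` gives the **sharpening map** (yellow =
   agreement, magenta = test only ⇒ sharpening, cyan = reference only ⇒
   missing structure), `C_b = 0.85` plus skeletonisation and re-blurring
   at the scale gives the **structure map**, sensitive to collapse;
3. correlate the two representations with a sliding-window Pearson
   correlation (window = the current scale) and combine into

   `S_conf = ½·min(1, PCC_sharp/0.85) + ½·min(1, PCC_str/0.85)`,

   clamped to [0, 1] — the **confidence map**, red (0) to cyan (1);
4. record per pixel the smallest scale with `S_conf ≥ 0.9` — the
   **artefact scale map**, the local length scale above which the test
   reconstruction can be trusted.

Whole-frame Pearson correlations of the sharpening masks and the
structure grids (`PCC sharpening`, `PCC structure`) summarise each scale
as single numbers.

A built-in simulator generates paired test/reference fixtures with ground
truth: emitters on a 10 nm grid along line pairs, crossings, rings or
sarcomere-like doublets (100 emitters/µm, ~5 appearances each, 270 nm
PSF, 10 nm reconstruction pixels), with controllable localisation
precision and a tunable density-bias pull towards the centroid of
same-frame overlapping appearances.

## Worked example

`examples/detect_collapse.py` simulates a 100 nm line pair whose test
reconstruction suffers 80% density bias and compares it against an
unbiased reference:

```
simulated 320 emitters, 1575 test appearances
scale  fwhm_nm  pcc_sharp  pcc_str  mean_conf
    1       10      0.577    0.142      0.531
    4       40      0.705    0.759      0.617
    7       70      0.809    0.629      0.807
   10      100      0.880    0.927      0.880
   ...
confidence first exceeds 0.9 at scale 14 (140 nm)
```

Low correlations at small scales say the fine structure of the test image
disagrees with the reference — the pair has partially collapsed towards
its midline; confidence recovers once the comparison scale exceeds the
size of the displacement artefact.  For an unbiased pair at matched
precision the same statistic recovers by roughly twice the localisation
precision instead (`examples/self_check.py` shows the degenerate case:
an image always agrees with itself, all correlations exactly 1).

The same analysis is available from the shell
(`examples/cli_workflow.sh`):

```sh
hawkman simulate --config sim.cfg --out fixture/
hawkman run --test fixture/test.tif --ref fixture/reference.tif \
            --pixel-size 10 --psf-fwhm 270 --out run/
hawkman report run/ --scales 2,10,20
```

writing per-scale sharpening/structure/confidence maps (PNG), the
artefact scale map, `metrics.json`/`metrics.csv` and a montage report.

## Layout

- `src/hawkman/recon_io.py` — image/localisation-table I/O, rendering,
  intensity flattening and normalisation
- `src/hawkman/scalespace.py` — scale ladder, adaptive thresholds,
  binarisation, skeletonisation
- `src/hawkman/compare.py` — local/global correlations, confidence
  score, all four map types, the `run_hawkman` pipeline
- `src/hawkman/simulate.py` — synthetic fixture generator
- `src/hawkman/cli.py` — `hawkman run | simulate | report`
- `docs/methods.md` — modelling assumptions, parameter choices and
  limitations
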