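#!/bin/sh
# Full shell workflow: simulate a fixture, analyse it, render a report.
set -e

cat > /tmp/line_pair.cfg <<EOF
structure = line_pair
separation_nm = 100
bias_fraction = 0.8
precision_test_nm = 5
precision_ref_nm = 5
seed = 0
EOF

hawkman simulate --config /tmp/line_pair.cfg --out /tmp/hawkman_fixture
hawkman run \
    --test /tmp/hawkman_fixture/test.tif \
    --ref /tmp/hawkman_fixture/reference.tif \
    --pixel-size 10 --psf-fwhm 270 \
    --out /tmp/hawkman_run
hawkman report /tmp/hawkman_run --scales 2,10,20
# Outputs: per-scale sharpening/structure/confidence maps (PNG), the
# artefact scale map, metrics.json/csv and a montage report.png.
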