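# rootsu

Regional-consistency OTSU segmentation and lymph-node candidate detection for
abdominal CT slices, plus a synthetic phantom generator with full ground truth.

The pipeline mirrors a classic CT preprocessing/segmentation chain:

1. **Preprocess** — binarise the slice (OTSU), morphologically close and erode,
   keep the largest 8-connected component to drop the strip-shaped exam bed,
   then zero a 15-px band of window-unions around the body's outermost contour
   to remove the subcutaneous fat layer.
2. **Regional consistency** — per-pixel 25×25 windowed mean/variance features;
   a single-level OTSU cut on the 256-bin variance histogram separates the
   gray-consistent area (organ interiors) from the region of interest (fat,
   vessels, nodes).
3. **Multi-threshold OTSU** — exact maximisation of the k-class between-class
   variance (default k = 4) via prefix-sum dynamic programming; ties go to the
   lexicographically smallest threshold tuple.
4. **Detection** — 8-connected components of brighter-than-fat classes adjacent
   to the fat class, gated by area and circularity; each candidate is flagged as
   fully embedded in fat or wall-touching.
5. **Evaluation** — greedy one-to-one centroid matching against manual labels;
   per-sample suspected/node missed-detection rates (mean of per-slice ratios),
   plus confusion-count sensitivity/specificity/accuracy helpers.

All stages are deterministic; the phantom generator is driven by a single seed
and reproduces bit-exactly.

## Tests

```bash
python -m pytest -q tests/
```

`tests/test_acceptance.py` holds the property-based acceptance suite (exact
oracle equivalence for the OTSU searches, morphology algebra, phantom
ground-truth checks, end-to-end zero-miss and noise-monotonicity properties,
and byte-level determinism).

## CLI

```bash
ro-otsu --version                       # algorithm defaults
ro-otsu simulate --n 10 --slices 5 --seed 42 --size 256 --out data/
ro-otsu preprocess data/sample_000/slice_000.png --out-dir pre/ --band-window 15
ro-otsu segment pre/cleaned.png --classes 4 --window 25 --out-dir seg/
ro-otsu detect seg/labels.png --fat-class 1 --min-area 9 --out cand.json
ro-otsu run --dataset data/ --out-dir results/     # full pipeline + evaluation
ro-otsu evaluate --candidates results/sample_000/candidates.json \
                 --truth data/sample_000/truth.json --max-dist 5
ro-otsu diag --confusion 83,5,17,95
```

Exit codes: 0 success, 2 validation error, 3 I/O error.

## Library layout

| module | contents |
| --- | --- |
| `rootsu.image_io` | PNG/TIFF/DICOM reading, HU windowing, mask and annotation I/O |
| `rootsu.morphology` | binary dilate/erode/opening/closing with explicit offset elements |
| `rootsu.preprocess` | bed removal, outermost-contour tracing, fat-band stripping |
| `rootsu.segmentation` | gray histograms, exact single/multi-level OTSU, windowed features, consistency split |
| `rootsu.detection` | fat mask, candidate components, greedy ground-truth matching |
| `rootsu.metrics` | missed-detection rates, confusion diagnostics, sign combination |
| `rootsu.phantom` | seeded phantom slices/cohorts with ground-truth masks |
| `rootsu.pipeline` / `rootsu.cli` | orchestration, config handling, `ro-otsu` entry point |
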