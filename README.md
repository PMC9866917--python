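# ihcquant

Rule-based quantification of immunohistochemical (IHC) biomarker images and
molecular subtype assignment for breast-cancer cases.

A case consists of four RGB microscopy images, one per biomarker (ER, PR,
HER2/neu, Ki-67), plus an optional histological grade (G1/G2/G3) supplied by
the diagnostician. The pipeline runs four stages per image:

1. **Adaptive preprocessing** — a 3×3 probe median filter estimates the
   impulse-noise level via PSNR; the noise-removal median window (3×3 or 5×5)
   is selected by an IF–THEN rule (5×5 iff PSNR ≤ 20 dB), then a brightness
   gain α ∈ {4, 6, 8, 12, 20} is chosen from the mean luma Y and applied with
   saturation. Every stage is recorded in a provenance record (PSNR, window,
   Y, α, per-stage checksums).
2. **Segmentation** — pixels whose luma lies in the biomarker's inclusive
   threshold band (PR 160–180, ER 180–210, HER2 40–230, Ki-67 160–180) form
   the candidate mask; morphological opening, a distance-transform marker
   recipe and a marker-controlled watershed on the luma gradient split
   touching nuclei. Ridge pixels count as background; components below 30 px
   are dropped.
3. **Indicators** — the relative positive area δS = Sp/Sw (exact rational on
   pixel counts) and the ordinal intensity coefficient KI ∈ {1, 2, 3} binned
   from the mean luma of segmented pixels measured on the original image
   (KI = 1 if Y ≤ 15, 2 if 15 < Y ≤ 30, 3 if Y > 30).
4. **Subtype rules** — four conjunctive rule systems (Luminal A, Luminal B,
   HER2-amplified, basal-like) over the indicators; exactly one fully
   satisfied system yields the diagnosis, otherwise the result is
   Indeterminate (with full per-condition detail). The grade never changes
   the decision; it only adds consistency warnings.

A seeded synthetic-fixture generator (`ihcquant.synthetic`) renders IHC-like
images — brown elliptical positive nuclei, blue negative nuclei, light
background, controlled positive-area fraction, stain luma and impulse noise —
with exact ground truth, so the whole pipeline is testable without any image
downloads. `ihcquant.scenarios` provides four-image cases parameterized to
land on each rule system.

## CLI

```bash
# full case: four biomarker images -> report.json (+ optional masks)
ihcquant run --er er.png --pr pr.png --her2 her2.png --ki67 ki67.png \
    --grade G1 --out-dir out/ --save-masks

# single stages, for debugging
ihcquant preprocess --input noisy.png --out-dir out/
ihcquant segment --input preprocessed.png --biomarker er --out-dir out/
ihcquant indicators --input er.png --biomarker er --out-dir out/

# synthetic fixture with ground truth (image + mask + nucleus table + spec)
ihcquant simulate --seed 7 --height 512 --width 512 \
    --positive-fraction 0.25 --noise 0.02 --out-dir fixture/
```

An Indeterminate diagnosis is a successful run (exit code 0): the output is
advisory, not an error.

### Configuration

All defaults (threshold tables, window/α rules, morphology, rule bindings)
live in one optional YAML document passed with `--config`:

```yaml
pipeline:
  segment_on: filtered        # "amplified" (default, literal chain) or "filtered"
  intensity_channel: luma     # or "inverted_luma"
  min_object_px: 30
rules:                        # knowledge-base overrides, merged by rule id
  families:
    threshold:
      - id: threshold-er
        if: {image_type: {eq: ER}}
        then: {t_low: 170, t_high: 220}
```

Rule families must partition their input space; overlapping or gapped
rulesets are rejected at load time. Every fired rule is logged at INFO.

## Layout

| Path | Contents |
| --- | --- |
| `src/ihcquant/core_io.py` | image I/O, biomarker/grade enums, provenance record |
| `src/ihcquant/preprocessing.py` | MSE/PSNR, median filtering, brightness gain |
| `src/ihcquant/segmentation.py` | threshold band + marker-controlled watershed |
| `src/ihcquant/indicators.py` | δS, masked brightness, KI, per-case indicator set |
| `src/ihcquant/subtype_rules.py` | the four rule systems and the classifier |
| `src/ihcquant/knowledge_base.py` | declarative IF–THEN rule store |
| `src/ihcquant/synthetic.py` | seeded fixture generator with ground truth |
| `src/ihcquant/scenarios.py` | subtype-parameterized four-image cases |
| `src/ihcquant/cli.py` | `ihcquant` command group |
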