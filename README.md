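# mhseg — macular-hole segmentation on retinal OCT B-scans

A macular hole is a full-thickness defect of the neurosensory retina at
the fovea. On an optical coherence tomography (OCT) B-scan it appears
as a hypo-reflective gap interrupting the bright retinal band at the
foveal depression. `mhseg` segments that gap automatically with a
hybrid of **multilevel gray-level thresholding** and **derivative
(Sobel) edge evidence**, then measures the clinically relevant shape
features (base width, minimum diameter, height, area).

The package is aimed at image-analysis researchers working with retinal
OCT who need a deterministic, dependency-light, fully testable baseline
segmenter — plus a synthetic B-scan phantom generator so every stage
can be exercised and validated without any clinical data.

## Method

For a standardized B-scan `L` (224×224, intensities in [0, 1]):

1. **Adaptive speckle filtering.** A local-statistics (Lee/Wiener-type)
   filter: `out = m + max(0, v − v_n)/max(v, ε)·(L − m)` with window
   mean `m`, variance `v` and noise variance `v_n` (estimated from the
   flattest image tiles). Flat regions collapse to their mean; layer
   boundaries keep gain ≈ 1.
2. **Derivation.** Sobel responses `Lx`, `Ly`, magnitude
   `|∇L| = √(Lx² + Ly²)` and direction `θ = atan2(Ly, Lx)`; the edge
   map keeps pixels with `|∇L| ≥ 0.2·max|∇L|`. A sub-pixel erf
   blurred-step model
   `f(x) = (Ir−Iℓ)/2·erf((x−x₀)/(σ√2)) + (Ir+Iℓ)/2`
   is available for scanline edge localization (edge outset/end at
   `x₀ ± 2σ`).
3. **Multilevel thresholding.** K = 3 cut points (4 classes:
   vitreous, inner/outer retina, RPE) by exhaustive between-class-
   variance maximization (multilevel Otsu); a histogram-valley mode
   (minimum between smoothed peaks) is available and falls back to
   Otsu when the histogram has too few modes.
4. **Hole extraction.** The retinal band is traced per column from the
   class map, the foveal depression located as the thickness minimum
   near the scan centre, and darkest-class components inside the band
   are scored by `area · edge_support · exp(−|c − c_fovea|/(W/8))`.
   The best-scoring candidate is morphologically refined into the
   final mask.

Evaluation uses pixel-wise accuracy, sensitivity, Jaccard index `J`
and Dice similarity coefficient `DSC = 2J/(1+J)`.

## Worked example

```python
from mhseg import PhantomSpec, generate_phantom, segment_image
from mhseg.features import compute_hole_features, evaluate_masks

img, truth, spec = generate_phantom(PhantomSpec(seed=7))   # 224x224, 30 px hole
seg = segment_image(img)
metrics = evaluate_masks(seg.mask, truth)
feats = compute_hole_features(seg.mask)
print(f"hole detected: {seg.has_hole}, fovea column: {seg.fovea_column}")
print(f"Dice {metrics.dsc:.3f}  Jaccard {metrics.jaccard:.3f}  "
      f"sensitivity {metrics.sensitivity:.3f}  accuracy {metrics.accuracy:.4f}")
print(f"base width {feats.base_width} px  min diameter {feats.min_diameter} px  "
      f"height {feats.height} px  area {feats.area} px^2")
```

prints

```
hole detected: True, fovea column: 127
Dice 0.933  Jaccard 0.874  sensitivity 0.983  accuracy 0.9940
base width 30 px  min diameter 28 px  height 79 px  area 2335 px^2
```

i.e. the segmenter recovered the generated 30-px-wide full-thickness
hole with 93% Dice overlap against the latent (pre-noise) truth mask,
and the estimated base width matches the generative width exactly.

The same pipeline is available from the shell:

```bash
mhseg simulate --n 5 --seed 1 --out-dir phantoms/
mhseg segment --input phantoms/img_0000.png --output-mask mask.png --report prov.json
mhseg evaluate --pred mask.png --truth phantoms/truth_0000.png --json metrics.json
mhseg pipeline --config run.toml        # TOML/YAML config; flags override
```

Exit codes: 0 success, 2 validation error, 3 no hole found (with
`--require-hole`).

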