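# tvac — total variation-based active contour lung segmentation

`tvac` segments the lung fields of chest radiographs without any training
data. It targets the hard case: portable bedside (anterior-posterior)
films of critically ill patients, where ECG leads and wires cross the
thorax, diffuse opacities fill the lungs, and learning-based segmenters
fail unpredictably. The pipeline is deterministic, parameter-light, and
ships with a synthetic phantom generator so every stage can be validated
against exact ground truth without downloading any data.

## Method

Four stages, each with a quality mechanism:

1. **Normalize** — resample to a 512-row working height and apply CLAHE.
2. **Denoise** — solve the Rudin–Osher–Fatemi model
   `min_u λ‖u‖_TV + ½∫(f−u)²` with a primal–dual hybrid gradient (PDHG)
   solver. TV denoising diffuses thin bright wires while preserving lung
   boundaries.
3. **Localize** — binarize at the ISODATA threshold θ (fixed point of the
   class-mean-midpoint update; lungs are dark, so foreground is `< θ`),
   remove small objects, pick the two components nearest the upper-left
   and upper-right expectation points, and score them against four
   criteria (lateral purity α = 0.98, centroid-row bound β = 135/256,
   area bounds γ = 1/3 and δ = 1/100). If more than one of the eight
   checks fails, reduce θ by 5% and repeat. Emit the convex hull of each
   accepted lung.
4. **Refine** — split each hull into overlapping upper/lower quadrants
   and evolve each with a morphological geodesic active contour under a
   fixed schedule: 50 balloon-expansion + 50 contraction iterations,
   repeated 10 times (exactly 1000 iterations per quadrant); then merge
   and smooth. Quadrant-wise evolution captures the costophrenic recess
   and apex that whole-lung contours round off.

Accuracy is measured with the Sørensen–Dice coefficient
`2TP/(2TP+FP+FN)`; a Dice below 0.70 counts as a failed segmentation.
See `docs/methods.md` for the full model, parameters, and limitations.

## Worked example

```python
from tvac import PhantomSpec, add_opacity, add_wires, generate_phantom, segment_lungs
from tvac.metrics import dice

spec = PhantomSpec()
pt = generate_phantom(spec, seed=4)                  # exact truth masks included
pt = add_wires(pt, n=3, seed=401, spec=spec)         # ECG-lead-like wires
pt = add_opacity(pt, "both", severity=0.5, seed=402) # bilateral opacities

result = segment_lungs(pt.image)
print(result.quality.satisfied, len(result.quality.theta_history))
print(f"{dice(result.combined, pt.lungs):.4f}")
```

prints

```
True 1
0.8583
```

— the quality criteria accepted the first ISODATA threshold, and despite
three wires and moderate bilateral opacities the combined-lung Dice is
0.86, well above the 0.70 failure cutoff. On clean phantoms the pipeline
reaches Dice ≈ 0.99 (see `examples/`, one script per capability, each of
which prints the numbers it computes and what they mean).

## Command line

```sh
tvac phantom --n 20 --seed 0 --out phantoms/ --wires 3 --opacity both:0.5
tvac segment phantoms/phantom_000.png --out seg/        # masks + quality JSON
tvac evaluate --pred seg/ --truth truth/ --out eval.csv # Dice table + summary
tvac batch list.txt --out seg/
```

`segment` reads single-frame grayscale DICOM (rescale slope/intercept and
MONOCHROME1 inversion applied) as well as 8/16-bit PNG/TIFF.

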