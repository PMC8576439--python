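# rssm — sparse-smooth foreground estimation for neuronal images

Fluorescence microscopy volumes of neurons (fMOST, light-sheet) mix the
signal of interest — somas, dendrites, axons — with a slowly varying
background and noise. Downstream quantification tools (soma localization,
neurite tracing) depend on thresholds that are hard to pick when the
background drifts across a volume. `rssm` separates an observed image `Y`
into a foreground `Is` and a background `B` by solving the convex program

```
min_{Is, B >= 0}  1/2 ||Y - Is - B||²₂ + λ₁||Is||₁
                  + 1/2 λ₂ ||∇^(k₀) Is||²₂ + 1/2 λ₃ ||∇^(k₁) B||²₂
```

where `∇^(k)` is the k-th order forward-difference operator applied along
each in-plane axis. The three penalties encode the priors that the
foreground is sparse (it occupies a small fraction of the volume), that it
is moderately smooth, and that the background is smoother still
(`k₀ < k₁`). The problem is solved by proximal gradient descent with
closed-form safe step sizes `1/Ls`, `1/L_B` where
`Ls = 1 + 2λ₂(k₀² + k₀)²` and `L_B = 1 + 2λ₃(k₁² + k₁)²`. Defaults
(`λ₁ = 0.1, λ₂ = 0.1, λ₃ = 0.5, k₀ = 2, k₁ = 5`, hard foreground floor 3)
are fixed and intended to be used unchanged across datasets.

The package provides, beyond the solver: TIFF stack I/O, slice-wise 3D
processing with tiling for volumes larger than memory, a synthetic neurite
benchmark with ground truth, single-term ablation variants, and evaluation
metrics (intensity profiles, Pearson correlation, point-set
precision/recall/F1 with a physical matching radius).

## Worked example

```python
import numpy as np
from rssm.synthetic import SyntheticSpec, simulate_image
from rssm.solver import solve
from rssm.evaluation import pearson_correlation

# simulated neurite: vertical bar 15 counts above a background of 200,
# blurred 7x7, uniform noise on [-2.5, 2.5]
spec = SyntheticSpec(delta=15, n_images=1, seed=0)
img, mask, truth = simulate_image(spec, 0)

dec, report = solve(img)                     # default parameters
row = 63                                     # crosses the bar
r = pearson_correlation(dec.foreground[row], truth[row])
```

Printing the result fields gives:

```
iterations            : 19 (converged=True)
objective             : 19783.0 -> 22736.6
foreground mean (bar) : 11.54  (true excess 15)
foreground mean (bg)  : 0.1059
background mean       : 199.6  (true level 200)
profile correlation   : 0.939
```

The foreground estimate retains the bar (mean 11.5 of a nominal 15; the
7×7 blur attenuates the bar's rim) while the background region of the
foreground image is essentially empty (mean 0.1), and the recovered
background sits at the true 200 level. The profile correlation of 0.94 is
measured along an image row crossing the bar. Note the objective value may
rise under the default hard-floor mode — the floor is a denoising
heuristic, not the exact proximal map; the `prox_mode="soft"` variant is a
textbook monotone-descent method (see `docs/methods.md`).

Command-line equivalents:

```
rssm simulate --delta 15 --n 10 --seed 0 --out sim/
rssm decompose sim/sim_000.tif --fg fg.tif --bg bg.tif
rssm decompose-big big.tif --fg fg.tif --bg bg.tif --tile 512,512,512
rssm evaluate --detected det.tsv --gold gold.tsv --radius 6
rssm benchmark --out table.tsv --seed 0 --n-per-group 10
```

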