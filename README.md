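# tmmdesign

Wide-angular-tolerance thin-film optical filter design, with an imaging
pipeline that measures what a better filter buys a crop-segmentation
network.

## The problem

Interference filters (multilayer dielectric stacks) shift their
transmittance toward shorter wavelengths as light arrives obliquely: the
phase thickness of each layer is δ = 2π·n·d·cosθ/λ, so tilting the filter
blue-shifts every passband. For a camera that must recognize *near-color*
objects — e.g. green peppers against green leaves, whose RGB appearance
overlaps although their reflectance spectra differ — a filter designed
only for normal incidence degrades off-axis, and so does any downstream
segmentation network trained on its colors.

`tmmdesign` provides:

1. **A differentiable transfer-matrix simulator** (`tmmdesign.tmm`) for
   lossless dielectric stacks: s/p Fresnel coefficients, per-layer 2×2
   transfer matrices `M_j = diag(e^{-iδ_j}, e^{iδ_j})·(1/t_j)[[1,r_j],[r_j,1]]`,
   amplitude coefficients `r = M̃₁₀/M̃₀₀`, `t = 1/M̃₀₀`, and power spectra
   `R = |r|²`, `T = (n_s cosθ_s / n₀ cosθ₀)|t|²`, plus *exact analytic
   thickness gradients* via the product rule on the matrix chain.
2. **Dual-angle merit functions** (`tmmdesign.merit`) optimized over layer
   thicknesses with bound-constrained L-BFGS-B (thicknesses ≥ 0):

   - Merit 1: `(1/N)·Σ_λ [(T^θ₀ − T^t)² + (T^θ₁ − T^t)²]` with
     unpolarized `T = (T_s + T_p)/2`,
   - Merit 2: `(1/N)·Σ_λ [(T^θ₀ − T^t)² + (T_p^θ₁ − T^t)² + (T_s^θ₁ − T^t)²]`,
   - a normal-only baseline objective for comparison.
3. **Imaging simulation** (`tmmdesign.imaging`): hyperspectral cube ×
   filter transmittance × 3-channel camera spectral response →
   exposure-normalized RGB.
4. **Synthetic data** (`tmmdesign.synthetic`): band-pass design targets,
   seeded known-truth stacks, and two-class pepper/leaf scenes whose
   reflectances are *camera-metameric* (identical bare-camera RGB,
   distinct spectra) with ground-truth masks.
5. **Freeze-and-swap evaluation** (`tmmdesign.segmentation`): train a
   small seeded pixel segmenter on RGB rendered through one filter curve,
   freeze it, swap in competing curves (each design's 0° unpolarized and
   20° s/p curves, plus the all-ones no-filter baseline), and compare
   mean IoU rows produced by the *same* frozen model.

## Worked example

```python
import numpy as np
from tmmdesign import (default_grid, make_target_curve, alternating_stack,
                       initialize_design, MeritConfig, optimize_thicknesses,
                       transmittance_spectrum, mae_curve, SpectralCurve)

grid = default_grid()                      # 400–800 nm, 2 nm steps
target = make_target_curve("bandpass", 550.0, 60.0, grid=grid)
template = alternating_stack(60)           # {air | 2.3 | 1.46 | … | glass}
x0 = initialize_design(60, "quarter_wave", seed=0,
                       indices=template.layer_indices, jitter_nm=10.0)

for variant in ("normal_only", "merit2"):
    cfg = MeritConfig(variant, 0.0, np.deg2rad(20), grid)
    res = optimize_thicknesses(x0, target, cfg, template, max_iter=300, seed=0)
    stack = template.with_thicknesses(res.thicknesses)
    sr20 = transmittance_spectrum(stack, np.deg2rad(20), grid)
    mae_s = mae_curve(SpectralCurve(grid, sr20.T_s), target.as_curve())
    print(f"{variant}: 20° s-pol MAE vs target = {mae_s:.4f}")
```

prints (seed 0):

```
normal_only: 20° s-pol MAE vs target = 0.0634
merit2: 20° s-pol MAE vs target = 0.0193
```

The normal-only design fits the target beautifully at 0° but loses three
times as much fidelity at 20°; the dual-angle Merit 2 design trades a
little 0° accuracy for a roughly threefold smaller oblique error — the
wide-angular-tolerance effect the toolkit exists to produce. Running the
freeze-and-swap evaluation on the synthetic dataset shows the downstream
consequence: the segmenter keeps mIoU ≈ 1.0 when the Merit 2 design's 20°
curves are swapped in, while the normal-only design's 20° curves drop it
to ≈ 0.43, the level of the no-filter baseline.

## Command line

```bash
tmmdesign design-filter --merit 2 --num-layers 60 --seed 0 --out-prefix out/run
tmmdesign gen-synthetic --n-scenes 30 --size 64 --seed 0 --out-dir out/data
tmmdesign simulate-rgb --cube out/data/train_000.img --no-filter --out out/rgb.png
tmmdesign train-seg --data-dir out/data --filter out/run_spectrum_0deg.csv --out out/ckpt.json
tmmdesign evaluate-swap --data-dir out/data --stack out/run_stack.yaml --out out/swap.csv
```

Every run writes a JSON manifest (parameters, seed, input hashes) beside
its outputs.

## Acceptance script

```bash
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

recomputes the whole pipeline from scratch at the given seed: optimizes
the 60-layer stack with the normal-only and both dual-angle merits
against the synthetic band-pass target, logs each design's MAE at 0° and
20° (s and p), then trains the segmenter, freezes it, and logs the mIoU
of every swapped curve. The JSON output records the externally comparable
targets for this run.
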