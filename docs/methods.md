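# Methods

## Optical model

A filter is a stack of `L` homogeneous, lossless dielectric layers
(real, dispersion-free refractive indices) between a semi-infinite
injection medium (air, n₀ = 1) and a semi-infinite substrate (optical
glass, n = 1.52). For a vacuum wavelength λ and incidence angle θ₀, the
angle in each medium follows Snell's law (n·sinθ invariant), and each
layer contributes the 2×2 complex transfer matrix

    M_j = diag(e^{-iδ_j}, e^{+iδ_j}) · (1/t_j) [[1, r_j], [r_j, 1]],

where δ_j = 2π·n_j·d_j·cosθ_j/λ is the oblique phase thickness and
(r_j, t_j) are the Fresnel amplitude coefficients of the j → j+1
interface for the chosen polarization (s or p). The injection medium is
treated as layer 0 with zero thickness, so the ordered product
M̃ = M₀M₁⋯M_L starts with the first interface. With no backward wave in
the substrate, r = M̃₁₀/M̃₀₀ and t = 1/M̃₀₀, and the power coefficients
are R = |r|² and T = (n_sub·cosθ_sub)/(n₀·cosθ₀)·|t|². For lossless
stacks R + T = 1 holds to ≈ 1e-15 in practice (tested at 1e-9), and
T_s = T_p exactly at normal incidence.

**Assumptions and limitations.** No dispersion (each material is one real
constant), no absorption or scattering, coherent treatment only, and the
substrate's back surface is not modelled — the simulated T is the flux
entering the substrate. Absorbing (complex) indices pass through the
arithmetic but are untested. Total internal reflection raises an explicit
error rather than returning evanescent-wave results.

## Thickness gradients without autodiff

Each thickness d_m enters only its own factor of the matrix product, and
∂M_m/∂d_m = k_m·diag(-i, +i)·M_m with k_m = 2π·n_m·cosθ_m/λ. With prefix
products A_m = M₀⋯M_{m-1} and suffix products B_m = M_{m+1}⋯M_L, the
product rule gives ∂M̃/∂d_m = A_m·(k_m·diag(-i,+i)·M_m)·B_m, and from
T = c/|M̃₀₀|², ∂T/∂d_m = −2T·Re(∂M̃₀₀/M̃₀₀). This is exact (verified
against central finite differences to ≲ 1e-7 relative error; the test
tolerance is 1e-5) and costs three passes over the layer chain per
spectrum. No deep-learning framework is needed or used.

## Merit functions and optimization

The design objective compares the simulated transmittance with a target
curve T^t(λ) on a shared grid at normal (θ₀ = 0°) and oblique
(θ₁ = 20° by default) incidence:

- Merit 1 uses the unpolarized transmittance (T_s + T_p)/2 at both angles;
- Merit 2 replaces the oblique term with separate s and p penalties
  (hence merit2 ≥ merit1 always, by convexity of the square);
- the normal-only objective keeps just the θ₀ term, serving as the
  single-angle baseline the dual-angle designs are compared against.

Merit functions also accept a per-angle target pair (θ₀-target,
θ₁-target); this form makes recovery experiments well-posed, since a
stack's own spectra at the two angles then constitute an exact zero of
the merit.

Optimization is bound-constrained L-BFGS-B over the thickness vector with
lower bound 0 nm (non-negativity is a physical requirement) and a default
upper bound of 1000 nm as a practical regularizer, using the analytic
gradient. Stopping: merit change < 1e-10, projected-gradient ∞-norm
< 1e-8, or the iteration cap (default 500; the packaged experiments cap
at 300, past the point of useful progress for this problem size). The
trace of accepted iterates is recorded and is non-increasing. The default
design task is the 60-layer alternating 2.3/1.46 stack on glass at
{0°, 20°}; initialization is quarter-wave at 550 nm with seeded ±10 nm
jitter (a uniform-random strategy is also provided). Defaults follow the
filter class the toolkit targets; the wavelength grid defaults to
400–800 nm in 2 nm steps (N = 201) and is configurable.

## Imaging model

RGB_c(x,y) = exposure · Σ_λ cube(x,y,λ)·T_filter(λ)·CSR_c(λ)·Δλ, with
trapezoidal Δλ weights, clipping to [0,1] after exposure only. The
exposure maps the 99th percentile of the *no-filter* rendering of the
evaluation scenes to 0.95 and is then held fixed across curve swaps, so
swapped images are radiometrically comparable. The default camera
spectral response is three Gaussian channels peaking at 600/540/460 nm
(widths 45/42/38 nm) — a generic machine-vision stand-in; a measured CSR
can be supplied as CSV. Not modelled: lens vignetting, per-pixel
incidence-angle variation, sensor noise, demosaicing.

## Synthetic stated world

No public dataset pairs hyperspectral crop scenes with a designed-filter
target, so the generator builds one with explicit, fixed choices:

- **Materials.** Leaf reflectance is a smooth vegetation curve (green
  peak at 556 nm, red edge at ~712 nm). Pepper = leaf + δ(λ), where δ is
  a mix of four narrow green-region Gaussian bumps chosen in the null
  space of the three CSR channel responses and scaled to max |δ| = 0.12.
  The two classes are therefore *camera-metameric*: a bare RGB camera
  sees identical colors (their spectral correlation is ≈ 0.99, satisfying
  the near-color requirement), while any filter that cuts into δ's lobes
  re-exposes the difference. A nearest-class-spectrum classifier reaches
  100% pixel accuracy on noise-free scenes, so the scene is solvable from
  spectra and hard from unfiltered RGB — which is precisely the regime in
  which a spectral filter is worth designing.
- **Scenes.** 64×64 px by default; 3 elliptical peppers (semi-axes
  5–12 px, random orientation) over a leaf background with smooth
  low-frequency brightness texture (amplitude 0.08), per-object
  multiplicative jitter (sd 0.05), flat illumination, and additive
  Gaussian noise with sd 0.01 of peak radiance. All geometry and noise
  derive from a single per-scene seed; datasets derive per-scene seeds
  from one master seed.

A green test on this world establishes that the pipeline's *orderings*
(dual-angle beats normal-only off-axis; filtered beats no-filter) hold
under controlled conditions. It does not establish absolute segmentation
accuracy on real greenhouse imagery, radiometric realism (no BRDF,
occlusion, or camera noise model), or robustness to fabrication errors.

## Segmenter

With no deep-learning framework among the dependencies, the segmenter is
a pixelwise MLP (hidden layers 24/12, ReLU, Adam, 60 epochs, seeded) over
9 features per pixel: the RGB triple raw and Gaussian-smoothed at σ = 2
and σ = 6 px, each channel plane standardized per image. The multi-scale
context plus per-pixel decision mirrors the role of a small
encoder–decoder; the per-image standardization plays the role of the
instance/batch normalization such networks contain — without it the
model keys on absolute brightness and any swapped curve collapses to a
one-class prediction, which would make the evaluation protocol
uninformative about curve *shape*. Training pixels are subsampled to
60,000 with a seeded choice. The binary threshold is 0.5. Checkpoints
serialize all weights to sorted-key JSON, so the frozen-model contract
(weights byte-identical before and after a swap evaluation) is checked
directly, and identically seeded runs produce identical checkpoint
hashes.

mIoU aggregates intersection and union counts per class over all test
scenes, averages over classes, and excludes classes whose union is empty
everywhere (rather than scoring them 1).

## Numerical choices

- Complex128 throughout the optical core; batched 2×2 products over the
  wavelength axis.
- Grid-mismatch anywhere (target vs merit grid, curve vs CSR) raises
  rather than silently resampling; `resample_curve` (linear, edge-hold,
  range-clipped) is the explicit alignment step.
- Degenerate configurations raise: M̃₀₀ = 0 (perfect reflector), t = 0
  interfaces, grazing-incidence zero denominators, total internal
  reflection.
- Curve resampling clips to the source range so interpolation cannot
  manufacture out-of-range transmittance.
- ENVI I/O is float32 band-sequential with a text header (`wavelength`
  field mandatory); masks are 8-bit PNG (0 background / 255 pepper).

## Known limitations

- Single-angle-pair design: merits combine exactly two angles; a
  many-angle generalization is straightforward but out of scope.
- The segmenter is a stand-in at desk scale; absolute mIoU values are
  not comparable to any full U-Net result, only the within-run orderings
  are meaningful.
- No fabrication-tolerance analysis (thickness-error robustness) and no
  global/generative inverse design; the optimizer is local quasi-Newton
  from a quarter-wave start, optionally multi-started by seed.
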