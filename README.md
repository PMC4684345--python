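# polyct

Polychromatic fan-beam CT simulation and iterative beam-hardening
correction for multi-material objects.

X-ray tubes emit a broad spectrum, and attenuation is energy dependent:
low-energy photons are absorbed preferentially, so the beam *hardens* as it
crosses an object and measured projections are sub-linear in path length.
Reconstructing such data with a single-energy (linear) model produces the
classic beam-hardening artifacts — cupping inside uniform regions and
streaks between strongly attenuating inclusions. `polyct` is aimed at
simulation studies of this problem (e.g. nondestructive testing of
workpieces with a few known materials): it provides the full polychromatic
forward model, a segmentation-aware iterative solver that removes the
artifacts, a SART baseline that exhibits them, and the phantom/noise/metric
machinery to quantify the difference.

## The model and the solver

For an object made of K known materials, each point occupied by exactly one
material, the attenuation map factorises through a reference energy E₀ at
which the K linear attenuation values are pairwise distinct:

    μ(E, x) = μ̂_k(E) · μ(E₀, x),        k = material at x,

where μ̂_k(E) = μ_mk(E)/μ_mk(E₀) is material k's mass attenuation curve
normalised to 1 at E₀, and the material label k is recovered from μ(E₀, x)
itself by thresholding. The discrete polychromatic projections are then

    p_i = −log Σ_n S_n δ exp( −Σ_k μ̂_k,n Σ_j R_ij χ(μ_j, k) μ_j ),

with S_n δ the sampled normalised spectrum, R_ij the ray–pixel intersection
lengths and χ the thresholding characteristic function. This is a nonlinear
system in the single image μ = μ(E₀, ·); its solution is attenuation *at one
energy* and therefore free of beam-hardening artifacts by construction.

The solver is E-ART, a row-action scheme pairing the exact polychromatic
forward projection with a linearised correction per ray:

    μ ← μ + (p_i − p_i(μ)) · A_i / |A_i|²,

where A_i is the gradient of p_i at the current image (with the labels
treated as locally constant, its j-th entry is R_ij times the
transmission-weighted spectral average of pixel j's curve μ̂). With a
single-bin spectrum this is exactly classical ART. Iteration stops when the
relative change e(r) = ‖μ⁽ʳ⁾ − μ⁽ʳ⁻¹⁾‖²/‖μ⁽ʳ⁻¹⁾‖² drops below 10⁻⁴
(at most 100 sweeps), starting from μ⁽⁰⁾ = 0.

## Worked example

`examples/03_beam_hardening_correction.py` simulates the default
multi-material phantom — a 240 mm water disk with two 40 mm bone and two
10 mm titanium disks — at miniature scale (64² grid, 60 views) and
reconstructs it both ways:

```
SART: 6 sweeps;  BHC: 15 sweeps (e(r) < 1e-4)
material        truth    SART     BHC   (cm^-1)
water           0.236   0.196   0.235
bone_cortical   0.837   0.444   0.837
titanium        5.518   1.640   5.161
MSE vs ground truth: SART 0.03660, BHC 0.00113
```

SART's water value is depressed 17% by cupping and bone/titanium far more;
the corrected reconstruction recovers the 50 keV ground-truth attenuation
of every material (titanium is a 2-pixel-radius disk at this scale, hence
the residual bias; at 256² it reconstructs to 5.52 cm⁻¹). The other
examples cover spectrum generation and hardening (`01`), sinogram
simulation with Poisson noise (`02`), and tolerance to an erroneous
spectrum estimate (`04`).

A thin CLI wraps the same pipeline:

```sh
polyct run --out results/demo          # simulate + reconstruct + evaluate
polyct simulate --out sino.tif
polyct recon --method bhc --sinogram sino.tif --out img.tif
polyct evaluate --image img.tif --reference truth.tif
polyct fixtures --out fixtures/        # miniature test file set
```

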