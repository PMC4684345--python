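# Methods

## Physical model

A polychromatic projection along ray L is
p(L) = −log ∫ S(E) exp(−∫_L μ(E, x) dl) dE, with S the normalised spectrum.
`polyct` restricts attention to objects built from K known materials, one
material per point, each with density close to nominal. Under these
assumptions the energy dependence factorises: choosing a reference energy
E₀ at which the K linear attenuation values are pairwise distinct,
μ(E, x) = μ̂_k(E) μ(E₀, x) with μ̂_k the mass attenuation curve of the
point's material normalised to 1 at E₀, and the material label is a
*function of the image value itself*, recovered by comparing μ(E₀, x) to
K−1 thresholds. The unknown is the single image μ(E₀, ·); solving for it
removes beam hardening by construction because the reconstructed quantity
refers to one energy.

Discretisation follows the rectangle rule: a uniform spectrum grid of N
points with spacing δ (Σ S_n δ = 1), per-material curves μ̂_k,n sampled on
that grid, and exact ray–pixel intersection lengths R_ij, giving

p_i = −log Σ_n S_n δ exp(−Σ_k μ̂_k,n t_k),  t_k = 0.1 Σ_{j: label k} R_ij μ_j,

where 0.1 converts mm lengths to cm to match cm⁻¹ attenuation.

## Solver

E-ART sweeps all rays in turn. For ray i the exact nonlinear forward
projection p_i(μ) is evaluated, then the image receives the Kaczmarz-style
correction (p_i − p_i(μ)) A_i / |A_i|². A_i is the gradient of p_i with the
characteristic function treated as locally constant — its derivative, a
distribution concentrated on the thresholds, is set to zero. (A Gaussian
smoothing of that derivative is a conceivable alternative; the
constant-label form is simpler and the finite-difference tests confirm it
is the exact gradient between label changes.) The entry for pixel j is then

a_ij = 0.1 R_ij · [Σ_n S_n δ e^(−s_n) μ̂_{k(j),n}] / [Σ_n S_n δ e^(−s_n)],

the transmission-weighted spectral mean of the pixel's material curve.
This quantity is positive for nonnegative curves, which is what the
corrective update requires; a sign-flipped variant would move projections
*away* from the measurements. The implementation therefore uses the
analytic (positive) derivative of the discrete forward model, validated
against central finite differences to better than 10⁻⁵ relative error.

Choices the problem statement leaves open, fixed here:

* **Initialisation** μ⁽⁰⁾ = 0; **stopping** when
  e(r) = ‖μ⁽ʳ⁾ − μ⁽ʳ⁻¹⁾‖²/‖μ⁽ʳ⁻¹⁾‖² < 10⁻⁴ (e is +∞ while the previous
  image is zero, so the first sweep never stops the run), or 100 sweeps.
  A guard aborts if e(r) exceeds 10³.
* **Ray order**: views in a fixed golden-ratio-stride permutation
  (stride ≈ 0.382 · n_views made coprime with n_views), cells sequential.
  Row-action methods converge faster when consecutive rows are nearly
  orthogonal; the fixed point is unchanged. The order is deterministic.
* **Labels** are refreshed from the current image at every ray (a per-ray
  cost of one threshold comparison per crossed pixel). A per-sweep variant
  would also converge but reacts more slowly to label migration.
* **Nonnegativity**: μ is clamped to ≥ 0 after every ray update. Negative
  excursions otherwise cause label thrashing at the background boundary.
* **Relaxation** λ = 1 by default (the plain update carries none);
  exposed for noisy data.
* **Numerics**: spectral sums are evaluated with a max-shift so large
  optical depths cannot overflow the exponent; a ray whose gradient norm
  is zero (missed the object or the grid) is skipped.

With a single-bin spectrum, μ̂ ≡ 1 and the update reduces exactly to
classical ART; the test suite pins this equivalence at 10⁻⁸ against an
independent Kaczmarz implementation.

The SART baseline solves the linear single-energy model with simultaneous
per-view updates (length-weighted residual normalisation), the same start,
stopping rule and clamp. It represents what a standard algebraic
reconstruction does to polychromatic data: cupping and streaks.

## Attenuation data and the material model

Mass attenuation tables for water, cortical bone, titanium and copper ship
as CSV on the standard sparse 10–150 keV grid, with nominal densities
(1.00, 1.92, 4.54, 8.96 g/cm³) in a manifest. Interpolation is log-log
linear, the standard choice for attenuation data (piecewise power law,
exact at the nodes, monotone between them); no K-edge handling is needed
above 10 keV for these materials. Queries outside the tabulated range
raise, except when sampling normalised curves on a spectrum grid, where
sub-10 keV bins are evaluated at the table edge — those bins carry zero
weight after any realistic filtration.

The default phantom pins the ground-truth linear attenuations at
E₀ = 50 keV to 0.236 (water), 0.837 (bone) and 5.518 (titanium) cm⁻¹ and
takes only the curve *shapes* from the tables. Tabulated water × 1.0 g/cm³
gives 0.227 cm⁻¹ at 50 keV, about 4% below the pinned value — effective
density and interpolation conventions differ between published variants of
these tables — so pinning makes the recovery targets exact and
self-consistent: classification thresholds (midpoints between consecutive
μ(E₀), user-overridable) and recovery checks all refer to the same values.

## Synthetic data

The default phantom is a 240 mm water disk containing two 40 mm bone disks
(centres x = ±65 mm) and two 10 mm titanium disks (x = ±25 mm); only the
diameters are prescribed by the study the layout emulates, so the
symmetric-on-the-horizontal-axis placement is this package's choice and is
config-exposed. The scan is fan-beam: SOD 1000 mm, SDD 1200 mm, 512 cells
of 0.6 mm (FOV 256 mm), 720 views over a full turn at full scale.

The spectrum is a Kramers-law bremsstrahlung surrogate, S(E) ∝ kvp/E − 1,
attenuated by a 1 mm copper filter via Beer–Lambert and normalised, on a
1 keV grid (δ and the grid are configurable). Its mean energy with the
default filtration is 75.6 keV, matching the ≈75 keV of the measured-tube
simulation it stands in for; it omits characteristic lines, anode
self-filtration and detector response, so absolute MSE/NMSD figures of any
particular tube simulation are reproduced only in order of magnitude, and
the package's quantitative claims are recovery and comparison properties
rather than spectrum-specific error values. Spectrum estimation error is
modelled by the detector-efficiency factor 1 − 0.25 sin(2πE/E_max) applied
to the reconstruction's spectrum only (data stay simulated with the true
spectrum).

Pixels are labelled by their centre (no partial-volume anti-aliasing), so
the one-material-per-point assumption holds exactly in simulated data;
real data violate it at every boundary, and passing recovery tests here
says nothing about partial-volume behaviour. Poisson noise draws counts
~ Poisson(flux · e^(−p)) per measurement, default flux 10⁵ photons; zero
counts are clamped to one count before the log. The noise path is the only
source of randomness and is driven by a caller-supplied seed.

## Metrics

MSE is the plain pixel mean of squared error over the full grid. NMSD is
the classical normalized mean square distance
sqrt(Σ(f − g)² / Σ(g − ḡ)²) — the name is used with several
normalisations in the literature; this definition is documented here
precisely because comparisons across implementations depend on it. Region
means are taken over label masks binary-eroded away from boundaries (3 px
for the large regions, 2 px for the 10 mm titanium disks at the 256²
scale) to exclude edge blur. Cupping is quantified on the water region as
the centre mean (r < 25 mm) versus a near-rim annulus (100–115 mm).

## Problem sizes

Unit and property tests run at 64² pixels / 60 views / 128 cells with 5 keV
spectral bins; the end-to-end validation and the acceptance script use
256² pixels / 360 views / 512 cells with 1 keV bins, where the BHC solver
converges in 8 sweeps and recovers all three region means to within 0.2%.
These sizes are the package's reproducibility scale; the full 512² / 720
view configuration is available through the same config.

## Known limitations

* 2-D fan-beam only; no cone-beam, scatter, detector cross-talk or focal
  spot model.
* The Kramers surrogate has no characteristic lines; users with a measured
  spectrum should load it from CSV instead.
* No regularisation: the tangent-line singularity streaks of disk phantoms
  remain, as expected without TV-type constraints.
* The threshold classifier assumes the materials' μ(E₀) are well separated
  relative to reconstruction noise; heavy noise with close materials would
  need relaxation < 1 and possibly per-sweep labels.
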