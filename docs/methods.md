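# Methods

`stillsolver` is a self-contained serial-crystallography "stills" engine: it
synthesizes femtosecond still-shot diffraction images from a known toy
structure with a physics-based kinematic model, then estimates per-shot
crystal parameters and a global set of structure-factor amplitudes directly
from the pixel values by maximum likelihood, benchmarking the result against
a conventional integrate-then-merge reduction using ground-truth metrics.

## Forward model

A shot is a single exposure of a randomly oriented tetragonal crystal
(default cell a = b = 79.1 Å, c = 38.4 Å) by a polychromatic X-ray pulse.
The expected Bragg photons in pixel *i* are

    I_i = ΔΩ_i Σ_λ J(λ) [ r_e² κ_i (Z / N_j) Σ_j |F_h|² I0(Δh_{i,j,λ}, m) ]

where ΔΩ is the pixel solid angle, κ the Kahn polarization factor, J(λ) the
spectral fluence (photons/area), Z the per-shot crystal scale (number of
mosaic blocks, sampled Normal(1150, 115) truncated positive), N_j = 100 the
number of texture domains, and the lattice-interference factor is the
truncated Gaussian

    I0(Δh, m) = m⁶ exp(−C m² |Δh|²),   C = 3.175,  m = 10.

Δh is the Ewald offset: the residual of the fractional Miller index
(U_j U B)ᵀ q against its nearest integer, with q = (ŝ − ŝ₀)/λ in the
crystallographic convention. The m⁶ peak equals the squared number of unit
cells per mosaic block; C fixes the full width at half maximum to that of a
parallelepiped block. Mosaic texture is an average over 100 domains with
random axes and Normal(0, 0.01°) angles, drawn once and shared by all shots
(only the scale Z varies per crystal, mimicking crystal-volume variation).

The interference factor is evaluated only where it exceeds ~1.4 × 10⁻¹¹ of
its peak (exponent cutoff 25, support radius capped at |Δh| = 0.45 so the
per-reflection evaluation is equivalent to the nearest-integer form). The
same cutoff is used by the refinement model, making the monochromatic
single-domain render and the refinement model agree pixel for pixel — the
suite's core cross-module identity.

Pulses are SASE-like: 30 narrow modes with centers Normal(E₀, 0.2% E₀)
around E₀ = 9034 eV and exponentially distributed weights; each mode is far
narrower (0.02%) than the interference width and is carried as a single
spectral channel. Pulse energy averages 8 × 10¹⁰ photons (15% relative
jitter — a typical pulse-energy variation at a SASE source) focused into a
1 µm beam. Background is liquid-water scattering from a 5 µm jet crossing
the beam, using a bundled smooth per-molecule amplitude curve |F_w(q)| with
the characteristic broad maximum near d ≈ 3.2 Å (a synthetic stand-in for a
measured curve); pixels are 2 × 2 oversampled everywhere.

The toy structure is built per asymmetric unit (12 light sites, flat
f₀ = 20 e, plus 2 heavy sites, f₀ = 60, f′ = −8, f″ = 10 e) and expanded by
the eight rotations of point group 422, so ground-truth amplitudes are
exactly 422-symmetric and Friedel differences carry only the absorptive
heavy-atom signal. The flat f₀ = 20 gives the ~112-atom cell a per-cell
scattering power (Σf² ≈ 4.4 × 10⁴ e²) comparable to a small protein; there
are no q-dependent form factors or B factors. Measurement noise follows the
three-stage detector model: Poisson counting, fixed per-pixel gain drawn
once from Normal(28, 0.84) ADU/photon, and Normal(0, 3) ADU readout,
reported in photon units after division by the nominal gain (values can be
negative where readout dominates).

## Symmetry bookkeeping

Miller indices are reduced under the 8 rotations of point group 422 with
Friedel mates kept distinct; the canonical representative is the
lexicographically greatest image. Translational symmetry and systematic
absences are not modeled. Under this convention the 79.1/38.4 cell has
13 639 unique amplitudes to 2.1 Å inclusive — confirmed independently by
gemmi's anomalous-unique count for P422. (A published table size of 13 704
for the same nominal cell corresponds to no round cutoff under either P422
or P4₃2₁2; the 0.5% discrepancy is documented rather than tuned away.)

## Data reduction

Reflections are predicted from the current crystal model: a shoebox
(11 × 11 pixels on the desk preset) is cut around every reflection whose
monochromatic Ewald offset satisfies |Δh|∞ < 0.15. Over-prediction is
deliberate and harmless for the likelihood. The outer two-pixel ring of
each box is fitted with a tilt plane T = t₁x + t₂y + t₃ by weighted least
squares, weights 1/v_crude with v_crude = σ_r² + max(X,0) + σ_g² max(X,0)².
Because the observed-value weights are severely biased at photon-scale
backgrounds (downward fluctuations get far more weight, dragging the plane
toward zero), the fit is iterated to convergence with the variance
re-evaluated at the plane prediction; the first iterate is exactly the
one-step observed-value solve. Spot SNR is the background-subtracted
foreground sum over its propagated sigma, including the tilt-parameter
covariance; on pure-background boxes this statistic is standard normal to
within a few percent. Shoeboxes whose plane dips below zero anywhere are
discarded (~0.3 per 145 boxes per shot on the desk preset) since a negative
background would break the positivity of the model variance.

Where two predictions' boxes overlap, each physical pixel is owned by the
prediction with the nearest centroid and enters the likelihood exactly once;
evaluating it under the other box's single-index model would leave a bright
neighbour spot unmodeled and dominate the target with spurious residuals.
Integration and tilt fitting still use the full boxes.

The integration baseline reduces each surviving shoebox to its summed
background-subtracted intensity, removes per-shot scales by three rounds of
least-squares scaling against the running per-index means, and averages
symmetry-equivalent observations with inverse-variance weights (negative
merged intensities clamp to zero; indices with multiplicity < 3 are
dropped). Amplitudes are square roots of merged intensities.

## Likelihood and refinement

Each selected pixel contributes a normal term with mean
n = T + ΔΩ J̄ r_e² κ G_s |F_h|² I0(Δh̄, m_s) — the monochromatic (central
wavelength), single-domain model with the tilt plane frozen — and variance
v(n) = σ_r² + n + σ_g² n². Gradients with respect to the three orientation
angles (lab-axis rotations composed with the reference orientation), cell
edges a and c, scale G_s, mosaic parameter m_s and the amplitudes are fully
analytic, including the variance's n-dependence, and are certified against
central finite differences to 10⁻⁵ relative. Every optimizer coordinate is
reparameterized to start at 1 with unit expected variation (σ_U = 0.001°,
σ_B = 0.1 Å, σ_G = σ_F = 1, σ_m = 0.1); G, m and |F| use an exponential map
θ = θ_min + (θ₀ − θ_min) exp[σ(x − 1)] that keeps them strictly positive
(the exponent is clipped at ±500 so line-search excursions cannot underflow
onto the bound). Optimization is L-BFGS (scipy, memory 10).

Stage 1 refines each shot alone: first (G_s, m_s) on low-resolution
(d > 5 Å) shoeboxes with SNR > 3, then orientation and cell on all
shoeboxes with SNR > 0.2; shots with fewer than three qualifying boxes are
flagged unrefinable. Shots whose a, c, m or log G falls outside
median ± 4 × (1.4826 MAD) of the across-shot distribution are removed.
Stage 2 resets every m_s and G_s to its across-shot median (the two are
strongly correlated per shot), then refines all G_s and the full amplitude
set globally; m_s stays fixed. Amplitudes never measured by any pixel keep
their initial values exactly (zero gradient through the bound map). Initial
amplitudes come from the integration baseline, extended to the full index
set with per-shell median fills and floored strictly above zero for the
bound map; initial scales are deliberately large (G = 10⁶) so the model
predicts finite scattering everywhere, and the initial mosaic parameter is
13.7 (an indexing-grade overestimate).

The default protocol runs two full stage-1/stage-2 cycles followed by a
final per-shot polish pass. With an integration-grade starting table the
orientation/cell part of stage 1 is ineffective (amplitude misfits dominate
the target and can even displace orientations); after one global refinement
the amplitude set is accurate enough that the later per-shot passes recover
orientations to the method's floor. Stage 1's two parts are block
coordinate descent, so passes against a refined amplitude set alternate
the blocks twice; the closing polish repeats stage 1 against the converged
amplitudes and is what the orientation metrics and partiality corrections
report. The full-scale (`paper`) preset keeps the single published cycle.

Two deliberate properties of this likelihood are worth noting. (1) The
model is gauge-degenerate: G_s → γG_s with |F| → |F|/√γ leaves every pixel
prediction unchanged; the ground-truth R factor absorbs the gauge through
its fitted scale k. (2) Because v depends on n, the maximum-likelihood
optimum on even perfectly modeled data sits about half a photon per pixel
below the data (the ½ log v term rewards smaller variances). At desk-scale
brightness this biases recovered scales by ~1% and sets the orientation
floor near 0.007°; it vanishes as signals brighten, which the bright-signal
stationarity and single-spot closed-loop tests exploit.

The model-derived partiality of an integrated observation is
P = I0(Δh̄, m_s)/m_s⁶ ∈ (0, 1] under the shot's refined stage-1 model,
floored at 0.05 to avoid noise blow-up; dividing intensities by P before
merging gives the intermediate "partiality-corrected integration"
comparator.

## Metrics

R_GT = Σ| |F| − k|F_GT| | / Σ k|F_GT| with k minimized by adaptive
Nelder–Mead (started at the ratio of sums; verified against a dense grid).
CC_ano is the Pearson correlation of Friedel amplitude differences against
the heavy-only-anomalous ground-truth table, over pairs with both mates
measured. Misorientation is the rotation angle of U_refinedᵀ U_true,
summarized by medians and quartiles.

## Problem sizes and presets

The `desk` preset — 200 shots on a single 256 × 256-pixel panel
(109.92 µm pixels) at 60 mm, resolution cutoff 4.5 Å (just inside the
panel-corner limit), 1 407 unique amplitudes, ~145 shoeboxes per shot, two
refinement cycles of at most 100/150 stage-1/stage-2 L-BFGS iterations —
is the supported single-CPU configuration (minutes end to end) and the one
the test suite and the acceptance script run. The `paper` preset exposes
the full-scale configuration (32-panel camera of 185 × 388-pixel tiles at
124 mm, 2.1 Å cutoff, thousands of shots, 500 stage-2 iterations); it is
cluster-scale work and is provided for completeness, not exercised by the
suite (a single full-scale shot renders in ~40 s on one CPU and yields
roughly 690 shoeboxes, the expected several hundred per image). The `micro` preset is a seconds-scale smoke configuration. The
idealized coplanar 32-panel layout stands in for the real camera's
metrology-specific panel rotations, which are not public.

## What the synthetic data does and does not emulate

The generator reproduces the features that drive still-shot reduction
errors: random partiality sampling, spiky per-pulse spectra, per-shot scale
and fluence jitter, mosaic texture, realistic pixel noise with calibration
error, photon-scale water background, and indexing-grade initial models
(orientations perturbed by half-normal angles of median 0.038°, cell edges
by ~0.05 Å, mosaic parameter started at 13.7 and scales at 10⁶). It does
not model q-dependent atomic form factors, beam divergence, detector
point-spread or crosstalk, parallax, multi-lattice scattering, or per-image
Debye–Waller variation; passing tests therefore demonstrate the estimator's
behavior under the modeled error sources only. Two pipeline-level stand-ins
matter when comparing with real-data workflows: indexing is a surrogate
(truth perturbed) rather than a peak-search indexer, and the integration
baseline is a minimal scale-then-average merge rather than a production
merging program with frame rejection and error-model refitting.

## Numerical choices

All randomness flows from a single root seed through named substreams
(structure, texture, crystals, spectra, noise, indexing, gain), so runs are
exactly reproducible. Nearest-integer rounding of fractional indices is
half-away-from-zero, componentwise. Degenerate inputs raise: non-positive
cell edges or scales, the (0,0,0) index, singular crystal matrices,
rank-deficient background rings, non-positive model variances. Shots and
parameters are processed in sorted order. The polychromatic render
evaluates each predicted reflection over a local pixel region with
conservative screening (closest-approach distance of the wavelength line,
per-channel quadratics, mosaic drift margins) and is bit-identical to the
direct per-pixel triple sum; overflow-prone line-search excursions in the
refinement report a large finite target value so the optimizer backtracks.
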