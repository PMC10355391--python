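# Methods

This note documents the models, parameter choices, numerical decisions and
known limitations behind `retseg`. Everything quantitative stated here is
computed by the test suite or by `scripts/acceptance.py`.

## Pipeline model and assumptions

The method treats a fundus photograph as dark tubular ridges (vessels) on
a smooth bright background, corrupted by a multiplicative illumination
field, additive noise, and a bright specular streak along wide vessels.
Each stage addresses one of these:

* **Morphology (bottom-hat − top-hat).** With a flat disk `b` larger than
  the widest vessel (default radius 8 px for 565–768-px-wide images), the
  closing residue captures dark structures, the opening residue bright
  ones, and their difference maps vessels to high values on a flattened
  background. The subtraction *over-corrects* the reflex streak: the
  streak both reduces the bottom-hat and contributes its full height to
  the top-hat, so the vessel centerline ends up near background level
  rather than at vessel level. This is a property of the construction
  itself, verified directly in the tests; downstream stages tolerate it
  because the oriented ridge bank integrates across the full vessel
  cross-section.
* **Homomorphic filter.** `exp(F⁻¹{H · F{ln(f + ε)}}) − ε` with the
  Gaussian high-pass transfer `H(d) = (γ_H − γ_l)(1 − e^{−d²/D₀²}) + γ_l`.
  `D(u,v)` is the Euclidean distance, in frequency bins, to the DC bin
  after a centering shift (computed with `fftfreq(n)·n`, so no explicit
  shift is applied). Defaults `γ_H = 1.8`, `γ_l = 0.4`, `ε = 0.01`, and
  `D₀ = 10` bins. The cutoff matters: illumination varies over hundreds
  of pixels (bins 1–3) while a 10-px vessel has spectral content near
  bin ≈ 38 of a 768-px image, so `D₀ = 10` flattens the vignette at gain
  ≈ γ_l while passing all vessel scales at gain ≈ γ_H. A cutoff of 30
  bins (wavelengths below ~26 px passed) measurably attenuates the widest
  vessels ~3× relative to thin ones and was rejected for that reason.
  The `[0,1]` min-max presentation rescale is an affine map that can
  mechanically inflate a coefficient of variation; the filter's
  illumination-attenuation contract is therefore measured on the raw
  (pre-rescale) output, available via `rescale=False`.
* **Adaptive Wiener.** Local mean and variance over an odd window
  (default 3×3, reflect padding); gain `max(σ² − v, 0)/σ²`, zero where
  `σ² = 0`. With `noise_variance="estimate"` (default), `v` is the FOV
  mean of the local-variance map — the classical fallback, which
  over-estimates the noise floor on structure-rich images and thus smooths
  conservatively.
* **Channel selection.** CNR = (std of FOV intensities) / (robust noise
  scale), the latter `1.4826·MAD(Laplacian)/√20` — the √20 is the L2 norm
  of the 4-neighbor Laplacian stencil, and the MAD makes the estimate
  insensitive to the sparse vessel edges. Ties break green > red > blue.
  A noiseless structured channel scores +∞, a constant channel 0.
* **Ridge bank.** The oriented second-derivative kernel differentiates
  along its `u` axis (`u = x cosθ − y sinθ`, x = column offset,
  y = row offset), so `σ_u` is the **cross-section** scale and `σ_v`
  smooths **along** the ridge. The per-pixel maximum of the positive
  (dark-ridge) response over the whole lattice is kept with its argmax
  parameters, zeroed outside the FOV, and min-max rescaled. Under the
  default normalization (α = 1) the selected cross-section scale is
  `σ_r/√2` for a ridge of width σ_r — deliberate under-matching that
  favors thin vessels; α = 1.5 is the exact-matching exponent. Because
  the response of a straight uniform ridge is independent of the
  along-ridge σ_v, the `σ_v^β` factor always prefers the larger σ_v;
  width information lives in the σ_u argmax, and the tests assert scale
  *ordering* (wider ridge → larger modal σ_u) rather than exact recovery.
  The detector assumes dark ridges; the pipeline negates the working
  channel unconditionally under the default `dark-ridge` polarity, since
  the morphology stage maps vessels to high values. Disabling the
  morphology stage without changing the polarity inverts the detector's
  input — which is precisely what the enhancement-ablation comparison
  measures.
* **Coherence diffusion.** Weickert-style: structure tensor from
  gradients at `gradient_sigma = 1`, tensor smoothing at
  `structure_sigma = 6`; across-structure conductivity fixed at the floor
  `10⁻³`, along-structure conductivity
  `c + (1−c)·exp(−gain/(μ₁−μ₂)²)`. The explicit step (τ = 0.15 ≤ 0.25)
  uses staggered half-point fluxes for the principal tensor terms with
  zero-flux boundaries — the wide central-difference form has an odd/even
  checkerboard decoupling that fails to damp noise (measured before the
  change: centerline noise variance *rose* over 20 iterations; after:
  it drops ~15×). Interior mean is conserved exactly. Iteration stops
  when the last two changes of the 64-bin FOV entropy both fall below
  `10⁻³` nats. On the sparse ridge response the entropy stabilizes
  immediately (the histogram is dominated by the zero bin and the
  tensor contrast `(μ₁−μ₂)²` ≈ 10⁻⁶ sits far below the default gain
  10⁻⁴), so the stage is nearly inert with default parameters; forcing
  40–80 active iterations was measured to slightly *worsen* the final
  segmentation by spreading the response, so the defaults stand.
* **Binarization.** Candidate A lies `k·std` (k = 0.7) from the FOV mean
  on the **vessel side** of the histogram — `mean + k·std` for the
  vessel-bright response (default), `mean − k·std` for a vessel-dark
  image (`tail="dark"`). Candidate B is the mean response over the top
  decile of Sobel gradient magnitude inside the FOV. The smaller becomes
  the mask threshold, the larger the marker threshold, guaranteeing
  marker ⊆ mask; reconstruction keeps exactly the 8-connected mask
  components seeded by the marker, and components under 70 px are
  dropped. The vessel-side-tail choice is essential: on a right-skewed
  response histogram `mean − 0.7·std` is ≤ 0 and would make the mask
  threshold vacuous (the whole FOV becomes one component).
* **Evaluation.** Counts over FOV pixels only; AUC = (Se+Sp)/2 by
  definition (not a trapezoidal integral); zero-denominator rates report
  1 with a warning flag; table values round half away from zero to three
  decimals.

## The phantom

`generate_phantom` renders a recursive binary-branching tree: per
generation, widths decay by 0.62 from 10 px (clamping at 1 px, so
single-pixel vessels exist by construction), segment lengths decay by
0.85 from 60 px, and branch angles are drawn uniformly in ±[20°, 50°].
Six trees start on a ring at 85 % of the FOV radius pointing inward. The
cross-section profile is a Gaussian with FWHM equal to the nominal width,
truncated at the half-width — so the rendered support coincides exactly
with the analytic ground truth (`d ≤ w/2` plus the rasterized centerline
pixels). Vessels wider than 3 px get a bright centerline streak (the
light reflex) of width 0.3·w and amplitude 0.12. The background is a
per-channel base level (red 0.80, green 0.52, blue 0.30) times a radial
vignette (strength 0.25) and a linear tilt (0.08 per image width), with
vessel depths (0.25, 0.45, 0.18) — green deepest, as in real fundus
images — and additive Gaussian noise σ = 0.02. The geometry yields a
vessel fraction ≈ 0.09 of the FOV with most vessel *area* in medium and
large vessels, mirroring public-benchmark manual annotations in which
observers do not resolve most capillaries.

What the phantom does **not** emulate: optical point-spread blur (thin
vessels keep full contrast), background texture (choroidal structure,
pigmentation), pathology (exudates, hemorrhages), the optic disc, and
vessel curvature within segments. Passing the phantom tests therefore
demonstrates the pipeline's mechanics and its degradation behavior, not
clinical-grade performance on real retinas.

## Test-suite problem sizes

Unit and property tests run on grids up to ~220², with oracle-equivalence
checks on 200 random small grids per primitive (loop-based morphology,
per-pixel Wiener, geodesic-dilation fixpoint, flood-fill area filter).
End-to-end checks use the full 768×584 phantom where the claim concerns
the default conditions (segmentation quality, ablation directions) and a
reduced 384×288 phantom for repeated-run properties (determinism, noise
degradation) — a deliberate size split so the whole suite stays fast
while the headline claims are tested at full scale.

## Known limitations

* The smallest available cross-section scale is σ_u = 2 px, so 1–2-px
  vessels are detected with a 1–2-px halo; specificity on
  capillary-dense images saturates around 0.95 and the Dice score is
  bounded by boundary mislocalization rather than missed vessels.
* The sensitivity ordering between scale-normalization cases 2 and 3 is
  robust on real low-contrast capillaries (the regime case 2 targets) but
  is within seed noise on the phantom, whose thin vessels keep full
  contrast; the rescale-invariant thin-to-wide response ratio shows the
  direction clearly and is what the unit suite asserts.
* The entropy stopping rule makes the diffusion stage effectively a
  no-op on sparse ridge responses (see above); it is retained for
  fidelity and configurability rather than measured benefit.
* Threshold selection assumes a unimodal response histogram; images whose
  FOV contains large non-retinal regions would bias both candidates.
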