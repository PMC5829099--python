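# Methods

`lcacomp` implements a retinal model of how the visual system compensates
for longitudinal chromatic aberration (LCA): the wavelength dependence of
the eye's refractive power (~2 diopters across the visible spectrum) leaves
the S-cone (blue) image strongly defocused whenever the eye is accommodated
for mid/long wavelengths, yet perception shows neither blur nor the
blue–yellow border fringes the optics produce. The model attributes the
compensation to two known properties of the S pathway: the high-spatial-
resolution (form) pathway is built from L and M signals only, and the
blue–yellow signal is carried by spatially coextensive type-II receptive
fields (small bistratified cells, SBC) that respond only to chromatic — not
achromatic — structure.

## Pipeline

1. **Stimulus / cone encoding** (`stimuli`). Input RGB rasters (or the
   built-in synthetic fixtures) are converted to linear light and then to
   L, M, S cone planes with a fixed matrix: linear sRGB → CIE XYZ (D65) →
   Hunt–Pointer–Estévez fundamentals, row-normalized so equal-RGB pixels
   give L = M = S exactly. Any fixed invertible transform with this
   "achromatic closure" suffices for the model; the normalization makes the
   achromatic null-response properties exact rather than approximate.

2. **Optics** (`optics`). LCA is emulated by blurring each cone plane with
   a Gaussian PSF of width

   `sigma_px = k · defocus(D) · pupil(mm) · ppd / 60`,

   with calibration constant k = 1 (for the defaults — 1.5 D of S defocus,
   3 mm pupil, 64 px/deg — this gives sigma ≈ 4.8 px, comparable to the
   geometric blur-disc radius of ~8 px for that defocus). Defaults: L and M
   in focus (0 D), S at 0.75 of the 2 D span, reflecting a reference focus
   near 589 nm with most of the chromatic shift at short wavelengths. This
   is a deliberate simplification of wavefront optics: the model under test
   needs a realistic, controllable blue-channel blur, not optical fidelity.
   All convolutions in the package use reflective (half-sample symmetric)
   padding, which conserves per-channel flux and avoids border fringes.

3. **Adaptation** (`adaptation`). Each cone plane passes a compressive
   nonlinearity with local and remote gain control:

   `sigma = a·photo + b + c·remote`, `adapted = photo/(photo+sigma) · (photo+remote)`,

   a = c = 1 (equal local/remote strength), b = 3 (adaptation strength).
   The remote signal is a unit-sum weighted mean over an annulus of 35 px
   outer diameter (weights `exp(-r²/rho_remote²)`, rho_remote = diameter/4,
   inner radius 9 px = 3·rho_sur — just outside the classical RF). Values
   not printed in the source material (rho_remote, inner radius) are
   defaults here and configurable. A pure Naka–Rushton variant (without the
   `(photo+remote)` factor) is switchable via `AdaptationParams.form`; the
   downstream pipeline is agnostic to the exact compressive form since both
   preserve achromatic closure.

4. **Opponent receptive fields** (`opponent`). Type-I difference-of-
   Gaussians responses `L+M- = L_ad*f_c − M_ad*f_s` and
   `M+L- = M_ad*f_c − L_ad*f_s` with `f(r) ∝ exp(-r²/rho²)`, rho_cen = 1 px,
   rho_sur = 3 px ("three times larger"), truncated at 3·rho and
   renormalized to unit sum (the printed continuous normalization 1/(π·rho)
   is dimensionally inconsistent; unit discrete weight is what the model's
   uniform-field null response requires). The type-II blue–yellow response
   integrates the coextensive chromatic difference
   `S_ad − (L_ad+M_ad)/2` under a single-signed Gaussian with
   rho_s_rf = rho_sur = 3 px (the SBC radius is not separately printed;
   equating it with the surround scale is the documented default).

5. **Inverse transformation** (`inverse`). Perceived L and M planes are
   defined by `L+M- = L_per − M_per*f_s` and `M+L- = M_per − L_per*f_s`
   (surrounds now in the perceived domain) and found by minimizing the
   squared error E of these equations. Solvers:
   - `jacobi` — relaxation of the fixed point (diagonal of the system is
     the identity); relaxation factor 1.0, step-halving guard keeps E
     non-increasing. Chromaticity visibly fills in from edges inward.
   - `gradient` — descent on E with dt = 0.1 and the same guard. The
     update is the exact gradient `2·Aᵀ(Ax−b)`; the cross-term is a full
     convolution with f_s rather than only its central tap.
   - `direct` — sparse 2N×2N ridge least squares (ridge 1e-9), the oracle
     for small images.
   - `spectral` (pipeline default) — exact FFT solution of the identical
     reflective-boundary system via symmetric extension onto a doubled
     periodic domain, where the surround operator is diagonal and each
     frequency is a closed-form 2×2 solve. It is mathematically the same
     solution as `direct` (verified in tests to ~1e-6) at a fraction of
     the cost, which keeps 256×256 runs in the low seconds.

   The operator annihilates constant achromatic offsets (u, u); this null
   mode is pinned by the achromatic initialization
   `L0 = M0 = S0 = (L_ad+M_ad)/2`. The unmatchable symmetric mean of the
   opponent maps (exactly the component the least-squares solution leaves
   as residual) is projected out before solving. Convergence of the
   iterative schemes is declared when the max-abs per-pixel update drops
   below `tol` (1e-6 default, cap 5000 iterations; non-convergence is
   flagged on the result, not raised).

   Finally `S_per = S+(L+M)- + (L_per+M_per)/2`; S_per contributes to
   perceived color only, not to brightness.

6. **Metrics** (`metrics`). Blue–yellow contrast is the per-pixel ratio of
   blue to the yellow channel Y = (R+G)/2 on linear renderings, so an
   achromatic pixel reads exactly 1; fringe magnitude is the max |B/Y − 1|
   within ±9 px (3·rho_sur) of known edge positions. Induction is the
   difference in mean S_per/(L_per+M_per) over the test-ring mask between
   the two ring-pattern variants ("sum" denominator convention by default;
   "mean" is a documented switch since the bracket notation S/(L+M) is
   ambiguous).

## Synthetic stimuli

- **Achromatic grid**: 256×256, 64-px squares at linear gray levels 0.9 and
  0.1 (strictly positive so the blue/yellow ratio stays defined on the dark
  squares). Used for the fringe-reduction measurement.
- **S-cone ring pattern**: 256×256, thirteen concentric 8-px rings; the
  central (7th) ring is the test ring, flanking rings alternate between two
  inducers, and the two variants swap the inducers so the test ring is
  pixel-identical while its neighbors change. The published stimulus
  chromaticities are not printed; the defaults — test (0.8, 0.5, 0.6),
  purple inducer (0.5, 0.3, 0.8), lime inducer (0.6, 0.8, 0.3), gray
  background — are documented approximations of the Shevell–Monnier
  pattern. In the package's cone space these give S/(L+M) of 0.51 (test),
  0.97 (purple) and 0.25 (lime) against an achromatic level of 0.5.

These fixtures emulate the published demonstrations' geometry and chromatic
structure, not their spectral rendering: real scenes are multispectral and
pass through wavefront optics with diffraction, higher-order aberrations
and photoreceptor sampling, none of which are modeled. Passing tests
therefore show that the opponent-encode/inverse-decode architecture removes
defocus-induced blue–yellow fringes and produces assimilative induction
under a trichromatic Gaussian-defocus approximation — not that the optics
module reproduces any particular eye.

## Numerical choices

- Reflective padding everywhere; kernels truncated at 3·rho (> 98% of the
  Gaussian mass) and renormalized.
- The spectral solver handles the singular DC frequency analytically; the
  direct solver uses ridge 1e-9 instead.
- Degenerate inputs: zero photoreceptor signal adapts to zero; pixels with
  near-zero yellow channel are flagged in profiles rather than divided;
  empty induction masks raise.
- Problem sizes: experiments run at the fixtures' native 256×256;
  oracle-equivalence checks run at ≤32×32 where the brute-force reference
  and the sparse solve are exact and cheap.

## Known limitations

- Trichromatic (per-cone-plane) blur instead of per-wavelength blur
  integrated over cone fundamentals; no transverse chromatic aberration.
- One remote-adaptation definition shared by both cell types.
- The inverse stage reconstructs the *adapted* domain; no attempt is made
  to invert the adaptation nonlinearity back to photoreceptor units, so
  rendered perceived images are compressed in absolute level (ratios, which
  all metrics use, are unaffected).
- Induction magnitude depends on the undocumented stimulus chromaticities
  and ring geometry; the prediction is calibrated only in the sense that
  the defaults above are fixed and documented.
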