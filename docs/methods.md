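# Methods

This note documents the models, algorithms, numerical choices and known
limitations of tfmkit, in the order data flows through the pipeline.

## Elastic model

The substrate is a linear-elastic, isotropic, **semi-infinite**
half-space with Young's modulus *E* (Pa) and Poisson ratio ν.  The
hydrogels this models are polyacrylamide slabs (3–70 kPa) thick
relative to the bead-displacement decay length, so no finite-thickness
correction is applied; analyses of very thin gels would need one and
are out of scope.  ν is configurable with default **0.45**
(polyacrylamide is nearly incompressible; its exact value is rarely
measured in TFM practice).  ν = 0.5 is accepted for forward simulation
but rejected by the inversion.

Tangential surface tractions τ (Pa) map to surface displacements u
(μm) per wavevector through the Boussinesq/Cerruti Green's tensor

    G(k) = 2(1+ν)/(E k³) [ (1−ν)k² + ν k_y²   −ν k_x k_y
                           −ν k_x k_y          (1−ν)k² + ν k_x² ].

G is real, symmetric and positive definite for every k ≠ 0
(det G ∝ 1−ν), so forward and inverse maps are well defined.  Working
in Pa, μm and rad/μm makes 1 Pa·μm² = 1 pN, so no unit constants appear
anywhere; conversions to display units (nN/μm for energy per area,
nN/μm² ≡ kPa for stress) are exact factors of 10³.

Numerical conventions:

- **Zero mode.** The k = 0 (spatial-mean) component is unobservable —
  a uniform traction produces no relative deformation on a periodic
  domain — and is set to zero in both directions.  Consequently any
  comparison with the analytic point-load solution is made modulo an
  additive constant.
- **Nyquist coupling.** On even-sized grids the Nyquist frequency
  aliases ±k into one sample; the off-diagonal Green's entry (odd in
  each k component) has no consistent value there and is set to zero,
  which preserves the Hermitian symmetry that keeps real fields real.
  With this convention the λ=0 round trip is exact to ~1e−15.
- **Direct vs normal-equations inverse.** For λ = 0 the code inverts G
  per wavevector directly rather than solving (G² )⁻¹G, which would
  square the condition number.

## Synthetic scenes

The simulator emulates the study conditions of monolayer TFM: a flat
gel (3 kPa "soft", 35 kPa "stiff"), sub-resolution beads imaged with a
Gaussian PSF under shot + read noise, frames every 10 minutes over
hours, and a stress-free reference frame at the *end* of the movie
(the cells are detached with SDS after recording).

**Traction generator.** Monolayer tractions are drawn as the
divergence of a random smooth symmetric stress tensor: three
independent Gaussian-filtered white-noise fields σ_xx, σ_xy, σ_yy and
τ_i = ∂_j σ_ij (spectral derivative on the periodic domain).  This is
the physically correct structure for a confluent sheet — force balance
holds *locally*, so any region much larger than the correlation length
exerts almost no net force and spectral power vanishes as k → 0.
Plain low-pass-filtered noise, by contrast, concentrates power in
domain-scale modes; most of the measured deformation then originates
outside any finite field of view, which no inversion can attribute
correctly.  The stress components are filtered ~√2 wider than the
requested correlation length so that the parameter describes the
*traction* field's correlation scale.  Fields are rescaled so the peak
traction magnitude equals `peak_stress`; their mean is exactly zero by
construction.

**Default scene** (the package's benchmark): 512×512 px field of view
at 0.2 μm/px (a 40× objective), simulated on a domain twice that size
and cropped centrally to keep FFT wrap-around out of the analyzed
region; traction grid spacing 8 px (1.6 μm); peak stress 200 Pa;
correlation length 8 μm (cell-cluster scale); bead density 0.02 /px²
(~5200 beads in view) with a 1 px PSF and 20% log-normal brightness
variation; Poisson shot noise plus Gaussian read noise of 4 a.u.
against a bead peak amplitude of 300 a.u., i.e. ≈ 21 dB signal-to-noise
measured as Var(signal)/Var(noise) on rendered frames.  On a 3 kPa gel
these tractions produce RMS displacements of ~0.5 μm with μm-scale
peaks.  Time series use an AR(1) schedule, s_t = ρ s_{t−1} +
√(1−ρ²) e_t with ρ = 0.9 at 10-min cadence and independent smooth
innovations, so the lag-ℓ field correlation is ρ^ℓ in expectation.

**What the simulator does not model:** bead photobleaching, focal
drift in z, refractive-index artifacts, non-uniform illumination, gel
nonlinearity or viscoelasticity, and out-of-plane (z) displacements.
Passing the synthetic benchmarks therefore validates the geometry,
algebra and noise robustness of the analysis chain, not its robustness
to every imaging pathology of real movies; rigid in-plane drift is the
one such artifact the pipeline explicitly corrects.

## PIV

Windowed zero-normalized cross-correlation (ZNCC): 32 px interrogation
windows on an 8 px step (75% overlap — the common reading of
"32 × 8 (window × overlap)" interrogation settings, giving a dense
vector grid), matched within a ±12 px search margin.  The margin must
exceed the largest expected displacement; 12 px covers the default
scene's peaks with headroom.  Mean subtraction and unit normalization
per window make the match insensitive to illumination differences
between the deformed and reference frames.

- **Subpixel:** 3-point Gaussian fit per axis, parabolic fallback when
  a correlation sample is non-positive.  When the peak value is
  exactly 1 (perfect registration; ZNCC cannot exceed 1) the integer
  lag is returned as-is, since any fitted apex offset would be
  spurious.  Accuracy on the default bead pair: ~0.02 px RMS.
- **Validity:** windows without texture, peaks below a minimum
  correlation (0.2), peaks failing a primary/secondary peak ratio
  screen (1.15), and peaks landing on the border of the (possibly
  frame-clipped) search surface are flagged invalid, never silently
  interpolated.  Single-pass only — no iterative window deformation,
  which the ≲ few-px displacements of this regime do not require.
- **Outlier screen:** normalized median test per component with a
  5×5 neighborhood, threshold 2.5, noise floor 0.1 px.  The 5×5
  neighborhood (rather than the classical 3×3) avoids two failure
  modes found during development: one-sided corner neighborhoods flag
  good vectors on strong gradients, and *pairs* of adjacent bad
  vectors at the grid edge shield each other in a 3×3 median.  On
  noiseless idealized fields the test can still flag curvature extrema
  (the noise floor models measurement noise that real data always
  has); such rare false replacements are benign neighbor-medians.
- **Gap fill:** invalid nodes take the median of their valid
  8-neighbors, iterated inward; a >50% invalid field is a hard error.
- **Reference and drift:** the reference frame is the last frame by
  default (post-detachment); whole-frame phase correlation provides
  optional rigid drift correction, with the applied shifts logged.

## Traction inversion

Tikhonov-regularized FTTC: τ(k) = (G\*G + λ²I)⁻¹G\*u(k).  λ is
specified *dimensionlessly*, as a multiple of the median singular
value of G on the analysis grid, making one setting transferable
across grid sizes and stiffnesses; the default is 1e−2, which is
invisible on clean data and damps the highest-frequency content where
camera noise dominates.  An L-curve selector (`choose_lambda`, maximum
discrete curvature of log‖residual‖ vs log‖τ‖) is available when the
noise level is unknown.

A measured field of view breaks the FFT solver's periodicity
assumption twice over: the data are not periodic, and the
displacements inside the window also carry the long-range (1/r)
elastic signature of tractions *outside* it.  The default method
therefore poses the inversion as a partially observed problem:
tractions live on a domain `pad_factor`(=2)× the field of view, the
forward map is constrained only where displacements were measured, and
the normal equations (AᵀA + λ²I)τ = Aᵀu with A = restrict∘G are solved
by conjugate gradients with FFT-applied operators (≤120 iterations,
~0.2 s for a 61×61 grid).  On cropped synthetic fields this recovers
the strain energy within ~5–10% where one-shot padded inversions
(zero-pad + cosine taper, or mirror extension — both retained as the
`fft` method) err by 15–30% with scene-dependent sign.  With
`pad_factor = 1` (fully observed periodic grid) every route reduces to
the same direct per-wavevector solve.  Reconstructed fields are
mean-subtracted per component (the unobservable zero mode) and
reported on the PIV grid without upsampling.

## Metrics

- **Strain energy** U_s = ½ Σ_nodes (τ·u) Δ², a midpoint-rule surface
  integral, adequate on the dense PIV grid; also reported per
  field-of-view area.  Negative values (anti-aligned fields) are
  physically inconsistent with an elastic origin and trigger a
  warning.  Per-area normalization uses the full analyzed
  field-of-view area — for confluent monolayers the cell-covered area
  coincides with it.
- **Mean traction** is the spatial mean of |τ|, identical to the
  integral of the traction magnitude over the field of view divided by
  its area.
- **Deformation correlation** between frames t and t+ℓ is the
  normalized inner product Σ(u_t·u_{t+ℓ})/(‖u_t‖‖u_{t+ℓ}‖), averaged
  over pairs; the vector form is used (stricter than correlating
  magnitude images, and equal to it for collinear fields).  Zero-norm
  frames are skipped and logged.
- **movie_metrics** runs PIV → fill → inversion → metrics per frame;
  a frame-level failure yields a NaN row and is logged, not fatal.

## Statistics

Rank-sum comparisons use the Mann–Whitney U (scipy backend): exact
null enumeration when the pooled sample is ≤ 16 with no ties, normal
approximation with tie and continuity corrections otherwise (the exact
branch is verified against an independent brute-force enumeration in
the tests).  Two-sided by default.  Normalization to the control-group
mean is a display convention — tests run on raw values, and the test
is in any case invariant under the common positive scaling.  Fold
changes are ratios of medians with seeded percentile-bootstrap CIs
(2000 resamples).  Input samples that pool time points and fields of
view are treated as exchangeable observations; any within-recording
dependence structure is the caller's responsibility to consider.

## Validation problem sizes

The shipped test suite and the acceptance script use: 20 random
128×128 fields for the forward/inverse round trip; a 256×256 grid
(0.5 μm spacing) for the point-load comparison over radii 4–32 μm;
256–272 px bead scenes for PIV accuracy; 8–10 frames of the default
512 px scene for end-to-end energy recovery (across two independent
scenes in the acceptance script, since frames within one AR(1) movie
are correlated); 40 frames for the temporal-correlation check; and
1000 null replicates (n = 20 per group) for type-I-error calibration.
The full suite runs in about a minute on one CPU.

## Known limitations

- Semi-infinite substrate only; no finite-thickness or z-traction
  recovery (2D in-plane analysis).
- Energy recovery on a finite field of view carries an irreducible
  boundary term: tractions just outside the window influence the
  measured displacements, and scenes with strong structure at the
  boundary can still deviate by ~20% in a frame's strain energy even
  with the masked solver.
- Single-pass PIV limits accuracy for displacements with strong
  intra-window gradients; multi-pass window deformation is a non-goal
  at the ≤ few-px displacements targeted here.
- The L-curve corner is ill-defined on noise-free data (the residual
  is ~0 for all λ); the selector then returns the smallest candidate
  with a warning, which is the right answer for clean data.
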