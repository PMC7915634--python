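# Methods

## Scope and problem

`ccfs` quantifies cell–cell adhesion from AFM force–distance curves acquired
in cell–cell force spectroscopy: a living cell bound to a tipless cantilever
is pressed against a target cell with setpoint force F0, held in contact for
a dwell time τ (constant-force or constant-height feedback), and retracted at
constant speed v_r while force versus displacement is recorded. The package
(i) segments the retract trace into rupture events and integrates the
detachment work W, (ii) aggregates W across acquisition conditions and fits
four parametric models of W versus each parameter, and (iii) simulates the
whole experiment with known ground truth so every stage is testable without
instrument data.

Units are fixed throughout: z in μm, force in nN, work in fJ (1 nN·μm =
1 fJ), speeds in μm/s, spring constant in N/m. Adhesive force is negative,
so W = −∫F dz is positive for adhesive curves.

## Retract-segment analysis

1. **Baseline.** Median and MAD (×1.4826) of the furthest 20% of samples by
   z. A fixed tail fraction is used because "far from the sample" must be
   reproducible; 20% of an 80 μm ramp is comfortably beyond any adhesion
   tether. The window must contain ≥ 16 samples.
2. **Z origin.** The first crossing of the baseline scanning in retraction
   order (from the minimum-separation end outward), linearly interpolated
   between the bracketing samples. Scanning from the contact end prevents
   far-tail noise wiggles from defining the origin. All downstream distances
   are relative to this point.
3. **Derivative.** Savitzky–Golay first derivative, default window 21
   samples, polynomial order 3 — common practice for step detection in AFM
   traces; both are configuration-exposed. Non-uniform spacing is handled
   through the mean spacing.
4. **Rupture events.** Peaks of the positive derivative (ruptures step the
   force up toward baseline) with prominence above
   `prominence_factor × noise_sd / window_span` (default factor 5). Two
   additional gates are part of the detector design: candidate peaks closer
   than one SG window are merged (the derivative response of a single step
   spans one window, so sub-window structure is ringing, not a second
   event), and each candidate must show a flank-median force jump larger
   than `prominence_factor × noise_sd`. The jump gate is what rejects
   correlated noise maxima of the smoothed derivative, whose prominence can
   exceed the derivative threshold even on step-free traces; flank medians
   are taken one half-window to either side of the peak. On strictly
   noiseless input the prominence threshold degenerates to zero and is
   replaced by a ripple floor of 1e-3 of the largest derivative value.
   Consequence: two ruptures closer than one window span (0.21 μm at
   default sampling) are reported as one event; the work integral is
   unaffected because it does not depend on interior events.
5. **Detachment point.** The last event gives (Z_det, F_det), with F_det the
   pre-rupture flank median relative to baseline.
6. **Work.** W = −∫₀^{Z_det}(F − baseline) dz by the trapezoidal rule with
   sub-sample interpolation at both ends. Repulsive excursions subtract; no
   floor at zero is applied — a net-negative W flags the curve instead.

Curves that fail any stage (no contact above 5× the noise floor, no baseline
crossing, no detected event within the ramp) are returned flagged with the
reason, excluded from condition aggregates, and counted in the QC report:
the 80 μm ramp is chosen to guarantee complete detachment, so a
non-detaching curve is a protocol failure, not a zero-work measurement.

Analysis runs on tip–sample separation by default (bending correction
z − F/k applied when a curve is not already corrected); raw piezo distance
is available via `distance="piezo"`. Whether the derivative is signed or
absolute is switchable; signed (ruptures only) is the default.

## Models

With N bonds formed in contact and W ∝ N ∝ ∫S(t)dt (S the instantaneous
Hertzian contact area), the four fitted forms are

- delay:    W(τ) = A + B·τ
- setpoint: W(F0) = A + B·F0^(2/3), from A = πRδ0 and F0 ∝ δ0^(3/2)
- approach: W(v_a) = A·τ·B/(B + v_a) — the effective bond-formation time
  falls inversely with approach speed, saturating at A·τ for slow approach
  (half-saturation speed B)
- retract:  W(v_r) = A·g·v_r + B·ln(1 + v_r/v_ref) — linear viscous drag
  plus a logarithmic kinetic-activation (Bell-type) term

The approach and retract forms follow a verbal physical description rather
than an explicit printed equation, so they are registered behind `ModelSpec`
and alternates can be added without touching the fitter. The constants
g = 6πR (R = 10 μm, Stokes-like geometry; residual units absorbed into A)
and v_ref = 1 μm/s are fixed so both fits have exactly two free parameters.
The Hertz prefactor uses the standard C = (4/3)E*√R; every scaling property
the package tests depends only on the exponent, not on C.

Fits are nonlinear least squares on the condition *means* (matching how
averaged work is conventionally displayed), with deterministic initial
guesses built from the first/last points, B ≥ 0 bounds for the delay and
setpoint models, and standard errors from the Jacobian. Inverse-variance
weighting by the SEM of each condition and pooled per-curve fitting are
available behind flags; both default off because group-size imbalance then
changes the estimand. No hypothesis tests are produced — the pipeline's
outputs are descriptive statistics and fits.

## Simulator

`SimulationConfig` defaults define one reference condition: approach and
retract at 10 μm/s, τ = 45 s, F0 = 1 nN, constant-height dwell, k = 0.03
N/m, 80 μm ramp at 100 samples/μm. The contact trajectory is Hertzian:
approach indentation grows at v_a up to δ0(F0); a constant-force dwell holds
S = πRδ0; a constant-height dwell relaxes the force exponentially (time
constant 5 s) to 40% of the setpoint — a single-exponential stand-in for the
cell remodeling seen in constant-height data — with S following the Hertz
area of the relaxed force. Bond count is Poisson with mean
k_on·∫S(t)dt; k_on = 0.05 bonds/(μm²·s) puts the expected work at the
tens-of-fJ scale of real cell–cell experiments (≈ 26 bonds, ≈ 32 fJ at the
reference condition). Each bond loads linearly from the contact point and
breaks at a force drawn from N(0.3, 0.1²) nN truncated below at 0.1 nN, at
an extension drawn from 4 + Exp(4) μm (mean 8 μm); the independent draws
make the expected per-bond work analytic, ½·E[f]·E[z] ≈ 1.22 fJ. A viscous
term −c·v_r·e^(−z/λ) (c = 0.02 nN per μm/s, λ = 2 μm) shapes the
near-contact region, Gaussian noise (0.02 nN) is added, and an optional
Bell-like flag scales the mean rupture force logarithmically with retract
speed. Hertz parameters: R = 10 μm, E* = 0.5 nN/μm² (= 0.5 kPa, the cortical
stiffness scale of rounded cells).

Ground truth per curve records every rupture (position, force), and the
exact work of the noiseless trace integrated on a 10×-denser grid from its
true baseline crossing to the last rupture. `expected_detachment_work` gives
the analytic first-order mean, E[N]·½E[f]E[z] plus the drag contribution,
used as the generator-truth reference in end-to-end recovery checks.

Per-curve random streams derive from the master seed via
`SeedSequence(seed, spawn_key=(condition_index, curve_index))`, so adding
conditions never reshuffles existing curves and a fixed master seed yields
byte-identical folders.

**What the simulator does not emulate** — and therefore what passing tests
do not demonstrate about real data: cell viscoelasticity beyond a single
exponential (no power-law rheology), membrane-tether force plateaus,
correlated instrument drift, day/cell heterogeneity, and any active
mechanosensing response. Recovery results validate the *pipeline*, not the
biological model.

## Numerical choices and degenerate inputs

- Work integration is exact for piecewise-linear traces whose knots lie on
  the sample grid (trapezoid = polygon area); interval ends are interpolated.
- Baseline noise of exactly zero switches event detection to the ripple
  floor; with noise between zero and ~1e-3 of the step height the jump gate
  degenerates and smooth gradients can register as events — realistic noise
  (≥ 0.01 nN) or exactly zero are the supported regimes.
- Plateau derivative peaks resolve to the leftmost sample (scipy
  `find_peaks` convention).
- Bending correction can break z monotonicity at large force steps
  (Δz = Δf/k); the working curve is re-sorted and duplicate separations
  dropped, with a warning.
- Curves shorter than 64 samples, or whose baseline window would have fewer
  than 16, are flagged rather than analyzed; 3-point toy curves still
  round-trip through the file dialect.
- The file dialect stores floats at 17 significant digits: read∘write is
  the identity on float64.
- Bootstrap CIs (percentile, seeded) return (min, max) with a warning below
  n = 3.

## Problem sizes

Validation uses 1000 random polygon curves for the work oracle, 500
staircases each for noiseless and noisy event detection, 50
curves/condition for the delay (6 conditions) and setpoint (3 conditions)
recovery sweeps, and 200 Monte-Carlo replicates for fitter calibration —
sizes at which the stochastic checks are stable to well under their
tolerances while the whole suite stays interactive.

## Known limitations

- The ccfs-txt dialect is this package's own exchange format; vendor
  exports need a thin adapter before `read_curve_file` applies.
- Events merged within one SG window under-count N on dense rupture
  cascades; event *count* is therefore a resolution-limited observable,
  unlike W.
- The approach- and retract-speed model forms are physically motivated
  interpretations; their fitted coefficients are not directly comparable
  across packages that adopt different fixed constants.
- Constant-height dwell relaxation (exponential to 40% of setpoint) is
  phenomenological; only the qualitative force decay is represented.
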