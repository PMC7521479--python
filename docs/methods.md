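# Methods

## Model

### Cortical LGN turnover

Cortical LGN (standing in for the whole Gαi–LGN–NuMA–dynein module, whose
components share the same cortical distribution) is a concentration field
`c(x, t)` on a 1D cortex path — a periodic circle for flattened cells, a
finite line with no-flux ends for cells on micropatterned lines, or the
closed cell contour in 2D. It obeys

    ∂c/∂t = D ∂²c/∂x² + b − k_off(x) c .

The cytoplasmic pool is treated as an unlimited reservoir, so the binding
flux `b` is constant. The off-rate is fast near mitotic chromatin
(Ran-GTP-dependent inhibition) and slow elsewhere:

    k_off(x) = k_far + (k_near − k_far) · g(d(x)),

where `d(x)` is the distance from the cortex point to the edge of the DNA
region and `g` is a logistic step equal to ½ at one inhibition range
`d_inh` from the DNA edge.

Parameters (defaults, units):

| parameter | default | unit | meaning |
|---|---|---|---|
| `D` | 0.01 | μm²/min | cortical diffusion of bound LGN (small: cortical accumulations are stable for tens of minutes) |
| `k_near` | 1/10 | 1/min | unbinding within the inhibition range (~10 min timescale) |
| `k_far` | 1/90 | 1/min | unbinding far from the DNA (~90 min timescale) |
| `b` | `k_far` | conc/min | binding flux; default normalizes the far-field steady state to 1 |
| `d_inh` | 4 | μm | inhibition range, measured from the DNA edge |
| `σ` (transition width) | 0.5 | μm | smoothness of the near/far switch; 0 gives a hard step. No sharpness is fixed by the biology; a smooth switch avoids discretization artifacts |
| `w_dna` | 4 | μm | DNA interval half-extent in 1D (≈ half a metaphase chromatin mass). The DNA footprint shape is a modelling choice: interval in 1D, disc then plate segment in 2D |

The inhibition range is measured from the DNA **edge** (distance 0 inside
the region); whether the original calibration measured from edge or centre
is not fixed by the data, and the choice is configurable via `w_dna`.

### Spindle mechanics in 1D

Astral microtubules emanate from the centrosome at `x_c` with length
density ρ(ℓ) — by default exponential with mean 6 μm truncated at 20 μm;
an empirical histogram can be supplied instead
(`MicrotubuleModel.from_histogram`). Cortical dynein pulls each
microtubule plus end with a force proportional to the local LGN
concentration, so the DNA (rigidly linked to the centrosome, offset
Δ = x_c − x_n fixed during a run) moves at

    dx_n/dt = v₀ ∫ c̄(x) p_MT(x − x_c) dx,   p_MT(u) = sign(u) ρ(|u|)/2 ,

with c̄ the concentration normalized by its spatial mean. The single
coefficient v₀ (default 6.7 μm/min, the population mean of per-cell fits)
absorbs the dynein force at reference LGN concentration, the microtubule
number and the spindle friction coefficient; no separate force or friction
parameters are exposed in 1D. The bipolar variant sums the force integral
over both asters, with the off-rate source (the DNA plate) at the spindle
centre; microtubules are not occluded by the central plate — both asters
integrate over the full domain.

The feedback loop — motion depletes LGN where the DNA is, depleted cortex
stops pulling, intact cortex ahead keeps pulling — makes the symmetric
rest state unstable. On a periodic domain the system settles into a
traveling wave (constant spindle speed, co-moving LGN profile); on a
finite line the wave reflects at the ends, producing back-and-forth
oscillations with maximal speed at the line centre. The 1D model keeps Δ
fixed and therefore cannot capture spindle turning; on lines the spindle
turns by reversing, not flipping — a documented limitation of the 1D
reduction.

### Two-phase 2D orientation model

Mitosis is split at `t_bipolar` = 9 min after nuclear envelope breakdown
(NEB), when bipolar spindle assembly completes.

**Phase I (rounding).** The cell outline is an ellipse whose half-axes
relax exponentially toward the rounded radius:
a(t) = R + (a₀ − R)e^(−t/τ), likewise b(t). Defaults a₀ = 20 μm,
b₀ = 8 μm, R = 10 μm, τ = 4 min describe an elongated interphase cell
rounding within ~10 min, the shape dynamics seen in adherent HeLa cells.
The DNA is a disc of radius `r_dna` = 5 μm (a prometaphase chromatin
rosette) at the cell centre: the short-axis cortex (b₀ − r_dna = 3 μm from
the DNA) sits inside the 4 μm inhibition range and is cleared, while the
long-axis poles (a₀ − r_dna = 15 μm) are not; once rounded
(R − r_dna = 5 μm > d_inh) the whole cortex is outside the range, so the
pattern persists with the slow 90-min turnover. Cortical material
redistributes along the shrinking contour to uniform linear density, so
the total bound LGN is conserved and the mean concentration rises by the
perimeter ratio (~1.45× for the default schedule) — the LGN accumulation
that accompanies rounding. The spindle angle is frozen during phase I.

**Phase II (orientation).** The DNA becomes the metaphase plate, a segment
of half-length `w_plate` = 4 μm through the centre perpendicular to the
spindle axis, and the spindle (poles at ±ℓ_s = 5 μm from the centre,
pinned to the cell centre) rotates under the torque of cortical pulling:

    dφ/dt = μ_r Γ,
    Γ = Σ_poles ∫ dθ  P(ℓ ≥ d(θ)) · c(contact(θ)) · [r_contact × f̂(θ)]_z ,

quadrature over 720 microtubule directions per pole; `d(θ)` is the
pole-to-cortex distance along direction θ (analytic ray–ellipse
intersection), `P(ℓ ≥ d)` the probability that an astral microtubule
reaches the cortex, the pull is along the microtubule from the contact
point, and the lever arm is taken about the cell centre. The torque uses
the **absolute** concentration in reference units (far-field steady state
= 1 at full LGN expression), not a per-frame-normalized one: reducing LGN
expression must reduce the force. The rotational mobility μ_r = 0.1
rad/(min·torque unit) was calibrated once so that a defaults run completes
reorientation from φ₀ = π/4 within ~20 min of phase II, then frozen.

LGN RNAi is emulated by scaling the binding flux `b` (`lgn_scale`), since
RNAi lowers the available protein, i.e. the reservoir flux — not the
unbinding kinetics. An optional external polarity cue adds a localized
(Gaussian in polar angle, nematic — two antipodal patches) extra binding
source at a given contour angle; its strength is in units of the baseline
flux. The cue's mathematical form is a modelling choice; source modulation
was chosen over off-rate modulation for symmetry with the RNAi emulation.

### Quantification

- **Kymograph normalization**: background subtraction (negative values
  clamped to 0) then division by the spatiotemporal mean (`global`) or by
  each frame's spatial mean (`per-frame`, the display convention).
- **Per-cell v₀ fit**: with the DNA track imposed, the unit-v₀ velocity
  u(t_j) = ∫ c̄(x, t_j) p_MT(x − x_c(t_j)) dx is computed per frame from
  the normalized kymograph, integrated to a predicted displacement g(t) by
  cumulative trapezoid, and v₀ = Σ g·Δx_obs / Σ g² in closed form
  (least squares through the origin). Exactly scale-invariant in intensity
  and linear in the observed displacement; negative fits are clipped to 0
  and flagged.
- **Kinetic fit**: (D, k_near, k_far, d_inh) by Nelder–Mead in
  log-parameter space, minimizing the RMS difference between the observed
  kymograph and the imposed-DNA forward model, both globally
  mean-normalized. The original calibration was by hand; the formal fit
  makes it reproducible. Non-convergence is flagged, not raised.
- **Inhibition range**: the minimum DNA distance among cortex nodes at or
  above the 0.975 linear-interpolation sample quantile of intensity. The
  statistic is designed for profiles with localized high-LGN accumulations
  (as around a moving spindle); on a noiseless flat plateau it reports the
  approach to the plateau instead.
- **Off-rate transition distance**: on a stationary profile, k_off(x) is
  reconstructed from the stationary balance (D c″ + b)/c on the model's
  own grid and the crossing of the midpoint between its plateaus is
  interpolated — this reads the inhibition range directly off the profile.
- **Speeds/excursions**: per-interval forward differences (matching
  frame-to-frame experimental tracking); excursion is the maximum distance
  from the time-averaged position, flagged above 10 μm.
- **Phase portraits**: symmetric moving-average smoothing (window shrunk
  at the track ends, keeping linear tracks exact) and central-difference
  velocities, one-sided at the endpoints.
- **Nematic order**: Q = ∫ c(θ)(cos 2θ, sin 2θ) dθ / ∫ c(θ) dθ over the
  contour polar angle θ; S_LGN = |Q|, angle = ½ atan2(Q_y, Q_x) in
  (−π/2, π/2]. The dθ measure (rather than arclength) makes a uniform
  field perfectly disordered on any cell shape, so S_LGN measures LGN
  patterning rather than contour anisotropy; with it, S rises from ~0
  after NEB and stabilizes once the crescents form, and the closed form
  c = 1 + β cos 2(θ − θ₀) on a circle gives S = β/2 exactly under either
  convention.

## Synthetic data

The generator emulates the statistical structure of live GFP-LGN /
tubulin-mCherry acquisitions: frame intervals from {2, 3, 5} min,
multiplicative Gaussian noise on the signal (SD 0.1 of the signal) plus an
additive Gaussian background (0.05 ± 0.02 in normalized units), clamped at
zero. No noise statistics were reported for the original recordings; these
defaults are plausible for spinning-disc fluorescence and are
configuration, not claims. Cohorts draw per-cell v₀ from a normal with
mean = SD = 6.7 μm/min truncated at zero (the printed dispersion equals
the mean, so an untruncated normal would produce negative speeds), domain
lengths uniform over 60–100 μm, and derive every per-cell seed
deterministically from the master seed; the same seed reproduces files
byte-identically. Every dataset ships a ground-truth manifest that the
quantification stages never read, so recovery tests are honest.

What the generator does **not** emulate: pixel-level point-spread
functions, photobleaching, segmentation and manual-tracking errors in the
DNA track, out-of-focus light, or 3D geometry. Passing recovery tests
therefore demonstrate the estimators' correctness and noise tolerance
under the stated noise model, not robustness to every imaging artifact.

## Numerics

- **1D grid**: dx = 0.2 μm by default (the diffusive boundary layer
  √(D/k_near) ≈ 0.32 μm is marginally resolved; a convergence test halving
  dx and dt verifies the traveling-wave speed changes < 2%). Periodic
  nodes at i·dx on [0, L); line nodes include both ends, integrals use
  trapezoid weights.
- **Time stepper**: Strang splitting with dt = 0.05 min (capped so
  k_near·dt ≤ 0.1) — an exact per-node exponential relaxation toward
  b/k_off for half a step, the exact spectral propagator of the discrete
  Laplacian (rFFT on periodic domains, DCT-I on no-flux lines) for a full
  step, then the second reaction half-step. Both substeps preserve
  positivity unconditionally (the propagator of a matrix with non-negative
  off-diagonal entries is entrywise non-negative) and conserve the
  discrete LGN budget exactly; the splitting error is O(dt²).
- **Force quadrature**: the pulling integral is evaluated in the folded
  form ∫₀^∞ ρ(u)/2 · (c̄(x_c+u) − c̄(x_c−u)) du on a midpoint u-grid with
  linear interpolation of c̄. A naive node-sum of c̄·p_MT has an O(dx) bias
  that depends on the sub-grid centrosome position (p_MT jumps at u = 0)
  and acts as a spurious pinning potential; the folded form is exactly
  zero on uniform fields for any centrosome position, which is what allows
  symmetry breaking to proceed from a 10⁻³ seeded perturbation.
- **Spindle advection**: explicit Euler with the cortex dt, sub-stepped
  whenever the spindle would cross more than half a grid cell per step.
- **Seeded perturbation**: a single antisymmetric sinusoidal bump of
  relative amplitude 10⁻³ on the initial uniform field; the sign is drawn
  from the seed (recorded in the result), fixing the direction of symmetry
  breaking.
- **Regime labels**: over the final 20% of a run, speed = mean |dx_n/dt|
  and its coefficient of variation; *traveling* if CV < 5% and
  speed > 0.05 μm/min, *oscillatory* if the direction of significant
  motion (|v| > 0.05 μm/min) reverses ≥ 2 times, else *stationary*.
- **2D contour**: 256 nodes uniform in arclength, rebuilt each step;
  reaction–diffusion by finite volumes on the polygon (same exact
  reaction, implicit diffusion); remap before each step conserves bound
  LGN per material segment. Torque quadrature over 720 directions per pole
  agrees with a 10⁴-direction reference within 1%.
- **Degenerate inputs**: zero-mean fields, non-finite steps, poles outside
  the contour, tracks leaving the domain, and zero-length segments raise
  errors naming the offending quantity; the kinetic fit reports
  non-convergence in its result instead of raising.

## Scope and limitations

- The 1D model cannot turn the spindle (Δ is fixed); turning on lines
  appears as velocity reversal.
- The 2D spindle is pinned to the cell centre: off-centre translation,
  spindle elongation, 3D tilting, cortical stiffness gradients and
  actomyosin mechanics are outside the model.
- The bipolar 1D force law sums both asters without occlusion by the
  metaphase plate.
- Experimental population statistics (cell-to-cell variability of speeds,
  excursion fractions, inhibition-range medians) depend on biological
  variance that the model does not generate; the package reproduces the
  model's calibrated constants by parameter recovery and the dynamical
  regimes by direct simulation, not the biological population numbers.

## Problem sizes

The shipped tests and the acceptance script use an 80 μm periodic domain
(400 nodes) with runs of 120–450 min of model time, a 60 μm line, and
2D runs of 49–60 min at 256 contour nodes; these settle all reported
regimes and keep a full run of the suite within a few minutes on one CPU.
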