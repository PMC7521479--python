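# spindlecortex

Mechanochemical crosstalk between the mitotic spindle and the cell cortex:
a tested simulation and quantification pipeline for spindle positioning by
cortical pulling forces.

## The problem

Dividing animal cells orient their mitotic spindle along the interphase
long cell axis even though they round up into a sphere at mitotic entry.
The machinery is well known — cortical Gαi–LGN–NuMA recruits dynein, which
pulls on astral microtubules — but a fixed cortical cue cannot explain the
striking *dynamics*: in flattened cells with monopolar spindles, the
spindle never rests; it travels continuously, trailed by a moving shadow
of cortical LGN depletion. This package implements a minimal feedback
model of that behaviour and the measurement procedures used to confront it
with live-imaging data:

1. **Cortical LGN reaction–diffusion** with chromatin-proximity-dependent
   unbinding: LGN binds from a large cytoplasmic reservoir at a constant
   flux `b`, diffuses slowly (D = 0.01 μm²/min) and unbinds with timescale
   ~10 min within an inhibition range d_inh = 4 μm of the DNA (a Ran-GTP
   signal) and ~90 min elsewhere:

   ∂c/∂t = D ∂²c/∂x² + b − k_off(x − x_n) c

2. **LGN-weighted pulling forces** on astral microtubules move the spindle:

   dx_n/dt = v₀ ∫ c̄(x) p_MT(x − x_c) dx,  p_MT(u) = sign(u) ρ(|u|)/2

   with ρ the astral microtubule length distribution, c̄ the mean-normalized
   LGN concentration, and a single coefficient v₀ (μm/min) absorbing motor
   force, microtubule number and friction. The coupled system breaks
   symmetry spontaneously and settles into a traveling wave — the spindle
   surfs its own depletion trail — and oscillates back and forth on finite
   line patterns.

3. **Bipolar spindle orientation in 2D** during mitotic rounding, in two
   phases: while the cell rounds (half-axes relaxing exponentially toward a
   circle), DNA-proximal unbinding clears LGN from the short-axis cortex
   and rounding concentrates the remainder, leaving LGN crescents at the
   long-axis poles; after bipolar spindle assembly (~9 min after nuclear
   envelope breakdown) the spindle rotates under the cortical torque

   dφ/dt = μ_r Γ,  Γ = Σ_poles ∫ dθ P(ℓ ≥ d(θ)) c(contact) [r × f̂]_z,

   aligning with the interphase long axis without any external cue. The
   alignment parameter a = cos 2φ and the nematic order S_LGN of the
   contour LGN pattern quantify the process.

The quantification half mirrors the experimental measurements: kymograph
background subtraction and mean normalization, a per-cell closed-form
least-squares fit of v₀, a formal least-squares fit of
(D, k_near, k_far, d_inh) through the imposed-DNA forward model, the
DNA-to-high-LGN inhibition-range statistic (0.975 intensity quantile),
frame-to-frame speeds and excursions, phase portraits, and cohort
alignment summaries. A synthetic-data module generates noisy
"acquisitions" with ground-truth manifests so every fitter can be tested
by honest parameter recovery.

## Worked example

```python
import spindlecortex as sc

domain   = sc.Domain1D(80.0, periodic=True)       # cortex path, μm
kinetics = sc.LgnKinetics()                       # D=0.01, τ=10/90 min
mt       = sc.MicrotubuleModel.exponential()      # mean length 6 μm
spindle  = sc.MonopolarSpindle(dna_center=40.0)   # v0 = 6.7 μm/min

res = sc.simulate_monopolar(kinetics, spindle, mt, domain, T=450.0, seed=1)
print(res.regime, round(res.asymptotic_speed, 3), round(res.speed_cv, 4))
```

prints

```
traveling 1.291 0.0031
```

— starting from a uniform cortex with a 0.1% seeded perturbation, the
monopolar spindle settles into a traveling LGN wave moving at a constant
1.29 μm/min (speed coefficient of variation 0.3% over the final fifth of
the run), in the experimentally observed ~1 μm/min range. Fitting the
characteristic velocity back from the run's own kymograph recovers the
generating value:

```python
fit = sc.fit_v0(res.kymograph, mt, domain=domain)
print(round(fit.v0, 2))   # 6.7 (generated with v0 = 6.7 μm/min)
```

A 2D rounding run shows spindle alignment:

```python
import numpy as np
ori = sc.run_orientation(sc.RoundingSchedule(),
                         sc.SpindleState2D(phi=np.pi / 4),
                         kinetics, mt, T=49.0)
print(ori.regime, round(ori.a[-1], 3))   # aligned 0.985
```

— a spindle starting 45° off the interphase long axis reorients to
alignment a = cos 2φ ≈ 0.99 within 40 min of nuclear envelope breakdown.

A command-line interface wraps the same functionality
(`spindlecortex simulate-monopolar --seed 1 --out run/`, plus
`simulate-line`, `simulate-bipolar`, `simulate-orientation`, `impose-dna`,
`synth-monopolar`, `synth-rounding`, `synth-cohort`, `fit-v0`,
`fit-kinetics`, `quantify`, `quantify-nematic`); every run writes its
parameters and seed to a manifest from which it can be regenerated
bit-identically.

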