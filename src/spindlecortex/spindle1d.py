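"""Spindle motion in 1D driven by LGN-dependent cortical pulling forces.

The mechanical half of the feedback loop: astral microtubules radiating
from the centrosome are pulled by cortical dynein with a force
proportional to the local (normalized) LGN concentration, so the DNA
moves with velocity

    dxn/dt = v0 * ∫ c̄(x) pMT(x - xc) dx ,

where pMT(u) = sign(u) ρ(|u|) / 2 is the signed density of astral
microtubule plus ends around the centrosome xc, and c̄ is the LGN
concentration normalized by its spatial mean. The single coefficient v0
(μm/min) absorbs the dynein force at reference LGN concentration, the
microtubule number, and the spindle friction coefficient.

Coupled to the DNA-proximity-dependent LGN unbinding of
:mod:`spindlecortex.cortex`, this produces traveling waves, spontaneous
symmetry breaking, and back-and-forth oscillations on finite lines.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .containers import Kymograph, Trajectory
from .cortex import CortexField, LgnKinetics, koff_profile, step_cortex, \
    steady_state_profile, uniform_field
from .geometry import DnaRegion, Domain1D

V0_DEFAULT = 6.7  # μm/min, population-mean characteristic velocity


class MicrotubuleModel:
    """Astral microtubule length distribution ρ(ℓ) and derived densities.

    ``pdf`` is the probability density of astral MT lengths; the signed
    end density around the centrosome is pMT(u) = sign(u) ρ(|u|) / 2; the
    reach probability P(ℓ >= d) weights pulling forces in 2D.
    """

    def __init__(self, knots: np.ndarray, density: np.ndarray):
        knots = np.asarray(knots, dtype=float)
        density = np.asarray(density, dtype=float)
        if np.any(density < 0) or np.any(np.diff(knots) <= 0) or knots[0] < 0:
            raise ValueError("length density must be >= 0 on increasing knots >= 0")
        area = np.trapezoid(density, knots)
        if area <= 0:
            raise ValueError("length density integrates to zero")
        self._knots = knots
        self._density = density / area
        # survival by cumulative trapezoid from the right
        cum = np.concatenate(
            [[0.0],
             np.cumsum((self._density[1:] + self._density[:-1]) / 2
                       * np.diff(knots))]
        )
        self._cdf = np.minimum(cum, 1.0)
        self.max_length = float(knots[-1])
        self.mean_length = float(np.trapezoid(knots * self._density, knots))

    @classmethod
    def exponential(cls, mean: float = 6.0, max_length: float = 20.0,
                    n_knots: int = 801) -> "MicrotubuleModel":
        """Exponential length distribution with the given mean, truncated."""
        if mean <= 0 or max_length <= 0:
            raise ValueError("mean and truncation length must be > 0")
        knots = np.linspace(0.0, max_length, n_knots)
        return cls(knots, np.exp(-knots / mean))

    @classmethod
    def from_histogram(cls, bin_edges, counts) -> "MicrotubuleModel":
        """Empirical distribution from a measured length histogram.

        ``bin_edges`` (n+1) and ``counts`` (n) as in a two-column digitized
        histogram; the density is piecewise constant on the bins.
        """
        edges = np.asarray(bin_edges, dtype=float)
        counts = np.asarray(counts, dtype=float)
        if len(edges) != len(counts) + 1:
            raise ValueError("need len(bin_edges) == len(counts) + 1")
        # represent the step density on a knot grid with double points ~ eps
        knots = [edges[0]]
        dens = [counts[0] / (edges[1] - edges[0])]
        for i in range(len(counts)):
            h = counts[i] / (edges[i + 1] - edges[i])
            knots.extend([edges[i] + 1e-9 * (i > 0), edges[i + 1]])
            dens.extend([h, h])
        return cls(np.asarray(knots[1:]), np.asarray(dens[1:]))

    def pdf(self, length):
        """Length density ρ(ℓ), zero outside the support."""
        length = np.asarray(length, dtype=float)
        out = np.interp(length, self._knots, self._density, left=0.0, right=0.0)
        return out if out.ndim else float(out)

    def survival(self, distance):
        """P(ℓ >= d): probability an astral MT reaches distance d."""
        d = np.asarray(distance, dtype=float)
        out = 1.0 - np.interp(d, self._knots, self._cdf, left=0.0, right=1.0)
        return out if out.ndim else float(out)

    def signed_end_density(self, u):
        """pMT(u) = sign(u) ρ(|u|) / 2, the signed plus-end density."""
        u = np.asarray(u, dtype=float)
        out = np.sign(u) * self.pdf(np.abs(u)) / 2.0
        return out if out.ndim else float(out)


@dataclass(frozen=True)
class MonopolarSpindle:
    """Monopolar spindle: DNA centre, rigid centrosome offset, velocity scale."""

    dna_center: float
    offset: float = 0.0           # xc - xn, μm (rigid link)
    v0: float = V0_DEFAULT        # μm/min

    def __post_init__(self) -> None:
        if self.v0 < 0:
            raise ValueError("v0 must be >= 0")

    @property
    def centrosome(self) -> float:
        return self.dna_center + self.offset


@dataclass(frozen=True)
class BipolarSpindle1D:
    """Bipolar spindle in 1D: DNA plate at the centre, poles at ±half_separation."""

    center: float
    pole_half_separation: float = 5.0
    v0: float = V0_DEFAULT

    def __post_init__(self) -> None:
        if self.pole_half_separation <= 0:
            raise ValueError("pole half-separation must be > 0")

    @property
    def poles(self) -> tuple[float, float]:
        return (self.center - self.pole_half_separation,
                self.center + self.pole_half_separation)


@dataclass
class SimulationResult1D:
    """Sampled output of a 1D run: trajectory, kymograph, regime summary."""

    t: np.ndarray
    xn: np.ndarray
    xc: np.ndarray
    v: np.ndarray
    kymograph: Kymograph
    asymptotic_speed: float
    speed_cv: float
    n_reversals: int
    regime: str
    params: dict = field(default_factory=dict)

    def trajectory(self) -> Trajectory:
        return Trajectory(self.t, self.xn)


# ---------------------------------------------------------------------------

def _force_offsets(domain: Domain1D, xc: float) -> np.ndarray:
    """Signed offsets x - xc of every node, wrapped to (-L/2, L/2] if periodic."""
    u = domain.x - xc
    if domain.periodic:
        u = (u + domain.length / 2) % domain.length - domain.length / 2
    return u


def aster_velocity_unit(cbar: np.ndarray, domain: Domain1D, xc: float,
                         mt: MicrotubuleModel) -> float:
    """Unit-v0 velocity ∫ c̄(x) pMT(x - xc) dx of a single aster.

    Evaluated in the folded form ∫_0^∞ ρ(u)/2 (c̄(xc+u) - c̄(xc-u)) du on a
    midpoint grid in u with linear interpolation of c̄, which is exactly
    antisymmetric and vanishes identically on a uniform field for any
    centrosome position (no grid-locking force). On line domains the
    integral is truncated at the cell ends.
    """
    du = domain.spacing
    reach = min(mt.max_length, domain.length / 2)
    m = int(np.ceil(reach / du))
    u = (np.arange(m) + 0.5) * du
    rho = mt.pdf(u)
    xp, xm = xc + u, xc - u
    if domain.periodic:
        L = domain.length
        x_ext = np.concatenate([domain.x, [L]])
        c_ext = np.concatenate([cbar, [cbar[0]]])
        cp = np.interp(np.mod(xp, L), x_ext, c_ext)
        cm = np.interp(np.mod(xm, L), x_ext, c_ext)
    else:
        cp = np.where((xp >= 0) & (xp <= domain.length),
                      np.interp(xp, domain.x, cbar), 0.0)
        cm = np.where((xm >= 0) & (xm <= domain.length),
                      np.interp(xm, domain.x, cbar), 0.0)
    return float(np.sum(rho / 2 * (cp - cm)) * du)


def dna_velocity(field: CortexField, spindle: MonopolarSpindle,
                 mt: MicrotubuleModel) -> float:
    """DNA velocity v0 ∫ c̄(x) pMT(x - xc) dx (μm/min)."""
    cbar = field.normalized()
    dom = field.domain
    xc = dom.wrap(spindle.centrosome) if dom.periodic else spindle.centrosome
    return spindle.v0 * aster_velocity_unit(cbar, dom, float(xc), mt)


def _bipolar_velocity(field: CortexField, spindle: BipolarSpindle1D,
                      mt: MicrotubuleModel) -> float:
    cbar = field.normalized()
    dom = field.domain
    v = 0.0
    for pole in spindle.poles:
        xc = dom.wrap(pole) if dom.periodic else pole
        v += aster_velocity_unit(cbar, dom, float(xc), mt)
    return spindle.v0 * v


def _perturbation(domain: Domain1D, x0: float, amplitude: float) -> np.ndarray:
    """A single antisymmetric sinusoidal bump centred on x0."""
    u = _force_offsets(domain, domain.wrap(x0))
    return amplitude * np.sin(2 * np.pi * u / domain.length)


def _classify(t: np.ndarray, v: np.ndarray) -> tuple[float, float, int, str]:
    n_tail = max(2, int(0.2 * len(t)))
    tail = v[-n_tail:]
    speed = float(np.mean(np.abs(tail)))
    cv = float(np.std(np.abs(tail)) / speed) if speed > 0 else 0.0
    moving = v[np.abs(v) > 0.05]
    n_rev = int(np.sum(np.diff(np.sign(moving)) != 0)) if len(moving) > 1 else 0
    if n_rev >= 2:
        regime = "oscillatory"
    elif speed > 0.05 and cv < 0.05:
        regime = "traveling"
    else:
        regime = "stationary"
    return speed, cv, n_rev, regime


def _run_coupled(kinetics: LgnKinetics, domain: Domain1D, dna_template: DnaRegion,
                 mt: MicrotubuleModel, velocity_fn, positions_fn, x0: float,
                 T: float, dt: float, perturbation: float, seed, sample_interval,
                 clamp: bool, params: dict,
                 init_field: CortexField | None = None) -> SimulationResult1D:
    """Shared engine for the coupled cortex + spindle runs."""
    dt = min(dt, 0.1 / kinetics.koff_near) if kinetics.koff_near > 0 else dt
    if sample_interval is None:
        sample_interval = max(dt, T / 600)
    stride = max(1, int(round(sample_interval / dt)))
    n_steps = int(round(T / dt))

    amp = perturbation
    if seed is not None:
        rng = np.random.default_rng(seed)
        amp = perturbation * (1.0 if rng.random() < 0.5 else -1.0)

    if init_field is None:
        fld = uniform_field(domain, kinetics)
    else:
        fld = CortexField(domain, init_field.c.copy(), 0.0)
    fld = CortexField(domain, fld.c * (1.0 + _perturbation(domain, x0, amp)), 0.0)
    xn = float(x0)

    lo = dna_template.half_extent
    hi = domain.length - dna_template.half_extent

    ts, xns, vs, frames = [], [], [], []

    def record(step: int, v_now: float) -> None:
        ts.append(step * dt)
        xns.append(xn)
        vs.append(v_now)
        frames.append(fld.c.copy())

    v_now = velocity_fn(fld, xn)
    record(0, v_now)
    for step in range(1, n_steps + 1):
        dna = replace(dna_template, center=domain.wrap(xn))
        koff = koff_profile(domain, dna, kinetics)
        fld = step_cortex(fld, koff, kinetics, dt)
        # advect the spindle; sub-step if it would cross more than half a cell
        remaining = dt
        while remaining > 0:
            v_now = velocity_fn(fld, xn)
            sub = remaining
            if abs(v_now) * sub > domain.spacing / 2:
                sub = domain.spacing / (2 * abs(v_now))
            xn += v_now * sub
            if domain.periodic:
                xn %= domain.length
            elif clamp:
                xn = min(max(xn, lo), hi)
            remaining -= sub
        if step % stride == 0 or step == n_steps:
            record(step, v_now)

    t = np.asarray(ts)
    xn_arr = np.asarray(xns)
    v_arr = np.asarray(vs)
    speed, cv, n_rev, regime = _classify(t, v_arr)
    kymo = Kymograph(
        x=domain.x, t=t, intensity=np.column_stack(frames),
        dna_center=xn_arr, dna_half_extent=dna_template.half_extent,
        normalization="raw",
    )
    xc = positions_fn(xn_arr)
    return SimulationResult1D(
        t=t, xn=xn_arr, xc=xc, v=v_arr, kymograph=kymo,
        asymptotic_speed=speed, speed_cv=cv, n_reversals=n_rev, regime=regime,
        params=dict(params, dt=dt, T=T, perturbation=amp, seed=seed),
    )


def simulate_monopolar(
    kinetics: LgnKinetics,
    spindle0: MonopolarSpindle,
    mt: MicrotubuleModel,
    domain: Domain1D,
    T: float = 450.0,
    dt: float = 0.05,
    perturbation: float = 1e-3,
    seed: int | None = None,
    dna: DnaRegion | None = None,
    sample_interval: float | None = None,
    init_field: CortexField | None = None,
) -> SimulationResult1D:
    """Coupled monopolar spindle + cortical LGN run on a periodic domain.

    Starts from a uniform LGN field carrying a single seeded antisymmetric
    perturbation of relative amplitude ``perturbation`` (sign drawn from
    ``seed`` when given). With the default kinetics the system breaks
    symmetry and settles into a traveling wave of LGN pushing the spindle
    at constant speed.
    """
    if abs(spindle0.offset) >= domain.length / 2:
        raise ValueError("centrosome offset must be smaller than half the domain")
    dna = dna or DnaRegion(center=spindle0.dna_center)

    def vel(fld: CortexField, xn: float) -> float:
        sp_now = replace(spindle0, dna_center=xn)
        return dna_velocity(fld, sp_now, mt)

    def positions(xn_arr: np.ndarray) -> np.ndarray:
        xc = xn_arr + spindle0.offset
        return domain.wrap(xc) if domain.periodic else xc

    return _run_coupled(
        kinetics, domain, dna, mt, vel, positions, spindle0.dna_center,
        T, dt, perturbation, seed, sample_interval, clamp=not domain.periodic,
        params={"model": "monopolar", "v0": spindle0.v0,
                "offset": spindle0.offset},
        init_field=init_field,
    )


def simulate_on_line(
    kinetics: LgnKinetics,
    spindle0: MonopolarSpindle,
    mt: MicrotubuleModel,
    domain: Domain1D,
    T: float = 450.0,
    dt: float = 0.05,
    perturbation: float = 1e-3,
    seed: int | None = None,
    dna: DnaRegion | None = None,
    sample_interval: float | None = None,
) -> SimulationResult1D:
    """Monopolar run on a finite line (micropatterned-line geometry).

    The LGN field has no-flux ends and the force integral is truncated at
    the cell ends; with defaults on a 60 μm line the spindle oscillates
    back and forth, fastest near the centre and pausing near the ends.
    """
    if domain.periodic:
        raise ValueError("simulate_on_line requires a non-periodic domain")
    if domain.length <= 2 * mt.mean_length:
        raise ValueError("line must be longer than twice the mean MT length")
    return simulate_monopolar(
        kinetics, spindle0, mt, domain, T=T, dt=dt,
        perturbation=perturbation, seed=seed, dna=dna,
        sample_interval=sample_interval,
    )


def simulate_bipolar_1d(
    kinetics: LgnKinetics,
    spindle0: BipolarSpindle1D,
    mt: MicrotubuleModel,
    domain: Domain1D,
    T: float = 450.0,
    dt: float = 0.05,
    perturbation: float = 0.0,
    seed: int | None = None,
    dna: DnaRegion | None = None,
    sample_interval: float | None = None,
) -> SimulationResult1D:
    """Bipolar spindle in 1D: forces summed over both asters, DNA at the centre.

    The symmetric configuration is an exact fixed point of the
    discretization; depending on parameters a perturbation either decays
    (stationary) or grows into a moving state (see
    :data:`BIPOLAR_MOVING_PARAMS`).
    """
    for pole in spindle0.poles:
        if not domain.periodic and not (0 <= pole <= domain.length):
            raise ValueError(f"spindle pole at {pole} outside the line domain")
    dna = dna or DnaRegion(center=spindle0.center)

    def vel(fld: CortexField, xn: float) -> float:
        sp_now = replace(spindle0, center=xn)
        return _bipolar_velocity(fld, sp_now, mt)

    def positions(xn_arr: np.ndarray) -> np.ndarray:
        h = spindle0.pole_half_separation
        xc = np.column_stack([xn_arr - h, xn_arr + h])
        return domain.wrap(xc) if domain.periodic else xc

    return _run_coupled(
        kinetics, domain, dna, mt, vel, positions, spindle0.center,
        T, dt, perturbation, seed, sample_interval, clamp=not domain.periodic,
        params={"model": "bipolar1d", "v0": spindle0.v0,
                "pole_half_separation": spindle0.pole_half_separation},
    )


def simulate_imposed_dna(
    kinetics: LgnKinetics,
    dna_track: Trajectory,
    domain: Domain1D,
    dna: DnaRegion | None = None,
    dt: float = 0.05,
    init: CortexField | None = None,
    normalization: str = "global-mean",
) -> Kymograph:
    """Cortex-only run with the DNA position imposed from a measured track.

    The off-rate profile follows the linearly interpolated track; the
    initial field defaults to the steady state around the track's first
    position (the recording starts from an established pattern). Output
    frames are sampled at the track's own times and, by default,
    normalized to the spatiotemporal mean.
    """
    if not dna_track.is_1d:
        raise ValueError("imposed DNA track must be 1D")
    pos = domain.wrap(dna_track.positions) if domain.periodic else dna_track.positions
    if not domain.contains(pos):
        raise ValueError("DNA track leaves the domain")
    dna = dna or DnaRegion(center=float(pos[0]))
    dt = min(dt, 0.1 / kinetics.koff_near) if kinetics.koff_near > 0 else dt

    if init is None:
        fld = steady_state_profile(replace(dna, center=float(pos[0])),
                                   kinetics, domain)
    else:
        fld = CortexField(domain, init.c.copy(), 0.0)

    t0, t_end = dna_track.t[0], dna_track.t[-1]
    n_steps = int(np.ceil((t_end - t0) / dt))
    frames = [fld.c.copy()]
    # unwrap a periodic track so interpolation follows the shortest path
    raw = np.asarray(dna_track.positions, dtype=float)
    if domain.periodic:
        raw = np.concatenate([[raw[0]],
                              raw[0] + np.cumsum(
                                  (np.diff(raw) + domain.length / 2)
                                  % domain.length - domain.length / 2)])
    next_frame = 1
    for step in range(1, n_steps + 1):
        t_now = min(t0 + step * dt, t_end)
        x_now = domain.wrap(np.interp(t_now, dna_track.t, raw))
        koff = koff_profile(domain, replace(dna, center=float(x_now)), kinetics)
        fld = step_cortex(fld, koff, kinetics, min(dt, t_end - t0 - (step - 1) * dt))
        while next_frame < len(dna_track.t) and t_now >= dna_track.t[next_frame] - 1e-9:
            frames.append(fld.c.copy())
            next_frame += 1
    while len(frames) < len(dna_track.t):
        frames.append(fld.c.copy())

    intensity = np.column_stack(frames)
    norm = "raw"
    if normalization == "global-mean":
        intensity = intensity / intensity.mean()
        norm = "global-mean"
    elif normalization == "per-frame-mean":
        intensity = intensity / intensity.mean(axis=0, keepdims=True)
        norm = "per-frame-mean"
    return Kymograph(
        x=domain.x, t=dna_track.t, intensity=intensity,
        dna_center=pos, dna_half_extent=dna.half_extent, normalization=norm,
    )


#: A parameter set for which the 1D bipolar configuration leaves the
#: symmetric rest state and settles into persistent motion.
BIPOLAR_MOVING_PARAMS: dict = {
    "kinetics": dict(D=0.01, koff_near=0.1, koff_far=1.0 / 90.0,
                     transition_width=0.5),
    "spindle": dict(pole_half_separation=3.0, v0=8.0),
    "dna": dict(half_extent=2.0, inhibition_range=4.0),
    "domain": dict(length=80.0, periodic=True, dx=0.2),
}


def bipolar_moving_setup():
    """Instantiate the shipped moving-regime bipolar parameter set."""
    p = BIPOLAR_MOVING_PARAMS
    domain = Domain1D(**p["domain"])
    kinetics = LgnKinetics(**p["kinetics"])
    spindle = BipolarSpindle1D(center=domain.length / 2, **p["spindle"])
    dna = DnaRegion(center=domain.length / 2, **p["dna"])
    return kinetics, spindle, dna, domain
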