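"""Two-phase 2D model of mitotic rounding and bipolar spindle orientation.

Phase I (rounding, before bipolar spindle assembly ~9 min after nuclear
envelope breakdown): the cell contour relaxes exponentially from its
elongated interphase shape toward a circle; cortical LGN concentrates as
the contour shortens (bound material is conserved per cortical segment)
and is cleared within the inhibition range of the DNA disc at the cell
centre. Because the short-axis cortex sits within that range while the
long-axis poles do not, LGN crescents form at the long-axis poles.

Phase II (orientation): the DNA condenses into the metaphase plate,
perpendicular to the spindle axis, and the spindle rotates under the
torque generated by cortical dynein pulling on astral microtubules with a
force proportional to the LGN concentration at the microtubule plus end:

    dφ/dt = μ_r Γ,   Γ = Σ_poles ∫ dθ P(ℓ >= d(θ)) c(contact) [r × f̂]_z .

Only microtubules long enough to reach the cortex pull. The polarized LGN
pattern inherited from phase I steers the spindle toward the interphase
long axis without any external cue.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import NamedTuple

import numpy as np
import scipy.sparse as sp
from scipy.sparse.linalg import spsolve

from .cortex import LgnKinetics, smooth_step
from .geometry import CellGeometry2D, build_contour
from .spindle1d import MicrotubuleModel


@dataclass(frozen=True)
class RoundingSchedule:
    """Exponential relaxation of the cell half-axes toward a circle.

    Time is measured from nuclear envelope breakdown (NEB); the bipolar
    spindle is complete at ``t_bipolar`` (default 9 min after NEB).
    """

    a0: float = 20.0          # interphase long half-axis, μm
    b0: float = 8.0           # interphase short half-axis, μm
    R: float = 10.0           # rounded radius, μm
    tau_round: float = 4.0    # min
    t_bipolar: float = 9.0    # min after NEB
    axis_angle: float = 0.0   # lab-frame orientation of the interphase long axis

    def __post_init__(self) -> None:
        if not (self.a0 >= self.b0 > 0):
            raise ValueError("need a0 >= b0 > 0")
        if self.tau_round <= 0 or self.t_bipolar <= 0:
            raise ValueError("tau_round and t_bipolar must be > 0")

    def axes(self, t: float) -> tuple[float, float]:
        decay = np.exp(-max(t, 0.0) / self.tau_round)
        return (self.R + (self.a0 - self.R) * decay,
                self.R + (self.b0 - self.R) * decay)


def evolve_shape(schedule: RoundingSchedule, t: float) -> CellGeometry2D:
    """Cell geometry at time t (min after NEB; pre-NEB times give the initial shape)."""
    a, b = schedule.axes(t)
    return CellGeometry2D(a_long=a, b_short=b, axis_angle=schedule.axis_angle)


@dataclass(frozen=True)
class SpindleState2D:
    """Bipolar spindle in the rounding cell, pinned to the cell centre."""

    phi: float                        # angle to the interphase long axis (lab frame
    #                                   angle is phi + schedule.axis_angle)
    pole_half_separation: float = 5.0  # μm
    plate_half_length: float = 4.0     # μm, metaphase plate (phase II footprint)
    dna_disc_radius: float = 5.0       # μm, DNA disc (phase I footprint)
    rot_mobility: float = 0.1          # rad/(min · torque unit), calibrated default

    def __post_init__(self) -> None:
        if self.pole_half_separation <= 0:
            raise ValueError("pole half-separation must be > 0")
        if min(self.plate_half_length, self.dna_disc_radius) < 0:
            raise ValueError("footprint sizes must be >= 0")


class NematicOrder(NamedTuple):
    S: float
    angle: float
    degenerate: bool


@dataclass
class OrientationResult:
    """Time series of a 2D orientation run."""

    t: np.ndarray
    phi: np.ndarray               # lab-frame spindle angle
    a: np.ndarray                 # alignment cos 2(phi - axis_angle)
    S_lgn: np.ndarray
    nematic_angle: np.ndarray
    axes: np.ndarray              # (n, 2) half-axes over time
    kymograph: np.ndarray         # (n_nodes, n) contour LGN concentration
    psi: np.ndarray               # material coordinates of the contour nodes
    regime: str
    params: dict = field(default_factory=dict)


def wrap_nematic(angle):
    """Map an angle into the nematic fundamental interval (-π/2, π/2]."""
    a = np.mod(np.asarray(angle, dtype=float) + np.pi / 2, np.pi) - np.pi / 2
    a = np.where(a == -np.pi / 2, np.pi / 2, a)
    return a if a.ndim else float(a)


def alignment(phi):
    """Alignment parameter a = cos 2φ (1 aligned with the long axis, -1 across)."""
    return np.cos(2.0 * np.asarray(phi, dtype=float)) if np.ndim(phi) else float(
        np.cos(2.0 * phi))


# ---------------------------------------------------------------------------
# contour cortex step (finite volume on the closed polygon)

def _node_widths(geometry: CellGeometry2D) -> np.ndarray:
    seg = geometry.segment_lengths()
    return (seg + np.roll(seg, 1)) / 2.0


def remap_contour_field(c_old: np.ndarray, old_geometry: CellGeometry2D,
                        new_geometry: CellGeometry2D) -> np.ndarray:
    """Carry bound LGN through a shape change, conserving mass per material segment."""
    w_old = _node_widths(old_geometry)
    w_new = _node_widths(new_geometry)
    if np.any(w_new <= 0) or np.any(w_old <= 0):
        raise ValueError("degenerate (zero-length) contour segment")
    return np.asarray(c_old, dtype=float) * (w_old / w_new)


def _contour_step(geometry: CellGeometry2D, c: np.ndarray, koff: np.ndarray,
                  b_node: np.ndarray, D: float, dt: float) -> np.ndarray:
    """One reaction-diffusion step on the contour (exact reaction + implicit diffusion)."""
    with np.errstate(divide="ignore", invalid="ignore"):
        decay = np.exp(-koff * dt)
        target = np.where(koff > 0, b_node / np.where(koff > 0, koff, 1.0), 0.0)
    c1 = np.where(koff > 0, target + (c - target) * decay, c + b_node * dt)
    if D > 0:
        n = len(c1)
        seg = geometry.segment_lengths()          # seg[i]: node i -> i+1
        w = _node_widths(geometry)
        # flux coupling g[i] between node i and i+1
        g = D / seg
        main = (g + np.roll(g, 1)) / w
        upper = -g / w                            # coupling to node i+1
        lower = -np.roll(g, 1) / w                # coupling to node i-1
        idx = np.arange(n)
        rows = np.concatenate([idx, idx, idx])
        cols = np.concatenate([idx, (idx + 1) % n, (idx - 1) % n])
        data = np.concatenate([1.0 + dt * main, dt * upper, dt * lower])
        A = sp.csc_matrix((data, (rows, cols)), shape=(n, n))
        c1 = spsolve(A, c1)
    if not np.all(np.isfinite(c1)):
        raise FloatingPointError("contour cortex step produced non-finite values")
    return np.maximum(c1, 0.0)


# ---------------------------------------------------------------------------
# DNA footprints and off-rate on the contour

def _point_segment_distance(pts: np.ndarray, p0: np.ndarray, p1: np.ndarray
                            ) -> np.ndarray:
    d = p1 - p0
    denom = float(d @ d)
    if denom == 0:
        return np.linalg.norm(pts - p0, axis=1)
    tt = np.clip((pts - p0) @ d / denom, 0.0, 1.0)
    proj = p0 + tt[:, None] * d
    return np.linalg.norm(pts - proj, axis=1)


def contour_dna_distance(geometry: CellGeometry2D, spindle: SpindleState2D,
                         phase: str, schedule_axis: float = 0.0) -> np.ndarray:
    """Distance from each contour node to the DNA footprint.

    Phase I: disc of radius ``dna_disc_radius`` at the cell centre.
    Phase II: metaphase-plate segment through the centre, perpendicular to
    the spindle axis, half-length ``plate_half_length``.
    """
    pts = geometry.xy
    center = np.asarray(geometry.center, dtype=float)
    if phase == "I":
        return np.maximum(np.linalg.norm(pts - center, axis=1)
                          - spindle.dna_disc_radius, 0.0)
    if phase == "II":
        perp = spindle.phi + schedule_axis + np.pi / 2
        u = np.array([np.cos(perp), np.sin(perp)])
        p0 = center - spindle.plate_half_length * u
        p1 = center + spindle.plate_half_length * u
        return _point_segment_distance(pts, p0, p1)
    raise ValueError(f"phase must be 'I' or 'II', got {phase!r}")


def contour_koff(geometry: CellGeometry2D, spindle: SpindleState2D, phase: str,
                 kinetics: LgnKinetics, d_inh: float = 4.0,
                 schedule_axis: float = 0.0) -> np.ndarray:
    """Off-rate per contour node: fast within d_inh of the DNA footprint."""
    d = contour_dna_distance(geometry, spindle, phase, schedule_axis)
    g = smooth_step(d, d_inh, kinetics.transition_width)
    return kinetics.koff_far + (kinetics.koff_near - kinetics.koff_far) * g


# ---------------------------------------------------------------------------
# torque

def _ray_ellipse_distance(geometry: CellGeometry2D, origin: np.ndarray,
                          directions: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Distance along each unit ray from an interior point to the ellipse,
    plus the contact points (lab frame)."""
    a, b = geometry.a_long, geometry.b_short
    p = geometry.to_ellipse_frame(origin)[0]
    ca, sa = np.cos(geometry.axis_angle), np.sin(geometry.axis_angle)
    d_ell = np.column_stack([ca * directions[:, 0] + sa * directions[:, 1],
                             -sa * directions[:, 0] + ca * directions[:, 1]])
    # quadratic A t^2 + 2 B t + C = 0 in the scaled frame
    px, py = p[0] / a, p[1] / b
    ux, uy = d_ell[:, 0] / a, d_ell[:, 1] / b
    A = ux ** 2 + uy ** 2
    B = px * ux + py * uy
    C = px ** 2 + py ** 2 - 1.0
    if C >= 0:
        raise ValueError("spindle pole lies on or outside the cell contour")
    disc = np.sqrt(B ** 2 - A * C)
    t = (-B + disc) / A          # positive root (origin interior)
    contact_ell = p + t[:, None] * d_ell
    ca2, sa2 = np.cos(geometry.axis_angle), np.sin(geometry.axis_angle)
    contact = np.column_stack(
        [ca2 * contact_ell[:, 0] - sa2 * contact_ell[:, 1] + geometry.center[0],
         sa2 * contact_ell[:, 0] + ca2 * contact_ell[:, 1] + geometry.center[1]])
    return t, contact


def _interp_contour(geometry: CellGeometry2D, values: np.ndarray,
                    pts: np.ndarray) -> np.ndarray:
    """Interpolate node values at contour points, periodic in the material angle."""
    q = geometry.to_ellipse_frame(pts)
    psi_q = np.mod(np.arctan2(q[:, 1] / geometry.b_short,
                              q[:, 0] / geometry.a_long), 2 * np.pi)
    psi = geometry.psi
    psi_ext = np.concatenate([psi, [psi[0] + 2 * np.pi]])
    val_ext = np.concatenate([values, [values[0]]])
    return np.interp(psi_q, psi_ext, val_ext)


def spindle_torque(c: np.ndarray, spindle: SpindleState2D,
                   mt: MicrotubuleModel, geometry: CellGeometry2D,
                   n_directions: int = 720, phi_lab: float | None = None) -> float:
    """Net torque about the cell centre from LGN-weighted cortical pulling.

    Each pole emits astral microtubules isotropically; a microtubule in
    direction θ contacts the cortex at distance d(θ) and pulls with force
    P(ℓ >= d) c(contact) along its own direction. ``c`` is the LGN field
    on the contour nodes in reference units (far-field steady state 1 at
    full LGN levels).
    """
    if n_directions < 360:
        raise ValueError("use at least 360 microtubule directions")
    phi = spindle.phi if phi_lab is None else phi_lab
    center = np.asarray(geometry.center, dtype=float)
    axis = np.array([np.cos(phi), np.sin(phi)])
    theta = (np.arange(n_directions) + 0.5) * (2 * np.pi / n_directions)
    dirs = np.column_stack([np.cos(theta), np.sin(theta)])
    dtheta = 2 * np.pi / n_directions
    torque = 0.0
    for sign in (+1.0, -1.0):
        pole = center + sign * spindle.pole_half_separation * axis
        dist, contact = _ray_ellipse_distance(geometry, pole, dirs)
        weight = mt.survival(dist) * _interp_contour(geometry, c, contact)
        lever = contact - center
        cross_z = lever[:, 0] * dirs[:, 1] - lever[:, 1] * dirs[:, 0]
        torque += float(np.sum(weight * cross_z) * dtheta)
    return torque


# ---------------------------------------------------------------------------
# nematic order of the contour LGN pattern

def nematic_order(c: np.ndarray, geometry: CellGeometry2D,
                  degeneracy_tol: float = 1e-9) -> NematicOrder:
    """Magnitude and angle of the 2-fold moment of the contour LGN pattern.

    Q = ∫ c(θ) (cos 2θ, sin 2θ) dθ / ∫ c(θ) dθ with θ the polar angle of
    the contour point about the cell centre; S_LGN = |Q| in [0, 1] and the
    nematic angle = ½ atan2(Q_y, Q_x) in (-π/2, π/2]. The polar-angle
    measure makes a uniform intensity perfectly disordered (S = 0) on any
    cell shape, so S reports LGN patterning, not contour anisotropy.
    """
    c = np.asarray(c, dtype=float)
    rel = geometry.xy - np.asarray(geometry.center)
    theta = np.arctan2(rel[:, 1], rel[:, 0])
    # weight by polar angle (uniform intensity has S = 0 on any shape)
    dtheta = np.mod(np.roll(theta, -1) - np.roll(theta, 1), 2 * np.pi) / 2
    w = dtheta
    total = float(c @ w)
    if total <= 0:
        raise ValueError("zero total contour intensity")
    qx = float((c * np.cos(2 * theta)) @ w) / total
    qy = float((c * np.sin(2 * theta)) @ w) / total
    S = float(np.hypot(qx, qy))
    if S < degeneracy_tol:
        return NematicOrder(S, 0.0, True)
    return NematicOrder(S, wrap_nematic(0.5 * np.arctan2(qy, qx)), False)


# ---------------------------------------------------------------------------
# full run

def run_orientation(
    schedule: RoundingSchedule,
    spindle0: SpindleState2D,
    kinetics: LgnKinetics,
    mt: MicrotubuleModel,
    lgn_scale: float = 1.0,
    cue: tuple[float, float] | None = None,
    cue_width: float = 0.3,
    T: float = 49.0,
    dt: float = 0.05,
    d_inh: float = 4.0,
    n_nodes: int = 256,
    n_directions: int = 720,
    sample_interval: float = 1.0,
    seed: int | None = None,
) -> OrientationResult:
    """Simulate rounding (phase I) and torque-driven orientation (phase II).

    ``spindle0.phi`` is the initial spindle angle relative to the
    interphase long axis. ``lgn_scale`` multiplies the LGN binding flux
    (values << 1 emulate LGN RNAi). ``cue`` = (contour polar angle in the
    lab frame, strength) adds a localized extra binding source, emulating
    a dominant external polarity cue. Times are minutes after NEB.
    """
    kin = kinetics.with_source_scale(lgn_scale)
    geom = build_contour(evolve_shape(schedule, 0.0), n_nodes)
    psi = geom.psi.copy()
    c = np.full(n_nodes, kin.b / kin.koff_far)
    phi_lab = spindle0.phi + schedule.axis_angle

    b_base = np.full(n_nodes, kin.b)

    def b_nodes(geometry: CellGeometry2D) -> np.ndarray:
        if cue is None:
            return b_base
        angle, strength = cue
        rel = geometry.xy - np.asarray(geometry.center)
        theta = np.arctan2(rel[:, 1], rel[:, 0])
        # nematic cue: two antipodal patches, strength in units of the base flux
        dist = np.abs(wrap_nematic(theta - angle))
        return b_base * (1.0 + strength * np.exp(-(dist / cue_width) ** 2))

    n_steps = int(round(T / dt))
    stride = max(1, int(round(sample_interval / dt)))

    ts, phis, Ss, angs, axes_list, frames = [], [], [], [], [], []

    def record(t_now: float) -> None:
        ts.append(t_now)
        phis.append(phi_lab)
        nem = nematic_order(c, geom)
        Ss.append(nem.S)
        angs.append(nem.angle)
        axes_list.append([geom.a_long, geom.b_short])
        frames.append(c.copy())

    record(0.0)
    for step in range(1, n_steps + 1):
        t_now = step * dt
        # cortical material redistributes to uniform arclength density as the
        # contour shortens: nodes stay at fixed perimeter fractions, so the
        # per-segment remap reduces to a uniform concentration by the
        # perimeter ratio (global LGN accumulation during rounding)
        new_geom = build_contour(evolve_shape(schedule, t_now), n_nodes)
        c = remap_contour_field(c, geom, new_geom)
        geom = new_geom
        phase = "I" if t_now < schedule.t_bipolar else "II"
        state = SpindleState2D(
            phi=phi_lab - schedule.axis_angle,
            pole_half_separation=spindle0.pole_half_separation,
            plate_half_length=spindle0.plate_half_length,
            dna_disc_radius=spindle0.dna_disc_radius,
            rot_mobility=spindle0.rot_mobility,
        )
        koff = contour_koff(geom, state, phase, kin, d_inh, schedule.axis_angle)
        c = _contour_step(geom, c, koff, b_nodes(geom), kin.D, dt)
        if phase == "II":
            gamma = spindle_torque(c, state, mt, geom, n_directions,
                                   phi_lab=phi_lab)
            phi_lab += spindle0.rot_mobility * gamma * dt
        if step % stride == 0 or step == n_steps:
            record(t_now)

    t = np.asarray(ts)
    phi_arr = np.asarray(phis)
    a_arr = np.cos(2 * (phi_arr - schedule.axis_angle))
    final_a = float(a_arr[-1])
    if cue is not None and abs(wrap_nematic(phi_arr[-1] - cue[0])) < np.pi / 12:
        regime = "cue-captured"
    elif final_a > 0.9:
        regime = "aligned"
    else:
        regime = "misaligned"
    return OrientationResult(
        t=t, phi=phi_arr, a=a_arr, S_lgn=np.asarray(Ss),
        nematic_angle=np.asarray(angs), axes=np.asarray(axes_list),
        kymograph=np.column_stack(frames), psi=psi, regime=regime,
        params={"lgn_scale": lgn_scale, "cue": cue, "T": T, "dt": dt,
                "d_inh": d_inh, "n_nodes": n_nodes, "seed": seed,
                "phi0": spindle0.phi, "axis_angle": schedule.axis_angle,
                "rot_mobility": spindle0.rot_mobility},
    )
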