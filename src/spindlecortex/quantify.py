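"""Measurement procedures applied to kymographs, tracks and contour profiles.

These mirror how the live-imaging data are quantified: background-corrected
mean-normalized kymographs, a per-cell least-squares fit of the
characteristic velocity v0, a formal least-squares fit of the kinetic
parameters via the imposed-DNA forward model, the DNA-to-high-LGN
inhibition-range statistic (0.975 intensity quantile), frame-to-frame
speeds and excursions, smoothed phase portraits, and cohort alignment
summaries.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy.optimize import minimize

from .containers import Kymograph, Trajectory
from .cortex import CortexField, LgnKinetics, _laplacian
from .geometry import DnaRegion, Domain1D, distance_to_dna
from .spindle1d import MicrotubuleModel, aster_velocity_unit, \
    simulate_imposed_dna


# ---------------------------------------------------------------------------
# kymograph normalization

def normalize_kymograph(kymo: Kymograph, background: float = 0.0,
                        mode: str = "global") -> Kymograph:
    """Background-subtract and mean-normalize a kymograph.

    ``global``: divide by the spatiotemporal mean of the background-corrected
    intensity. ``per-frame``: divide each frame by its own spatial mean.
    Negative post-subtraction values are clamped to 0 before averaging.
    """
    corrected = np.maximum(kymo.intensity - background, 0.0)
    if mode == "global":
        m = corrected.mean()
        if m <= 0:
            raise ValueError("mean intensity is not positive after background "
                             "subtraction")
        out, state = corrected / m, "global-mean"
    elif mode == "per-frame":
        m = corrected.mean(axis=0, keepdims=True)
        if np.any(m <= 0):
            raise ValueError("a frame has non-positive mean after background "
                             "subtraction")
        out, state = corrected / m, "per-frame-mean"
    else:
        raise ValueError(f"unknown normalization mode {mode!r}")
    return Kymograph(kymo.x, kymo.t, out, kymo.dna_center,
                     kymo.dna_half_extent, state, dict(kymo.meta))


def _domain_from_kymo(kymo: Kymograph, periodic: bool = True) -> Domain1D:
    dx = float(np.mean(np.diff(kymo.x)))
    L = dx * len(kymo.x) if periodic else float(kymo.x[-1] - kymo.x[0])
    return Domain1D(length=L, periodic=periodic, dx=dx)


def _unwrap_track(positions: np.ndarray, L: float) -> np.ndarray:
    """Unwrap a periodic 1D track so displacements follow the shortest path."""
    steps = (np.diff(positions) + L / 2) % L - L / 2
    return np.concatenate([[positions[0]], positions[0] + np.cumsum(steps)])


# ---------------------------------------------------------------------------
# per-cell v0 fit

@dataclass(frozen=True)
class V0Fit:
    v0: float
    predicted_displacement: np.ndarray
    observed_displacement: np.ndarray
    unit_velocity: np.ndarray
    clipped: bool


def fit_v0(kymo: Kymograph, mt: MicrotubuleModel,
           dna_track: Trajectory | None = None, offset: float = 0.0,
           xc_track: np.ndarray | None = None,
           domain: Domain1D | None = None, periodic: bool = True) -> V0Fit:
    """Per-cell least-squares fit of the characteristic velocity v0.

    The unit-v0 velocity u(t_j) = ∫ c̄(x, t_j) pMT(x - xc_j) dx is
    integrated into a predicted displacement g(t); v0 minimizes
    Σ_j (v0 g(t_j) - Δxn_obs(t_j))², which has the closed form
    v0 = Σ g Δxn_obs / Σ g². Scale-invariant in intensity by construction;
    a negative fit is clipped to 0 and flagged.
    """
    track = dna_track if dna_track is not None else kymo.dna_track()
    if len(track) != kymo.n_frames:
        raise ValueError("kymograph and DNA track must share frames")
    dom = domain if domain is not None else _domain_from_kymo(kymo, periodic)
    xc = (np.asarray(xc_track, dtype=float) if xc_track is not None
          else np.asarray(track.positions, dtype=float) + offset)
    w = dom.node_weights
    u = np.empty(kymo.n_frames)
    for j in range(kymo.n_frames):
        frame = kymo.frame(j)
        m = float(frame @ w / w.sum())
        if m <= 0:
            raise ValueError(f"frame {j} has non-positive mean intensity")
        cbar = frame / m
        xc_j = dom.wrap(xc[j]) if dom.periodic else xc[j]
        u[j] = aster_velocity_unit(cbar, dom, float(xc_j), mt)
    g = np.concatenate([[0.0], np.cumsum((u[1:] + u[:-1]) / 2 * np.diff(track.t))])
    denom = float(g @ g)
    if denom == 0:
        raise ValueError("no force signal: unit-v0 displacement is identically zero")
    obs = _unwrap_track(np.asarray(track.positions, dtype=float), dom.length) \
        if dom.periodic else np.asarray(track.positions, dtype=float)
    obs = obs - obs[0]
    v0 = float(g @ obs) / denom
    clipped = v0 < 0
    v0 = max(v0, 0.0)
    return V0Fit(v0, v0 * g, obs, u, clipped)


# ---------------------------------------------------------------------------
# kinetic-parameter fit via the imposed-DNA forward model

@dataclass(frozen=True)
class KineticsFit:
    D: float
    koff_near: float
    koff_far: float
    d_inh: float
    residual: float
    converged: bool
    n_evaluations: int


def fit_kinetics(kymo: Kymograph, dna_track: Trajectory | None = None,
                 domain: Domain1D | None = None,
                 init: LgnKinetics | None = None, d_inh_init: float = 4.0,
                 dna_half_extent: float | None = None,
                 dt: float = 0.05, maxiter: int = 400,
                 xatol: float = 1e-3, fatol: float = 1e-10) -> KineticsFit:
    """Least-squares fit of (D, koff_near, koff_far, d_inh) to a kymograph.

    The forward model is :func:`simulate_imposed_dna` with the observed DNA
    track; the objective is the RMS difference between the globally
    mean-normalized observed and simulated kymographs. A derivative-free
    simplex search runs in log-parameter space from the initial guess.
    Non-convergence is reported in the result, not raised.
    """
    track = dna_track if dna_track is not None else kymo.dna_track()
    dom = domain if domain is not None else _domain_from_kymo(kymo)
    init = init or LgnKinetics()
    obs = kymo if kymo.normalization == "global-mean" else \
        normalize_kymograph(kymo, 0.0, "global")
    w_dna = (float(dna_half_extent) if dna_half_extent is not None
             else float(np.atleast_1d(kymo.dna_half_extent or 4.0)[0]))
    n_eval = 0

    def objective(logp: np.ndarray) -> float:
        nonlocal n_eval
        n_eval += 1
        D, k_near, k_far, d_inh = np.exp(logp)
        if k_near < k_far:
            return 1e6 * (1.0 + k_far / max(k_near, 1e-12))
        kin = replace(init, D=D, koff_near=k_near, koff_far=k_far)
        dna = DnaRegion(center=float(track.positions[0]), half_extent=w_dna,
                        inhibition_range=d_inh)
        try:
            sim = simulate_imposed_dna(kin, track, dom, dna=dna, dt=dt,
                                       normalization="global-mean")
        except FloatingPointError:
            return 1e6
        return float(np.sqrt(np.mean((sim.intensity - obs.intensity) ** 2)))

    x0 = np.log([init.D, init.koff_near, init.koff_far, d_inh_init])
    res = minimize(objective, x0, method="Nelder-Mead",
                   options={"maxiter": maxiter, "xatol": xatol, "fatol": fatol,
                            "adaptive": True})
    D, k_near, k_far, d_inh = np.exp(res.x)
    return KineticsFit(float(D), float(k_near), float(k_far), float(d_inh),
                       float(res.fun), bool(res.success), n_eval)


# ---------------------------------------------------------------------------
# inhibition-range statistic (0.975 intensity quantile)

def inhibition_range(intensity: np.ndarray, dna_distance: np.ndarray,
                     q: float = 0.975) -> float:
    """Minimum DNA distance of the high-LGN cortex (top-quantile threshold).

    ``intensity`` and ``dna_distance`` are per-node values on one frame;
    the threshold is the linear-interpolation sample quantile and nodes at
    or above it count as high-LGN.
    """
    intensity = np.asarray(intensity, dtype=float)
    dna_distance = np.asarray(dna_distance, dtype=float)
    if intensity.shape != dna_distance.shape:
        raise ValueError("intensity and distance arrays must match")
    if len(intensity) < 40:
        raise ValueError("need at least 40 nodes for the 0.975-quantile statistic")
    if not (0 < q < 1):
        raise ValueError("quantile must be in (0, 1)")
    thr = np.quantile(intensity, q)
    return float(dna_distance[intensity >= thr].min())


def inhibition_range_field(field: CortexField, dna: DnaRegion,
                           q: float = 0.975) -> float:
    """Inhibition range of a 1D cortical field around a DNA region."""
    d = distance_to_dna(field.domain.x, dna, field.domain)
    return inhibition_range(field.c, d, q)


def koff_transition_distance(field: CortexField, dna: DnaRegion,
                             kinetics: LgnKinetics) -> float:
    """Distance from the DNA edge where the local off-rate crosses its midpoint.

    Reconstructs koff(x) = (D c'' + b) / c from the stationary balance on
    the field's own grid and locates the crossing of the midpoint between
    the near and far plateau values (the model's inhibition range).
    """
    dom = field.domain
    lap = _laplacian(dom) @ field.c
    with np.errstate(divide="ignore", invalid="ignore"):
        koff = (kinetics.D * lap + kinetics.b) / field.c
    d = distance_to_dna(dom.x, dna, dom)
    order = np.argsort(d)
    d_sorted, k_sorted = d[order], koff[order]
    mid = (k_sorted.max() + k_sorted.min()) / 2
    below = np.nonzero(k_sorted <= mid)[0]
    if len(below) == 0 or below[0] == 0:
        return 0.0
    i = below[0]
    # linear interpolation between the bracketing distances
    d0, d1 = d_sorted[i - 1], d_sorted[i]
    k0, k1 = k_sorted[i - 1], k_sorted[i]
    if k1 == k0:
        return float(d1)
    return float(d0 + (k0 - mid) / (k0 - k1) * (d1 - d0))


# ---------------------------------------------------------------------------
# track statistics

@dataclass(frozen=True)
class TrackStats:
    speeds: np.ndarray       # μm/min per consecutive frame pair
    mean_speed: float
    max_excursion: float     # μm from the time-averaged position
    exceeds_10um: bool


def speeds_and_excursion(track: Trajectory) -> TrackStats:
    """Frame-to-frame speeds and the maximum excursion from the mean position."""
    if len(track) < 2:
        raise ValueError("need at least two frames")
    pos = track.positions if track.positions.ndim == 2 \
        else track.positions[:, None]
    step = np.linalg.norm(np.diff(pos, axis=0), axis=1)
    speeds = step / np.diff(track.t)
    centroid = pos.mean(axis=0)
    exc = float(np.linalg.norm(pos - centroid, axis=1).max())
    return TrackStats(speeds, float(speeds.mean()), exc, exc > 10.0)


def phase_portrait(track: Trajectory, window: int = 5
                   ) -> tuple[np.ndarray, np.ndarray]:
    """(position, velocity) series of a 1D track after moving-average smoothing.

    Velocities are central differences on the smoothed positions with
    one-sided differences at the endpoints.
    """
    if not track.is_1d:
        raise ValueError("phase portraits are defined for 1D tracks")
    if window % 2 == 0:
        raise ValueError("smoothing window must be odd")
    if window >= len(track):
        raise ValueError("smoothing window must be shorter than the track")
    half = window // 2
    pos = np.asarray(track.positions, dtype=float)
    n = len(pos)
    # symmetric window, shrunk near the ends (keeps linear tracks exact)
    sm = np.empty(n)
    for i in range(n):
        k = min(half, i, n - 1 - i)
        sm[i] = pos[i - k:i + k + 1].mean()
    vel = np.gradient(sm, track.t)
    return sm, vel


def alignment_summary(angle_tracks: list[Trajectory],
                      t_grid: np.ndarray | None = None
                      ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Pointwise mean and SD of the alignment a = cos 2φ across cells.

    Tracks are interpolated to a common time grid (the first track's times
    by default).
    """
    if not angle_tracks:
        raise ValueError("no angle tracks given")
    grid = np.asarray(t_grid, dtype=float) if t_grid is not None \
        else np.asarray(angle_tracks[0].t, dtype=float)
    a = np.vstack([
        np.cos(2 * np.interp(grid, trk.t, np.asarray(trk.positions, dtype=float)))
        for trk in angle_tracks
    ])
    return grid, a.mean(axis=0), a.std(axis=0)
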