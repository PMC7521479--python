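"""Reaction-diffusion dynamics of cortical LGN.

Cortical LGN diffuses slowly along the cortex and exchanges with a large
cytoplasmic reservoir: binding at a constant flux ``b`` and unbinding at a
rate that is high near the mitotic DNA (chromatin-centred Ran-GTP signal)
and low far from it,

    dc/dt = D d2c/dx2 + b - koff(x) c .

Defaults follow the flat-HeLa calibration: D = 0.01 μm²/min, unbinding
timescale ~10 min within the inhibition range of the DNA and ~90 min
outside it. Concentration is dimensionless; the binding flux is chosen so
the far-field steady state is 1 unless overridden.

The time stepper Strang-splits the equation into an exact per-node
exponential relaxation toward ``b/koff`` (the reaction) and the exact
propagator of the discrete Laplacian (the diffusion). Both substeps
preserve positivity for any time step and conserve the discrete LGN
budget exactly (diffusion) or to O(dt²) (splitting).
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import scipy.fft as fft
import scipy.sparse as sp
from scipy.sparse.linalg import splu

from .geometry import DnaRegion, Domain1D, distance_to_dna


@dataclass(frozen=True)
class LgnKinetics:
    """Kinetic parameters of cortical LGN turnover.

    ``source`` defaults to ``koff_far`` so that the steady-state
    concentration far from the DNA equals 1. ``transition_width`` is the
    width of the smooth switch of the off-rate at one inhibition range
    from the DNA edge (0 gives a hard step).
    """

    D: float = 0.01                 # μm²/min
    koff_near: float = 1.0 / 10.0   # 1/min, within the inhibition range
    koff_far: float = 1.0 / 90.0    # 1/min, far from the DNA
    source: float | None = None     # concentration/min; None -> koff_far
    transition_width: float = 0.5   # μm

    def __post_init__(self) -> None:
        if self.D < 0 or self.koff_near < 0 or self.koff_far < 0:
            raise ValueError("rates and diffusion constant must be >= 0")
        if self.koff_near < self.koff_far:
            raise ValueError(
                f"koff_near ({self.koff_near}) must be >= koff_far ({self.koff_far})"
            )
        if self.transition_width < 0:
            raise ValueError("transition width must be >= 0")
        if self.source is not None and self.source < 0:
            raise ValueError("binding source must be >= 0")

    @property
    def b(self) -> float:
        return self.koff_far if self.source is None else self.source

    def with_source_scale(self, scale: float) -> "LgnKinetics":
        """Kinetics with the binding flux multiplied by ``scale`` (RNAi emulation)."""
        return replace(self, source=self.b * scale)


@dataclass
class CortexField:
    """Cortical LGN concentration sampled on a 1D domain."""

    domain: Domain1D
    c: np.ndarray
    t: float = 0.0

    def __post_init__(self) -> None:
        self.c = np.asarray(self.c, dtype=float)
        if self.c.shape != (self.domain.n_nodes,):
            raise ValueError(
                f"field has {self.c.shape} values for {self.domain.n_nodes} nodes"
            )
        if np.any(self.c < 0):
            raise ValueError("concentration must be non-negative")

    def total(self) -> float:
        """Discrete ∫ c dx in concentration·μm."""
        return float(self.c @ self.domain.node_weights)

    def mean(self) -> float:
        """Spatial mean concentration."""
        w = self.domain.node_weights
        return float(self.c @ w / w.sum())

    def normalized(self) -> np.ndarray:
        """c̄ = c divided by its spatial mean."""
        m = self.mean()
        if m <= 0:
            raise ValueError("cannot normalize: spatial mean of c is not positive")
        return self.c / m


def smooth_step(distance, d_inh: float, width: float):
    """Proximity weight: 1 at the DNA, 0 far away, 1/2 at one inhibition range.

    Logistic in distance with the stated width; a hard step when width is 0.
    """
    d = np.asarray(distance, dtype=float)
    if width == 0:
        return np.where(d < d_inh, 1.0, 0.0)
    # clip the argument to keep exp well-behaved for distant nodes
    z = np.clip((d - d_inh) / width, -60.0, 60.0)
    return 1.0 / (1.0 + np.exp(z))


def koff_profile(domain: Domain1D, dna: DnaRegion, kinetics: LgnKinetics) -> np.ndarray:
    """Unbinding-rate field: fast within the DNA inhibition range, slow outside."""
    d = distance_to_dna(domain.x, dna, domain)
    g = smooth_step(d, dna.inhibition_range, kinetics.transition_width)
    return kinetics.koff_far + (kinetics.koff_near - kinetics.koff_far) * g


# ---------------------------------------------------------------------------
# diffusion operators


def _laplacian(domain: Domain1D) -> sp.csc_matrix:
    n = domain.n_nodes
    h2 = domain.spacing ** 2
    main = np.full(n, -2.0)
    off = np.ones(n - 1)
    L = sp.diags([off, main, off], [-1, 0, 1], format="lil")
    if domain.periodic:
        L[0, -1] = 1.0
        L[-1, 0] = 1.0
    else:
        # no-flux ends, finite-volume form consistent with trapezoid weights
        L[0, 0], L[0, 1] = -2.0, 2.0
        L[-1, -2], L[-1, -1] = 2.0, -2.0
    return sp.csc_matrix(L / h2)


def _diffuse_exact(c: np.ndarray, domain: Domain1D, D: float,
                   dt: float) -> np.ndarray:
    """Apply exp(dt D L) for the discrete Laplacian L, spectrally.

    The propagator of the discrete Laplacian (circulant for periodic
    domains, no-flux/DCT-I for lines) is entrywise non-negative, so
    positivity and the discrete mass are preserved exactly.
    """
    n = domain.n_nodes
    h2 = domain.spacing ** 2
    if domain.periodic:
        m = np.arange(n // 2 + 1)
        lam = (2.0 - 2.0 * np.cos(2.0 * np.pi * m / n)) / h2
        return fft.irfft(fft.rfft(c) * np.exp(-D * dt * lam), n=n)
    # line: cosines cos(πki/(n-1)) are exact eigenvectors of the no-flux
    # finite-volume Laplacian (whose row sums vanish against trapezoid weights)
    k = np.arange(n)
    lam = (2.0 - 2.0 * np.cos(np.pi * k / (n - 1))) / h2
    coeff = fft.dct(c, type=1) * np.exp(-D * dt * lam)
    return fft.idct(coeff, type=1)


def step_cortex(
    field: CortexField, koff: np.ndarray, kinetics: LgnKinetics, dt: float
) -> CortexField:
    """Advance the LGN field one time step.

    Strang splitting: exact exponential relaxation of each node toward
    b/koff for half a step, the exact discrete diffusion propagator for a
    full step, then reaction for the second half step. Positivity-preserving
    and mass-conserving for any dt; the splitting error is O(dt²).
    """
    if dt <= 0:
        raise ValueError(f"time step must be > 0, got {dt}")
    koff = np.asarray(koff, dtype=float)

    def react(c: np.ndarray, h: float) -> np.ndarray:
        with np.errstate(divide="ignore", invalid="ignore"):
            decay = np.exp(-koff * h)
            target = np.where(koff > 0,
                              kinetics.b / np.where(koff > 0, koff, 1.0), 0.0)
        return np.where(koff > 0, target + (c - target) * decay,
                        c + kinetics.b * h)

    c1 = react(field.c, dt / 2)
    if kinetics.D > 0:
        c1 = _diffuse_exact(c1, field.domain, kinetics.D, dt)
    c1 = react(c1, dt / 2)
    if not np.all(np.isfinite(c1)):
        raise FloatingPointError(
            "cortex step produced non-finite concentrations "
            f"(dt={dt}, dx={field.domain.spacing}); reduce the time step"
        )
    c1 = np.maximum(c1, 0.0)
    return CortexField(field.domain, c1, field.t + dt)


def steady_state_profile(
    dna: DnaRegion, kinetics: LgnKinetics, domain: Domain1D
) -> CortexField:
    """Stationary LGN profile around a fixed DNA region.

    Solves the linear boundary-value problem D c'' + b - koff(x) c = 0
    directly on the grid.
    """
    koff = koff_profile(domain, dna, kinetics)
    n = domain.n_nodes
    A = kinetics.D * _laplacian(domain) - sp.diags(koff, format="csc")
    rhs = np.full(n, -kinetics.b)
    c = splu(sp.csc_matrix(A)).solve(rhs)
    if not np.all(np.isfinite(c)):
        raise np.linalg.LinAlgError("singular steady-state system")
    return CortexField(domain, np.maximum(c, 0.0), 0.0)


def uniform_field(domain: Domain1D, kinetics: LgnKinetics, level: float | None = None
                  ) -> CortexField:
    """Uniform field at the far-field steady state b/koff_far (or a given level)."""
    if level is None:
        level = kinetics.b / kinetics.koff_far
    return CortexField(domain, np.full(domain.n_nodes, float(level)), 0.0)
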