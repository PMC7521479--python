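"""Spatial domains, distances, and cell-shape geometry.

Coordinates are continuous and in micrometres throughout. A periodic 1D
domain represents the cortex of a flat mitotic cell projected on a closed
path (the half-open interval ``[0, L)``); a finite line represents cells
on thin micropatterned line substrates. The 2D contour of a rounding cell
is an arclength-parameterized ellipse.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.integrate import quad


@dataclass(frozen=True)
class Domain1D:
    """Discretized 1D cortical domain.

    Parameters
    ----------
    length:
        Domain length L in μm.
    periodic:
        Closed path (True) or finite line with cortex ends (False).
    dx:
        Target grid spacing in μm. Node coordinates are ``i*dx`` for
        ``i = 0..n-1`` (periodic, n = round(L/dx)) or ``i = 0..n-1`` with
        both endpoints included (line, n = round(L/dx)+1).
    """

    length: float
    periodic: bool = True
    dx: float = 0.2

    def __post_init__(self) -> None:
        if not (self.length > 0):
            raise ValueError(f"domain length must be > 0, got {self.length}")
        if not (self.dx > 0):
            raise ValueError(f"grid spacing must be > 0, got {self.dx}")
        if self.dx >= self.length:
            raise ValueError("grid spacing must be smaller than the domain")

    @property
    def n_nodes(self) -> int:
        n = int(round(self.length / self.dx))
        return n if self.periodic else n + 1

    @property
    def x(self) -> np.ndarray:
        """Node coordinates in μm, strictly increasing in [0, L)."""
        if self.periodic:
            return np.arange(self.n_nodes) * (self.length / int(round(self.length / self.dx)))
        return np.linspace(0.0, self.length, self.n_nodes)

    @property
    def spacing(self) -> float:
        """Actual node spacing (length divided into equal intervals)."""
        if self.periodic:
            return self.length / int(round(self.length / self.dx))
        return self.length / (self.n_nodes - 1)

    @property
    def node_weights(self) -> np.ndarray:
        """Quadrature weights for ∫ dx (uniform for periodic, trapezoid for line)."""
        h = self.spacing
        if self.periodic:
            return np.full(self.n_nodes, h)
        w = np.full(self.n_nodes, h)
        w[0] = w[-1] = h / 2
        return w

    def wrap(self, x):
        """Map coordinates into the fundamental interval [0, L)."""
        if self.periodic:
            return np.mod(x, self.length)
        return x

    def contains(self, x) -> bool:
        x = np.asarray(x, dtype=float)
        if self.periodic:
            return bool(np.all((x >= 0) & (x < self.length)))
        return bool(np.all((x >= 0) & (x <= self.length)))


@dataclass(frozen=True)
class DnaRegion:
    """Mitotic chromatin footprint on the 1D cortex path.

    The DNA occupies the interval ``[center - half_extent, center + half_extent]``;
    the Ran-GTP-like inhibitory signal extends ``inhibition_range`` μm beyond the
    DNA edge (4 μm by default).
    """

    center: float
    half_extent: float = 4.0
    inhibition_range: float = 4.0

    def __post_init__(self) -> None:
        if self.half_extent < 0:
            raise ValueError(f"DNA half extent must be >= 0, got {self.half_extent}")
        if self.inhibition_range < 0:
            raise ValueError(
                f"inhibition range must be >= 0, got {self.inhibition_range}"
            )


def periodic_distance(x, y, domain: Domain1D):
    """Shortest distance between cortical positions.

    On a periodic domain this is the circle metric ``min_k |x - y + kL|``;
    on a line it is ``|x - y|``. Scalars or arrays accepted (broadcast).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if not domain.contains(x):
        raise ValueError(f"coordinate {x} outside domain [0, {domain.length})")
    if not domain.contains(y):
        raise ValueError(f"coordinate {y} outside domain [0, {domain.length})")
    d = np.abs(x - y)
    if domain.periodic:
        d = np.minimum(d, domain.length - d)
    return d if d.ndim else float(d)


def distance_to_dna(x, dna: DnaRegion, domain: Domain1D):
    """Distance from cortical position(s) to the DNA interval edge (0 inside)."""
    d = periodic_distance(x, domain.wrap(dna.center), domain)
    out = np.maximum(np.asarray(d) - dna.half_extent, 0.0)
    return out if out.ndim else float(out)


@dataclass
class CellGeometry2D:
    """Elliptical cell outline with an arclength-uniform contour discretization.

    Attributes set by :func:`build_contour`:

    - ``s``: arclength coordinate of each node (μm), starting at the point on
      the positive long axis;
    - ``xy``: node positions, shape (n, 2);
    - ``normal_angle``: angle of the outward normal at each node (radians);
    - ``psi``: elliptic parametric angle of each node (material coordinate
      under affine shape changes).
    """

    a_long: float
    b_short: float
    center: tuple[float, float] = (0.0, 0.0)
    axis_angle: float = 0.0
    s: np.ndarray = field(default=None, repr=False)
    xy: np.ndarray = field(default=None, repr=False)
    normal_angle: np.ndarray = field(default=None, repr=False)
    psi: np.ndarray = field(default=None, repr=False)

    def __post_init__(self) -> None:
        if not (self.a_long >= self.b_short > 0):
            raise ValueError(
                f"need a_long >= b_short > 0, got ({self.a_long}, {self.b_short})"
            )

    @property
    def perimeter(self) -> float:
        """Ellipse perimeter by adaptive quadrature."""
        return ellipse_perimeter(self.a_long, self.b_short)

    def segment_lengths(self) -> np.ndarray:
        """Length of each contour segment (node i to node i+1, closed)."""
        nxt = np.roll(self.xy, -1, axis=0)
        return np.linalg.norm(nxt - self.xy, axis=1)

    def point_at_psi(self, psi) -> np.ndarray:
        """Lab-frame contour points at elliptic parametric angle(s) psi."""
        psi = np.atleast_1d(np.asarray(psi, dtype=float))
        ex = self.a_long * np.cos(psi)
        ey = self.b_short * np.sin(psi)
        ca, sa = np.cos(self.axis_angle), np.sin(self.axis_angle)
        return np.column_stack(
            [
                self.center[0] + ca * ex - sa * ey,
                self.center[1] + sa * ex + ca * ey,
            ]
        )

    def to_ellipse_frame(self, pts: np.ndarray) -> np.ndarray:
        """Map lab-frame points into the axis-aligned, centred ellipse frame."""
        pts = np.atleast_2d(np.asarray(pts, dtype=float)) - np.asarray(self.center)
        ca, sa = np.cos(self.axis_angle), np.sin(self.axis_angle)
        return np.column_stack([ca * pts[:, 0] + sa * pts[:, 1],
                                -sa * pts[:, 0] + ca * pts[:, 1]])


def _arc_speed(psi: np.ndarray, a: float, b: float) -> np.ndarray:
    return np.sqrt((a * np.sin(psi)) ** 2 + (b * np.cos(psi)) ** 2)


def ellipse_perimeter(a: float, b: float) -> float:
    val, _ = quad(lambda p: float(_arc_speed(np.asarray(p), a, b)), 0.0, 2 * np.pi,
                  limit=200)
    return val


def build_contour(geometry: CellGeometry2D, n_nodes: int = 256) -> CellGeometry2D:
    """Discretize the elliptical outline with nodes uniform in arclength.

    The parametric angles of the nodes serve as material coordinates: under
    an affine shape change (the rounding schedule) the same ``psi`` values
    identify the same cortical material points.
    """
    if n_nodes < 16:
        raise ValueError(f"need at least 16 contour nodes, got {n_nodes}")
    a, b = geometry.a_long, geometry.b_short
    # cumulative arclength on a fine parametric grid, then invert
    fine = np.linspace(0.0, 2 * np.pi, 20 * n_nodes + 1)
    speed = _arc_speed(fine, a, b)
    s_fine = np.concatenate(
        [[0.0], np.cumsum((speed[1:] + speed[:-1]) / 2 * np.diff(fine))]
    )
    perim = s_fine[-1]
    s_target = np.arange(n_nodes) * perim / n_nodes
    psi = np.interp(s_target, s_fine, fine)
    xy = geometry.point_at_psi(psi)
    # outward normal of the ellipse at parametric angle psi (lab frame)
    normal = np.arctan2(a * np.sin(psi), b * np.cos(psi)) + geometry.axis_angle
    geometry.s = s_target
    geometry.xy = xy
    geometry.normal_angle = normal
    geometry.psi = psi
    return geometry
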