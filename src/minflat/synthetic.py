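"""Study inputs: the cell-shape library and synthetic oscillation signals.

The irregular flattened shapes (``shapeA``, ``shapeB``) stand in for the
microchannel-deformed cells of the experiments this model targets: wide
(shapeB exceeds 5 um across), flattened to 0.4 um, asymmetric along the long
axis but with exactly one in-plane mirror symmetry.  Their true outlines were
never published numerically, so they are defined here by documented Fourier
radius coefficients; results for them are approximation-dependent by
construction.  ``stadiumA``/``stadiumB`` are discorectangles matched to the
corresponding irregular shape in outline aspect ratio, thickness and volume.

The synthetic signal generator produces antiphase polar-count pairs from a
phase-diffusing oscillator (Wiener phase noise), chosen because its exact
cross-correlation is the damped cosine -cos(2*pi*tau/T) * exp(-tau/tau_c)
used to quantify oscillation coherence.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from shapely.geometry import Polygon

from .geometry import (
    CellGeometry,
    ShapeSpec,
    build_flattened,
    build_pill,
    match_stadium,
    stadium_polygon,
)

__all__ = [
    "SHAPE_NAMES",
    "FLATTENED_THICKNESS",
    "IrregularOutlineSpec",
    "SyntheticSignalSpec",
    "make_shape",
    "make_outline",
    "make_signal",
]

#: thickness of every flattened cell (um): the smallest slit thickness the
#: deformed cells are able to penetrate.
FLATTENED_THICKNESS = 0.4

#: wild-type pill dimensions (um): 4 um end to end, radius 0.5 um.
PILL_LENGTH = 4.0
PILL_RADIUS = 0.5

#: default disc outline diameter (um) for the small flattened control shape.
DISC_DIAMETER = 3.0


@dataclass(frozen=True)
class IrregularOutlineSpec:
    """Smooth closed outline r(theta) = sum_k a_k cos(k theta), theta measured
    from the +y (long) axis.  Cosine-only series guarantee invariance under
    theta -> -theta (the single mirror, x -> -x); any nonzero odd harmonic
    breaks the y -> -y symmetry so exactly one in-plane mirror remains."""

    coefficients: tuple[float, ...]
    n_points: int = 720

    def radius(self, theta: np.ndarray) -> np.ndarray:
        r = np.zeros_like(theta)
        for k, a in enumerate(self.coefficients):
            r = r + a * np.cos(k * theta)
        return r

    def polygon(self) -> Polygon:
        theta = np.linspace(0, 2 * np.pi, self.n_points, endpoint=False)
        r = self.radius(theta)
        if np.any(r <= 0):
            raise ValueError("outline radius must stay positive")
        x = r * np.sin(theta)
        y = r * np.cos(theta)
        poly = Polygon(np.column_stack([x, y]))
        if not poly.is_valid:
            raise ValueError("outline is self-intersecting")
        return poly


#: Documented outline coefficients (um).  shapeA is a moderately elongated
#: blob ~4.8 x 2.8 um; shapeB is larger and more distorted, ~7.6 um long and
#: just over 5 um wide, consistent with experimental cells reaching widths
#: over 5 um.
IRREGULAR_OUTLINES = {
    "shapeA": IrregularOutlineSpec((1.85, 0.30, 0.55, 0.12)),
    "shapeB": IrregularOutlineSpec((3.10, 0.42, 0.62, 0.18, 0.06)),
}

SHAPE_NAMES = ("pill", "shapeA", "shapeB", "stadiumA", "stadiumB", "disc", "slab")


def make_outline(name: str) -> Polygon:
    """2D outline polygon for a flattened library shape."""
    if name in IRREGULAR_OUTLINES:
        return IRREGULAR_OUTLINES[name].polygon()
    if name == "disc":
        theta = np.linspace(0, 2 * np.pi, 360, endpoint=False)
        r = DISC_DIAMETER / 2
        return Polygon(np.column_stack([r * np.sin(theta), r * np.cos(theta)]))
    if name in ("stadiumA", "stadiumB"):
        ref = IRREGULAR_OUTLINES["shapeA" if name == "stadiumA" else "shapeB"]
        # matching needs the built reference; go through make_shape
        raise ValueError("stadium outlines depend on dx; use make_shape")
    raise KeyError(f"no outline for shape {name!r}")


def make_shape(name: str, dx: float = 0.05) -> CellGeometry:
    """Build a library geometry by name.

    pill: 4 um capsule of radius 0.5 um.  shapeA/shapeB: irregular flattened
    outlines at 0.4 um thickness.  stadiumA/stadiumB: stadium matched to the
    corresponding irregular shape.  disc: 3 um circular outline, flattened.
    slab: a wide square slab (8 x 8 um outline), flattened, mainly for
    stability cross-checks.
    """
    if name == "pill":
        return build_pill(PILL_LENGTH, PILL_RADIUS, dx)
    if name in ("shapeA", "shapeB", "disc"):
        return build_flattened(make_outline(name), FLATTENED_THICKNESS, dx)
    if name in ("stadiumA", "stadiumB"):
        ref = make_shape("shapeA" if name == "stadiumA" else "shapeB", dx)
        spec = match_stadium(ref, FLATTENED_THICKNESS)
        return spec.build()
    if name == "slab":
        half = 4.0
        sq = Polygon(
            [(-half, -half), (half, -half), (half, half), (-half, half)]
        )
        return build_flattened(sq, FLATTENED_THICKNESS, dx)
    raise KeyError(
        f"unknown shape {name!r}; known shapes: {', '.join(SHAPE_NAMES)}"
    )


def make_disc(diameter: float, dx: float = 0.05) -> CellGeometry:
    """Flattened disc with the given outline diameter (um)."""
    theta = np.linspace(0, 2 * np.pi, 360, endpoint=False)
    r = diameter / 2
    poly = Polygon(np.column_stack([r * np.sin(theta), r * np.cos(theta)]))
    return build_flattened(poly, FLATTENED_THICKNESS, dx)


# ---------------------------------------------------------------------------
# synthetic oscillation signals
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SyntheticSignalSpec:
    """Ground-truth parameters for a synthetic antiphase polar-count pair."""

    period: float = 58.0
    coherence_time: float = 306.0
    stride: float = 1.0
    duration: float = 5 * 58.0
    noise_sd: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.period <= 0 or self.stride <= 0:
            raise ValueError("period and stride must be positive")
        if self.coherence_time <= 0:
            raise ValueError("coherence time must be positive (use np.inf for none)")
        if self.duration < 5 * self.period:
            raise ValueError("duration must cover at least 5 periods")


def make_signal(spec: SyntheticSignalSpec) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Generate (times, n_top, n_bottom) from a phase-diffusing oscillator.

    The phase advances by omega*dt plus a Wiener increment of variance
    2*dt/tau_c per step, which makes E[cos(phi(t)) cos(phi(t+tau))] equal to
    (1/2) cos(2*pi*tau/T) exp(-tau/tau_c): the normalized top/bottom
    cross-correlation is then exactly the damped-cosine decoherence model.
    Additive Gaussian noise (sd ``noise_sd``) is applied independently to the
    two channels.
    """
    rng = np.random.default_rng(spec.seed)
    n = int(round(spec.duration / spec.stride)) + 1
    t = np.arange(n) * spec.stride
    omega = 2 * np.pi / spec.period
    dphi = omega * spec.stride + rng.normal(
        0.0, np.sqrt(2 * spec.stride / spec.coherence_time), n - 1
    )
    phi = np.concatenate([[rng.uniform(0, 2 * np.pi)], np.cumsum(dphi)])
    phi[1:] += phi[0]
    top = np.cos(phi) + rng.normal(0.0, spec.noise_sd, n)
    bottom = -np.cos(phi) + rng.normal(0.0, spec.noise_sd, n)
    return t, top, bottom
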