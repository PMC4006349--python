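"""Open-loop, image-driven speed terms G(phi, I) for region competition.

Two variants are provided:

* ``global_means`` — classic two-phase mean separation (Chan--Vese): the
  interior/exterior means of I are computed with regularized-Heaviside
  weights over the whole domain and the data speed at x is
  -(I - mu_in)^2 + (I - mu_out)^2 (interior-matching pixels expand).
* ``localized_means`` — localized region statistics: at each cell the means
  are taken over a Euclidean ball of radius ``r_loc``, and the residual
  competition is averaged over near-interface (delta-weighted) cells of the
  ball.  This handles images whose region statistics vary across space.

Both exclude the curvature term lambda*kappa(phi); the evolution loop adds
it.  The module also provides the energy functional whose gradient flow the
global model follows, and a state-independent speed bound used to size the
control-input threshold.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import fftconvolve

from .grid import LevelSetField, ScalarField
from .levelset import gradient, heaviside_eps

__all__ = [
    "RegionModel",
    "SpeedBound",
    "CollapsedSegmentationError",
    "region_means",
    "chan_vese_speed",
    "energy",
    "localized_speed",
    "speed_bound",
]


class CollapsedSegmentationError(ValueError):
    """Interior or exterior region has vanished (degenerate means)."""


@dataclass(frozen=True)
class SpeedBound:
    """Upper bounds |G| <= G_M(x) <= Gbar_M valid for any state phi."""

    pointwise: np.ndarray
    global_bound: float


@dataclass
class RegionModel:
    """Configuration of the open-loop speed provider.

    Parameters
    ----------
    kind : {"global_means", "localized_means"}
    r_loc : float
        Ball radius (physical units) for the localized variant; >= 2 cells.
    lambda_smooth : float
        Base curvature weight of the open-loop PDE.
    """

    kind: str = "global_means"
    r_loc: float = 8.0
    lambda_smooth: float = 0.1

    def __post_init__(self):
        if self.kind not in ("global_means", "localized_means"):
            raise ValueError(f"unknown region model kind: {self.kind!r}")
        if self.kind == "localized_means" and self.r_loc <= 0:
            raise ValueError("r_loc must be > 0 for localized_means")

    def speed(self, image: ScalarField, phi: LevelSetField) -> ScalarField:
        if self.kind == "global_means":
            return chan_vese_speed(image, phi)
        return localized_speed(image, phi, self.r_loc)

    def bound(self, image: ScalarField) -> SpeedBound:
        return speed_bound(self, image)


def region_means(image: ScalarField, phi: LevelSetField) -> tuple[float, float]:
    """Heaviside-weighted interior and exterior means of the image."""
    H = heaviside_eps(phi.values, phi.eps_phys)
    w_in = H.sum()
    w_out = (1.0 - H).sum()
    if w_in <= 0.0 or w_out <= 0.0:
        raise CollapsedSegmentationError(
            "degenerate segmentation: empty interior or exterior region"
        )
    mu_in = float((H * image.values).sum() / w_in)
    mu_out = float(((1.0 - H) * image.values).sum() / w_out)
    return mu_in, mu_out


def chan_vese_speed(image: ScalarField, phi: LevelSetField) -> ScalarField:
    """Global mean-separation data speed -(I - mu_in)^2 + (I - mu_out)^2."""
    mu_in, mu_out = region_means(image, phi)
    I = image.values
    return ScalarField(-((I - mu_in) ** 2) + (I - mu_out) ** 2, image.grid)


def energy(image: ScalarField, phi: LevelSetField, lambda_smooth: float) -> float:
    """Two-phase mean-separation energy with length penalty.

    E = 1/2 * int[ H (I-mu_in)^2 + (1-H)(I-mu_out)^2 ] dx
        + lambda * int |grad H(phi)| dx
    """
    H = heaviside_eps(phi.values, phi.eps_phys)
    mu_in, mu_out = region_means(image, phi)
    I = image.values
    data = 0.5 * (H * (I - mu_in) ** 2 + (1.0 - H) * (I - mu_out) ** 2).sum()
    g = gradient(H, phi.grid.spacing)
    length = np.sqrt(sum(gi * gi for gi in g)).sum()
    vol = phi.grid.cell_volume
    return float((data + lambda_smooth * length) * vol)


def _ball_footprint(grid, r_loc: float) -> np.ndarray:
    """Binary ball kernel of physical radius r_loc on the grid's spacing."""
    radii = [max(1, int(np.floor(r_loc / h))) for h in grid.spacing]
    axes = [np.arange(-n, n + 1) * h for n, h in zip(radii, grid.spacing)]
    mesh = np.meshgrid(*axes, indexing="ij")
    return (sum(m * m for m in mesh) <= r_loc**2).astype(np.float64)


def _local_sum(values: np.ndarray, kernel: np.ndarray) -> np.ndarray:
    return fftconvolve(values, kernel, mode="same")


def localized_speed(image: ScalarField, phi: LevelSetField, r_loc: float) -> ScalarField:
    """Localized mean-separation speed with ball-restricted statistics.

    At each cell x the interior/exterior means mu_in(x), mu_out(x) are
    Heaviside-weighted means of I over the Euclidean ball B(x, r_loc), and
    the speed is the pointwise competition

        G(x) = -(I(x) - mu_in(x))^2 + (I(x) - mu_out(x))^2,

    the same sign convention as the global model (interior-matching pixels
    expand).  The speed only ever acts through the delta_eps(phi) prefactor
    of the narrowband PDE, so it is consumed at near-interface cells only.
    As r_loc grows to the domain size the local means become the global
    ones and the speed reduces to :func:`chan_vese_speed`.  Cells whose
    ball has an empty interior or exterior contribute zero.
    """
    if r_loc < 2 * phi.grid.h_min:
        raise ValueError("r_loc must be at least two cells wide")
    kernel = _ball_footprint(phi.grid, r_loc)
    H = heaviside_eps(phi.values, phi.eps_phys)
    I = image.values
    tiny = 1e-12
    w_in = _local_sum(H, kernel)
    w_out = _local_sum(1.0 - H, kernel)
    mu_in = _local_sum(H * I, kernel) / np.maximum(w_in, tiny)
    mu_out = _local_sum((1.0 - H) * I, kernel) / np.maximum(w_out, tiny)
    speed = -((I - mu_in) ** 2) + (I - mu_out) ** 2
    speed[(w_in <= tiny) | (w_out <= tiny)] = 0.0
    return ScalarField(speed, image.grid)


def speed_bound(model: RegionModel, image: ScalarField) -> SpeedBound:
    """State-independent bound on |G|: the squared intensity range.

    Both variants compare I against means that lie inside the image range,
    so each squared residual — and hence their difference, and any weighted
    average of it — is bounded by (I_max - I_min)^2 pointwise, for every
    segmentation state.  A static bound keeps the derived input threshold
    U_M fixed before any user interaction starts.
    """
    rng = float(image.values.max() - image.values.min())
    bound = rng * rng
    return SpeedBound(np.full(image.grid.shape, bound), bound)
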