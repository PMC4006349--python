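"""User-input processing: discrete click votes to a smooth control field U.

A click is a signed vote at a cell: +1 where the user wants the region to
grow (reference inside, current labeling outside), -1 to shrink, 0 when the
labeling already agrees.  Votes are splatted onto the grid with a kernel
that combines Gaussian spatial proximity and intensity similarity, and the
accumulated field U is regulated by a nonlinear diffusion whose coefficient
switches on only when |U| approaches the saturation level U_M:

    dU/dt = h(x, t) + div[ H_eps_diff((U/U_M)^2 - 1) grad U ],  U(x, 0) = 0.

The divergence form with zero-flux boundaries conserves the total input
mass while capping peaks near U_M.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .grid import Grid, ScalarField
from .levelset import StabilityError, heaviside_eps

__all__ = [
    "ClickEvent",
    "InputField",
    "vote",
    "kernel_h0",
    "deposit",
    "diffuse_U",
    "diffusion_dt_limit",
    "read_clicks",
    "write_clicks",
]

EPS_DIFF_DEFAULT = 0.25  # half-width of the switch on the (U/U_M)^2 - 1 axis


@dataclass(frozen=True)
class ClickEvent:
    """One discrete user vote: cell index, time, and sign in {-1, 0, +1}."""

    location: tuple[int, ...]
    time: float
    sign: int

    def __post_init__(self):
        if self.sign not in (-1, 0, 1):
            raise ValueError(f"vote sign must be -1, 0, or +1, got {self.sign}")


@dataclass
class InputField:
    """Accumulated control field U with its saturation and kernel scales.

    sigma_x is the spatial kernel scale (physical length); sigma_I the
    intensity-similarity scale.  eps_diff is the dimensionless half-width of
    the regularized switch in the diffusion coefficient, so diffusion is
    exactly zero while |U| < U_M * sqrt(1 - eps_diff).
    """

    U: ScalarField
    U_M: float
    sigma_I: float
    sigma_x: float
    eps_diff: float = EPS_DIFF_DEFAULT

    @classmethod
    def zeros(cls, grid: Grid, U_M: float, sigma_I: float, sigma_x: float,
              eps_diff: float = EPS_DIFF_DEFAULT) -> "InputField":
        return cls(ScalarField(np.zeros(grid.shape), grid), U_M, sigma_I, sigma_x, eps_diff)

    @property
    def values(self) -> np.ndarray:
        return self.U.values

    def copy(self) -> "InputField":
        return InputField(self.U.copy(), self.U_M, self.sigma_I, self.sigma_x, self.eps_diff)


def vote(ref_sign: float, phi_sign: float) -> int:
    """The user's vote given the reference and current labels at a cell.

    +1 if the reference is inside but phi labels outside, -1 for the
    converse, 0 whenever the two agree (including either being exactly on
    the boundary).
    """
    if ref_sign > 0 and phi_sign < 0:
        return 1
    if ref_sign < 0 and phi_sign > 0:
        return -1
    return 0


def kernel_h0(x, x_k, image: ScalarField, sigma_I: float, sigma_x: float) -> float:
    """Click-splat weight combining spatial and intensity proximity.

    h0 = sigma_I^2 / (sigma_I^2 + |I(x) - I(x_k)|) * exp(-||x-x_k||^2 / (2 sigma_x^2))

    with the coordinate distance taken in physical units.  Equals 1 at the
    click itself and decays with both distance and intensity dissimilarity.
    """
    if sigma_I <= 0 or sigma_x <= 0:
        raise ValueError("sigma_I and sigma_x must be positive")
    x = tuple(int(i) for i in x)
    x_k = tuple(int(i) for i in x_k)
    spacing = np.asarray(image.grid.spacing)
    d2 = float(((np.asarray(x) - np.asarray(x_k)) * spacing) ** 2 @ np.ones(len(x)))
    dI = abs(float(image.values[x]) - float(image.values[x_k]))
    return (sigma_I**2 / (sigma_I**2 + dI)) * float(np.exp(-d2 / (2.0 * sigma_x**2)))


def deposit(U: InputField, event: ClickEvent, image: ScalarField,
            gain: float | None = None, truncate: float = 3.0) -> InputField:
    """Splat one signed click onto U over a truncated kernel footprint.

    The impulse in time is realized as an instantaneous additive update;
    ``gain`` scales the unit-peak kernel (default U_M / 5, so roughly five
    co-located clicks reach the saturating regime).  Zero votes deposit
    nothing.
    """
    grid = U.U.grid
    if not grid.contains_index(event.location):
        raise ValueError(f"click location {event.location} outside grid {grid.shape}")
    if event.sign == 0:
        return U
    if gain is None:
        gain = U.U_M / 5.0
    spacing = np.asarray(grid.spacing)
    center = np.asarray(event.location, dtype=int)
    radii = np.maximum(1, np.ceil(truncate * U.sigma_x / spacing).astype(int))
    lo = np.maximum(center - radii, 0)
    hi = np.minimum(center + radii + 1, np.asarray(grid.shape))
    window = tuple(slice(a, b) for a, b in zip(lo, hi))
    axes = [np.arange(a, b) for a, b in zip(lo, hi)]
    mesh = np.meshgrid(*axes, indexing="ij")
    d2 = sum(((m - c) * h) ** 2 for m, c, h in zip(mesh, center, spacing))
    spatial = np.exp(-d2 / (2.0 * U.sigma_x**2))
    I_w = image.values[window]
    I_k = image.values[tuple(center)]
    similarity = U.sigma_I**2 / (U.sigma_I**2 + np.abs(I_w - I_k))
    out = U.copy()
    out.values[window] += event.sign * gain * similarity * spatial
    return out


def _face_flux_divergence(U: np.ndarray, coeff: np.ndarray, spacing) -> np.ndarray:
    """div(coeff * grad U) with face-averaged coefficients, zero-flux edges."""
    div = np.zeros_like(U)
    for axis, h in enumerate(spacing):
        lo = [slice(None)] * U.ndim
        hi = [slice(None)] * U.ndim
        lo[axis] = slice(0, -1)
        hi[axis] = slice(1, None)
        lo, hi = tuple(lo), tuple(hi)
        face_c = 0.5 * (coeff[lo] + coeff[hi])
        flux = face_c * (U[hi] - U[lo]) / h  # flux across interior faces
        div[lo] += flux / h
        div[hi] -= flux / h
    return div


def diffusion_dt_limit(grid: Grid) -> float:
    """Explicit stability bound for a unit-coefficient diffusion step."""
    return 0.5 / sum(1.0 / h**2 for h in grid.spacing)


def diffuse_U(U: InputField, dt: float, eps: float | None = None) -> InputField:
    """One explicit step of the saturation-gated nonlinear diffusion of U.

    The coefficient H_eps_diff((U/U_M)^2 - 1) vanishes for small |U| (the
    field then only accumulates clicks), ramps on as |U| crosses U_M, and
    spreads excess input to its neighborhood, enforcing sup|U| ~ U_M.
    """
    if eps is None:
        eps = U.eps_diff
    grid = U.U.grid
    limit = diffusion_dt_limit(grid)
    if dt > limit * (1.0 + 1e-12):
        raise StabilityError(f"diffusion dt={dt:g} exceeds stability bound {limit:g}")
    vals = U.values
    arg = (vals / U.U_M) ** 2 - 1.0
    coeff = np.asarray(heaviside_eps(arg, eps))
    out = U.copy()
    out.values[...] = vals + dt * _face_flux_divergence(vals, coeff, grid.spacing)
    return out


def read_clicks(path) -> list[ClickEvent]:
    """Read a click stream from CSV with columns t, x0, x1[, x2], u."""
    events = []
    with open(path, newline="") as f:
        reader = csv.reader(f)
        header = next(reader)
        ncoord = len(header) - 2
        for row in reader:
            if not row:
                continue
            t = float(row[0])
            loc = tuple(int(v) for v in row[1:1 + ncoord])
            u = int(row[1 + ncoord])
            events.append(ClickEvent(loc, t, u))
    times = [e.time for e in events]
    if any(b < a for a, b in zip(times, times[1:])):
        raise ValueError("click stream times must be non-decreasing")
    return events


def write_clicks(path, events) -> None:
    path = Path(path)
    with open(path, "w", newline="") as f:
        writer = csv.writer(f)
        ndim = len(events[0].location) if events else 2
        writer.writerow(["t"] + [f"x{i}" for i in range(ndim)] + ["u"])
        for e in events:
            writer.writerow([repr(e.time)] + list(e.location) + [e.sign])
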