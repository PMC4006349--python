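"""Synthetic phantoms with ground truth, and a scripted simulated user.

The two-ellipse "ventricle" phantom is two bright ellipses joined by a thin
bright bridge on a darker background with additive Gaussian noise; the
ground-truth reference covers only the left ellipse.  A purely image-driven
region-competition run started inside the left ellipse leaks through the
bridge and segments the union — the failure mode the closed loop exists to
fix.  The gradient phantom places an elongated bright-offset shape on a
linear intensity ramp positioned so that the global interior/exterior means
coincide (global mean separation is blind) while local means still separate
the shape from its surroundings.

The simulated user inspects the segmentation at a fixed step interval and
clicks where the current labeling disagrees most with the ground truth,
emulating a human correcting the worst visible error.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .grid import Grid, LevelSetField, ScalarField
from .inputs import ClickEvent, vote
from .levelset import heaviside_eps, redistance

__all__ = [
    "PhantomSpec",
    "GradientPhantomSpec",
    "UserPolicy",
    "SimulatedUser",
    "make_phantom",
    "make_gradient_phantom",
    "circle_seed",
    "ellipse_level_set",
]


@dataclass(frozen=True)
class PhantomSpec:
    """Geometry and appearance of the two-ellipse phantom (2-D)."""

    shape: tuple[int, int] = (128, 128)
    left_center: tuple[float, float] = (64.0, 38.0)
    left_axes: tuple[float, float] = (24.0, 17.0)
    left_angle: float = 0.0
    right_center: tuple[float, float] = (64.0, 95.0)
    right_axes: tuple[float, float] = (21.0, 15.0)
    right_angle: float = 0.0
    bridge_width: float = 3.0
    background: float = 2.0
    foreground: float = 10.0
    noise_sigma: float = 0.5
    eps: float = 1.5
    seed: int = 0

    def __post_init__(self):
        if self.background == self.foreground:
            raise ValueError("foreground and background intensities must differ")
        for c, a in ((self.left_center, self.left_axes),
                     (self.right_center, self.right_axes)):
            for ci, ai, n in zip(c, a, self.shape):
                if ci - ai < 1 or ci + ai > n - 2:
                    raise ValueError("ellipse exceeds the image bounds")
        if self.bridge_width <= 0:
            raise ValueError("bridge width must be positive")


def _ellipse_implicit(grid: Grid, center, axes, angle: float) -> np.ndarray:
    """Implicit function positive inside the (rotated) ellipse, zero on it."""
    rr, cc = grid.coordinate_arrays()
    dr = rr - center[0] * grid.spacing[0]
    dc = cc - center[1] * grid.spacing[1]
    ca, sa = np.cos(angle), np.sin(angle)
    u = ca * dr + sa * dc
    v = -sa * dr + ca * dc
    return 1.0 - np.sqrt((u / axes[0]) ** 2 + (v / axes[1]) ** 2 + 1e-300)


def ellipse_level_set(grid: Grid, center, axes, angle: float = 0.0,
                      eps: float = 1.5) -> LevelSetField:
    """Signed distance to an ellipse boundary, positive inside."""
    implicit = _ellipse_implicit(grid, center, axes, angle)
    # scale toward distance units before redistancing (zero set is exact)
    return redistance(LevelSetField(implicit * min(axes), grid, eps))


def circle_seed(grid: Grid, center, radius: float, eps: float = 1.5) -> LevelSetField:
    """Signed distance of a circle/sphere seed, positive inside."""
    coords = grid.coordinate_arrays()
    d = np.sqrt(sum((c - ci * h) ** 2 for c, ci, h in
                    zip(coords, center, grid.spacing)))
    return LevelSetField(radius - d, grid, eps)


def make_phantom(spec: PhantomSpec = PhantomSpec()) -> tuple[ScalarField, LevelSetField]:
    """Two-ellipse phantom image and its left-ellipse-only reference psi."""
    grid = Grid(spec.shape)
    left = _ellipse_implicit(grid, spec.left_center, spec.left_axes, spec.left_angle)
    right = _ellipse_implicit(grid, spec.right_center, spec.right_axes, spec.right_angle)

    rr, cc = grid.coordinate_arrays()
    r0 = spec.left_center[0] * grid.spacing[0]
    r1 = spec.right_center[0] * grid.spacing[0]
    c0 = spec.left_center[1] * grid.spacing[1]
    c1 = spec.right_center[1] * grid.spacing[1]
    # thin bright bridge along the segment joining the two centers
    span = np.clip((cc - c0) / (c1 - c0), 0.0, 1.0)
    center_row = r0 + span * (r1 - r0)
    bridge = (np.abs(rr - center_row) <= spec.bridge_width / 2.0) & \
             (cc >= c0) & (cc <= c1)

    fg_mask = (left > 0) | (right > 0) | bridge
    image = np.where(fg_mask, spec.foreground, spec.background).astype(np.float64)
    rng = np.random.default_rng(spec.seed)
    if spec.noise_sigma > 0:
        image = image + rng.normal(0.0, spec.noise_sigma, size=image.shape)

    psi = ellipse_level_set(grid, spec.left_center, spec.left_axes,
                            spec.left_angle, spec.eps)
    return ScalarField(image, grid), psi


@dataclass(frozen=True)
class GradientPhantomSpec:
    """Elongated shape on a linear intensity ramp (global means coincide)."""

    shape: tuple[int, int] = (128, 128)
    axes: tuple[float, float] = (9.0, 30.0)
    center_row: float = 64.0
    ramp_range: tuple[float, float] = (0.0, 10.0)
    offset: float = 2.0         # shape brightness above its local background
    noise_sigma: float = 0.2
    eps: float = 1.5
    seed: int = 0

    def __post_init__(self):
        if self.offset <= 0:
            raise ValueError("shape offset must be positive")
        if self.axes[1] * 2 + 4 >= self.shape[1]:
            raise ValueError("shape too long for the image")


def make_gradient_phantom(
        spec: GradientPhantomSpec = GradientPhantomSpec()
) -> tuple[ScalarField, LevelSetField]:
    """Gradient phantom: ramp background + locally-brighter elongated shape.

    The shape's column position is chosen (by a deterministic scan at
    generation time) so the ground-truth interior and exterior means of the
    final image agree to within a few percent of the intensity range; global
    mean competition then has no discriminative power while the shape stays
    ``offset`` brighter than its local surroundings everywhere.
    """
    grid = Grid(spec.shape)
    rr, cc = grid.coordinate_arrays()
    lo, hi = spec.ramp_range
    ramp = lo + (hi - lo) * cc / (spec.shape[1] - 1)

    # place the shape so the interior mean sits a fixed, small amount above
    # the exterior mean (2% of the ramp range): global competition is then
    # blind, but its residual sign is deterministic against the noise
    target = 0.02 * (hi - lo)
    best = None
    margin = spec.axes[1] + 3
    for c0 in np.arange(margin, spec.shape[1] - margin, 0.5):
        inside = ((rr - spec.center_row) / spec.axes[0]) ** 2 + \
                 ((cc - c0) / spec.axes[1]) ** 2 <= 1.0
        image = ramp + np.where(inside, spec.offset, 0.0)
        gap = image[inside].mean() - image[~inside].mean()
        score = abs(gap - target)
        if best is None or score < best[0]:
            best = (score, float(c0))
    _, c0 = best

    inside = ((rr - spec.center_row) / spec.axes[0]) ** 2 + \
             ((cc - c0) / spec.axes[1]) ** 2 <= 1.0
    image = ramp + np.where(inside, spec.offset, 0.0)
    rng = np.random.default_rng(spec.seed)
    if spec.noise_sigma > 0:
        image = image + rng.normal(0.0, spec.noise_sigma, size=image.shape)

    psi = ellipse_level_set(grid, (spec.center_row, c0), spec.axes, 0.0, spec.eps)
    return ScalarField(image, grid), psi


@dataclass(frozen=True)
class UserPolicy:
    """How the scripted user inspects and corrects the segmentation."""

    inspection_interval: int = 10    # steps between looks at the display
    clicks_per_inspection: int = 4
    stop_threshold: float = 0.85     # no clicks once max |xi| falls below
    max_total_clicks: int = 400
    warmup_steps: int = 30           # watch the automatic phase before acting
    strategy: str = "corrective"     # or "worst_error" / "random_error"
    seed: int = 0

    def __post_init__(self):
        if self.inspection_interval < 1:
            raise ValueError("inspection interval must be >= 1")
        if self.warmup_steps < 0:
            raise ValueError("warmup must be >= 0")
        if self.strategy not in ("corrective", "worst_error", "random_error"):
            raise ValueError(f"unknown user strategy {self.strategy!r}")


class SimulatedUser:
    """Scripted user that votes at the largest current labeling errors.

    At each inspection the pointwise error xi = H_eps(phi) - H_eps(psi) is
    computed against the ground truth the user has in mind; up to
    ``clicks_per_inspection`` cells maximizing |xi| (ties broken by
    lexicographic cell index) receive votes via the standard rule.  The
    user first watches the automatic evolution for ``warmup_steps`` before
    intervening — input is a correction to what the automatic system gets
    wrong, not a tracing of the whole boundary.  Nothing is emitted once
    max |xi| drops below the stop threshold or the click budget is
    exhausted.  Deterministic for a fixed seed and fields.
    """

    def __init__(self, psi: LevelSetField, policy: UserPolicy = UserPolicy()):
        self.psi = psi
        self.policy = policy
        self.clicks_sent = 0
        self.events: list[ClickEvent] = []   # full log of emitted clicks
        self._rng = np.random.default_rng(policy.seed)
        self._prev_under = np.inf            # under-segmented count last look

    def __call__(self, phi: LevelSetField, t: float, step: int) -> list[ClickEvent]:
        pol = self.policy
        if step < pol.warmup_steps or step % pol.inspection_interval != 0:
            return []
        if self.clicks_sent >= pol.max_total_clicks:
            return []
        return self.inspect(phi, t)

    def inspect(self, phi: LevelSetField, t: float) -> list[ClickEvent]:
        pol = self.policy
        xi = heaviside_eps(phi.values, phi.eps_phys) - \
            heaviside_eps(self.psi.values, self.psi.eps_phys)
        abs_xi = np.abs(xi)
        if abs_xi.max() < pol.stop_threshold:
            self._prev_under = 0
            return []
        budget = min(pol.clicks_per_inspection,
                     pol.max_total_clicks - self.clicks_sent)
        candidates = np.flatnonzero(abs_xi.ravel() >= pol.stop_threshold)
        if pol.strategy == "corrective":
            # react at once to over-segmentation (the contour creeping past
            # the intended boundary), but leave under-segmentation to the
            # automatic evolution unless it has stopped shrinking
            flat = xi.ravel()
            over = np.flatnonzero(flat >= pol.stop_threshold)
            under = np.flatnonzero(flat <= -pol.stop_threshold)
            stalled = under.size >= self._prev_under * 0.99
            self._prev_under = under.size
            if over.size:
                pool = over
            elif under.size and stalled:
                pool = under
            else:
                return []
            order = np.argsort(-abs_xi.ravel()[pool], kind="stable")
            chosen = pool[order[:budget]]
        elif pol.strategy == "worst_error":
            # stable sort on -|xi| keeps lexicographic (C-order) tie-break
            order = np.argsort(-abs_xi.ravel()[candidates], kind="stable")
            chosen = candidates[order[:budget]]
        else:
            k = min(budget, candidates.size)
            chosen = self._rng.choice(candidates, size=k, replace=False)
        events = []
        for flat in chosen:
            loc = tuple(int(i) for i in np.unravel_index(int(flat), phi.grid.shape))
            u = vote(self.psi.values[loc], phi.values[loc])
            if u != 0:
                events.append(ClickEvent(loc, t, u))
        self.clicks_sent += len(events)
        self.events.extend(events)
        return events
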