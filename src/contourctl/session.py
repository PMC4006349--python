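"""Coupled phi / psi_hat / U evolution loop with interleaved click ingestion.

One explicit step of the closed loop does, in order: ingest due clicks into
U, diffuse U, advance the observer psi_hat, assemble the closed-loop speed
(data term, -xi_hat U^2 forcing, adaptive error-aligned smoothing), and
advance phi — so a click becomes visible to phi within the same step.  Both
level-set fields are re-distanced on a fixed schedule.  The loop terminates
at steady state (labeling activity quiescent and no pending input) or after
``max_steps``.  Every run is deterministic given config, seed, and click
stream.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .control import (ControlConfig, adaptive_lambda, closed_loop_speed,
                      label_error)
from .grid import LevelSetField, ScalarField
from .inputs import (ClickEvent, InputField, deposit, diffuse_U,
                     diffusion_dt_limit)
from .levelset import (DegenerateLevelSetError, curvature_array, delta_eps,
                       evolve_step, heaviside_eps, redistance)
from .observer import (ObserverState, lyapunov_functionals, observer_errors,
                       observer_step)
from .region import RegionModel, energy

__all__ = [
    "SessionConfig",
    "DiagnosticsRecord",
    "SessionResult",
    "SessionAborted",
    "run_session",
    "run_open_loop",
    "run_known_reference",
    "effort_metrics",
]


class SessionAborted(RuntimeError):
    """The evolution collapsed; carries the diagnostics recorded so far."""

    def __init__(self, message: str, diagnostics: "DiagnosticsRecord"):
        super().__init__(message)
        self.diagnostics = diagnostics


@dataclass
class SessionConfig:
    """Aggregated run configuration for the coupled loop."""

    model: RegionModel = field(default_factory=RegionModel)
    control: ControlConfig | None = None     # None: derive U_M, alpha from image
    lambda0: float = 1.0                     # gains used when control is None
    lambda1: float = 0.1
    rho: float = 0.5
    mode: str = "closed_loop"                # or "open_loop"
    cfl: float = 0.45
    dt_max: float = 0.2
    redist_every: int = 5
    max_steps: int = 2000
    steady_tol: float = 2e-4
    steady_window: int = 50
    sigma_x: float = 2.0                     # click kernel spatial scale
    sigma_I: float | None = None             # None: sigma_I^2 = half image range
    click_gain: float | None = None          # None: U_M / 5
    seed: int = 0

    def __post_init__(self):
        if self.mode not in ("closed_loop", "open_loop"):
            raise ValueError(f"unknown session mode {self.mode!r}")
        for name in ("cfl", "dt_max", "steady_tol"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.redist_every < 1 or self.steady_window < 1 or self.max_steps < 1:
            raise ValueError("redist_every, steady_window, max_steps must be >= 1")


@dataclass
class DiagnosticsRecord:
    """Per-step time series of the run's functionals and effort counters."""

    t: list = field(default_factory=list)
    D: list = field(default_factory=list)            # vs. ground truth, if given
    D_hat: list = field(default_factory=list)
    F: list = field(default_factory=list)
    V: list = field(default_factory=list)
    E: list = field(default_factory=list)
    lam: list = field(default_factory=list)
    actuated: list = field(default_factory=list)     # cumulative distinct cells
    reclassified: list = field(default_factory=list)  # cumulative over rounds
    rounds: list = field(default_factory=list)       # (step, newly_actuated, reclassified)
    descent_ok: list = field(default_factory=list)   # known-reference runs only
    steady_step: int | None = None

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame({
            "t": self.t, "D": self.D, "D_hat": self.D_hat, "F": self.F,
            "V": self.V, "E": self.E, "lambda": self.lam,
            "actuated": self.actuated, "reclassified": self.reclassified,
        })

    @property
    def n_steps(self) -> int:
        return len(self.t)


@dataclass
class SessionResult:
    phi: LevelSetField
    psi_hat: LevelSetField | None
    U: InputField | None
    diagnostics: DiagnosticsRecord
    resolved: dict


def _window_drift_ok(hist: list, w: int, rtol: float, scale_floor: float) -> bool:
    """True when the mean over the last window matches the window before it.

    The explicit scheme settles into a small limit cycle (locked to the
    redistancing schedule and noise flicker) rather than a fixed point, so
    steadiness is judged by the drift of windowed means, which vanishes on
    a cycle but not during creep.
    """
    if len(hist) < 2 * w:
        return False
    m1 = float(np.mean(hist[-w:]))
    m2 = float(np.mean(hist[-2 * w:-w]))
    return abs(m1 - m2) <= rtol * max(abs(m2), scale_floor)


def _auto_sigma_I(image: ScalarField) -> float:
    rng = float(image.values.max() - image.values.min())
    return float(np.sqrt(max(rng, 1e-12) / 2.0))


def _unit_range(image: ScalarField) -> ScalarField:
    """Rescale intensities to [0, 1].

    All session dynamics run on unit-range intensities so that the image
    force (|G| <= 1), the control forcing (U^2 ~ U_M^2 = 1/rho + 1) and the
    observer drive (|xi_hat - e_U (alpha U)^2| ~ 1) evolve on commensurate
    time scales; the raw intensity scale would otherwise make the
    segmentation arbitrarily faster or slower than the estimator that is
    supposed to track it.
    """
    lo = float(image.values.min())
    rng = float(image.values.max()) - lo
    if rng <= 0:
        return ScalarField(np.zeros(image.grid.shape), image.grid)
    return ScalarField((image.values - lo) / rng, image.grid)


def run_session(image: ScalarField, phi0: LevelSetField,
                cfg: SessionConfig | None = None,
                clicks=None, user=None,
                reference: LevelSetField | None = None,
                initial_U: InputField | None = None,
                initial_psi_hat: LevelSetField | None = None) -> SessionResult:
    """Run the interactive closed loop (or the open loop, per cfg.mode).

    Parameters
    ----------
    clicks : sequence of ClickEvent, optional
        Pre-recorded stream sorted by time; events with time <= current t
        are ingested at the start of each step.
    user : callable, optional
        Simulated user ``user(phi, t, step) -> list[ClickEvent]``; called
        every step, typically emitting clicks only at inspection steps.
    reference : LevelSetField, optional
        Ground truth psi for diagnostics only; never used in the dynamics.
    initial_U, initial_psi_hat : optional
        Resume a session from a previous result's accumulated input field
        and observer state instead of the cold-start U = 0, psi_hat = phi0.
    """
    cfg = cfg or SessionConfig()
    if cfg.mode == "open_loop":
        return run_open_loop(image, phi0, cfg, reference=reference)

    grid = image.grid
    model = cfg.model
    work = _unit_range(image)
    bound = model.bound(work)
    control = cfg.control or ControlConfig.from_bound(
        bound, rho=cfg.rho, lambda0=cfg.lambda0, lambda1=cfg.lambda1, eps=phi0.eps)
    sigma_I = cfg.sigma_I if cfg.sigma_I is not None else _auto_sigma_I(work)
    gain = cfg.click_gain if cfg.click_gain is not None else control.U_M / 5.0
    resolved = {"U_M": control.U_M, "alpha": control.alpha, "rho": control.rho,
                "lambda0": control.lambda0, "lambda1": control.lambda1,
                "sigma_I": sigma_I, "sigma_x": cfg.sigma_x, "click_gain": gain,
                "mode": cfg.mode, "seed": cfg.seed}

    phi = redistance(phi0)
    U = initial_U.copy() if initial_U is not None else \
        InputField.zeros(grid, control.U_M, sigma_I, cfg.sigma_x)
    obs = ObserverState.from_phi(phi, U)
    if initial_psi_hat is not None:
        psi_hat0 = redistance(initial_psi_hat)
        obs = ObserverState(psi_hat0, *observer_errors(phi, psi_hat0, U))

    stream = sorted(clicks, key=lambda e: e.time) if clicks else []
    stream_idx = 0
    actuated: set = set()
    sign_at_round = np.sign(phi.values)
    reclassified_total = 0

    diag = DiagnosticsRecord()
    t = 0.0
    vol_hist: list[float] = []
    dhat_hist: list[float] = []
    last_event_step = -1
    dt_diff = 0.9 * diffusion_dt_limit(grid)

    for step in range(cfg.max_steps):
        # --- ingest due clicks -------------------------------------------
        events = []
        while stream_idx < len(stream) and stream[stream_idx].time <= t:
            events.append(stream[stream_idx])
            stream_idx += 1
        if user is not None:
            events.extend(user(phi, t, step))
        if events:
            new_cells = 0
            for e in events:
                if e.sign != 0:
                    U = deposit(U, e, work, gain=gain)
                    if e.location not in actuated:
                        actuated.add(e.location)
                        new_cells += 1
            flips = int((np.sign(phi.values) != sign_at_round).sum())
            sign_at_round = np.sign(phi.values)
            reclassified_total += flips
            diag.rounds.append((step, new_cells, flips))

        # --- assemble both speeds from one set of error fields -----------
        xi_hat, e_U = observer_errors(phi, obs.psi_hat, U)
        obs = ObserverState(obs.psi_hat, xi_hat, e_U)
        G = model.speed(work, phi)
        _, D_hat_pre, _ = lyapunov_functionals(obs, U, control.alpha)
        lam = adaptive_lambda(control, D_hat_pre)
        speed = closed_loop_speed(G, xi_hat, U.values, phi, lam)
        drive = xi_hat.values - e_U.values * (control.alpha * U.values) ** 2

        rate_phi = np.abs(delta_eps(phi.values, phi.eps_phys) * speed.values).max()
        rate_psi = np.abs(delta_eps(obs.psi_hat.values, obs.psi_hat.eps_phys) * drive).max()
        rate = max(rate_phi, rate_psi, 1e-12)
        dt = min(cfg.cfl * grid.h_min / rate, cfg.dt_max, dt_diff)

        # --- advance U, observer, phi ------------------------------------
        U = diffuse_U(U, dt)
        psi_hat = evolve_step(obs.psi_hat, drive, dt, check_stability=False)
        phi = evolve_step(phi, speed, dt, check_stability=False)
        obs = ObserverState(psi_hat, xi_hat, e_U)
        t += dt

        if (step + 1) % cfg.redist_every == 0:
            try:
                phi = redistance(phi)
                obs.psi_hat = redistance(obs.psi_hat)
            except DegenerateLevelSetError as err:
                raise SessionAborted(
                    f"segmentation collapsed at step {step}: {err}", diag
                ) from err

        # --- diagnostics (errors refreshed after the moves) ---------------
        xi_hat, e_U = observer_errors(phi, obs.psi_hat, U)
        obs = ObserverState(obs.psi_hat, xi_hat, e_U)
        F, D_hat, V = lyapunov_functionals(obs, U, control.alpha)
        D = label_error(phi, reference).D if reference is not None else np.nan
        E = _safe_energy(work, phi, model.lambda_smooth)
        diag.t.append(t)
        diag.D.append(D)
        diag.D_hat.append(D_hat)
        diag.F.append(F)
        diag.V.append(V)
        diag.E.append(E)
        diag.lam.append(lam)
        diag.actuated.append(len(actuated))
        diag.reclassified.append(reclassified_total)

        # --- steady-state detection --------------------------------------
        # the discrete system settles into a small limit cycle (locked to
        # the redistancing schedule and noise flicker), not a fixed point:
        # declare steady when the interior volume and D_hat have stayed
        # within a narrow relative band over a full window with no input
        H_cur = heaviside_eps(phi.values, phi.eps_phys)
        vol = float(H_cur.sum()) * grid.cell_volume
        vol_hist.append(vol)
        dhat_hist.append(D_hat)
        if events:
            last_event_step = step
        pending = stream_idx < len(stream)
        w = cfg.steady_window
        if not pending and step - last_event_step >= 2 * w and \
                _window_drift_ok(vol_hist, w, cfg.steady_tol, 1e-12) and \
                _window_drift_ok(dhat_hist, w, 10 * cfg.steady_tol, 1.0):
            diag.steady_step = step
            break

    return SessionResult(phi, obs.psi_hat, U, diag, resolved)


def run_open_loop(image: ScalarField, phi0: LevelSetField,
                  cfg: SessionConfig | None = None,
                  reference: LevelSetField | None = None) -> SessionResult:
    """Purely image-driven evolution: phi_t = delta * [G + lambda kappa(phi)]."""
    cfg = cfg or SessionConfig(mode="open_loop")
    grid = image.grid
    model = cfg.model
    work = _unit_range(image)
    phi = redistance(phi0)
    diag = DiagnosticsRecord()
    t = 0.0
    vol_hist: list[float] = []

    for step in range(cfg.max_steps):
        G = model.speed(work, phi)
        kappa = curvature_array(phi.values, grid.spacing)
        speed = ScalarField(G.values + model.lambda_smooth * kappa, grid)

        rate = max(np.abs(delta_eps(phi.values, phi.eps_phys) * speed.values).max(), 1e-12)
        dt = min(cfg.cfl * grid.h_min / rate, cfg.dt_max)
        phi = evolve_step(phi, speed, dt, check_stability=False)
        t += dt

        if (step + 1) % cfg.redist_every == 0:
            try:
                phi = redistance(phi)
            except DegenerateLevelSetError as err:
                raise SessionAborted(
                    f"segmentation collapsed at step {step}: {err}", diag
                ) from err

        D = label_error(phi, reference).D if reference is not None else np.nan
        E = _safe_energy(work, phi, model.lambda_smooth)
        diag.t.append(t)
        diag.D.append(D)
        diag.D_hat.append(np.nan)
        diag.F.append(np.nan)
        diag.V.append(np.nan)
        diag.E.append(E)
        diag.lam.append(model.lambda_smooth)
        diag.actuated.append(0)
        diag.reclassified.append(0)

        H_cur = heaviside_eps(phi.values, phi.eps_phys)
        vol = float(H_cur.sum()) * grid.cell_volume
        vol_hist.append(vol)
        if _window_drift_ok(vol_hist, cfg.steady_window, cfg.steady_tol, 1e-12):
            diag.steady_step = step
            break

    return SessionResult(phi, None, None, diag, {"mode": "open_loop"})


def run_known_reference(image: ScalarField, phi0: LevelSetField,
                        psi: LevelSetField, cfg: SessionConfig | None = None,
                        n_steps: int = 2000) -> SessionResult:
    """Regulate phi toward a *known* reference psi with a saturated input.

    The idealized configuration of the stability analysis: the labeling
    error xi is computed against psi directly, the input is held at the
    threshold magnitude U = U_M everywhere, and the smoothing gain is
    lambda(t) = lambda0 + lambda1 * D.  Records per-step D and whether the
    error-dominance (descent) condition held, so monotone decrease of D can
    be audited wherever the condition was satisfied.
    """
    from .control import descent_condition

    cfg = cfg or SessionConfig()
    grid = image.grid
    model = cfg.model
    work = _unit_range(image)
    bound = model.bound(work)
    control = cfg.control or ControlConfig.from_bound(
        bound, rho=cfg.rho, lambda0=cfg.lambda0, lambda1=cfg.lambda1, eps=phi0.eps)
    phi = redistance(phi0)
    U_sat = np.full(grid.shape, control.U_M)
    diag = DiagnosticsRecord()
    t = 0.0

    for step in range(n_steps):
        err = label_error(phi, psi)
        lam = adaptive_lambda(control, err.D)
        G = model.speed(work, phi)
        speed = closed_loop_speed(G, err.xi, U_sat, phi, lam)
        rate = max(np.abs(delta_eps(phi.values, phi.eps_phys) * speed.values).max(), 1e-12)
        dt = min(cfg.cfl * grid.h_min / rate, cfg.dt_max)
        phi = evolve_step(phi, speed, dt, check_stability=False)
        t += dt
        if (step + 1) % cfg.redist_every == 0:
            phi = redistance(phi)
        post = label_error(phi, psi)
        diag.t.append(t)
        diag.D.append(post.D)
        diag.D_hat.append(np.nan)
        diag.F.append(np.nan)
        diag.V.append(np.nan)
        diag.E.append(_safe_energy(work, phi, model.lambda_smooth))
        diag.lam.append(lam)
        diag.actuated.append(0)
        diag.reclassified.append(0)
        diag.descent_ok.append(descent_condition(phi, err.xi, control.rho))

    return SessionResult(phi, None, None, diag,
                         {"mode": "known_reference", "U_M": control.U_M})


def _safe_energy(image, phi, lam) -> float:
    try:
        return energy(image, phi, lam)
    except Exception:
        return np.nan


def effort_metrics(diag: DiagnosticsRecord,
                   reference_boundary_cells: int | None = None) -> dict:
    """Interaction-effort summary from a run's diagnostics.

    Returns the total number of actuated cells (distinct cells the user
    clicked), the per-round (newly actuated, reclassified) pairs used for
    dynamic-response regression, and — when the reference boundary size is
    supplied — the actuated count as a percentage of a fully manual tracing.
    """
    total_actuated = diag.actuated[-1] if diag.actuated else 0
    out = {
        "total_actuated": int(total_actuated),
        "total_reclassified": int(diag.reclassified[-1]) if diag.reclassified else 0,
        "rounds": [(int(a), int(r)) for _, a, r in diag.rounds],
        "n_rounds": len(diag.rounds),
    }
    if reference_boundary_cells:
        out["actuated_pct_of_boundary"] = 100.0 * total_actuated / reference_boundary_cells
    return out
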