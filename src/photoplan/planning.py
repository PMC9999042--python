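"""Constrained treatment planning: choose (tau, I0) to hit a desired kill rate.

The planning criterion is the squared deviation of the predicted death rate
from the desired one,

    loss(tau, I0) = (D_desired - D(tau, I0))^2,   tau <= tau_max, I0 <= I0_max,

minimised over a regular lattice (deterministic, auditable) with an optional
continuous local refinement.  Ties are broken lexicographically, preferring
smaller tau then smaller I0 — a stand-in for the latency and safety costs
the reduced criterion drops.  Constraints are closed (<=): the reference
training grid itself uses the boundary settings (8 min, 30 mW/cm^2).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize

from .surfaces import ResponseSurface


@dataclass(frozen=True)
class PlanningProblem:
    """A dose-planning instance.

    ``grid_step`` is (delta_tau, delta_I0); the lattice runs from
    ``tau_min``/``intensity_min`` (default: one step, keeping doses strictly
    positive) to the constraint maxima inclusive.
    """

    surface: ResponseSurface
    d_desired: float
    tau_max: float
    intensity_max: float
    grid_step: tuple[float, float] = (0.1, 0.5)
    tau_min: float | None = None
    intensity_min: float | None = None

    def __post_init__(self) -> None:
        if not 0.0 <= self.d_desired <= 1.0:
            raise ValueError("d_desired must be in [0, 1]")
        if self.tau_max <= 0 or self.intensity_max <= 0:
            raise ValueError("constraint maxima must be > 0")
        if self.grid_step[0] <= 0 or self.grid_step[1] <= 0:
            raise ValueError("grid steps must be > 0")

    def lattice(self) -> tuple[np.ndarray, np.ndarray]:
        """(tau values, intensity values) of the feasible lattice."""
        dt, di = self.grid_step
        t0 = self.tau_min if self.tau_min is not None else dt
        i0 = self.intensity_min if self.intensity_min is not None else di
        taus = np.arange(t0, self.tau_max + 1e-9, dt)
        i0s = np.arange(i0, self.intensity_max + 1e-9, di)
        if taus.size == 0 or i0s.size == 0:
            raise ValueError("empty feasible lattice")
        return taus, i0s


@dataclass(frozen=True)
class PlanResult:
    """Solution of a planning problem."""

    tau_hat: float
    intensity_hat: float
    achieved_d: float
    loss: float
    on_tau_boundary: bool
    on_intensity_boundary: bool
    converged: bool = True


def _result(p: PlanningProblem, tau: float, i0: float, converged: bool = True) -> PlanResult:
    d = float(p.surface.predict(tau, i0))
    return PlanResult(
        tau_hat=float(tau),
        intensity_hat=float(i0),
        achieved_d=d,
        loss=(p.d_desired - d) ** 2,
        on_tau_boundary=bool(abs(tau - p.tau_max) < 1e-9),
        on_intensity_boundary=bool(abs(i0 - p.intensity_max) < 1e-9),
        converged=converged,
    )


def solve_grid(p: PlanningProblem) -> PlanResult:
    """Exhaustive lattice minimisation of the planning loss.

    Returns the lattice point of minimal loss; exact ties resolve to the
    smallest tau, then the smallest intensity.
    """
    taus, i0s = p.lattice()
    tt, ii = np.meshgrid(taus, i0s, indexing="ij")
    d = np.asarray(p.surface.predict(tt.ravel(), ii.ravel()))
    loss = (p.d_desired - d) ** 2
    best = loss.min()
    tie = np.flatnonzero(loss == best)
    # lattice is enumerated tau-major then intensity, so the first tied index
    # already realises the (smaller tau, then smaller intensity) preference
    idx = tie[0]
    return _result(p, tt.ravel()[idx], ii.ravel()[idx])


def solve_refined(p: PlanningProblem) -> PlanResult:
    """Continuous local refinement seeded at the lattice solution.

    Runs bound-constrained L-BFGS-B from the grid optimum; returns whichever
    of the two solutions has the smaller loss, so refinement never degrades
    the plan.  A failed/non-improving refinement returns the grid solution
    with ``converged=False`` only when the optimizer itself reported failure.
    """
    grid_sol = solve_grid(p)
    taus, i0s = p.lattice()
    bounds = [(float(taus[0]), float(taus[-1])), (float(i0s[0]), float(i0s[-1]))]

    def objective(x: np.ndarray) -> float:
        return (p.d_desired - float(p.surface.predict(x[0], x[1]))) ** 2

    res = minimize(
        objective,
        x0=np.array([grid_sol.tau_hat, grid_sol.intensity_hat]),
        method="L-BFGS-B",
        bounds=bounds,
    )
    refined = _result(p, float(res.x[0]), float(res.x[1]), converged=bool(res.success))
    if refined.loss <= grid_sol.loss:
        return refined
    return PlanResult(**{**grid_sol.__dict__, "converged": bool(res.success)})


def loss_landscape(p: PlanningProblem) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Full loss lattice for diagnostics.

    Returns ``(taus, intensities, loss)`` with ``loss[i, j]`` the squared
    deviation at ``(taus[i], intensities[j])``; its minimum equals the
    :func:`solve_grid` loss.
    """
    taus, i0s = p.lattice()
    tt, ii = np.meshgrid(taus, i0s, indexing="ij")
    d = np.asarray(p.surface.predict(tt.ravel(), ii.ravel())).reshape(tt.shape)
    return taus, i0s, (p.d_desired - d) ** 2
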