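"""Numerical integration of the chemostat consumer-resource dynamics.

Species abundances evolve as

    dn_i/dt = n_i ( sum_mu R_i,mu s_mu / sum_k n_k R_k,mu - (d + d_i) ),

integrated with an explicit adaptive Runge-Kutta method.  Species whose
abundance crosses below the extinction threshold (1e-7 in dimensionless
units) are clamped to zero and removed from subsequent competition
(extinction is absorbing within a run).  A run has reached steady state when
every species either satisfies |d^2 ln n_i / dt^2| < 1e-6 or is below the
extinction threshold; a species counts toward richness when n_i > 1e-7 and
d ln n_i / dt > -1e-3 at steady state.

The direct geometric solver (:mod:`rescomp.geometry`) computes the same
steady states in closed form; this module is the dynamical route, used for
trajectories and as the independent cross-check of the geometry.
"""

from __future__ import annotations

import numpy as np
from scipy.integrate import solve_ivp
from scipy.optimize import root

from .community import Community, SteadyState, Trajectory

__all__ = [
    "EXTINCTION_THRESHOLD",
    "integrate",
    "steady_state",
    "steady_state_with_reservoir",
]

#: abundances below this (dimensionless) value signify extinction
EXTINCTION_THRESHOLD = 1e-7
#: convergence criterion on |d^2 ln n / dt^2|
CURVATURE_TOL = 1e-6
#: a species counts toward richness when d ln n / dt exceeds this
DECAY_TOL = -1e-3
#: |d ln n / dt| below this counts as stationary once curvature has settled
STATIONARY_TOL = 1e-6

_RTOL = 1e-8
_ATOL = 1e-10


def _rhs_factory(R: np.ndarray, s: np.ndarray, delta: np.ndarray):
    """Per-capita growth RHS; resources consumed by nobody contribute 0."""

    def rhs(t, n):
        n = np.maximum(n, 0.0)
        h = n @ R
        avail = np.divide(s, h, out=np.zeros_like(s), where=h > 0)
        growth = R @ avail - delta
        return n * growth

    return rhs


def integrate(
    community: Community,
    initial_abundances,
    t_max: float,
    max_step: float = np.inf,
    n_eval: int = 200,
) -> Trajectory:
    """Integrate the dynamics from ``initial_abundances`` up to ``t_max``.

    Species that cross below the extinction threshold are clamped to zero
    and stay extinct.  Returns a :class:`Trajectory` sampled on ``n_eval``
    points; if every species goes extinct the trajectory is flagged.
    """
    n0 = np.asarray(initial_abundances, dtype=float).copy()
    if n0.shape != (community.m,):
        raise ValueError("initial abundances must have length m")
    R = community.R
    s = community.s
    delta = community.delta
    rhs = _rhs_factory(R, s, delta)

    alive = n0 > 0
    n0[~alive] = 0.0
    t = 0.0
    times = [0.0]
    states = [n0.copy()]
    t_grid = np.linspace(0, t_max, n_eval + 1)

    def extinction_event(t, n):
        live = n > 0
        return float(n[live].min() - EXTINCTION_THRESHOLD) if live.any() else -1.0

    extinction_event.terminal = True
    extinction_event.direction = -1.0

    n = n0.copy()
    while t < t_max and np.any(n > 0):
        t_eval = t_grid[(t_grid > t) & (t_grid <= t_max)]
        sol = solve_ivp(
            rhs,
            (t, t_max),
            n,
            method="RK45",
            rtol=_RTOL,
            atol=_ATOL,
            max_step=max_step,
            t_eval=t_eval if t_eval.size else None,
            events=extinction_event,
        )
        sol_t = np.asarray(sol.t, dtype=float)
        sol_y = np.asarray(sol.y, dtype=float)
        if sol_t.size:
            for tt, col in zip(sol_t, sol_y.T):
                if tt > t:
                    times.append(float(tt))
                    states.append(np.maximum(col, 0.0))
        t_end = float(sol_t[-1]) if sol_t.size else t
        n = np.maximum(sol_y[:, -1], 0.0) if sol_t.size else n
        if sol.status == 1:  # extinction event: clamp and restart
            t_end = float(sol.t_events[0][0])
            n = np.maximum(sol.y_events[0][0], 0.0)
            # the event root can land a rounding error above the threshold;
            # clamp generously, and always remove the crossing species so the
            # restarted integration cannot refire at the same instant
            crossing = n <= EXTINCTION_THRESHOLD * (1.0 + 1e-6)
            if not crossing.any():
                live = np.flatnonzero(n > 0)
                crossing = np.zeros_like(n, dtype=bool)
                crossing[live[np.argmin(n[live])]] = True
            n[crossing] = 0.0
            times.append(t_end)
            states.append(n.copy())
        t = t_end
        if sol.status == 0:
            break

    traj = Trajectory(np.asarray(times), np.asarray(states))
    traj.all_extinct = bool(np.all(traj.abundances[-1] <= 0))
    return traj


def _window_logs(rhs, t0, n, window: float):
    """Integrate one window; return (t_end, n_end, ln-samples, extinct_flag).

    Samples log-abundances at 3 equally spaced points spanning the window for
    finite-difference derivative estimates.
    """
    h = window / 2.0
    t_eval = t0 + np.array([0.0, h, 2 * h])
    sol = solve_ivp(
        rhs, (t0, t0 + window), n, method="RK45", rtol=_RTOL, atol=_ATOL,
        t_eval=t_eval, dense_output=False,
    )
    ys = np.maximum(sol.y.T, 0.0)
    return t0 + window, ys[-1], ys, h


def steady_state(
    community: Community,
    present_species=None,
    t_max: float = 1e4,
    max_restarts: int = 3,
    window: float = 20.0,
    initial_abundances=None,
    polish: bool = True,
) -> SteadyState:
    """Integrate from equal abundances of the present species to steady state.

    Convergence and richness follow the module criteria; the result is
    independent of initial abundances for this model class (checked by the
    test suite, not assumed here).  Non-convergence within the time budget
    (``t_max`` with up to ``max_restarts`` extensions) is flagged via
    ``converged=False``.

    The stopping rule accepts the state while the slowest modes are still
    relaxing at the 1e-4 scale; with ``polish=True`` the surviving species'
    abundances are refined to the exact fixed point of their per-capita
    growth balance with a root finder seeded by the ODE endpoint (survivor
    identification itself remains purely dynamical).
    """
    m = community.m
    if present_species is None:
        present_species = range(m)
    present = np.zeros(m, dtype=bool)
    present[list(present_species)] = True
    if not present.any():
        raise ValueError("present_species must be non-empty")

    n = np.zeros(m)
    if initial_abundances is not None:
        n0 = np.asarray(initial_abundances, dtype=float)
        if np.any(n0[present] <= 0):
            raise ValueError("present species need positive initial abundance")
        n[present] = n0[present]
    else:
        # equal dimensionless abundances 1/m_present, i.e. S/(d * m_present)
        n[present] = community.S / community.d / present.sum()

    rhs = _rhs_factory(community.R, community.s, community.delta)
    budget = t_max * (1 + max_restarts)
    t = 0.0
    converged = False
    dlogdt = np.zeros(m)

    while t < budget:
        t, n, ys, h = _window_logs(rhs, t, n, window)
        extinct = n <= EXTINCTION_THRESHOLD
        n[extinct] = 0.0
        alive = ~extinct
        if not alive.any():
            break
        if np.any(ys[:, alive] <= 0):
            continue  # a clamp happened mid-window; derivatives unreliable
        logs = np.log(ys[:, alive])
        d2 = (logs[0] - 2 * logs[1] + logs[2]) / h**2
        d1 = (logs[2] - logs[0]) / (2 * h)
        dlogdt[alive] = d1
        dlogdt[extinct] = -np.inf
        if np.all(np.abs(d2) < CURVATURE_TOL):
            decaying = alive & (dlogdt < -STATIONARY_TOL)
            settled = alive & ~decaying
            if not decaying.any():
                converged = True
                break
            if np.all(np.abs(dlogdt[settled]) < STATIONARY_TOL):
                # The environment is stationary.  A declining species is
                # truly doomed only if it could not even grow with its own
                # biomass removed (the most favorable availabilities it can
                # ever see); such species are removed instead of integrating
                # out an arbitrarily slow exponential tail.  A decliner that
                # could re-grow is merely relaxing toward a positive value.
                j = int(np.flatnonzero(decaying)[np.argmin(dlogdt[decaying])])
                h_wo = n @ community.R - n[j] * community.R[j]
                if np.any((community.R[j] > 0) & (h_wo <= 0)):
                    continue  # sole consumer of a resource: cannot be doomed
                growth_j = float(
                    community.R[j] @ np.divide(
                        community.s, h_wo,
                        out=np.zeros_like(community.s), where=h_wo > 0,
                    )
                )
                if growth_j < community.delta[j] - 1e-9:
                    n[j] = 0.0
                    dlogdt[j] = -np.inf

    survivors = tuple(
        int(i)
        for i in range(m)
        if n[i] > EXTINCTION_THRESHOLD and dlogdt[i] > DECAY_TOL
    )
    abund = np.where(n > EXTINCTION_THRESHOLD, n, 0.0)
    if polish and survivors and converged:
        abund = _polish_fixed_point(community, survivors, abund)
    h_res = abund @ community.R
    c = np.divide(
        community.s, h_res, out=np.full_like(community.s, np.inf), where=h_res > 0
    )
    return SteadyState(abund, survivors, c, converged=converged)


def _polish_fixed_point(community: Community, survivors, abund: np.ndarray):
    """Refine survivor abundances to the growth-balance fixed point."""
    idx = np.asarray(survivors, dtype=int)
    Rs = community.R[idx]
    s = community.s
    delta = community.delta[idx]

    def balance(n):
        h = n @ Rs
        avail = np.divide(s, h, out=np.zeros_like(s), where=h > 0)
        return Rs @ avail - delta

    sol = root(balance, abund[idx], method="hybr", tol=1e-12)
    n_ref = sol.x
    ok = (
        sol.success
        and np.all(n_ref > 0)
        and np.all(np.abs(n_ref - abund[idx]) <= 0.1 * np.abs(abund[idx]))
    )
    if ok:
        out = abund.copy()
        out[idx] = n_ref
        return out
    return abund


def steady_state_with_reservoir(community: Community, **kwargs) -> SteadyState:
    """Steady state evaluated from the full species pool.

    Models an external re-seeding reservoir: every species of the community
    is present initially (at equal abundances) regardless of any earlier
    extinction, so the outcome is the coexisting set over the full pool.
    """
    return steady_state(community, present_species=range(community.m), **kwargs)
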