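"""Analytic coexistence machinery on the resource simplex.

At steady state every surviving species ``i`` satisfies
``sum_mu R_i,mu c*_mu = d + d_i`` where ``c*_mu = s_mu / sum_k n*_k R_k,mu``
is the effective availability of resource ``mu``.  Geometrically, the
survivors' rescaled consumption rates ``R^_i,mu = R_i,mu c*_mu`` lie on a
common hyperplane, and the community coexists on that hyperplane when

1. all ``c*_mu`` are positive and finite,
2. no other species lies on the far side of the hyperplane
   (``sum_mu R_j,mu c*_mu <= d + d_j`` for every non-member ``j``), and
3. the normalized supply ``s^_mu = s_mu d / S`` falls inside the convex hull
   of the survivors' rescaled rates — equivalently, the abundance system
   ``sum_k n_k R_k,mu = s_mu / c*_mu`` has an all-positive solution.

The module enumerates candidate survivor subsets, solves each directly
(a linear solve when the subset size equals ``p``, a damped Newton iteration
on the abundance fixed point otherwise), and screens with the conditions
above.  This reproduces the ODE steady state in a few microseconds-scale
linear solves, which is what makes million-community ensembles tractable.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass

import numpy as np
from scipy.optimize import brentq, root

from .community import Community, SteadyState

__all__ = [
    "RescaledFrame",
    "candidate_hyperplanes",
    "coexisting_set",
    "direct_steady_state",
    "coexistence_region_size",
    "rescaled_frame",
]

logger = logging.getLogger(__name__)

#: tolerance for hull-boundary / hyperplane-side decisions (condition 2 and
#: abundance positivity); boundary cases count as contained.
BOUNDARY_TOL = 1e-9


# ---------------------------------------------------------------------------
# low-level subset solvers (arrays only, no Community overhead)


def _solve_subset(R: np.ndarray, s: np.ndarray, delta: np.ndarray, subset):
    """Steady state restricted to ``subset``; ``(n_sub, c_star)`` or None.

    ``c_star`` entries are ``inf`` for resources the subset does not consume.
    Returns None when the restricted system has no all-positive solution.
    """
    idx = np.asarray(subset, dtype=int)
    k = idx.size
    p = R.shape[1]
    Rsub = R[idx]
    dsub = delta[idx]

    if k == p:
        try:
            c = np.linalg.solve(Rsub, dsub)
        except np.linalg.LinAlgError:
            return None
        if not np.all(np.isfinite(c)) or np.any(c <= 0):
            return None
        n = np.linalg.solve(Rsub.T, s / c)
        if np.any(n <= 0):
            return None
        return n, c

    # subset smaller than the number of resources: nonlinear fixed point
    consumed = Rsub.max(axis=0) > 0
    Rc = Rsub[:, consumed]
    sc = s[consumed]

    if k == 1:
        n = np.array([sc.sum() / dsub[0]])
    elif k == 2:
        n = _pair_fixed_point(Rc, sc, dsub)
        if n is None:
            return None
    else:
        n = _newton_abundances(Rc, sc, dsub)
        if n is None:
            return None

    h = Rc.T @ n
    c = np.full(p, np.inf)
    c[consumed] = sc / h
    return n, c


def _pair_fixed_point(R: np.ndarray, s: np.ndarray, delta: np.ndarray):
    """Exact interior fixed point for a two-species subset (any p).

    Writing ``n = T (1-t, t)``, the availabilities depend on ``t`` only
    through ``q(t) = (1-t) R_1 + t R_2``, so the balance equations reduce to
    one scalar equation ``phi(t) = delta_2 G_1(t) - delta_1 G_2(t) = 0``
    with ``G_i(t) = sum_mu R_i,mu s_mu / q_mu(t)``, plus ``T = G_1/delta_1``.
    Strict concavity of the underlying potential makes the interior root
    unique, so a sign check at the interval ends is decisive: no sign change
    means the subset has no interior steady state.
    """
    R1, R2 = R[0], R[1]

    def phi(t):
        w = s / ((1.0 - t) * R1 + t * R2)
        return delta[1] * (R1 @ w) - delta[0] * (R2 @ w)

    eps = 1e-13
    lo, hi = eps, 1.0 - eps
    p_lo, p_hi = phi(lo), phi(hi)
    if not (np.isfinite(p_lo) and np.isfinite(p_hi)):
        return None
    if p_lo == 0.0:
        t_star = lo
    elif p_hi == 0.0:
        t_star = hi
    elif (p_lo > 0) == (p_hi > 0):
        return None
    else:
        t_star = brentq(phi, lo, hi, xtol=1e-15, rtol=8.9e-16)
    w = s / ((1.0 - t_star) * R1 + t_star * R2)
    T = (R1 @ w) / delta[0]
    n = T * np.array([1.0 - t_star, t_star])
    if np.any(n <= 0) or not np.all(np.isfinite(n)):
        return None
    return n


def _newton_abundances(R: np.ndarray, s: np.ndarray, delta: np.ndarray,
                       tol: float = 1e-11):
    """Interior fixed point of ``sum_mu R_i,mu s_mu / (R^T n)_mu = delta_i``.

    The fixed point is the stationary point of the strictly concave
    potential ``sum_mu s_mu ln (R^T n)_mu - sum_i delta_i n_i``, so an
    interior root, when it exists, is unique.  Iterates use the
    multiplicative update ``n_i <- n_i * growth_i / delta_i`` (monotone
    ascent of the potential and automatically positive), finished with
    Newton steps once inside the quadratic basin.

    When the iteration stalls, interior vs boundary is decided exactly
    rather than by an iteration cap: the species with the worst growth
    deficit is removed, the face subproblem is solved recursively, and the
    removed species' growth at the face solution tells whether it re-invades
    (an interior point exists; restart from just inside the face) or not
    (the potential peaks on the boundary; no interior steady state — return
    None).
    """
    k = R.shape[0]
    if k == 1:
        return np.array([s.sum() / delta[0]])
    if k == 2:
        return _pair_fixed_point(R, s, delta)
    n = (s.sum() / k) / delta  # flux-balance-scale start
    floor = 1e-14 * s.sum() / delta.max()
    newton_tol = 1e-4 * delta.max()
    restarts = 0
    budget = 400
    it = 0
    while it < budget:
        it += 1
        h = R.T @ n
        if np.any(h <= 0):
            return None
        w = s / h
        growth = R @ w
        g = growth - delta
        if np.max(np.abs(g)) < newton_tol:
            # quadratic finish
            for _ in range(40):
                J = -(R * (w / h)) @ R.T
                try:
                    step = np.linalg.solve(J, -g)
                except np.linalg.LinAlgError:
                    return None
                n_new = n + step
                if np.any(n_new <= 0):
                    break  # not in the basin yet; resume multiplicative
                n = n_new
                h = R.T @ n
                w = s / h
                growth = R @ w
                g = growth - delta
                if np.max(np.abs(g)) < tol * delta.max():
                    return n
        n = n * (growth / delta)
        if np.any(n < floor):
            return None
        if it == budget and restarts < 2:
            # stalled: diagnose boundary vs slow interior convergence
            j = int(np.argmin(g))
            keep = [i for i in range(k) if i != j]
            cols = R[keep].max(axis=0) > 0
            face = _newton_abundances(R[keep][:, cols], s[cols], delta[keep], tol)
            if face is None:
                return None
            if np.any(R[j][~cols] > 0):
                growth_j = np.inf  # face leaves a resource untouched
            else:
                growth_j = float(
                    R[j][cols] @ (s[cols] / (R[keep][:, cols].T @ face))
                )
            if growth_j <= delta[j] + BOUNDARY_TOL:
                return None  # confirmed: the potential peaks on this face
            # re-invasion: an interior point exists; it may have a very
            # small j-component, where multiplicative steps crawl — hand the
            # polished face seed to a general root finder first
            seed = np.empty(k)
            seed[keep] = face
            seed[j] = 1e-6 * face.max()
            sol = _root_abundances(R, s, delta, seed)
            if sol is not None:
                return sol
            sol = _root_abundances(R, s, delta, n)
            if sol is not None:
                return sol
            n = seed
            restarts += 1
            budget += 4000
    logger.debug("interior fixed point unresolved after %d iterations", it)
    return None


def _root_abundances(R, s, delta, seed):
    """General root-finder pass on the growth balance; None if unusable."""

    def balance(n):
        h = R.T @ n
        if np.any(h <= 0):
            return np.full_like(n, 1e6)
        return R @ (s / h) - delta

    sol = root(balance, seed, method="hybr", tol=1e-13)
    n = sol.x
    if (
        sol.success
        and np.all(n > 0)
        and np.max(np.abs(balance(n))) < 1e-9 * delta.max()
    ):
        return n
    return None


def _invaders(R: np.ndarray, delta: np.ndarray, c: np.ndarray, members) -> bool:
    """True if any non-member grows at the availabilities ``c``."""
    m = R.shape[0]
    mask = np.ones(m, dtype=bool)
    mask[list(members)] = False
    if not mask.any():
        return False
    Rout = R[mask]
    finite = np.isfinite(c)
    if not finite.all() and np.any(Rout[:, ~finite] > 0):
        return True  # unconsumed resource offers unbounded growth
    growth = Rout[:, finite] @ c[finite]
    return bool(np.any(growth > delta[mask] + BOUNDARY_TOL))


def _subsets_by_size(m: int, p: int):
    for k in range(min(m, p), 0, -1):
        yield from itertools.combinations(range(m), k)


# ---------------------------------------------------------------------------
# public API


@dataclass
class RescaledFrame:
    """Simplex-geometry view of a candidate survivor subset."""

    c_star: np.ndarray
    s_hat: np.ndarray
    R_hat: np.ndarray
    member_subset: tuple[int, ...]
    hull_contains_supply: bool


def direct_steady_state(community: Community, subset):
    """Solve the steady state restricted to ``subset`` of species.

    Returns ``(abundances, c_star)`` for the subset (abundances in subset
    order) when the subset admits an uninvadable all-positive steady state,
    or ``None`` when it does not (negative abundances, non-positive
    availabilities, or an outside species that could invade).
    """
    R = community.R
    delta = community.delta
    sol = _solve_subset(R, community.s, delta, subset)
    if sol is None:
        return None
    n, c = sol
    if _invaders(R, delta, c, subset):
        return None
    return n, c


def candidate_hyperplanes(community: Community):
    """Enumerate survivor subsets whose hyperplane passes conditions 1-2.

    For subsets of size ``p`` the hyperplane is the solution of
    ``R_sub c* = d + d_i`` (supply-independent); smaller subsets are screened
    through their direct steady state, whose availabilities define the
    hyperplane.  Rank-deficient subsets are skipped with a log record.
    Returns a list of ``(subset, c_star)`` pairs.
    """
    R = community.R
    delta = community.delta
    p = community.p
    out = []
    for subset in _subsets_by_size(community.m, p):
        if len(subset) == p:
            Rsub = R[list(subset)]
            try:
                c = np.linalg.solve(Rsub, delta[list(subset)])
            except np.linalg.LinAlgError:
                logger.debug("skipping rank-deficient subset %s", subset)
                continue
            if not np.all(np.isfinite(c)) or np.any(c <= 0):
                continue
            if _invaders(R, delta, c, subset):
                continue
            out.append((subset, c))
        else:
            sol = direct_steady_state(community, subset)
            if sol is not None:
                out.append((subset, sol[1]))
    return out


def coexisting_set(community: Community, check_unique: bool = False) -> SteadyState:
    """The uninvadable steady-state community, found geometrically.

    Enumerates subsets from largest to smallest and returns the first whose
    direct steady state is feasible and uninvadable.  For this model class
    the uninvadable state is unique (it maximizes a strictly concave
    potential), so enumeration order does not affect the result;
    ``check_unique=True`` verifies this and logs violations.
    """
    R = community.R
    s = community.s
    delta = community.delta
    m = community.m
    found = None
    for subset in _subsets_by_size(m, community.p):
        sol = _solve_subset(R, s, delta, subset)
        if sol is None:
            continue
        n, c = sol
        if _invaders(R, delta, c, subset):
            continue
        if found is None:
            abund = np.zeros(m)
            abund[list(subset)] = n
            found = SteadyState(abund, subset, c)
            if not check_unique:
                return found
        else:
            logger.warning(
                "multiple uninvadable states: %s and %s", found.survivors, subset
            )
    if found is None:
        raise RuntimeError("no feasible steady state found (degenerate community)")
    return found


def rescaled_frame(community: Community, subset=None) -> RescaledFrame:
    """Rescaled-consumption-rate view for ``subset`` (default: coexisting set)."""
    if subset is None:
        subset = coexisting_set(community).survivors
    sol = _solve_subset(community.R, community.s, community.delta, subset)
    s_hat = community.s * community.d / community.S
    if sol is None:
        c = np.full(community.p, np.nan)
        return RescaledFrame(c, s_hat, community.R * c, tuple(subset), False)
    n, c = sol
    contained = bool(np.all(n > 0)) and not _invaders(
        community.R, community.delta, c, subset
    )
    R_hat = np.where(community.R > 0, community.R * c, 0.0)
    return RescaledFrame(c, s_hat, R_hat, tuple(subset), contained)


def coexistence_region_size(
    R,
    death_rates=None,
    d: float = 1.0,
    *,
    S: float = 1.0,
    n_samples: int = 20_000,
    seed: int = 0,
    full_output: bool = False,
):
    """Fraction of the supply simplex on which all species coexist.

    For two resources the region is an interval in the supply share and is
    computed exactly; otherwise seeded Monte Carlo over uniform simplex
    samples is used (binomial standard error reported with
    ``full_output=True``).
    """
    R = np.atleast_2d(np.asarray(R, dtype=float))
    m, p = R.shape
    if death_rates is None:
        death_rates = np.zeros(m)
    delta = d + np.asarray(death_rates, dtype=float)

    if p == 2 and m <= 2:
        frac = _region_size_exact_p2(R, delta, S)
        return (frac, 0.0, "exact") if full_output else frac

    rng = np.random.default_rng(seed)
    supplies = rng.dirichlet(np.ones(p), size=n_samples) * S
    hits = 0
    for s in supplies:
        comm = Community(R, s, d, death_rates=np.asarray(death_rates, float))
        if coexisting_set(comm).richness == m:
            hits += 1
    frac = hits / n_samples
    stderr = float(np.sqrt(frac * (1 - frac) / n_samples))
    return (frac, stderr, "monte-carlo") if full_output else frac


def _region_size_exact_p2(R: np.ndarray, delta: np.ndarray, S: float) -> float:
    """Exact coexistence-region fraction for p = 2, m <= 2."""
    m = R.shape[0]
    if m == 1:
        # a lone species persists for any interior supply it can consume
        return 1.0
    try:
        c = np.linalg.solve(R, delta)
    except np.linalg.LinAlgError:
        return 0.0
    if not np.all(np.isfinite(c)) or np.any(c <= 0):
        return 0.0
    # n(s1) is linear in s1 where s = (s1, S - s1)
    A = np.linalg.solve(R.T, np.array([0.0, S / c[1]]))
    B = np.linalg.solve(R.T, np.array([1.0 / c[0], -1.0 / c[1]]))
    lo, hi = 0.0, S
    for a, b in zip(A, B):
        if abs(b) < 1e-15:
            if a <= 0:
                return 0.0
            continue
        root = -a / b
        if b > 0:
            lo = max(lo, root)
        else:
            hi = min(hi, root)
    return max(0.0, hi - lo) / S
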