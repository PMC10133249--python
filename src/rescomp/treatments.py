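"""Antibiotic treatment protocols and ensemble statistics.

Three protocols are implemented on top of the geometric steady-state solver:

* **Dose scans** — all death rates are scaled by a concentration multiplier
  ``c`` and the steady-state richness (with re-seeding reservoir semantics)
  is traced as ``c`` grows until the targeted species goes extinct; the
  number of richness changes quantifies non-monotonicity.

* **Sequential treatment** — two single-target antibiotics are applied one
  after the other (antibiotics are swapped directly, with no drug-free
  interlude, and extinct species stay extinct).  Non-transitivity is a
  dependence of the final richness on the order; its mechanism is either
  *promotion* (competition causes an antibiotic-induced extinction that
  would not happen without the other target present) or *neutralization*
  (competition prevents an extinction that would happen without the other
  target present).

* **Combination treatment** — both antibiotics applied simultaneously; the
  outcome is compared against the additive baseline, the union of the two
  single-antibiotic extinction sets.  Fewer extinctions than the baseline is
  *antagonism*, more is *synergism*.

``ensemble_scan`` tabulates the joint occurrence of the sequential and
combination classifications over random community ensembles.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

from .community import Community
from .geometry import _invaders, _solve_subset, _subsets_by_size
from .sampling import (
    MAX_CENTROID_DISTANCE,
    StructuredFamilySpec,
    build_structured_community,
    sample_random_community,
)

__all__ = [
    "DoseScanResult",
    "SequenceResult",
    "CombinationResult",
    "EnsembleResult",
    "dose_scan",
    "sequential_treatment",
    "classify_mechanism",
    "combination_treatment",
    "ensemble_scan",
    "two_target_sampler",
    "structured_family_scan",
    "aggregate_symmetric_species",
]

logger = logging.getLogger(__name__)

MECHANISMS = ("transitive", "promotion", "neutralization")
ADDITIVITY = ("additive", "antagonistic", "synergistic")


# ---------------------------------------------------------------------------
# fast survivor-set evaluation on raw arrays


def _survivor_set(
    R: np.ndarray, s: np.ndarray, delta: np.ndarray, pool: tuple[int, ...]
) -> tuple[int, ...]:
    """Uninvadable survivor subset of ``pool`` (original species indices).

    Raw-array twin of :func:`rescomp.geometry.coexisting_set`, restricted to
    a species pool; kept allocation-light because ensemble pipelines call it
    millions of times.
    """
    if not pool:
        return ()
    idx = np.asarray(pool, dtype=int)
    Rp = R[idx]
    dp = delta[idx]
    for subset in _subsets_by_size(len(pool), R.shape[1]):
        sol = _solve_subset(Rp, s, dp, subset)
        if sol is None:
            continue
        if _invaders(Rp, dp, sol[1], subset):
            continue
        return tuple(int(idx[j]) for j in subset)
    raise RuntimeError(f"no feasible steady state within pool {pool}")


def _as_death_vector(antibiotic, m: int) -> np.ndarray:
    v = np.asarray(antibiotic, dtype=float).ravel()
    if v.shape != (m,):
        raise ValueError(f"antibiotic death-rate vector must have length {m}")
    if np.any(v < 0):
        raise ValueError("death rates must be non-negative")
    return v


def _single_target(antibiotic: np.ndarray) -> int:
    nz = np.flatnonzero(antibiotic > 0)
    if nz.size != 1:
        raise ValueError("mechanism classification requires single-target antibiotics")
    return int(nz[0])


# ---------------------------------------------------------------------------
# dose scans


@dataclass
class DoseScanResult:
    """Richness trajectory versus antibiotic concentration multiplier."""

    concentration_grid: np.ndarray
    base_death_rates: np.ndarray
    richness_path: np.ndarray
    change_points: np.ndarray
    n_changes: int
    extinction_dose: float
    capped: bool = False  # c_max reached without target extinction


def dose_scan(
    community: Community,
    target_profile,
    c_max: float,
    n_grid: int = 401,
    resolution: float = 1e-4,
) -> DoseScanResult:
    """Scan richness as death rates ``c * target_profile`` increase from 0.

    Richness uses reservoir semantics (the coexisting set over the full
    species pool at each dose).  Change points are refined by bisection to
    ``resolution`` in ``c``; ``n_changes`` counts richness transitions from
    c = 0 up to and including the extinction of the targeted species (the
    species with the largest entry of ``target_profile``).  If the target is
    not extinct by ``c_max`` the scan is flagged ``capped`` and changes are
    counted over the whole grid.
    """
    profile = _as_death_vector(target_profile, community.m)
    if not np.any(profile > 0):
        raise ValueError("target_profile must have a positive entry")
    target = int(np.argmax(profile))
    R, s, d = community.R, community.s, community.d

    def state(c: float) -> tuple[int, bool]:
        surv = _survivor_set(R, s, d + c * profile, tuple(range(community.m)))
        return len(surv), target in surv

    grid = np.linspace(0.0, c_max, n_grid)
    rho = np.empty(n_grid, dtype=int)
    alive = np.empty(n_grid, dtype=bool)
    for j, c in enumerate(grid):
        rho[j], alive[j] = state(c)

    def bisect(lo: float, hi: float, f: Callable[[float], bool]) -> float:
        # f flips between lo and hi; return the flip point to `resolution`
        f_lo = f(lo)
        while hi - lo > resolution:
            mid = 0.5 * (lo + hi)
            if f(mid) == f_lo:
                lo = mid
            else:
                hi = mid
        return hi

    # extinction dose of the target
    if alive[0] and alive.all():
        extinction_dose = np.inf
        capped = True
    elif not alive[0]:
        extinction_dose = 0.0
        capped = False
    else:
        j = int(np.argmax(~alive))  # first grid point with target extinct
        extinction_dose = bisect(grid[j - 1], grid[j], lambda c: state(c)[1])
        capped = False

    # refine richness change points
    change_points = []
    for j in range(1, n_grid):
        if rho[j] != rho[j - 1]:
            lo, hi = grid[j - 1], grid[j]
            rho_lo = rho[j - 1]
            # there may be several transitions inside one grid cell; split
            # recursively down to the resolution
            stack = [(lo, hi, rho_lo, rho[j])]
            while stack:
                a, b, ra, rb = stack.pop()
                if ra == rb:
                    continue
                if b - a <= resolution:
                    change_points.append(b)
                    continue
                mid = 0.5 * (a + b)
                rm = state(mid)[0]
                stack.append((mid, b, rm, rb))
                stack.append((a, mid, ra, rm))
    change_points = np.asarray(sorted(change_points))

    cutoff = extinction_dose if np.isfinite(extinction_dose) else c_max
    n_changes = int(np.sum(change_points <= cutoff + resolution))
    if capped:
        logger.warning("dose_scan: target not extinct by c_max=%s", c_max)
    return DoseScanResult(
        concentration_grid=grid,
        base_death_rates=profile,
        richness_path=rho,
        change_points=change_points,
        n_changes=n_changes,
        extinction_dose=extinction_dose,
        capped=capped,
    )


# ---------------------------------------------------------------------------
# sequential treatment


@dataclass
class SequenceResult:
    """Outcome of applying two antibiotics in both orders."""

    order_AB_survivors: tuple[int, ...]
    order_BA_survivors: tuple[int, ...]
    delta_rho: int
    mechanism: str
    context_flags: dict = field(default_factory=dict)

    @property
    def rho_AB(self) -> int:
        return len(self.order_AB_survivors)

    @property
    def rho_BA(self) -> int:
        return len(self.order_BA_survivors)


def _sequence_protocol(R, s, d, A, B, S0, cache):
    """Final survivor sets for orders A->B and B->A, from pool S0."""
    if "SA" not in cache:
        cache["SA"] = _survivor_set(R, s, d + A, S0)
    if "SB" not in cache:
        cache["SB"] = _survivor_set(R, s, d + B, S0)
    cache["final_AB"] = _survivor_set(R, s, d + B, cache["SA"])
    cache["final_BA"] = _survivor_set(R, s, d + A, cache["SB"])
    return cache["final_AB"], cache["final_BA"]


def sequential_treatment(
    community: Community, antibiotic_A, antibiotic_B
) -> SequenceResult:
    """Apply two antibiotics sequentially in both orders and compare richness.

    Protocol: (i) steady state of the full pool with no antibiotic gives the
    pre-treatment survivors; (ii) the first antibiotic is applied to those
    survivors (no reservoir; extinctions are permanent); (iii) the first
    antibiotic is swapped for the second directly.  The richness difference
    ``delta_rho = |rho_AB - rho_BA|`` measures non-transitivity, and the
    mechanism is classified via :func:`classify_mechanism`.
    """
    m = community.m
    A = _as_death_vector(antibiotic_A, m)
    B = _as_death_vector(antibiotic_B, m)
    R, s, d = community.R, community.s, community.d
    S0 = _survivor_set(R, s, np.full(m, d), tuple(range(m)))
    cache: dict = {}
    final_AB, final_BA = _sequence_protocol(R, s, d, A, B, S0, cache)
    delta_rho = abs(len(final_AB) - len(final_BA))
    mechanism = _classify_mechanism_raw(delta_rho, S0, cache)
    flags = _context_flags(R, s, d, A, B, S0, cache)
    return SequenceResult(final_AB, final_BA, delta_rho, mechanism, flags)


def _classify_mechanism_raw(delta_rho, S0, cache):
    """Mechanism from the extinction sets of the two application contexts.

    Each antibiotic is applied in two contexts during the order swap: first
    (to the pre-antibiotic pool ``S0``) or second (to the survivors of the
    other antibiotic).  A species killed in the first-position context but
    spared in the second-position context — where a competitor is absent —
    witnesses competition *promoting* the antibiotic's action; a species
    spared first-position but killed second-position witnesses competition
    *neutralizing* it.  The witnessed extinction is usually the antibiotic's
    own target but can be collateral.
    """
    if delta_rho == 0:
        return "transitive"
    pool0 = set(S0)
    promoted = neutralized = False
    for first_key, second_pool_key, second_final_key in (
        ("SA", "SB", "final_BA"),  # antibiotic A applied first vs second
        ("SB", "SA", "final_AB"),  # antibiotic B
    ):
        kills_first = pool0 - set(cache[first_key])
        second_pool = set(cache[second_pool_key])
        kills_second = second_pool - set(cache[second_final_key])
        if kills_first & (second_pool - kills_second):
            promoted = True
        if kills_second - kills_first:
            neutralized = True
    if promoted and not neutralized:
        return "promotion"
    if neutralized and not promoted:
        return "neutralization"
    logger.debug("nonzero delta-rho with mixed/no context signals: unclassified")
    return "unclassified"


def _context_flags(R, s, d, A, B, S0, cache):
    """Per-antibiotic context dependence of the targeted extinction."""
    try:
        x, y = _single_target(A), _single_target(B)
    except ValueError:
        return {}
    flags = {}
    for label, X, tgt, other, first_key in (
        ("A", A, x, y, "SA"),
        ("B", B, y, x, "SB"),
    ):
        e_full = tgt not in cache[first_key]
        pool_wo = tuple(i for i in S0 if i != other)
        e_alone = tgt not in _survivor_set(R, s, d + X, pool_wo)
        flags[label] = {
            "target": tgt,
            "extinct_in_full": e_full,
            "extinct_without_other_target": e_alone,
        }
    return flags


def classify_mechanism(community: Community, antibiotic_A, antibiotic_B) -> str:
    """Classify the mechanism behind order-dependence of two antibiotics.

    Competition *promotes* an antibiotic's action when it causes an
    extinction in the fuller first-position community that does not occur
    when the antibiotic is applied second (after the other antibiotic has
    removed a competitor); it *neutralizes* the action in the converse case.
    With ``delta_rho = 0`` the sequence is transitive; with
    ``delta_rho > 0`` exactly one signal type occurs and is returned
    (``"unclassified"`` surfaces any case with mixed or absent signals).
    """
    return sequential_treatment(community, antibiotic_A, antibiotic_B).mechanism


# ---------------------------------------------------------------------------
# combination treatment


@dataclass
class CombinationResult:
    """Outcome of simultaneous application of two antibiotics."""

    extinct_A: frozenset
    extinct_B: frozenset
    extinct_AB: frozenset
    rho_additive: int
    rho_AB: int
    classification: str
    d_min: float


def combination_treatment(
    community: Community, antibiotic_A, antibiotic_B
) -> CombinationResult:
    """Compare the combined antibiotic effect against the additive baseline.

    From the pre-antibiotic survivor pool, extinction sets are computed under
    A alone, B alone, and A+B simultaneously.  The additive expectation is
    that the combination removes the union of the single-drug extinction
    sets; a combined richness above that baseline is antagonism, below it is
    synergism.
    """
    m = community.m
    A = _as_death_vector(antibiotic_A, m)
    B = _as_death_vector(antibiotic_B, m)
    R, s, d = community.R, community.s, community.d
    S0 = _survivor_set(R, s, np.full(m, d), tuple(range(m)))
    return _combination_raw(R, s, d, A, B, S0, {})


def _combination_raw(R, s, d, A, B, S0, cache) -> CombinationResult:
    if "SA" not in cache:
        cache["SA"] = _survivor_set(R, s, d + A, S0)
    if "SB" not in cache:
        cache["SB"] = _survivor_set(R, s, d + B, S0)
    surv_AB = _survivor_set(R, s, d + A + B, S0)
    pool = set(S0)
    extinct_A = frozenset(pool - set(cache["SA"]))
    extinct_B = frozenset(pool - set(cache["SB"]))
    extinct_AB = frozenset(pool - set(surv_AB))
    rho_additive = len(S0) - len(extinct_A | extinct_B)
    rho_AB = len(surv_AB)
    if rho_AB < rho_additive:
        cls = "synergistic"
    elif rho_AB > rho_additive:
        cls = "antagonistic"
    else:
        cls = "additive"
    applied = np.concatenate([A[A > 0], B[B > 0]])
    d_min = float(applied.min()) if applied.size else float("nan")
    return CombinationResult(
        extinct_A, extinct_B, extinct_AB, rho_additive, rho_AB, cls, d_min
    )


# ---------------------------------------------------------------------------
# ensembles


@dataclass
class EnsembleResult:
    """Cross-occurrence table of sequence mechanism vs additivity class."""

    counts: dict
    n_total: int
    n_failed: int
    n_unclassified: int

    def fraction(self, mechanism: str = None, additivity: str = None) -> float:
        """Fraction of the ensemble in the given row/column/cell."""
        total = 0
        for (mech, add), cnt in self.counts.items():
            if mechanism is not None and mech != mechanism:
                continue
            if additivity is not None and add != additivity:
                continue
            total += cnt
        return total / self.n_total if self.n_total else 0.0

    def conditional_fraction(self, mechanism: str, additivity: str) -> float:
        """P(additivity class | mechanism class) within the ensemble."""
        row = self.fraction(mechanism=mechanism)
        if row == 0:
            return float("nan")
        return self.fraction(mechanism=mechanism, additivity=additivity) / row

    def to_records(self) -> list[dict]:
        recs = []
        for mech in MECHANISMS:
            for add in ADDITIVITY:
                cnt = self.counts.get((mech, add), 0)
                recs.append(
                    {
                        "mechanism": mech,
                        "additivity": add,
                        "count": cnt,
                        "fraction": cnt / self.n_total if self.n_total else 0.0,
                    }
                )
        return recs


def two_target_sampler(m: int = 3, p: int = 3, targets: tuple[int, int] = (0, 1)):
    """Sampler for the random-combination ensemble.

    Consumption vectors uniform on the unit simplex, equal supply, d = 1,
    and the two targets' death rates drawn i.i.d. from U(0,1).  Yields
    ``(community, antibiotic_A, antibiotic_B)``.
    """

    def sample(rng: np.random.Generator):
        comm = sample_random_community(m, p, rng, death_scheme="targets",
                                       targets=targets)
        dr = comm.effective_death_rates
        A = np.zeros(m)
        B = np.zeros(m)
        A[targets[0]] = dr[targets[0]]
        B[targets[1]] = dr[targets[1]]
        return comm, A, B

    return sample


def ensemble_scan(
    sampler: Callable[[np.random.Generator], tuple],
    n_communities: int,
    seed: int,
    require_full_coexistence: bool = False,
) -> EnsembleResult:
    """Joint sequential/combination classification over a random ensemble.

    For every sampled ``(community, A, B)`` the sequential protocol (both
    orders, mechanism classification) and the combination protocol are run
    and the 3x3 mechanism-by-additivity table accumulated.  Deterministic
    given ``seed``.  Communities whose protocol fails are logged and
    excluded; ``require_full_coexistence=True`` additionally rejects
    communities that do not start with all species coexisting (resampling to
    keep ``n_communities``).
    """
    rng = np.random.default_rng(seed)
    counts: dict = {}
    n_failed = 0
    n_unclassified = 0
    done = 0
    while done < n_communities:
        comm, A, B = sampler(rng)
        m = comm.m
        R, s, d = comm.R, comm.s, comm.d
        try:
            S0 = _survivor_set(R, s, np.full(m, d), tuple(range(m)))
            if require_full_coexistence and len(S0) < m:
                continue
            cache: dict = {}
            final_AB, final_BA = _sequence_protocol(R, s, d, A, B, S0, cache)
            delta_rho = abs(len(final_AB) - len(final_BA))
            mech = _classify_mechanism_raw(delta_rho, S0, cache)
            combo = _combination_raw(R, s, d, A, B, S0, cache)
        except RuntimeError as err:
            logger.warning("ensemble member failed: %s", err)
            n_failed += 1
            done += 1
            continue
        if mech == "unclassified":
            n_unclassified += 1
            done += 1
            continue
        key = (mech, combo.classification)
        counts[key] = counts.get(key, 0) + 1
        done += 1
    return EnsembleResult(counts, n_communities, n_failed, n_unclassified)


def structured_family_scan(
    n_samples: int,
    seed: int,
    mode: str = "random",
) -> dict:
    """Mechanism statistics over the structured three-species family.

    Parameters ``D_T1, D_T2, D_N`` span (0, sqrt(2/3)) and death rates
    ``d_1, d_2`` span (0, 1), varied independently — uniformly at random
    (``mode="random"``) or on a regular grid (``mode="grid"``, with
    ``n_samples`` as an approximate total budget).  Returns counts of
    transitive / promotion / neutralization / unclassified cases and the
    promotion and neutralization shares among nonzero-delta-rho cases.
    """
    if mode == "random":
        rng = np.random.default_rng(seed)
        Ds = rng.uniform(0.0, MAX_CENTROID_DISTANCE, size=(n_samples, 3))
        ds = rng.uniform(0.0, 1.0, size=(n_samples, 2))
        params = np.hstack([Ds, ds])
    elif mode == "grid":
        # balanced grid: finer in distances than in death rates
        k = max(2, int(round((n_samples / 4) ** (1.0 / 5) * 1.5)))
        kd = max(2, k // 2)
        eps = 1e-3
        axD = np.linspace(eps, MAX_CENTROID_DISTANCE - eps, k)
        axd = np.linspace(eps, 1.0 - eps, kd)
        grids = np.meshgrid(axD, axD, axD, axd, axd, indexing="ij")
        params = np.stack([g.ravel() for g in grids], axis=1)
    else:
        raise ValueError(f"unknown mode {mode!r}")

    counts = {k: 0 for k in ("transitive", "promotion", "neutralization",
                             "unclassified", "failed")}
    for D_T1, D_T2, D_N, d1, d2 in params:
        spec = StructuredFamilySpec(D_T1, D_T2, D_N, d1, d2)
        comm = build_structured_community(spec)
        A = np.array([d1, 0.0, 0.0])
        B = np.array([0.0, d2, 0.0])
        try:
            res = sequential_treatment(comm, A, B)
        except RuntimeError:
            counts["failed"] += 1
            continue
        counts[res.mechanism] += 1

    nonzero = counts["promotion"] + counts["neutralization"] + counts["unclassified"]
    return {
        "counts": counts,
        "n_samples": len(params),
        "n_nonzero_delta_rho": nonzero,
        "promotion_share": counts["promotion"] / nonzero if nonzero else float("nan"),
        "neutralization_share": (
            counts["neutralization"] / nonzero if nonzero else float("nan")
        ),
    }


# ---------------------------------------------------------------------------
# symmetric-species aggregation


def aggregate_symmetric_species(
    community: Community, non_target_indices: Sequence[int], tol: float = 1e-9
) -> Community:
    """Merge symmetric non-targeted species into one effective species.

    The named species must have consumption niches that map onto each other
    under a permutation of their private resources (species ``i``'s private
    resource is resource ``i``, the m = p convention), equal death rates,
    and equal private supply; the rest of the community must consume the
    private resources interchangeably.  The merged community has one species
    and one resource replacing the group, and reproduces the original's
    steady states and treatment classifications.  Symmetry violations beyond
    ``tol`` (relative to the largest consumption rate) raise ``ValueError``;
    small violations are symmetrized by averaging.
    """
    group = sorted(int(i) for i in non_target_indices)
    m, p = community.m, community.p
    if m != p:
        raise ValueError("aggregation assumes m = p with species i private to resource i")
    if len(group) <= 1:
        return community
    if len(set(group)) != len(group) or group[0] < 0 or group[-1] >= m:
        raise ValueError("invalid group indices")

    R = community.R
    s = community.s
    dr = community.effective_death_rates
    scale = R.max()
    others = [i for i in range(m) if i not in group]
    shared = [mu for mu in range(p) if mu not in group]

    # symmetry checks: group rows agree on shared resources; diagonal
    # (own-private) and off-diagonal (other-private) rates each agree; the
    # remaining species treat the private resources interchangeably
    g_shared = R[np.ix_(group, shared)]
    diag = np.array([R[i, i] for i in group])
    off = np.array([R[i, j] for i in group for j in group if j != i])
    dev = 0.0
    if shared:
        dev = max(dev, np.ptp(g_shared, axis=0).max(initial=0.0))
    dev = max(dev, float(np.ptp(diag)), float(np.ptp(off)) if off.size else 0.0)
    for i in others:
        dev = max(dev, float(np.ptp(R[i, group])))
    dev = max(dev, float(np.ptp(s[group])) * scale / max(s.max(), 1e-300))
    dev = max(dev, float(np.ptp(dr[group])))
    if dev > tol * scale:
        raise ValueError(
            f"group not symmetric within tolerance (deviation {dev:.3g})"
        )

    k = len(group)
    keep = group[0]
    new_species = others + [keep]
    # build reduced matrix: shared resources unchanged, private resources of
    # the group merged into a single column (sum of consumption)
    rows = []
    for i in new_species:
        if i == keep:
            shared_part = g_shared.mean(axis=0) if shared else np.empty(0)
            merged = diag.mean() + (k - 1) * (off.mean() if off.size else 0.0)
            row = np.concatenate([shared_part, [merged]])
        else:
            row = np.concatenate([R[i, shared], [R[i, group].sum()]])
        rows.append(row)
    order = np.argsort(new_species)
    R_new = np.vstack(rows)[order]
    s_new = np.concatenate([s[shared], [s[group].sum()]])
    dr_new = np.array(
        [dr[i] if i != keep else dr[group].mean() for i in new_species]
    )[order]
    return Community(R_new, s_new, community.d, death_rates=dr_new)
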