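"""Core community objects for the chemostat consumer-resource model.

A community of ``m`` species competing for ``p`` substitutable resources in a
chemostat is parameterized by a consumption-rate matrix ``R`` (species x
resources), resource supply rates ``s``, a dilution rate ``d`` shared by all
species, and an antibiotic perturbation expressed either as bactericidal
death rates ``d_i >= 0`` or as bacteriostatic susceptibilities ``b_i >= 1``
(a factor by which species i's consumption rates shrink).  The two
representations are equivalent at steady state when ``b_i = (d + d_i)/d``;
everything downstream works with the bactericidal form.
"""

from __future__ import annotations

import io
import json
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

__all__ = [
    "Community",
    "Trajectory",
    "SteadyState",
    "enzyme_budget",
    "cidal_to_static",
    "static_to_cidal",
    "normalize",
    "evenness",
]


@dataclass(frozen=True)
class Community:
    """A chemostat consumer-resource community.

    Parameters
    ----------
    R : (m, p) array
        Consumption rates; ``R[i, mu]`` is the rate at which species ``i``
        consumes resource ``mu``.  Non-negative, each row has at least one
        strictly positive entry.
    s : (p,) array
        Resource supply rates, non-negative with positive total.
    d : float
        Chemostat dilution rate, positive.
    death_rates : (m,) array, optional
        Bactericidal death rates ``d_i >= 0``.  Mutually exclusive with
        ``susceptibilities``.
    susceptibilities : (m,) array, optional
        Bacteriostatic susceptibilities ``b_i >= 1``.
    """

    R: np.ndarray
    s: np.ndarray
    d: float = 1.0
    death_rates: np.ndarray | None = None
    susceptibilities: np.ndarray | None = None

    def __post_init__(self) -> None:
        R = np.atleast_2d(np.asarray(self.R, dtype=float))
        s = np.asarray(self.s, dtype=float).ravel()
        object.__setattr__(self, "R", R)
        object.__setattr__(self, "s", s)
        m, p = R.shape
        if s.shape != (p,):
            raise ValueError(f"supply vector has length {s.size}, expected {p}")
        if np.any(R < 0):
            raise ValueError("consumption rates must be non-negative")
        if np.any(R.max(axis=1) <= 0):
            raise ValueError("every species must consume at least one resource")
        if np.any(s < 0) or s.sum() <= 0:
            raise ValueError("supply rates must be non-negative with S > 0")
        if self.d <= 0:
            raise ValueError("dilution rate must be positive")
        if self.death_rates is not None and self.susceptibilities is not None:
            raise ValueError(
                "death_rates and susceptibilities are mutually exclusive"
            )
        if self.death_rates is not None:
            dr = np.asarray(self.death_rates, dtype=float).ravel()
            if dr.shape != (m,):
                raise ValueError("death_rates must have length m")
            if np.any(dr < 0):
                raise ValueError("death rates must be non-negative")
            object.__setattr__(self, "death_rates", dr)
        if self.susceptibilities is not None:
            b = np.asarray(self.susceptibilities, dtype=float).ravel()
            if b.shape != (m,):
                raise ValueError("susceptibilities must have length m")
            if np.any(b < 1):
                raise ValueError("susceptibilities must be >= 1")
            object.__setattr__(self, "susceptibilities", b)

    # -- basic dimensions -------------------------------------------------
    @property
    def m(self) -> int:
        return self.R.shape[0]

    @property
    def p(self) -> int:
        return self.R.shape[1]

    @property
    def S(self) -> float:
        """Total resource supply rate."""
        return float(self.s.sum())

    # -- antibiotic representation ----------------------------------------
    @property
    def effective_death_rates(self) -> np.ndarray:
        """Death rates in the bactericidal representation.

        Susceptibilities convert via ``d_i = d (b_i - 1)``; no antibiotic
        means a zero vector.
        """
        if self.death_rates is not None:
            return self.death_rates
        if self.susceptibilities is not None:
            return self.d * (self.susceptibilities - 1.0)
        return np.zeros(self.m)

    @property
    def delta(self) -> np.ndarray:
        """Per-species loss rates ``d + d_i``."""
        return self.d + self.effective_death_rates

    def with_death_rates(self, death_rates: Sequence[float]) -> "Community":
        return replace(
            self,
            death_rates=np.asarray(death_rates, dtype=float),
            susceptibilities=None,
        )

    def restrict(self, species: Sequence[int]) -> "Community":
        """Community restricted to a subset of species (resources unchanged)."""
        idx = np.asarray(list(species), dtype=int)
        dr = self.effective_death_rates[idx]
        return Community(self.R[idx], self.s, self.d, death_rates=dr)

    # -- serialization -----------------------------------------------------
    def to_json(self) -> str:
        obj = {
            "m": self.m,
            "p": self.p,
            "R": self.R.ravel().tolist(),
            "s": self.s.tolist(),
            "d": self.d,
            "death_rates": self.effective_death_rates.tolist(),
        }
        return json.dumps(obj)

    @classmethod
    def from_json(cls, text: str) -> "Community":
        obj = json.loads(text)
        R = np.asarray(obj["R"], dtype=float).reshape(obj["m"], obj["p"])
        return cls(
            R,
            np.asarray(obj["s"], dtype=float),
            float(obj["d"]),
            death_rates=np.asarray(obj["death_rates"], dtype=float),
        )

    def to_csv(self) -> str:
        """CSV layout: a header block (#d, #s) then one species per row."""
        buf = io.StringIO()
        buf.write(f"#d,{float(self.d)!r}\n")
        buf.write("#s," + ",".join(repr(float(x)) for x in self.s) + "\n")
        buf.write(
            "id," + ",".join(f"R_{mu + 1}" for mu in range(self.p)) + ",death_rate\n"
        )
        dr = self.effective_death_rates
        for i in range(self.m):
            row = ",".join(repr(float(x)) for x in self.R[i])
            buf.write(f"{i},{row},{float(dr[i])!r}\n")
        return buf.getvalue()

    @classmethod
    def from_csv(cls, text: str) -> "Community":
        d = 1.0
        s: np.ndarray | None = None
        rows: list[list[float]] = []
        deaths: list[float] = []
        for line in text.strip().splitlines():
            if line.startswith("#d,"):
                d = float(line.split(",", 1)[1])
            elif line.startswith("#s,"):
                s = np.asarray([float(x) for x in line.split(",")[1:]])
            elif line.startswith("id,") or not line.strip():
                continue
            else:
                parts = [float(x) for x in line.split(",")]
                rows.append(parts[1:-1])
                deaths.append(parts[-1])
        if s is None:
            raise ValueError("missing #s header line")
        return cls(np.asarray(rows), s, d, death_rates=np.asarray(deaths))


@dataclass
class Trajectory:
    """Time course of species abundances (times strictly increasing)."""

    times: np.ndarray
    abundances: np.ndarray  # (len(times), m)
    all_extinct: bool = False

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.abundances = np.atleast_2d(np.asarray(self.abundances, dtype=float))

    def to_tidy_csv(self) -> str:
        buf = io.StringIO()
        buf.write("time,species_id,abundance\n")
        for t, row in zip(self.times, self.abundances):
            for i, n in enumerate(row):
                buf.write(f"{t!r},{i},{n!r}\n")
        return buf.getvalue()


@dataclass
class SteadyState:
    """Steady state of a community.

    ``survivors`` indexes species above the extinction threshold; richness is
    their count; ``resource_availabilities`` are the effective steady-state
    resource concentrations ``c*_mu = s_mu / sum_k n*_k R_k,mu`` (``inf`` for
    resources no survivor consumes).
    """

    abundances: np.ndarray
    survivors: tuple[int, ...]
    resource_availabilities: np.ndarray
    converged: bool = True

    def __post_init__(self) -> None:
        self.abundances = np.asarray(self.abundances, dtype=float)
        self.survivors = tuple(int(i) for i in self.survivors)
        self.resource_availabilities = np.asarray(
            self.resource_availabilities, dtype=float
        )

    @property
    def richness(self) -> int:
        return len(self.survivors)

    @property
    def evenness(self) -> float:
        return evenness(self.abundances)


# ---------------------------------------------------------------------------
# operations


def enzyme_budget(community: Community) -> np.ndarray:
    """Total consumption capacity ``E_i = sum_mu R_i,mu`` per species.

    In the bacteriostatic representation the budget shrinks by the
    susceptibility factor ``b_i``.
    """
    E = community.R.sum(axis=1)
    if community.susceptibilities is not None:
        E = E / community.susceptibilities
    return E


def cidal_to_static(community: Community) -> Community:
    """Convert bactericidal death rates to equivalent susceptibilities.

    ``b_i = (d + d_i)/d``; the two forms share survivor sets, and abundances
    map as ``n_static,i = b_i * n_cidal,i``.
    """
    b = community.delta / community.d
    return replace(community, death_rates=None, susceptibilities=b)


def static_to_cidal(community: Community) -> Community:
    """Inverse of :func:`cidal_to_static` (``d_i = d (b_i - 1)``)."""
    return replace(
        community,
        death_rates=community.effective_death_rates,
        susceptibilities=None,
    )


def normalize(community: Community) -> Community:
    """Nondimensionalize to ``d = 1`` and ``S = 1``.

    Uses the substitutions t' = t d, n' = n d/S, R' = R S/d^2, s' = s/S.
    Death rates scale as d_i' = d_i/d so that (d + d_i)' = 1 + d_i'.  The
    survivor set and richness are invariant.
    """
    d, S = community.d, community.S
    return Community(
        community.R * (S / d**2),
        community.s / S,
        1.0,
        death_rates=community.effective_death_rates / d,
    )


def denormalize(community: Community, d: float, S: float) -> Community:
    """Inverse of :func:`normalize` for given original ``d`` and ``S``."""
    return Community(
        community.R * (d**2 / S),
        community.s * S,
        d,
        death_rates=community.effective_death_rates * d,
    )


def evenness(abundances: Sequence[float]) -> float:
    """Effective species number: exponential of the Shannon index.

    Zero abundances contribute nothing (0 ln 0 := 0).  Ranges from 1 (one
    dominant species) to the number of nonzero entries (all equal).
    """
    n = np.asarray(abundances, dtype=float)
    if np.any(n < 0):
        raise ValueError("abundances must be non-negative")
    total = n.sum()
    if total <= 0:
        raise ValueError("at least one abundance must be positive")
    q = n[n > 0] / total
    q = q[q > 0]  # guard against underflow of extreme ratios
    return float(np.exp(-np.sum(q * np.log(q))))
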