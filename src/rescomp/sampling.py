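"""Synthetic community generators.

Two sampling schemes stand in for study data:

* **Random ensembles** — each species' consumption vector is drawn uniformly
  from the unit simplex (so all enzyme budgets equal 1), all resources are
  supplied at equal rates with S = 1, and the dilution rate is 1.  Antibiotic
  death rates are drawn either as a simplex-uniform vector across all species
  or as independent U(0,1) rates on two designated target species.

* **Structured three-species families** — each species' consumption vector
  sits on the segment from the simplex centroid toward its own vertex, at a
  prescribed Euclidean distance from the centroid (the supplied-resource
  point under equal supply).  Distances range over (0, sqrt(2/3)), the
  centroid-to-vertex distance of the unit simplex.  Species 1 and 2 are the
  antibiotic targets; species 3 is untargeted.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .community import Community

__all__ = [
    "MAX_CENTROID_DISTANCE",
    "StructuredFamilySpec",
    "sample_simplex",
    "sample_random_community",
    "build_structured_community",
    "sample_leakage_fractions",
]

#: Euclidean distance from the centroid of the unit 2-simplex to a vertex.
MAX_CENTROID_DISTANCE = float(np.sqrt(2.0 / 3.0))


def sample_simplex(rng: np.random.Generator, dim: int, size: int = 1) -> np.ndarray:
    """Uniform samples from the unit (dim-1)-simplex, shape (size, dim).

    Uses normalized exponentials (the Dirichlet(1,...,1) construction);
    naive normalization of uniforms would not be uniform on the simplex.
    """
    return rng.dirichlet(np.ones(dim), size=size)


def sample_random_community(
    m: int,
    p: int,
    seed: int | np.random.Generator,
    death_scheme: str = "targets",
    targets: tuple[int, int] = (0, 1),
) -> Community:
    """Random community with simplex-uniform consumption vectors.

    ``death_scheme``:

    * ``"targets"`` — death rates i.i.d. U(0,1) on the two ``targets``
      (the random-combination ensemble scheme);
    * ``"simplex"`` — the death-rate vector drawn uniformly from the unit
      simplex across all species (the dose-response ensemble scheme);
    * ``"none"`` — no antibiotic.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if m < 1 or p < 1:
        raise ValueError("m and p must be >= 1")
    R = sample_simplex(rng, p, size=m)
    s = np.full(p, 1.0 / p)
    if death_scheme == "targets":
        dr = np.zeros(m)
        dr[list(targets)] = rng.uniform(0.0, 1.0, size=len(targets))
    elif death_scheme == "simplex":
        dr = sample_simplex(rng, m)[0]
    elif death_scheme == "none":
        dr = np.zeros(m)
    else:
        raise ValueError(f"unknown death_scheme {death_scheme!r}")
    return Community(R, s, 1.0, death_rates=dr)


@dataclass(frozen=True)
class StructuredFamilySpec:
    """Parameters of the structured three-species family.

    ``D_T1``, ``D_T2`` are the centroid distances of the two targeted
    species' consumption vectors, ``D_N`` that of the non-targeted species;
    all lie in (0, sqrt(2/3)).  ``d_1``, ``d_2`` are the death rates applied
    to the targets, in (0, 1).
    """

    D_T1: float
    D_T2: float
    D_N: float
    d_1: float = 0.0
    d_2: float = 0.0

    def __post_init__(self) -> None:
        for name in ("D_T1", "D_T2", "D_N"):
            v = getattr(self, name)
            if not (0.0 <= v <= MAX_CENTROID_DISTANCE):
                raise ValueError(
                    f"{name}={v} outside [0, sqrt(2/3)={MAX_CENTROID_DISTANCE:.4f}]"
                )
        for name in ("d_1", "d_2"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")

    @property
    def D_T(self) -> float:
        """Euclidean distance between the two targets' consumption vectors."""
        v1 = _place_on_axis(0, self.D_T1)
        v2 = _place_on_axis(1, self.D_T2)
        return float(np.linalg.norm(v1 - v2))


def _place_on_axis(vertex: int, distance: float) -> np.ndarray:
    """Point on the centroid-to-vertex axis of the unit 2-simplex."""
    centroid = np.full(3, 1.0 / 3.0)
    direction = np.zeros(3)
    direction[vertex] = 1.0
    direction -= centroid
    return centroid + (distance / MAX_CENTROID_DISTANCE) * direction


def build_structured_community(spec: StructuredFamilySpec) -> Community:
    """Three species / three resources community from a structured spec.

    Species i's consumption vector lies on the centroid-to-vertex-i axis at
    the requested distance; supply is equal (the supplied-resource point is
    the centroid); d = S = 1.  Death rates d_1, d_2 go on species 0 and 1.
    """
    R = np.vstack(
        [
            _place_on_axis(0, spec.D_T1),
            _place_on_axis(1, spec.D_T2),
            _place_on_axis(2, spec.D_N),
        ]
    )
    if np.any(R < -1e-12):
        raise ValueError("placement left the simplex (distance too large)")
    R = np.clip(R, 0.0, None)
    s = np.full(3, 1.0 / 3.0)
    return Community(R, s, 1.0, death_rates=np.array([spec.d_1, spec.d_2, 0.0]))


def sample_leakage_fractions(
    p: int, seed: int | np.random.Generator
) -> np.ndarray:
    """Leakage fractions l_mu drawn i.i.d. from U(0, 0.5)."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if p < 1:
        raise ValueError("p must be >= 1")
    return rng.uniform(0.0, 0.5, size=p)
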