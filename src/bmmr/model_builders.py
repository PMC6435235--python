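"""Process rate matrices U, B, T and the projection matrix A.

The life cycle is decomposed into three simultaneous continuous-time
processes, each with its own rate matrix on the stage space
``(m1, m2, f1, f2, u_1, ..., u_h)``:

- **U** (union formation): single adults leave ``m2``/``f2`` and enter the
  largest union ``u_h`` at rates set by the mating function.  The per-capita
  rates are halved in the union row to avoid double counting a union formed
  from both its male and its female members.
- **B** (births): a union with i females produces offspring at rate i*k,
  split s1 male : (1 - s1) female into the juvenile stages.
- **T** (transitions): juvenile mortality and maturation, adult mortality,
  and union dynamics.  A union ``u_i`` changes when its male leader dies
  (rate mu_m2; returns i females to ``f2``), a female member dies (rate
  mu_f2; shrinks the union to ``u_{i-1}``), or a female departs (divorce
  rate d; shrinks the union and returns one female to ``f2``).  ``u_1``
  dissolves entirely, returning the male to ``m2``.

The projection matrix is the average A = (T + B + U) / 3; its entries
depend on the population only through composition (degree-0 homogeneous),
so the dynamics are frequency-dependent.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .mating import MatingSpec, polygynous_rates
from .stage_space import StageSpace

__all__ = [
    "ModelParams",
    "ProcessMatrices",
    "build_union_matrix",
    "build_birth_matrix",
    "build_transition_matrix",
    "apply_harvest",
    "projection_matrix",
]


@dataclass(frozen=True)
class ModelParams:
    """Vital rates, mating-system, and harvest parameters.

    All rates are per unit time.  ``per_female_union_mortality`` switches
    female mortality inside a union from one death event per union per unit
    time (rate mu_f2, the standard model) to one per female (rate i*mu_f2 in
    ``u_i``); the default is the standard model.
    """

    mu_m1: float = 0.5  # juvenile male mortality
    mu_f1: float = 0.5  # juvenile female mortality
    mu_m2: float = 0.1  # adult male mortality
    mu_f2: float = 0.1  # adult female mortality
    alpha_m: float = 0.5  # male maturation rate
    alpha_f: float = 0.5  # female maturation rate
    d: float = 0.1  # divorce rate (per union)
    k: float = 20.0  # per-female union reproductive rate
    s1: float = 0.5  # primary sex ratio (proportion of offspring male)
    h: int = 1  # maximum harem size
    E: float = 0.0  # total adult harvest rate
    s_h: float = 0.5  # proportion of harvest targeting males
    per_female_union_mortality: bool = False

    def __post_init__(self) -> None:
        for name in ("mu_m1", "mu_f1", "mu_m2", "mu_f2", "alpha_m", "alpha_f", "d", "k", "E"):
            v = getattr(self, name)
            if v < 0:
                raise ValueError(f"{name} must be >= 0, got {v}")
        for name in ("s1", "s_h"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if isinstance(self.h, bool) or not isinstance(self.h, (int, np.integer)):
            raise TypeError(f"h must be an integer, got {self.h!r}")
        if self.h < 1:
            raise ValueError(f"h must be >= 1, got {self.h}")


@dataclass(frozen=True)
class ProcessMatrices:
    """The U, B, T rate matrices and projection matrix A at one composition."""

    U: np.ndarray
    B: np.ndarray
    T: np.ndarray
    A: np.ndarray


def _check_composition(space: StageSpace, n: np.ndarray) -> np.ndarray:
    n = np.asarray(n, dtype=float)
    if n.shape != (space.s,):
        raise ValueError(f"composition has shape {n.shape}, expected ({space.s},)")
    if np.any(n < 0):
        raise ValueError("stage densities must be nonnegative")
    return n


def build_union_matrix(
    space: StageSpace, params: ModelParams, spec: MatingSpec, n: np.ndarray
) -> np.ndarray:
    """Union-formation rate matrix U evaluated at composition ``n``.

    Single males leave ``m2`` at per-capita rate U_m and single females
    leave ``f2`` at h*U_f (a new union absorbs one male and h females); new
    unions enter ``u_h`` at total rate M = (U_m*m2 + U_f*f2) / 2.
    """
    n = _check_composition(space, n)
    h = space.h
    if params.h != h:
        raise ValueError(f"params.h={params.h} does not match stage space h={h}")
    m2, f2 = n[space.M2], n[space.F2]
    _, um, uf = polygynous_rates(spec, m2, f2, h)

    U = np.zeros((space.s, space.s))
    U[space.M2, space.M2] = -um
    U[space.F2, space.F2] = -h * uf
    top = space.union_index(h)
    U[top, space.M2] = 0.5 * um
    U[top, space.F2] = 0.5 * uf
    return U


def build_birth_matrix(space: StageSpace, params: ModelParams) -> np.ndarray:
    """Birth rate matrix B: union ``u_i`` bears offspring at rate i*k."""
    B = np.zeros((space.s, space.s))
    for i in range(1, space.h + 1):
        j = space.union_index(i)
        B[space.M1, j] = i * params.k * params.s1
        B[space.F1, j] = i * params.k * (1.0 - params.s1)
    return B


def build_transition_matrix(space: StageSpace, params: ModelParams) -> np.ndarray:
    """Transition rate matrix T: mortality, maturation, union dynamics."""
    p = params
    T = np.zeros((space.s, space.s))
    # juveniles: die or mature
    T[space.M1, space.M1] = -(p.mu_m1 + p.alpha_m)
    T[space.M2, space.M1] = p.alpha_m
    T[space.F1, space.F1] = -(p.mu_f1 + p.alpha_f)
    T[space.F2, space.F1] = p.alpha_f
    # single adults: die
    T[space.M2, space.M2] = -p.mu_m2
    T[space.F2, space.F2] = -p.mu_f2
    # unions: leader death, member death, divorce
    for i in range(1, space.h + 1):
        j = space.union_index(i)
        fdeath = i * p.mu_f2 if p.per_female_union_mortality else p.mu_f2
        T[j, j] = -(p.mu_m2 + fdeath + p.d)
        # leader death frees i females; divorce frees one
        T[space.F2, j] = i * p.mu_m2 + p.d
        if i == 1:
            # union dissolves: male back to m2 (female flux is in T[F2, j])
            T[space.M2, j] = fdeath + p.d
        else:
            T[space.union_index(i - 1), j] = fdeath + p.d
    return T


def apply_harvest(params: ModelParams) -> ModelParams:
    """Fold adult harvest into the mortality rates.

    Adds E*s_h to adult male mortality and E*(1 - s_h) to adult female
    mortality (juveniles are not harvested), and resets E to 0 in the
    returned copy so harvest cannot be applied twice.
    """
    if params.E == 0.0:
        return params
    return replace(
        params,
        mu_m2=params.mu_m2 + params.E * params.s_h,
        mu_f2=params.mu_f2 + params.E * (1.0 - params.s_h),
        E=0.0,
    )


def projection_matrix(
    space: StageSpace, params: ModelParams, spec: MatingSpec, n: np.ndarray
) -> ProcessMatrices:
    """Assemble A = (T + B + U[n]) / 3 with all three process matrices.

    Harvest must already be folded into ``params`` (see
    :func:`apply_harvest`); ``E`` carried by ``params`` is ignored here.
    """
    U = build_union_matrix(space, params, spec, n)
    B = build_birth_matrix(space, params)
    T = build_transition_matrix(space, params)
    A = (T + B + U) / 3.0
    return ProcessMatrices(U=U, B=B, T=T, A=A)
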