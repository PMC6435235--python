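"""Mating (union-formation) functions.

The total mating function M(m, f) gives the rate at which new unions form
from available single adult males m and females f (unions per unit time).
All families implemented here belong to the generalized weighted-mean
(Hölder) family

    M(m, f) = scale * [beta * f**a + (1 - beta) * m**a] ** (1/a),   a < 0,

which is degree-1 homogeneous in (m, f), vanishes when either sex is absent,
and increases in both arguments.  Named special cases:

- ``harmonic``:  2mf / (m + f)        (beta = 1/2, a = -1)
- ``geometric``: sqrt(mf)             (a -> 0 limit)
- ``minimum``:   min(m, f)            (a -> -inf limit)

Per-capita rates are U_m = M/m and U_f = M/f, each degree-0 homogeneous.
For polygyny with maximum harem size h, new unions absorb one male and h
females, so the female argument is the number of *prospective harems* f/h:

    M = 2 m (f/h) / (m + f/h) = 2 m f / (h m + f)   (harmonic case).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

__all__ = ["MatingSpec", "total_mating_rate", "per_capita_rates", "polygynous_rates"]

_FAMILIES = ("harmonic", "geometric", "minimum", "generalized")


@dataclass(frozen=True)
class MatingSpec:
    """Mating-function family and parameters.

    Parameters
    ----------
    family : {"harmonic", "geometric", "minimum", "generalized"}
        Named families fix ``beta = 1/2``; ``generalized`` uses the Hölder
        form with explicit ``beta`` (weight on females) and exponent
        ``alpha_exp < 0``.
    beta : float
        Weight on the female density, in [0, 1].  Only used by
        ``generalized``.
    alpha_exp : float
        Hölder exponent, < 0.  Only used by ``generalized``
        (``alpha_exp = -1`` recovers the harmonic family).
    scale : float
        Overall multiplier on M; the default 1.0 makes
        ``generalized(beta=1/2, alpha_exp=-1)`` coincide exactly with
        ``harmonic``.
    """

    family: str = "harmonic"
    beta: float = 0.5
    alpha_exp: float = -1.0
    scale: float = 1.0

    def __post_init__(self) -> None:
        if self.family not in _FAMILIES:
            raise ValueError(
                f"unknown mating family {self.family!r}; expected one of {_FAMILIES}"
            )
        if not 0.0 <= self.beta <= 1.0:
            raise ValueError(f"beta must be in [0, 1], got {self.beta}")
        if self.family == "generalized" and not self.alpha_exp < 0:
            raise ValueError(f"alpha_exp must be < 0, got {self.alpha_exp}")
        if self.scale <= 0:
            raise ValueError(f"scale must be positive, got {self.scale}")


def _check_nonneg(m: float, f: float) -> None:
    if m < 0 or f < 0:
        raise ValueError(f"densities must be nonnegative, got m={m}, f={f}")


def total_mating_rate(spec: MatingSpec, m: float, f: float) -> float:
    """Total union-formation rate M(m, f), unions per unit time.

    Degree-1 homogeneous; zero whenever either density is zero.
    """
    _check_nonneg(m, f)
    if m == 0.0 or f == 0.0:
        return 0.0
    if spec.family == "harmonic":
        return spec.scale * 2.0 * m * f / (m + f)
    if spec.family == "geometric":
        return spec.scale * math.sqrt(m * f)
    if spec.family == "minimum":
        return spec.scale * min(m, f)
    # generalized Hölder mean, computed in the smaller density's units:
    # both ratio terms then lie in (0, 1], so no overflow at very
    # negative exponents, and underflow of the larger-density term is
    # benign (it vanishes from the mean in exact arithmetic too)
    a, b = spec.alpha_exp, spec.beta
    if b == 0.0:
        return spec.scale * m
    if b == 1.0:
        return spec.scale * f
    base = min(m, f)
    term = b * (f / base) ** a + (1.0 - b) * (m / base) ** a
    return spec.scale * base * term ** (1.0 / a)


def _own_sex_limits(spec: MatingSpec) -> tuple[float, float]:
    """Finite limits of (U_m as m->0, U_f as f->0) where they exist.

    Geometric has no finite limit; 0 is returned there (the rate always
    multiplies a zero density, so no flux is affected).
    """
    if spec.family == "harmonic":
        return 2.0 * spec.scale, 2.0 * spec.scale
    if spec.family == "minimum":
        return spec.scale, spec.scale
    if spec.family == "geometric":
        return 0.0, 0.0
    a, b = spec.alpha_exp, spec.beta
    um = spec.scale * (1.0 - b) ** (1.0 / a) if b < 1.0 else 0.0
    uf = spec.scale * b ** (1.0 / a) if b > 0.0 else 0.0
    return um, uf


def per_capita_rates(spec: MatingSpec, m: float, f: float) -> tuple[float, float]:
    """Per-capita mating rates (U_m, U_f) with U_m*m = U_f*f = M.

    When the own-sex density is zero with the other sex positive, the rate
    takes its finite algebraic limit (e.g. harmonic U_m -> 2 as m -> 0); it
    then multiplies a zero density, so no flux results.  Both rates are 0
    when m + f = 0.
    """
    _check_nonneg(m, f)
    if m == 0.0 and f == 0.0:
        return 0.0, 0.0
    lim_m, lim_f = _own_sex_limits(spec)
    if m == 0.0:
        return lim_m, 0.0
    if f == 0.0:
        return 0.0, lim_f
    mtot = total_mating_rate(spec, m, f)
    return mtot / m, mtot / f


def polygynous_rates(
    spec: MatingSpec, m2: float, f2: float, h: int
) -> tuple[float, float, float]:
    """Union formation with prospective harems: (M, U_m, U_f).

    Replaces the single-female density by the number of prospective harems
    f2/h, so for the harmonic family

        M = 2 m2 f2 / (h m2 + f2),
        U_m = 2 f2 / (h m2 + f2),   U_f = 2 m2 / (h m2 + f2),

    with U_m*m2 = U_f*f2 = M.  ``h = 1`` reduces to the monogamous rates.
    """
    _check_nonneg(m2, f2)
    if h < 1:
        raise ValueError(f"harem size h must be >= 1, got {h}")
    if m2 == 0.0 and f2 == 0.0:
        return 0.0, 0.0, 0.0
    mtot = total_mating_rate(spec, m2, f2 / h)
    if m2 == 0.0:
        um, _ = _own_sex_limits(spec)
        return 0.0, um, 0.0
    if f2 == 0.0:
        _, uf = _own_sex_limits(spec)
        return 0.0, 0.0, uf / h
    return mtot, mtot / m2, mtot / f2
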