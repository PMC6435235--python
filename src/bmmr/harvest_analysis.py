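"""Population-level summaries and harvest scenario sweeps.

Outputs of interest at the stable stage distribution:

- the long-term growth rate lambda,
- the secondary sex ratio s2 (proportion of *adults* that is male,
  counting individuals inside unions: a union u_i holds 1 male and i
  females),
- the proportion of adults that is mated (inside some union stage).

``run_sweep`` evaluates these over a Cartesian grid of parameter values
(harvest bias s_h, harvest rate E, divorce rate d, harem size h, ...),
together with the change in lambda and s2 relative to the matched
unharvested (E = 0) baseline.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import replace

import numpy as np
import pandas as pd

from .dynamics import equilibrate
from .mating import MatingSpec
from .model_builders import ModelParams, apply_harvest
from .stage_space import StageSpace, make_stage_space

__all__ = ["secondary_sex_ratio", "proportion_mated", "run_sweep"]

logger = logging.getLogger("bmmr")

#: columns of a sweep table that are always present, after the swept parameters
SWEEP_COLUMNS = ["lam", "s2", "prop_mated", "delta_lam", "delta_s2", "converged"]


def secondary_sex_ratio(space: StageSpace, p: np.ndarray) -> float:
    """Proportion of adults that is male, counting union members.

    Union stage u_i contributes 1 male and i females per unit.
    """
    p = np.asarray(p, dtype=float)
    males = float(space.adult_males @ p)
    adults = float(space.adults @ p)
    if adults <= 0:
        raise ZeroDivisionError("no adults in the population; s2 undefined")
    return males / adults


def proportion_mated(space: StageSpace, p: np.ndarray) -> float:
    """Proportion of adult individuals that is inside a union."""
    p = np.asarray(p, dtype=float)
    adults_per_stage = space.adults.astype(float)
    mated = float(adults_per_stage[space.union_slice] @ p[space.union_slice])
    adults = float(adults_per_stage @ p)
    if adults <= 0:
        raise ZeroDivisionError("no adults in the population; proportion undefined")
    return mated / adults


def _evaluate(
    params: ModelParams, spec: MatingSpec, **integrator
) -> tuple[float, float, float, bool]:
    """Equilibrate one parameterization; return (lam, s2, prop_mated, converged)."""
    space = make_stage_space(params.h)
    res = equilibrate(space, apply_harvest(params), spec, **integrator)
    return (
        res.lam,
        secondary_sex_ratio(space, res.p_hat),
        proportion_mated(space, res.p_hat),
        res.converged,
    )


def run_sweep(
    base_params: ModelParams,
    grid: dict[str, list],
    spec: MatingSpec | None = None,
    **integrator,
) -> pd.DataFrame:
    """Sweep a parameter grid and tabulate equilibrium population outputs.

    Parameters
    ----------
    base_params : ModelParams
        Values for every parameter not being swept.
    grid : dict
        Maps ModelParams field names to lists of values; the sweep covers
        the Cartesian product.
    spec : MatingSpec, optional
        Mating function (harmonic by default).
    **integrator
        Forwarded to :func:`bmmr.dynamics.equilibrate` (tol, t_max, ...).

    Returns
    -------
    DataFrame
        One row per grid point with columns: the swept parameters, ``lam``,
        ``s2``, ``prop_mated``, ``delta_lam``, ``delta_s2`` (changes
        relative to the same parameter vector with E = 0), ``converged``.
        Non-converged points are flagged, never dropped.  The sweep is
        fully deterministic.
    """
    if spec is None:
        spec = MatingSpec()
    unknown = [k for k in grid if k not in ModelParams.__dataclass_fields__]
    if unknown:
        raise KeyError(f"unknown sweep parameter(s): {unknown}")

    names = list(grid)
    baseline_cache: dict[tuple, tuple] = {}
    rows = []
    for combo in itertools.product(*(grid[name] for name in names)):
        params = replace(base_params, **dict(zip(names, combo)))
        lam, s2, mated, conv = _evaluate(params, spec, **integrator)

        # baseline: identical parameters with harvest switched off
        base = replace(params, E=0.0)
        key = tuple(getattr(base, f) for f in ModelParams.__dataclass_fields__)
        if key not in baseline_cache:
            if params.E == 0.0:
                baseline_cache[key] = (lam, s2, mated, conv)
            else:
                baseline_cache[key] = _evaluate(base, spec, **integrator)
        lam0, s20, _, conv0 = baseline_cache[key]

        row = dict(zip(names, combo))
        row.update(
            lam=lam,
            s2=s2,
            prop_mated=mated,
            delta_lam=lam - lam0,
            delta_s2=s2 - s20,
            converged=bool(conv and conv0),
        )
        rows.append(row)
        logger.debug("sweep point %s: lam=%.6g s2=%.6g", dict(zip(names, combo)), lam, s2)

    return pd.DataFrame(rows, columns=names + SWEEP_COLUMNS)
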