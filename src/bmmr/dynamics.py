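"""Density and frequency dynamics, equilibration, and growth rate.

The density dynamics are dn/dt = A[n] n with A = (T + B + U[n]) / 3.
Because every entry of A is degree-0 homogeneous in n, the dynamics of the
composition p = n / ||n||_1 close on the simplex:

    dp/dt = (I - p 1') A[p] p.

Frequency-dependent models of this type generally converge to a stable
stage distribution p_hat; the population then grows exponentially at the
Malthusian rate lambda, the dominant (largest-real-part) eigenvalue of
A[p_hat], whose right eigenvector w is proportional to p_hat.

Equilibration integrates the simplex dynamics with an adaptive
Runge-Kutta 4(5) scheme in fixed-length checkpoint windows, renormalizing
at checkpoints and declaring convergence when both the windowed change in p
and the residual ||dp/dt|| fall below tolerance.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.integrate import solve_ivp
from scipy.linalg import eig

from .mating import MatingSpec
from .model_builders import (
    ModelParams,
    build_birth_matrix,
    build_transition_matrix,
    build_union_matrix,
    projection_matrix,
)
from .stage_space import StageSpace

__all__ = [
    "PopulationState",
    "EquilibriumResult",
    "density_rhs",
    "frequency_rhs",
    "integrate_frequencies",
    "integrate_densities",
    "growth_rate_and_structure",
    "equilibrate",
]

#: default integrator settings; step tolerances sit two decades below the
#: convergence tolerance so integrator noise cannot mask equilibrium
RTOL = 1e-10
ATOL = 1e-12
CONV_TOL = 1e-10
CHECKPOINT = 10.0
T_MAX = 1e4


@dataclass(frozen=True)
class PopulationState:
    """Stage densities n, composition p = n/||n||_1, and time t."""

    n: np.ndarray
    p: np.ndarray
    t: float


@dataclass(frozen=True)
class EquilibriumResult:
    """Converged stage structure and long-term growth rate.

    Attributes
    ----------
    p_hat : ndarray
        Equilibrium stage-frequency vector (sums to 1).
    lam : float
        Long-term growth rate; dominant eigenvalue of A[p_hat] (may be
        negative for declining populations).
    w : ndarray
        Dominant right eigenvector, nonnegative, normalized to sum 1;
        coincides with ``p_hat`` at a true equilibrium.
    converged : bool
        Whether the convergence criteria were met before ``t_final``.
    residual : float
        ||dp/dt||_inf at ``p_hat``.
    t_final : float
        Integration time used.
    """

    p_hat: np.ndarray
    lam: float
    w: np.ndarray
    converged: bool
    residual: float
    t_final: float


def _check_simplex(space: StageSpace, p: np.ndarray, tol: float = 1e-6) -> np.ndarray:
    p = np.asarray(p, dtype=float)
    if p.shape != (space.s,):
        raise ValueError(f"frequency vector has shape {p.shape}, expected ({space.s},)")
    if np.any(p < -tol) or abs(p.sum() - 1.0) > tol:
        raise ValueError(
            f"p is not on the simplex (min {p.min():.3g}, sum {p.sum():.12g})"
        )
    return p


def density_rhs(
    space: StageSpace, params: ModelParams, spec: MatingSpec, n: np.ndarray
) -> np.ndarray:
    """Right-hand side A[n] n of the density dynamics."""
    n = np.asarray(n, dtype=float)
    if np.any(n < 0):
        raise ValueError("stage densities must be nonnegative")
    A = projection_matrix(space, params, spec, n).A
    return A @ n


def frequency_rhs(
    space: StageSpace, params: ModelParams, spec: MatingSpec, p: np.ndarray
) -> np.ndarray:
    """Simplex-tangent right-hand side (I - p 1') A[p] p.

    The components sum to zero in exact arithmetic, so trajectories stay on
    the simplex.
    """
    p = _check_simplex(space, p)
    A = projection_matrix(space, params, spec, np.clip(p, 0.0, None)).A
    Ap = A @ p
    return Ap - p * Ap.sum()


def _uniform_p0(space: StageSpace) -> np.ndarray:
    return np.full(space.s, 1.0 / space.s)


def integrate_frequencies(
    space: StageSpace,
    params: ModelParams,
    spec: MatingSpec,
    p0: np.ndarray | None = None,
    tol: float = CONV_TOL,
    t_max: float = T_MAX,
    checkpoint: float = CHECKPOINT,
    rtol: float = RTOL,
    atol: float = ATOL,
) -> tuple[np.ndarray, np.ndarray, EquilibriumResult]:
    """Integrate the frequency dynamics until the composition converges.

    Integration proceeds in windows of length ``checkpoint``; at each
    checkpoint, round-off negatives are clipped and p is renormalized.
    Convergence requires both max|Delta p| over the window and
    ||dp/dt||_inf to fall below ``tol``.

    Returns
    -------
    times : ndarray
        Checkpoint times (starting at 0).
    trajectory : ndarray, shape (len(times), s)
        Composition at each checkpoint.
    result : EquilibriumResult
        ``converged`` is False (never an exception) if ``t_max`` is reached
        first.
    """
    if tol <= 0:
        raise ValueError(f"tol must be positive, got {tol}")
    p = _uniform_p0(space) if p0 is None else _check_simplex(space, p0)
    p = np.clip(p, 0.0, None)
    p = p / p.sum()

    # B and T do not depend on the composition; only U must be rebuilt
    BT = build_birth_matrix(space, params) + build_transition_matrix(space, params)

    def rhs(_t: float, y: np.ndarray) -> np.ndarray:
        yc = np.clip(y, 0.0, None)
        A = (BT + build_union_matrix(space, params, spec, yc)) / 3.0
        Ay = A @ y
        return Ay - y * Ay.sum()

    times = [0.0]
    traj = [p.copy()]
    t = 0.0
    converged = False
    residual = float(np.max(np.abs(rhs(0.0, p))))
    if residual < tol:
        converged = True  # already at equilibrium
    while not converged and t < t_max:
        sol = solve_ivp(
            rhs, (t, t + checkpoint), p, method="RK45", rtol=rtol, atol=atol
        )
        if not sol.success:  # pragma: no cover - smooth system
            break
        q = np.clip(sol.y[:, -1], 0.0, None)
        q /= q.sum()
        t = float(sol.t[-1])
        delta = float(np.max(np.abs(q - p)))
        p = q
        times.append(t)
        traj.append(p.copy())
        residual = float(np.max(np.abs(rhs(t, p))))
        if delta < tol and residual < tol:
            converged = True

    lam, w = growth_rate_and_structure(space, params, spec, p)
    result = EquilibriumResult(
        p_hat=p, lam=lam, w=w, converged=converged, residual=residual, t_final=t
    )
    return np.asarray(times), np.asarray(traj), result


def integrate_densities(
    space: StageSpace,
    params: ModelParams,
    spec: MatingSpec,
    n0: np.ndarray,
    t_span: tuple[float, float],
    t_eval: np.ndarray | None = None,
    rtol: float = RTOL,
    atol: float = ATOL,
) -> tuple[np.ndarray, np.ndarray]:
    """Integrate the density dynamics dn/dt = A[n] n directly.

    Used mainly as an independent check on the frequency route: the log of
    total density grows asymptotically with slope lambda.  Returns
    ``(times, densities)`` with one row of ``densities`` per time.
    """
    n0 = np.asarray(n0, dtype=float)
    if np.any(n0 < 0):
        raise ValueError("initial densities must be nonnegative")
    BT = build_birth_matrix(space, params) + build_transition_matrix(space, params)

    def rhs(_t: float, y: np.ndarray) -> np.ndarray:
        yc = np.clip(y, 0.0, None)
        A = (BT + build_union_matrix(space, params, spec, yc)) / 3.0
        return A @ y

    sol = solve_ivp(rhs, t_span, n0, method="RK45", t_eval=t_eval, rtol=rtol, atol=atol)
    return sol.t, sol.y.T


def growth_rate_and_structure(
    space: StageSpace,
    params: ModelParams,
    spec: MatingSpec,
    p_hat: np.ndarray,
    ambiguity_tol: float = 1e-9,
) -> tuple[float, np.ndarray]:
    """Dominant eigenvalue and right eigenvector of A[p_hat].

    ``lam`` is the eigenvalue with largest real part (continuous-time
    convention: growth goes like exp(lam*t)); it is real for these matrices,
    whose off-diagonals are nonnegative.  ``w`` is rescaled nonnegative with
    unit sum.  An ambiguous dominant pair (tie in real part within
    ``ambiguity_tol``) triggers a warning; a genuinely complex dominant
    eigenvalue or a sign-indefinite eigenvector raises.
    """
    p_hat = _check_simplex(space, p_hat)
    A = projection_matrix(space, params, spec, np.clip(p_hat, 0.0, None)).A
    vals, vecs = eig(A)
    order = np.argsort(vals.real)[::-1]
    vals, vecs = vals[order], vecs[:, order]
    lam = vals[0]
    if abs(lam.imag) > ambiguity_tol * max(1.0, abs(lam.real)):
        raise ArithmeticError(
            f"dominant eigenvalue is complex: {lam:.6g}; eigenvalues {vals[:3]}"
        )
    ties = np.sum(np.abs(vals.real - lam.real) < ambiguity_tol)
    if ties > 2:  # a conjugate subdominant pair at the same real part counts too
        warnings.warn(
            f"ambiguous dominant eigenvalue: {ties} eigenvalues within "
            f"{ambiguity_tol} of {lam.real:.6g}",
            stacklevel=2,
        )
    w = vecs[:, 0]
    if np.max(np.abs(w.imag)) > 1e-8:
        raise ArithmeticError("dominant eigenvector has a non-real component")
    w = w.real
    # fix sign so the eigenvector is nonnegative
    if w.sum() < 0:
        w = -w
    if np.min(w) < -1e-8 * max(1.0, np.max(np.abs(w))):
        raise ArithmeticError(
            f"dominant eigenvector is sign-indefinite: min {w.min():.3g}"
        )
    w = np.clip(w, 0.0, None)
    w /= w.sum()
    return float(lam.real), w


def equilibrate(
    space: StageSpace,
    params: ModelParams,
    spec: MatingSpec,
    p0: np.ndarray | None = None,
    **kwargs,
) -> EquilibriumResult:
    """Convenience wrapper: integrate to equilibrium, discard the trajectory."""
    _, _, result = integrate_frequencies(space, params, spec, p0=p0, **kwargs)
    return result
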