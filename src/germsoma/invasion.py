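"""Deterministic adaptive-dynamics analysis of the colony model.

Invasion fitness
----------------
With ecology fast relative to evolution, a resident population with
monomorphic colony components ``(F_r, V_r)`` sits at its carrying capacity
``K_r = K0 * V_r * (S*F_r - 1)/(b - 1)``. A rare mutant founder with
components ``(F_m, V_m)`` then has invasion fitness

.. math::

    \\lambda(m; r) = \\frac{S F_m}{1 + (V_r/V_m)(S F_r - 1)},

which equals 1 at ``m = r`` and is approximately ``(F_m V_m)/(F_r V_r)``
when ``S F_r \\gg 1``. Its log-derivative at the resident decomposes as

.. math::

    \\partial_z \\ln\\lambda = \\partial_z \\ln F + q\\, \\partial_z \\ln V,
    \\qquad q = 1 - \\frac{1}{S F_r},

so viability (the colony-level component) is selected with weight ``q < 1``:
the residue of the individual-vs-colony conflict. ``q -> 1`` as colonies
grow large.

Major loci (no regulation, ``g = s = 0``)
-----------------------------------------
The gradients are ``D_x = alpha/x - q*beta/(1-x)`` and
``D_y = q*alpha/y - beta/(1-y)``; at the joint root
``x_hat = alpha/(alpha + q*beta) > alpha/(alpha+beta) > y_hat =
q*alpha/(q*alpha + beta)``, and eliminating ``q`` gives the equilibrium
relation ``alpha**2 (1-x)(1-y) = beta**2 x y``. Both effects converge to
the common limit ``alpha/(alpha+beta)`` as ``S -> inf``.

Regulatory loci
---------------
At the large-colony major-locus optimum the no-regulation state is a
singular point of the ``(g, s)`` dynamics; its local stability is governed
by the (symmetric) Jacobian of the linearized selection gradients, computed
here both in closed form and by finite differences of the invasion fitness.
For strong trade-offs the differentiated corner ``x = y = 1`` carries a
singular suppressor value ``g = s = c * sqrt(beta/2)``; when plasticity is
cheap (``c >= sqrt(2/beta)``) complete suppression (``g = s = 1``) evolves
instead.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import NamedTuple

import numpy as np
from scipy.optimize import brentq

from . import model
from .params import ModelParams, ParameterError

__all__ = [
    "TraitPoint",
    "EquilibriumResult",
    "StabilityResult",
    "ResidentNotViableError",
    "invasion_fitness",
    "numeric_selection_gradients",
    "selection_gradients_major",
    "solve_major_equilibrium",
    "selection_gradients_minor",
    "linearized_minor_gradients",
    "no_regulation_stability",
    "stability_boundary_curve",
    "minor_singular_point",
]

#: colony size used to emulate the ``S -> inf`` regime numerically
_BIG_DIVISIONS = 24


class ResidentNotViableError(ValueError):
    """The resident population has non-positive carrying capacity."""


class TraitPoint(NamedTuple):
    """Resident (or mutant) trait values."""

    x: float
    y: float
    g: float = 0.0
    s: float = 0.0


@dataclass
class EquilibriumResult:
    """Solution of a singular-point problem."""

    x_hat: float
    y_hat: float
    g_hat: float | None = None
    s_hat: float | None = None
    residual: float = 0.0
    converged: bool = True
    feasible: bool = True
    boundary: bool = False
    exists: bool = True


@dataclass
class StabilityResult:
    """Local stability verdict for the no-regulation equilibrium."""

    stable: bool
    margin: float            # max real eigenvalue of the (g, s) Jacobian
    method: str              # "closed-form" | "finite-difference"


def _components(point: TraitPoint, params: ModelParams):
    return model.monomorphic_colony_components(
        point.x, point.y, point.g, point.s, params)


def invasion_fitness(mutant: TraitPoint, resident: TraitPoint,
                     params: ModelParams) -> float:
    """Expected offspring colonies of a rare mutant founder at resident K."""
    mutant, resident = TraitPoint(*mutant), TraitPoint(*resident)
    F_r, V_r = _components(resident, params)
    if params.S * F_r <= 1.0 or V_r <= 0.0:
        raise ResidentNotViableError(
            f"resident {tuple(resident)} has carrying capacity <= 0")
    F_m, V_m = _components(mutant, params)
    if V_m <= 0.0:
        return 0.0
    return float(params.S * F_m / (1.0 + (V_r / V_m) * (params.S * F_r - 1.0)))


def numeric_selection_gradients(point: TraitPoint, params: ModelParams,
                                step: float = 1e-6) -> np.ndarray:
    """Central-difference gradient of invasion fitness in the mutant traits.

    Independent numerical oracle for every closed-form expression in this
    module (the invasion fitness at the resident equals 1, so the plain
    derivative coincides with the log-derivative).
    """
    point = TraitPoint(*point)
    grads = np.empty(4)
    for i in range(4):
        up = np.asarray(point, dtype=float)
        dn = up.copy()
        up[i] += step
        dn[i] -= step
        grads[i] = (invasion_fitness(TraitPoint(*up), point, params)
                    - invasion_fitness(TraitPoint(*dn), point, params)
                    ) / (2.0 * step)
    return grads


def _viability_weight(F: float, params: ModelParams,
                      large_S: bool) -> float:
    if large_S:
        return 1.0
    SF = params.S * F
    if SF <= 1.0:
        raise ResidentNotViableError(
            "resident fertility too low for a viable population (S*F <= 1)")
    return 1.0 - 1.0 / SF


def selection_gradients_major(x: float, y: float, params: ModelParams,
                              large_S: bool = False):
    """Invasion-fitness gradients in (x, y) with regulation absent."""
    if not (0.0 < x < 1.0 and 0.0 < y < 1.0):
        raise ParameterError("gradients require interior x, y")
    a, be = params.alpha, params.beta
    f = x ** a * (1.0 - y) ** be
    q = _viability_weight(f, params, large_S)
    D_x = a / x - q * be / (1.0 - x)
    D_y = q * a / y - be / (1.0 - y)
    return D_x, D_y


def solve_major_equilibrium(params: ModelParams,
                            large_S: bool = False) -> EquilibriumResult:
    """Singular point of the major loci with no regulation.

    Solved by one-dimensional bracketed root finding in the viability
    weight ``q`` (both gradient equations are solved exactly for given
    ``q``; the root closes the self-consistency ``q = 1 - 1/(S f)``).
    In the large-colony limit the equilibrium is the symmetric point
    ``x_hat = y_hat = alpha/(alpha + beta)``. With trade-offs absent
    (``beta = 0``) both effects fix at the boundary 1.
    """
    a, be = params.alpha, params.beta
    if be == 0.0:
        return EquilibriumResult(1.0, 1.0, residual=0.0, boundary=True)
    if large_S:
        xh = a / (a + be)
        return EquilibriumResult(xh, xh, residual=0.0)

    def x_of(q):
        return a / (a + q * be)

    def y_of(q):
        return q * a / (q * a + be)

    def fert(q):
        return x_of(q) ** a * (1.0 - y_of(q)) ** be

    def h(q):
        return q - 1.0 + 1.0 / (params.S * fert(q))

    lo, hi = 1e-12, 1.0
    if h(lo) >= 0.0:
        # even a maximally fertile resident cannot replace itself
        return EquilibriumResult(np.nan, np.nan, residual=np.inf,
                                 converged=False, feasible=False,
                                 exists=False)
    q = brentq(h, lo, hi, xtol=1e-15, rtol=8.9e-16)
    xh, yh = x_of(q), y_of(q)
    D = selection_gradients_major(xh, yh, params)
    return EquilibriumResult(xh, yh, residual=float(np.max(np.abs(D))),
                             converged=True)


def selection_gradients_minor(point: TraitPoint, params: ModelParams,
                              large_S: bool = False) -> np.ndarray:
    """Closed-form invasion-fitness gradients in (x, y, g, s).

    Built from the monomorphic-colony decomposition
    ``F = p f_g + (1-p) f_s``, ``V = p v_g + (1-p) v_s`` with the
    role-specific components of the core algebra; requires an interior
    resident point.
    """
    x, y, g, s = TraitPoint(*point)
    if not (0.0 < x < 1.0 and 0.0 < y < 1.0):
        raise ParameterError("closed-form gradients require interior x, y")
    a, be, c, p = params.alpha, params.beta, params.cost_scale, params.p
    ybar = (1.0 - g) * y          # expressed somatic effect in germ cells
    xbar = (1.0 - s) * x          # expressed reproductive effect in soma
    phi_g = math.exp(-((g / c) ** 2))
    phi_s = math.exp(-((s / c) ** 2))

    f_g = x ** a * (1.0 - ybar) ** be * phi_g
    f_s = xbar ** a * (1.0 - y) ** be
    v_g = ybar ** a * (1.0 - x) ** be
    v_s = y ** a * (1.0 - xbar) ** be * phi_s
    F = p * f_g + (1.0 - p) * f_s
    V = p * v_g + (1.0 - p) * v_s
    q = _viability_weight(F, params, large_S)

    dF = np.array([
        p * a * f_g / x + (1.0 - p) * a * f_s / x,
        -p * be * (1.0 - g) * f_g / (1.0 - ybar)
        - (1.0 - p) * be * f_s / (1.0 - y),
        p * f_g * (be * y / (1.0 - ybar) - 2.0 * g / c ** 2),
        -(1.0 - p) * a * f_s / (1.0 - s),
    ])
    dV = np.array([
        -p * be * v_g / (1.0 - x)
        - (1.0 - p) * be * (1.0 - s) * v_s / (1.0 - xbar),
        p * a * v_g / y + (1.0 - p) * a * v_s / y,
        -p * a * v_g / (1.0 - g),
        (1.0 - p) * v_s * (be * x / (1.0 - xbar) - 2.0 * s / c ** 2),
    ])
    return dF / F + q * dV / V


def linearized_minor_gradients(g: float, s: float,
                               params: ModelParams) -> np.ndarray:
    """First-order (g, s) selection gradients near the no-regulation state.

    Valid in the large-colony limit at the major-locus optimum
    ``x = y = alpha/(alpha+beta)``; the gradients vanish at ``g = s = 0``
    (the plasticity cost has zero slope there) and are linear in ``(g, s)``
    to leading order.
    """
    J = _stability_jacobian(params)
    return J @ np.array([g, s])


def _stability_jacobian(params: ModelParams) -> np.ndarray:
    a, be, c, p = params.alpha, params.beta, params.cost_scale, params.p
    if be == 0.0:
        raise ParameterError("no-regulation stability requires beta > 0")
    diag = 2 * a ** 2 - a ** 2 / be - a - 2.0 / c ** 2
    a_g = diag - 2 * a ** 2 * p
    a_s = diag - 2 * a ** 2 * (1.0 - p)
    off = 2 * a ** 2
    return np.array([
        [p * a_g, p * off * (1.0 - p)],
        [(1.0 - p) * off * p, (1.0 - p) * a_s],
    ])


def _numeric_stability_jacobian(params: ModelParams,
                                step: float = 1e-4) -> np.ndarray:
    """Jacobian of the numeric (g, s) gradient map at the no-regulation
    state, via central differences of the invasion fitness at ``S = 2**24``
    (emulating the large-colony limit) — the independent oracle route."""
    big = params.with_(n_divisions=_BIG_DIVISIONS)
    xh = big.alpha / (big.alpha + big.beta)

    def grad(g, s):
        return numeric_selection_gradients(
            TraitPoint(xh, xh, g, s), big, step=1e-6)[2:]

    J = np.empty((2, 2))
    J[:, 0] = (grad(step, 0.0) - grad(-step, 0.0)) / (2 * step)
    J[:, 1] = (grad(0.0, step) - grad(0.0, -step)) / (2 * step)
    return J


def no_regulation_stability(params: ModelParams,
                            method: str = "closed-form") -> StabilityResult:
    """Local stability of the no-regulation equilibrium (large colonies).

    The state ``g = s = 0`` at the major-locus optimum is singular; with
    equal mutational variation in both suppressor genes, its stability is
    that of the symmetric Jacobian of the linearized (g, s) gradients.
    For ``p = 1/2`` instability reduces to

    ``alpha**2 * (2 - 1/beta) - alpha > 2 / cost_scale**2``:

    strong trade-offs, strong direct effects and cheap plasticity
    destabilize the undifferentiated state.
    """
    if params.beta == 0.0:
        return StabilityResult(True, -np.inf, method)
    if method == "closed-form":
        J = _stability_jacobian(params)
    elif method == "finite-difference":
        J = _numeric_stability_jacobian(params)
    else:
        raise ValueError(f"unknown method {method!r}")
    margin = float(np.max(np.linalg.eigvals(J).real))
    return StabilityResult(margin < 0.0, margin, method)


def stability_boundary_curve(alpha: float, cost_grid,
                             params: ModelParams | None = None,
                             beta_max: float | None = None) -> np.ndarray:
    """Critical trade-off strength versus plasticity cost (phase boundary).

    For each cost scale, bisects the stability margin over ``beta``; points
    with no sign change in the scan range are omitted with a warning.
    Returns an array of rows ``(cost_scale, beta_crit, margin)``.
    """
    base = params if params is not None else ModelParams()
    beta_hi = beta_max if beta_max is not None else 4.0 * alpha
    rows = []
    for c in np.asarray(cost_grid, dtype=float):
        def margin(beta):
            pp = base.with_(alpha=alpha, beta=beta, cost_scale=c)
            return no_regulation_stability(pp).margin

        lo, hi = 1e-6, beta_hi
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")  # beta may exceed alpha in scan
            if margin(lo) * margin(hi) > 0:
                warnings.warn(
                    f"no stability boundary for cost_scale={c:g} with "
                    f"beta in ({lo:g}, {hi:g}); point omitted", stacklevel=2)
                continue
            bc = brentq(margin, lo, hi, xtol=1e-12)
            rows.append((c, bc, margin(bc)))
    return np.asarray(rows)


def minor_singular_point(params: ModelParams) -> EquilibriumResult:
    """Singular point of the differentiated state in the large-colony limit.

    With sufficiently strong trade-offs the major effects fix at the
    boundary ``x = y = 1`` (suppression has relieved the trade-offs) and
    the suppressor effects equilibrate at ``g = s = cost_scale *
    sqrt(beta/2)``, the maximum of ``z**beta * exp(-(z/c)**2)``. The value
    is biologically feasible (< 1) only when plasticity costs are high
    (``cost_scale < sqrt(2/beta)``); for cheaper plasticity complete
    suppression ``g = s = 1`` evolves. For weak trade-offs the boundary
    ``x = y = 1`` is not attracting and the singular point does not exist.
    """
    a, be, c = params.alpha, params.beta, params.cost_scale
    if be == 0.0:
        return EquilibriumResult(np.nan, np.nan, np.nan, np.nan,
                                 residual=np.inf, converged=False,
                                 feasible=False, exists=False)
    z = c * math.sqrt(be / 2.0)
    if z >= 1.0:
        # cheap plasticity: complete suppression, all traits at the corner
        return EquilibriumResult(1.0, 1.0, 1.0, 1.0, residual=0.0,
                                 boundary=True)
    # partial suppression: exists only if x = y = 1 is attracting, which
    # needs strong trade-offs (beta > 1 keeps the boundary terms finite and
    # the inward viability pull weaker than the outward fertility pull)
    exists = be > 1.0 and a >= be * (1.0 - z) / z
    residual = abs(be / z - 2.0 * z / c ** 2)
    return EquilibriumResult(1.0, 1.0, z, z, residual=residual,
                             boundary=True, feasible=z <= 1.0,
                             exists=bool(exists))
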