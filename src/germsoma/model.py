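"""Core model algebra: the single source of truth for all fitness quantities.

Every other module (simulator, invasion analysis, sweep driver) calls the
functions defined here; none of them re-derives any fitness expression.

Cell-level components
---------------------
A cell with major-gene effects ``x`` (fertility gene) and ``y`` (viability
gene) and no gene regulation has

.. math::

    f = x^\\alpha (1 - y)^\\beta, \\qquad v = y^\\alpha (1 - x)^\\beta,

a multiplicative model in which the first factor is the direct gene effect
(shape ``alpha``) and the second the reduction imposed by the need to
develop/maintain the other function (trade-off strength ``beta``; trade-offs
vanish for ``beta = 0``).

With regulation, a proto-germ cell expresses the germ suppressor ``g`` which
lowers the viability-gene effect from ``y`` to ``(1-g)y``; a proto-soma cell
expresses ``s`` which lowers the fertility-gene effect from ``x`` to
``(1-s)x``. The suppressed effect is substituted everywhere it appears, so
suppression simultaneously abolishes the suppressed function and relieves the
trade-off on the enhanced one. Evolving plasticity is costly: the fertility
of proto-germ cells and the viability of proto-soma cells are multiplied by
the Gaussian factor ``exp(-(effect/c)**2)`` (``c = cost_scale``).

Colony and population level
---------------------------
Colony viability ``V`` is the average of its cells' viabilities; the colony
survives density-dependent selection with Beverton-Holt probability

.. math::

    P(V, N) = \\frac{1}{1 + (b - 1) N / (K_0 V)},

after which each released cell founds a daughter colony with probability
equal to its own fertility. The fitness of a founder cell (expected number
of offspring colonies) and the induced carrying capacity are

.. math::

    w(f, v, N) = \\frac{S f}{1 + (b-1) N/(K_0 v)}, \\qquad
    K(f, v) = K_0 v \\frac{S f - 1}{b - 1}.
"""

from __future__ import annotations

import logging
from typing import Iterable, Sequence

import numpy as np

from .params import (
    GERM,
    SOMA,
    FitnessComponents,
    Genotype,
    ModelParams,
    ParameterError,
)

__all__ = [
    "suppression_cost",
    "cell_fitness_components",
    "fitness_arrays",
    "colony_components",
    "colony_survival_prob",
    "founder_fitness",
    "carrying_capacity",
    "monomorphic_colony_components",
]

log = logging.getLogger(__name__)


def suppression_cost(effect, params: ModelParams):
    """Multiplicative Gaussian cost factor of expressing a suppressor.

    Equals 1 at zero suppression, decreases strictly as suppression becomes
    more efficient, and approaches 1 for any fixed effect as
    ``cost_scale -> inf`` (cheap plasticity).
    """
    effect = np.asarray(effect, dtype=float)
    if np.any((effect < 0) | (effect > 1)):
        raise ParameterError("suppressor effect outside [0, 1]")
    out = np.exp(-((effect / params.cost_scale) ** 2))
    return float(out) if out.ndim == 0 else out


def fitness_arrays(genotypes: np.ndarray, germ_mask: np.ndarray,
                   params: ModelParams):
    """Vectorized fertility/viability for arrays of cells.

    Parameters
    ----------
    genotypes : ndarray, shape (..., 4)
        Allelic effects ``(x, y, g, s)`` per cell.
    germ_mask : ndarray of bool, shape (...)
        True where the cell is a proto-germ cell.

    Returns
    -------
    fertility, viability : ndarray, shape (...)
    """
    x = genotypes[..., 0]
    y = genotypes[..., 1]
    g = genotypes[..., 2]
    s = genotypes[..., 3]
    germ = np.asarray(germ_mask, dtype=bool)

    # expressed (role-conditional) gene effects
    repro = np.where(germ, x, (1.0 - s) * x)
    soma = np.where(germ, (1.0 - g) * y, y)
    # plasticity cost hits the component the suppressor is meant to spare:
    # fertility in germ cells (which suppress viability) and vice versa
    cost_g = np.where(germ, np.exp(-((g / params.cost_scale) ** 2)), 1.0)
    cost_s = np.where(germ, 1.0, np.exp(-((s / params.cost_scale) ** 2)))

    fertility = repro ** params.alpha * (1.0 - soma) ** params.beta * cost_g
    viability = soma ** params.alpha * (1.0 - repro) ** params.beta * cost_s
    return _clipped(fertility), _clipped(viability)


def _clipped(values: np.ndarray) -> np.ndarray:
    """Defensively clip fitness components to [0, 1], loudly if it matters."""
    if np.any((values < -1e-12) | (values > 1.0 + 1e-12)):
        log.warning(
            "fitness component outside [0, 1] (min=%g, max=%g); clipping",
            float(np.min(values)), float(np.max(values)),
        )
    return np.clip(values, 0.0, 1.0)


def cell_fitness_components(genotype: Genotype, role: str,
                            params: ModelParams) -> FitnessComponents:
    """Role-specific fertility and viability of a single cell."""
    genotype = Genotype(*genotype).validate()
    if role not in (GERM, SOMA):
        raise ParameterError(f"unknown role {role!r}")
    f, v = fitness_arrays(
        np.asarray(genotype, dtype=float),
        np.asarray(role == GERM),
        params,
    )
    return FitnessComponents(float(f), float(v))


def colony_components(cells: Sequence | np.ndarray,
                      params: ModelParams | None = None,
                      viabilities: np.ndarray | None = None):
    """Colony viability and mean fertility from its member cells.

    ``cells`` may be a sequence of objects with ``fitness`` attributes (see
    :class:`germsoma.simulate.Cell`) or an array of fertilities paired with
    ``viabilities``. Colony viability is the arithmetic mean of the cells'
    viabilities; colony mean fertility likewise.
    """
    if viabilities is not None:
        fert = np.asarray(cells, dtype=float)
        viab = np.asarray(viabilities, dtype=float)
    else:
        if len(cells) == 0:
            raise ParameterError("colony must contain at least one cell")
        fert = np.array([c.fitness.fertility for c in cells])
        viab = np.array([c.fitness.viability for c in cells])
    if fert.size == 0:
        raise ParameterError("colony must contain at least one cell")
    return float(viab.mean()), float(fert.mean())


def colony_survival_prob(V, N, params: ModelParams):
    """Beverton-Holt probability that a colony survives to reproduction.

    Zero for a colony of zero viability, strictly decreasing in the number
    of colonies ``N`` for ``V > 0``.
    """
    V = np.asarray(V, dtype=float)
    N = np.asarray(N, dtype=float)
    if np.any(N < 0):
        raise ParameterError("number of colonies N must be >= 0")
    with np.errstate(divide="ignore"):
        out = np.where(
            V > 0.0,
            1.0 / (1.0 + (params.b - 1.0) * N / (params.K0 * np.maximum(V, 1e-300))),
            0.0,
        )
    return float(out) if out.ndim == 0 else out


def founder_fitness(f, v, N, params: ModelParams):
    """Expected number of offspring colonies of a cell founding a colony.

    The founder grows a (monomorphic) colony of ``S`` cells with viability
    ``v``; the colony survives with the Beverton-Holt probability and each
    released cell starts a daughter colony with probability ``f``.
    Equals 1 exactly at ``N = carrying_capacity(f, v)``.
    """
    f = np.asarray(f, dtype=float)
    out = params.S * f * colony_survival_prob(v, N, params)
    return float(out) if np.ndim(out) == 0 else out


def carrying_capacity(f, v, params: ModelParams):
    """Equilibrium colony number of a monomorphic population.

    ``K = K0 * v * (S*f - 1) / (b - 1)``, the fixed point of the
    deterministic Beverton-Holt recursion; 0 (extinction) when ``S*f <= 1``.
    For large colonies ``K ~ K0 * S * f * v / (b - 1)``.
    """
    f = np.asarray(f, dtype=float)
    v = np.asarray(v, dtype=float)
    K = params.K0 * v * (params.S * f - 1.0) / (params.b - 1.0)
    K = np.maximum(K, 0.0)
    return float(K) if K.ndim == 0 else K


def monomorphic_colony_components(x, y, g, s, params: ModelParams):
    """Mean fertility ``F`` and viability ``V`` of a monomorphic colony.

    With a fraction ``p`` of proto-germ cells,

    ``F = p*f_g + (1-p)*f_s`` and ``V = p*v_g + (1-p)*v_s``

    where the role-specific components come from the cell-level algebra.
    This is the decomposition on which the invasion analysis operates.
    """
    geno = np.stack(np.broadcast_arrays(
        np.asarray(x, dtype=float), np.asarray(y, dtype=float),
        np.asarray(g, dtype=float), np.asarray(s, dtype=float)), axis=-1)
    f_g, v_g = fitness_arrays(geno, np.asarray(True), params)
    f_s, v_s = fitness_arrays(geno, np.asarray(False), params)
    p = params.p
    F = p * f_g + (1.0 - p) * f_s
    V = p * v_g + (1.0 - p) * v_s
    if np.ndim(F) == 0:
        return float(F), float(V)
    return F, V
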