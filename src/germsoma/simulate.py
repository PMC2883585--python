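"""Stochastic individual-based simulation of the colony life cycle.

One generation consists of, in order:

1. density-dependent viability selection on colonies (Beverton-Holt survival
   with probability depending on colony viability and colony count),
2. disintegration of surviving colonies; each released cell founds a
   daughter colony with probability equal to its own fertility,
3. growth of each daughter colony from its founder through ``n_divisions``
   rounds of binary division, with per-gene mutation in each daughter cell
   at every division (continuum-of-alleles: truncated Gaussian steps),
4. environmental assignment of proto-germ / proto-soma roles to exactly
   ``round(p*S)`` / remaining cells, uniformly at random (roles are not
   heritable), and evaluation of every cell's fertility and viability.

The population is stored as dense arrays (colonies x cells x genes) so a
generation is a handful of vectorized operations; a desk-scale run
(~300 colonies of 16 cells) takes on the order of a millisecond per
generation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np

from . import model
from .params import GERM, SOMA, FitnessComponents, Genotype, ModelParams, ParameterError

__all__ = [
    "Cell",
    "PopulationState",
    "Trajectory",
    "MutantExpectation",
    "mutate_effect",
    "grow_colony",
    "assign_roles",
    "step_generation",
    "run_simulation",
    "initial_state",
    "expected_mutant_fraction",
    "ColonyCapError",
]

_ALL_GENES = np.ones(4, dtype=bool)
_MAJOR_GENES = np.array([True, True, False, False])


class ColonyCapError(RuntimeError):
    """The colony count exceeded the configured hard cap."""


@dataclass
class Cell:
    """A single cell: genotype, developmental role, realized fitness."""

    genotype: Genotype
    role: str
    fitness: FitnessComponents = None  # type: ignore[assignment]
    _params: ModelParams | None = None

    def __post_init__(self):
        if self.fitness is None:
            if self._params is None:
                raise ParameterError("Cell needs params to evaluate fitness")
            self.fitness = model.cell_fitness_components(
                self.genotype, self.role, self._params)


@dataclass
class PopulationState:
    """The population at one generation, as dense arrays."""

    generation: int
    genotypes: np.ndarray      # (N, S, 4)
    germ_mask: np.ndarray      # (N, S) bool
    fertility: np.ndarray      # (N, S)
    viability: np.ndarray      # (N, S)
    extinct: bool = False

    @property
    def N(self) -> int:
        return 0 if self.extinct else self.genotypes.shape[0]

    def colony_viabilities(self) -> np.ndarray:
        return self.viability.mean(axis=1)

    def trait_means(self) -> dict:
        """Per-cell means of the four allelic effects and both components."""
        g = self.genotypes.reshape(-1, 4)
        return {
            "mean_x": g[:, 0].mean(), "mean_y": g[:, 1].mean(),
            "mean_g": g[:, 2].mean(), "mean_s": g[:, 3].mean(),
            "mean_f": self.fertility.mean(), "mean_v": self.viability.mean(),
            "mean_V": self.colony_viabilities().mean(),
        }

    def colonies(self, params: ModelParams) -> list:
        """Materialize per-colony lists of :class:`Cell` (small states only)."""
        out = []
        for i in range(self.N):
            cells = [
                Cell(
                    Genotype(*self.genotypes[i, j]),
                    GERM if self.germ_mask[i, j] else SOMA,
                    FitnessComponents(self.fertility[i, j],
                                      self.viability[i, j]),
                )
                for j in range(self.genotypes.shape[1])
            ]
            out.append(cells)
        return out


def _truncated_steps(values: np.ndarray, sigma: float,
                     rng: np.random.Generator) -> np.ndarray:
    """Mutated trait values: ``value + d`` with ``d ~ N(0, sigma)`` redrawn
    (rejection sampling) until the result lies in [0, 1]."""
    if sigma == 0.0 or values.size == 0:
        return values.copy()
    out = np.empty_like(values)
    pending = np.arange(values.size)
    flat = values.ravel()
    for _ in range(10_000):
        cand = flat[pending] + rng.normal(0.0, sigma, size=pending.size)
        ok = (cand >= 0.0) & (cand <= 1.0)
        out.ravel()[pending[ok]] = cand[ok]
        pending = pending[~ok]
        if pending.size == 0:
            break
    else:  # pragma: no cover - sigma would have to be astronomically large
        out.ravel()[pending] = np.clip(
            flat[pending] + rng.normal(0.0, sigma, size=pending.size), 0, 1)
    return out


def mutate_effect(value: float, params: ModelParams,
                  rng: np.random.Generator) -> float:
    """Apply one continuum-of-alleles mutation to a single allelic effect."""
    if not 0.0 <= value <= 1.0:
        raise ParameterError(f"trait value {value} outside [0, 1]")
    return float(_truncated_steps(np.asarray([value]), params.sigma_m, rng)[0])


def _grow_colonies(founders: np.ndarray, params: ModelParams,
                   rng: np.random.Generator,
                   mutable: np.ndarray = _ALL_GENES) -> np.ndarray:
    """Grow colonies from founder genotypes through the binary division tree.

    Each of the two daughters of every division mutates each mutable gene
    independently with probability ``mu``; a mutation is inherited by all
    subsequent descendants. Returns genotypes of shape ``(M, S, 4)``.
    """
    arr = founders[:, None, :].astype(float, copy=True)  # (M, 1, 4)
    mu = params.mu
    for _ in range(int(params.n_divisions)):
        arr = np.repeat(arr, 2, axis=1)
        if mu > 0.0 and params.sigma_m > 0.0:
            mask = rng.random(arr.shape) < mu
            if not mutable.all():
                mask &= mutable
            idx = np.nonzero(mask)
            if idx[0].size:
                arr[idx] = _truncated_steps(arr[idx], params.sigma_m, rng)
    return arr


def grow_colony(founder, params: ModelParams,
                rng: np.random.Generator) -> np.ndarray:
    """Genotypes of the ``S`` cells grown from a single founder."""
    founder = np.asarray(founder, dtype=float)
    Genotype(*founder).validate()
    return _grow_colonies(founder[None, :], params, rng)[0]


def _assign_roles_many(n_colonies: int, params: ModelParams,
                       rng: np.random.Generator) -> np.ndarray:
    """Proto-germ masks for many colonies: exactly ``round(p*S)`` germ cells
    per colony, in uniformly random positions."""
    S, k = params.S, params.n_germ
    if k <= 0 or k >= S:
        raise ParameterError(
            f"degenerate role split: round(p*S)={k} of S={S} proto-germ cells")
    ranks = rng.random((n_colonies, S)).argsort(axis=1)
    return ranks < k


def assign_roles(S: int, params: ModelParams,
                 rng: np.random.Generator) -> np.ndarray:
    """Role labels for one colony of size ``S`` (must equal ``params.S``)."""
    if S != params.S:
        raise ParameterError(f"S={S} does not match params.S={params.S}")
    mask = _assign_roles_many(1, params, rng)[0]
    return np.where(mask, GERM, SOMA)


def _build_state(generation: int, genotypes: np.ndarray,
                 params: ModelParams, rng: np.random.Generator
                 ) -> PopulationState:
    germ = _assign_roles_many(genotypes.shape[0], params, rng)
    fert, viab = model.fitness_arrays(genotypes, germ, params)
    return PopulationState(generation, genotypes, germ, fert, viab)


def initial_state(params: ModelParams, rng: np.random.Generator,
                  founder: Genotype | None = None,
                  n_colonies: int | None = None) -> PopulationState:
    """Monomorphic starting population.

    Following the numerical protocol, the founder genotype has major-locus
    effects drawn uniformly from (0, 1) and suppressor effects zero, and all
    initial colonies are genetically identical. The initial colony count
    defaults to half the predicted carrying capacity of the founder.
    """
    if founder is None:
        # redraw until the monomorphic founder is demographically viable
        # (a founder with S*f <= 1 heads a trivially doomed population);
        # if the parameters keep K small everywhere, take the best draw
        best, best_K = None, 0.0
        for _ in range(200):
            cand = Genotype(float(rng.uniform()), float(rng.uniform()),
                            0.0, 0.0)
            F, V = model.monomorphic_colony_components(*cand, params)
            K = model.carrying_capacity(F, V, params)
            if K > best_K:
                best, best_K = cand, K
            if K >= 150.0:
                break
        if best is None or best_K < 2.0:
            raise ParameterError(
                "could not draw a viable founder genotype (carrying "
                "capacity < 2 colonies everywhere sampled)")
        founder = best
    founder = Genotype(*founder).validate()
    if n_colonies is None:
        F, V = model.monomorphic_colony_components(*founder, params)
        K = model.carrying_capacity(F, V, params)
        n_colonies = max(2, int(round(K)))
    genotypes = np.broadcast_to(
        np.asarray(founder, dtype=float),
        (int(n_colonies), params.S, 4)).copy()
    return _build_state(0, genotypes, params, rng)


def step_generation(state: PopulationState, params: ModelParams,
                    rng: np.random.Generator,
                    mutable_genes: np.ndarray = _ALL_GENES
                    ) -> PopulationState:
    """Advance the population by one full life cycle."""
    if state.extinct or state.N == 0:
        return PopulationState(state.generation + 1, state.genotypes[:0],
                               state.germ_mask[:0], state.fertility[:0],
                               state.viability[:0], extinct=True)
    N = state.N
    V = state.colony_viabilities()
    surv = rng.random(N) < model.colony_survival_prob(V, N, params)
    if not surv.any():
        return PopulationState(state.generation + 1, state.genotypes[:0],
                               state.germ_mask[:0], state.fertility[:0],
                               state.viability[:0], extinct=True)
    fert = state.fertility[surv]
    founds = rng.random(fert.shape) < fert
    founders = state.genotypes[surv][founds]
    if founders.shape[0] == 0:
        return PopulationState(state.generation + 1, state.genotypes[:0],
                               state.germ_mask[:0], state.fertility[:0],
                               state.viability[:0], extinct=True)
    if founders.shape[0] > params.max_colonies:
        raise ColonyCapError(
            f"{founders.shape[0]} daughter colonies exceed the hard cap "
            f"{params.max_colonies} (={params.max_colonies_factor} * K0)")
    genotypes = _grow_colonies(founders, params, rng, mutable_genes)
    germ = _assign_roles_many(genotypes.shape[0], params, rng)
    f, v = model.fitness_arrays(genotypes, germ, params)
    return PopulationState(state.generation + 1, genotypes, germ, f, v)


_TRAIT_KEYS = ("mean_x", "mean_y", "mean_g", "mean_s",
               "mean_f", "mean_v", "mean_V")


@dataclass
class Trajectory:
    """Recorded time series of a simulation run."""

    generations: np.ndarray
    N: np.ndarray
    means: dict            # key -> ndarray, keys per _TRAIT_KEYS
    seed: int | None
    params: ModelParams
    status: str = "ok"                 # "ok" | "extinct"
    stopped_early: bool = False
    snapshot: dict | None = None       # terminal per-cell arrays

    def to_dataframe(self):
        import pandas as pd

        data = {"generation": self.generations, "N": self.N}
        data.update({k: self.means[k] for k in _TRAIT_KEYS})
        return pd.DataFrame(data)

    def tail_means(self, tail_fraction: float = 0.1) -> dict:
        """Means of the recorded series over the final fraction of records."""
        n = len(self.generations)
        if n == 0:
            raise ValueError("empty trajectory")
        k = max(1, int(round(tail_fraction * n)))
        return {key: float(np.mean(self.means[key][-k:]))
                for key in _TRAIT_KEYS} | {
                    "N": float(np.mean(self.N[-k:]))}


def run_simulation(params: ModelParams,
                   generations: int,
                   seed: int | None = None,
                   rng: np.random.Generator | None = None,
                   record_every: int = 100,
                   regulation: bool = True,
                   founder: Genotype | None = None,
                   n_colonies: int | None = None,
                   stop_when_complete: bool = False,
                   complete_threshold: float = 0.9,
                   stop_window: int = 20,
                   take_snapshot: bool = False,
                   progress: Callable[[int, PopulationState], None] | None = None,
                   ) -> Trajectory:
    """Run the individual-based model and record trait means.

    Parameters
    ----------
    regulation : bool
        When False the suppressor loci are frozen at zero (mutation applies
        to the major loci only) — the no-plasticity variant of the model.
    stop_when_complete : bool
        Stop as soon as the running means of x, y, g, s over the last
        ``stop_window`` records all exceed ``complete_threshold`` (used by
        the sweep driver; cannot change the outcome classification, only
        shortens runs that have already differentiated).
    """
    if rng is None:
        rng = np.random.default_rng(seed)
    mutable = _ALL_GENES if regulation else _MAJOR_GENES
    state = initial_state(params, rng, founder=founder,
                          n_colonies=n_colonies)
    recs: list[tuple] = []

    def record(st: PopulationState):
        m = st.trait_means()
        recs.append((st.generation, st.N) + tuple(m[k] for k in _TRAIT_KEYS))

    record(state)
    status, stopped = "ok", False
    for gen in range(1, int(generations) + 1):
        state = step_generation(state, params, rng, mutable)
        if state.extinct:
            status = "extinct"
            recs.append((state.generation, 0) + (np.nan,) * len(_TRAIT_KEYS))
            break
        if gen % record_every == 0 or gen == generations:
            record(state)
            if progress is not None:
                progress(gen, state)
            if stop_when_complete and len(recs) >= stop_window:
                block = np.array([r[2:6] for r in recs[-stop_window:]])
                if np.all(block.mean(axis=0) > complete_threshold):
                    stopped = True
                    break

    arr = np.array(recs, dtype=float)
    snapshot = None
    if take_snapshot and not state.extinct:
        n, S = state.genotypes.shape[:2]
        snapshot = {
            "colony_id": np.repeat(np.arange(n), S),
            "role": np.where(state.germ_mask.ravel(), GERM, SOMA),
            "x": state.genotypes[..., 0].ravel(),
            "y": state.genotypes[..., 1].ravel(),
            "g": state.genotypes[..., 2].ravel(),
            "s": state.genotypes[..., 3].ravel(),
            "f": state.fertility.ravel(),
            "v": state.viability.ravel(),
        }
    means = {k: arr[:, 2 + i] for i, k in enumerate(_TRAIT_KEYS)}
    return Trajectory(arr[:, 0].astype(int), arr[:, 1], means,
                      seed, params, status, stopped, snapshot)


class MutantExpectation(tuple):
    """(exact, approximation) expected mutant-cell count per colony."""

    __slots__ = ()

    def __new__(cls, exact, approximation):
        return tuple.__new__(cls, (exact, approximation))

    exact = property(lambda self: self[0])
    approximation = property(lambda self: self[1])


def expected_mutant_fraction(n: int, mu: float) -> MutantExpectation:
    """Expected number of cells per colony carrying a mutation at one gene.

    A leaf of the division tree escapes mutation at a given gene only if
    none of its ``n`` ancestral daughter-steps mutated, so the exact
    expectation is ``S * (1 - (1-mu)**n)`` with ``S = 2**n``; for small
    ``mu`` this is approximately ``mu * S * log2(S)``.
    """
    if n < 1 or not 0.0 <= mu <= 1.0:
        raise ParameterError("need n >= 1 and mu in [0, 1]")
    S = 2 ** int(n)
    exact = S * (1.0 - (1.0 - mu) ** n)
    approx = mu * S * n
    return MutantExpectation(exact, approx)
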