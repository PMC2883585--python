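"""Batch driver: parameter grids, outcome classification, phase cube.

Maps the (trade-off strength x plasticity cost x mutation rate) parameter
space to differentiation outcomes by running replicated individual-based
simulations and classifying the tail of each trajectory as

``complete``
    all four trait means above the upper threshold (germ-soma division of
    labor fully evolved),
``no_plasticity``
    both suppressor means below the lower threshold,
``partial``
    anything in between,
``extinct``
    the population died out.

Desk-scale ("reduced") runs calibrate the maximum carrying capacity so the
undifferentiated population holds a few hundred colonies and cap the run
length; they are scaled-down proxies of cluster-scale experiments.
"""

from __future__ import annotations

import itertools
import logging
import warnings
from dataclasses import dataclass, field

import numpy as np

from . import invasion, model
from .params import ModelParams
from .simulate import Trajectory, run_simulation

__all__ = [
    "Thresholds",
    "SweepRecord",
    "classify_outcome",
    "calibrate_K0",
    "run_sweep",
    "phase_cube",
    "DEFAULT_GRID",
    "REDUCED_COLONY_TARGET",
]

log = logging.getLogger(__name__)

#: default desk-scale target for the undifferentiated colony count
REDUCED_COLONY_TARGET = 300.0

#: default sweep grid (trade-off strength, plasticity cost scale, mutation
#: rate); chosen to span the stable and unstable sides of the no-regulation
#: phase boundary at alpha = 2
DEFAULT_GRID = {
    "beta": (0.25, 0.5, 1.0),
    "cost_scale": (0.5, 1.0, 2.0),
    "mu": (1e-4, 3e-4, 1e-3),
}

OUTCOMES = ("no_plasticity", "partial", "complete", "extinct", "error")


@dataclass(frozen=True)
class Thresholds:
    """Classification cutoffs applied to tail-window trait means."""

    complete: float = 0.9
    none: float = 0.1
    tail_fraction: float = 0.1
    min_records: int = 10


@dataclass
class SweepRecord:
    """Outcome of a single replicate run at one parameter combination."""

    beta: float
    cost_scale: float
    mu: float
    replicate: int
    seed: int
    outcome: str
    tail_x: float
    tail_y: float
    tail_g: float
    tail_s: float
    generations_run: int
    first_complete_generation: int | None = None
    params: dict = field(default_factory=dict, repr=False)


def classify_outcome(trajectory: Trajectory,
                     thresholds: Thresholds = Thresholds()) -> str:
    """Classify a trajectory from the means over its tail window.

    A pure function of the recorded series and the thresholds; re-running it
    on a stored trajectory gives the same answer.
    """
    if trajectory.status == "extinct":
        return "extinct"
    n = len(trajectory.generations)
    if n < thresholds.min_records:
        raise ValueError(
            f"trajectory has {n} records; classification needs at least "
            f"{thresholds.min_records}")
    tail = trajectory.tail_means(thresholds.tail_fraction)
    traits = [tail["mean_x"], tail["mean_y"], tail["mean_g"], tail["mean_s"]]
    if all(t > thresholds.complete for t in traits):
        return "complete"
    if tail["mean_g"] < thresholds.none and tail["mean_s"] < thresholds.none:
        return "no_plasticity"
    return "partial"


def calibrate_K0(params: ModelParams,
                 target: float = REDUCED_COLONY_TARGET,
                 method: str = "analytic",
                 seed: int | None = 0,
                 prerun_generations: int = 2000) -> ModelParams:
    """Choose ``K0`` so the no-plasticity population equilibrates near
    ``target`` colonies.

    ``analytic`` places the major loci at their predicted equilibrium and
    inverts the carrying-capacity formula (instant). ``prerun`` runs the
    regulation-frozen model and rescales ``K0`` by the measured mean colony
    count (the carrying capacity is proportional to ``K0``).
    """
    if method == "analytic":
        eq = invasion.solve_major_equilibrium(params)
        if not eq.converged:
            raise ValueError("no viable major-locus equilibrium to calibrate")
        F, V = model.monomorphic_colony_components(
            eq.x_hat, eq.y_hat, 0.0, 0.0, params)
        K_per_K0 = model.carrying_capacity(F, V, params) / params.K0
        if K_per_K0 <= 0:
            raise ValueError("equilibrium population not viable")
        return params.with_(K0=float(target / K_per_K0))
    if method == "prerun":
        traj = run_simulation(params, prerun_generations, seed=seed,
                              record_every=10, regulation=False)
        if traj.status == "extinct":
            raise ValueError("calibration pre-run went extinct")
        meanN = traj.tail_means(0.5)["N"]
        return params.with_(K0=float(params.K0 * target / meanN))
    raise ValueError(f"unknown calibration method {method!r}")


def _first_complete(trajectory: Trajectory, threshold: float) -> int | None:
    m = trajectory.means
    above = (np.asarray(m["mean_x"]) > threshold) \
        & (np.asarray(m["mean_y"]) > threshold) \
        & (np.asarray(m["mean_g"]) > threshold) \
        & (np.asarray(m["mean_s"]) > threshold)
    idx = np.nonzero(above)[0]
    return int(trajectory.generations[idx[0]]) if idx.size else None


def run_sweep(grid: dict | None = None,
              base_params: ModelParams = ModelParams(),
              replicates: int = 3,
              generations: int = 200_000,
              seed: int = 0,
              reduced: bool = True,
              colony_target: float = REDUCED_COLONY_TARGET,
              record_every: int = 100,
              thresholds: Thresholds = Thresholds(),
              stop_when_complete: bool = True) -> list[SweepRecord]:
    """Run replicated simulations over a full parameter grid.

    Seeds are spawned deterministically from ``seed`` per (combination,
    replicate), so the record set is reproducible regardless of execution
    order. Individual run failures are recorded, not fatal.
    """
    grid = dict(DEFAULT_GRID if grid is None else grid)
    betas = tuple(grid.pop("beta"))
    costs = tuple(grid.pop("cost_scale"))
    mus = tuple(grid.pop("mu"))
    if grid:
        raise ValueError(f"unknown grid axes: {sorted(grid)}")

    combos = list(itertools.product(betas, costs, mus))
    records: list[SweepRecord] = []
    for ci, (beta, cost, mu) in enumerate(combos):
        params = base_params.with_(beta=beta, cost_scale=cost, mu=mu)
        if reduced:
            try:
                params = calibrate_K0(params, colony_target)
            except ValueError as exc:
                log.warning("combination %s not calibratable: %s",
                            (beta, cost, mu), exc)
        for rep in range(replicates):
            run_seed = int(
                np.random.SeedSequence([seed, ci, rep]).generate_state(1)[0]
                % 2**31)
            try:
                traj = run_simulation(
                    params, generations, seed=run_seed,
                    record_every=record_every,
                    stop_when_complete=stop_when_complete,
                    complete_threshold=thresholds.complete)
                outcome = classify_outcome(traj, thresholds)
                tail = traj.tail_means(thresholds.tail_fraction)
                records.append(SweepRecord(
                    beta, cost, mu, rep, run_seed, outcome,
                    tail["mean_x"], tail["mean_y"],
                    tail["mean_g"], tail["mean_s"],
                    int(traj.generations[-1]),
                    _first_complete(traj, thresholds.complete),
                    params.to_dict()))
            except Exception as exc:  # noqa: BLE001 - record, don't abort
                log.warning("run (beta=%g cost=%g mu=%g rep=%d) failed: %s",
                            beta, cost, mu, rep, exc)
                records.append(SweepRecord(
                    beta, cost, mu, rep, run_seed, "error",
                    np.nan, np.nan, np.nan, np.nan, 0, None,
                    params.to_dict()))
    return records


def phase_cube(records: list[SweepRecord]):
    """Majority-vote outcome per (beta, cost, mu) cell of the grid.

    Returns ``(beta_vals, cost_vals, mu_vals, outcome_grid)`` where the grid
    holds outcome strings ("missing" for cells with no successful run).
    """
    betas = sorted({r.beta for r in records})
    costs = sorted({r.cost_scale for r in records})
    mus = sorted({r.mu for r in records})
    out = np.full((len(betas), len(costs), len(mus)), "missing", dtype=object)
    for i, be in enumerate(betas):
        for j, c in enumerate(costs):
            for k, m in enumerate(mus):
                votes = [r.outcome for r in records
                         if (r.beta, r.cost_scale, r.mu) == (be, c, m)
                         and r.outcome != "error"]
                if not votes:
                    continue
                counts = {o: votes.count(o) for o in set(votes)}
                # majority vote, ties broken toward the less derived outcome
                order = {o: n for n, o in enumerate(OUTCOMES)}
                out[i, j, k] = max(
                    sorted(counts, key=lambda o: order[o]),
                    key=lambda o: counts[o])
    return np.asarray(betas), np.asarray(costs), np.asarray(mus), out


def plot_cube(records: list[SweepRecord], path=None):
    """3-D filled-cube rendering of the differentiation phase diagram."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    betas, costs, mus, grid = phase_cube(records)
    filled = grid == "complete"
    fig = plt.figure(figsize=(6, 5))
    ax = fig.add_subplot(projection="3d")
    ax.voxels(filled.transpose(0, 1, 2), facecolors="#c44e52",
              edgecolor="k", alpha=0.8)
    ax.set_xlabel("trade-off strength index")
    ax.set_ylabel("cost-scale index")
    ax.set_zlabel("mutation-rate index")
    ax.set_xticks(np.arange(len(betas)) + 0.5, [f"{b:g}" for b in betas])
    ax.set_yticks(np.arange(len(costs)) + 0.5, [f"{c:g}" for c in costs])
    ax.set_zticks(np.arange(len(mus)) + 0.5, [f"{m:g}" for m in mus])
    ax.set_title("complete germ-soma differentiation (filled)")
    if path is not None:
        fig.savefig(path, dpi=150, bbox_inches="tight")
        plt.close(fig)
    return fig
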