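"""Full-scale headline check: complete differentiation within 1e6 generations.

Runs the individual-based model at full scale (undifferentiated population of
~2000 colonies, favorable parameters: strong trade-offs, cheap plasticity,
high mutation rate, S = 16) for up to one million generations and reports the
first generation at which the population is completely differentiated
(tail means of x, y, g, s all above 0.9).

This is an overnight computation on one CPU; it is deliberately not part of
the test suite. Usage::

    python scripts/headline_timescale.py --seed 1 [--out results/headline.json]
"""

from __future__ import annotations

import argparse
import json
import time
from pathlib import Path


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--generations", type=int, default=1_000_000)
    ap.add_argument("--colonies", type=float, default=2000.0,
                    help="target undifferentiated population size")
    ap.add_argument("--out", type=Path, default=None)
    args = ap.parse_args()

    from germsoma import ModelParams, classify_outcome, run_simulation
    from germsoma.sweep import calibrate_K0

    params = calibrate_K0(
        ModelParams(beta=1.0, cost_scale=2.0, mu=1e-3), args.colonies)
    t0 = time.time()

    def progress(gen, state):
        if gen % 10_000 == 0:
            m = state.trait_means()
            print(f"gen {gen:>8d}  N={state.N:>6d}  "
                  f"x={m['mean_x']:.3f} y={m['mean_y']:.3f} "
                  f"g={m['mean_g']:.3f} s={m['mean_s']:.3f}  "
                  f"[{time.time()-t0:.0f}s]", flush=True)

    traj = run_simulation(params, args.generations, seed=args.seed,
                          record_every=100, stop_when_complete=True,
                          progress=progress)
    outcome = classify_outcome(traj)
    from germsoma.sweep import _first_complete

    first = _first_complete(traj, 0.9)
    result = {
        "outcome": outcome,
        "first_complete_generation": first,
        "generations_run": int(traj.generations[-1]),
        "within_1e6": bool(outcome == "complete"
                           and traj.generations[-1] <= 1_000_000),
        "elapsed_s": round(time.time() - t0, 1),
    }
    print(json.dumps(result, indent=2))
    if args.out:
        args.out.parent.mkdir(parents=True, exist_ok=True)
        args.out.write_text(json.dumps(result) + "\n")


if __name__ == "__main__":
    main()
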