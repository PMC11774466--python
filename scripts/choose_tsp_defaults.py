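"""Choose the default TSP hyperparameters (b, λ) on the sphere benchmark.

Runs a coarse grid over the direction-retention weight b and the L2 weight λ
on the toggle-switch-on-a-sphere benchmark with normal-component noise, and
picks, among grid points whose projected velocities are tangent (mean
|normal component|/speed < 0.05), the one with the smallest speed RMSE
(ties broken by median cosine).  The winning pair is hard-coded as the
TSPConfig default.

Usage: python scripts/choose_tsp_defaults.py [--seed 0]
"""

import argparse
import json

import numpy as np

from graphvelo.benchmarks import sphere_benchmark
from graphvelo.tangent import TSPConfig

B_GRID = [0.0, 0.5, 1.0, 2.0]
LAM_GRID = [0.01, 0.1, 0.5, 1.0]


def main():
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=0)
    args = ap.parse_args()

    rows = []
    for b in B_GRID:
        for lam in LAM_GRID:
            res = sphere_benchmark(seed=args.seed, cfg=TSPConfig(b=b, lam=lam))
            rows.append({"b": b, "lam": lam,
                         "normal_ratio": res["normal_ratio_projected"],
                         "median_cosine": res["median_cosine"],
                         "speed_rmse_frac": res["speed_rmse_frac"]})
            print(json.dumps(rows[-1]))
    tangent = [r for r in rows if r["normal_ratio"] < 0.05]
    best = min(tangent or rows,
               key=lambda r: (round(r["speed_rmse_frac"], 3), -r["median_cosine"]))
    print("chosen defaults:", json.dumps(best))


if __name__ == "__main__":
    main()
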