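#!/usr/bin/env python
"""Hierarchical parameter recovery on a synthetic cohort.

Generates a cohort of subjective-optimality agents at the fitted group
scale (r = 110.51, rho = 0.62, s ~ 10; 20 subjects x 200 rounds, K = 5),
fits the model hierarchically by Metropolis-Hastings, and compares the
back-transformed group posterior with the generating values.  A reduced
chain (12,000 iterations) keeps this driver quick; the acceptance script
runs the full 40,000-iteration protocol.

Writes results/recovery_group_posterior.tsv and results/recovery_map.tsv.
"""

from pathlib import Path

import numpy as np
import pandas as pd

from subjopt.task import TaskSpec
from subjopt import transforms
from subjopt.synth import sample_population, simulate_cohort
from subjopt.hierarchical import (
    HierarchicalSpec, fit_hierarchical, group_posterior, map_estimates,
)

OUT = Path(__file__).resolve().parents[1] / "results"
OUT.mkdir(exist_ok=True)
SEED = 11


def main():
    truth = {"r": 110.51, "rho": 0.62, "s": 10.0}
    mus = {"r": float(transforms.to_sampling("r", truth["r"])),
           "rho": float(transforms.to_sampling("rho", truth["rho"])),
           "s": float(np.log(truth["s"]))}
    rng = np.random.default_rng(SEED)
    pop = sample_population(mus, {"r": 0.3, "rho": 0.3, "s": 0.2}, 20, rng)
    data = simulate_cohort(pop, "subjective", TaskSpec(K=5, n_rounds=200), rng)
    print(f"cohort: 20 subjects, {len(data)} rows; "
          f"true group means r = {truth['r']}, rho = {truth['rho']}")

    chain = fit_hierarchical(data, HierarchicalSpec(
        model_tag="subjective", n_iter=12_000, burn_in=4_000, seed=SEED + 1))
    gp = group_posterior(chain)
    gp.to_csv(OUT / "recovery_group_posterior.tsv", sep="\t")

    maps = map_estimates(chain)
    map_tab = pd.DataFrame(maps).T.rename_axis("subject_id")
    map_tab["true_r"] = [p.r for p in pop]
    map_tab["true_rho"] = [p.rho for p in pop]
    map_tab.to_csv(OUT / "recovery_map.tsv", sep="\t")

    for name in ("r", "rho", "s"):
        err = gp.loc[name, "mean"] - truth[name]
        print(f"  {name}: recovered {gp.loc[name, 'mean']:.3f} "
              f"(posterior SD {gp.loc[name, 'sd']:.3f}), "
              f"truth {truth[name]}, error {err:+.3f}")
    r_corr = float(np.corrcoef(map_tab["r"], map_tab["true_r"])[0, 1])
    rho_corr = float(np.corrcoef(map_tab["rho"], map_tab["true_rho"])[0, 1])
    print(f"subject-level MAP vs truth correlations: r {r_corr:.3f}, "
          f"rho {rho_corr:.3f}")
    print("note: single-cohort posterior means carry a small skew along the "
          "r/rho ridge (weakly identified high-rho subjects); the recovery "
          "protocol in scripts/acceptance.py takes the median over 5 "
          "cohort-plus-fit replicates")
    print(f"wrote {OUT/'recovery_group_posterior.tsv'} and {OUT/'recovery_map.tsv'}")


if __name__ == "__main__":
    main()
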