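#!/usr/bin/env python
"""Calibration of rho dating on simulated founder expansions.

Simulates 500 star genealogies of 20 lineages with an expected two
mutations per lineage (TMRCA 7,248 y at the default rate of one
substitution per 3,624 y), rebuilds each clade, and checks that the mean
rho estimate recovers the truth and that the 95% intervals cover the true
TMRCA at close to nominal rate. Mutations are drawn from the observable
(non-hotspot) site spectrum so every simulated event is countable.

Writes results/dating_calibration.tsv.
"""

from pathlib import Path

import numpy as np
import pandas as pd

from mitorho.dating import estimate_age
from mitorho.parsimony import build_tree
from mitorho.simulate import (
    SimConfig,
    observable_spectrum,
    simulate_genealogy,
    sprinkle_mutations,
)

OUT = Path(__file__).resolve().parent.parent / "results"
REPS = 500
N_TIPS = 20
MU_T = 2.0
SEED = 4001


def main():
    rng = np.random.default_rng(SEED)
    true_t = MU_T * 3624.0
    spectrum = observable_spectrum()
    rows = []
    for rep in range(REPS):
        cfg = SimConfig(n=N_TIPS, model="star", tmrca_years=true_t,
                        seed=int(rng.integers(2 ** 31)))
        haps, _ = sprinkle_mutations(simulate_genealogy(cfg),
                                     spectrum=spectrum,
                                     seed=int(rng.integers(2 ** 31)))
        est = estimate_age(build_tree([h.masked() for h in haps],
                                      method="greedy"))
        rows.append({"rep": rep, "rho": est.rho, "sigma": est.sigma,
                     "age_years": est.t_years,
                     "covered": est.ci95[0] <= true_t <= est.ci95[1]})
    frame = pd.DataFrame(rows)
    OUT.mkdir(exist_ok=True)
    frame.to_csv(OUT / "dating_calibration.tsv", sep="\t", index=False)
    mean = frame["rho"].mean()
    se = frame["rho"].std(ddof=1) / np.sqrt(REPS)
    print(f"true muT={MU_T}: mean rho-hat {mean:.3f} (MC SE {se:.4f}), "
          f"CI coverage {frame['covered'].mean():.1%} over {REPS} reps")
    print(f"wrote {OUT / 'dating_calibration.tsv'}")


if __name__ == "__main__":
    main()
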