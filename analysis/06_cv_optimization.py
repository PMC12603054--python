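#!/usr/bin/env python
"""FAIMS compensation-voltage optimization on simulated single-CV runs.

Simulates one scaled-down acquisition per single CV from -30 V to -90 V,
identifies crosslinks in each, builds the per-CV URP sets, and selects
CV triplets under the three criteria: maximal yield with minimal
overlap, minimal total overlap, and maximal common core.  Also verifies
the charge-transmission picture: low charge states are detected best
near -30 V, 3+ and above near -49 V.
"""

import dataclasses
import json
from pathlib import Path

import numpy as np

from xlmsbench.optimization_metrics import select_cv_combinations, upset_regions
from xlmsbench.pipeline import RunConfig, run_pipeline
from xlmsbench.synthetic_data import cv_transmission

OUT = Path(__file__).resolve().parents[1] / "results"
CVS = [-30.0, -40.0, -48.0, -55.0, -60.0, -75.0, -90.0]


def main() -> None:
    base = RunConfig().with_seed(2)
    base = dataclasses.replace(
        base,
        sim=dataclasses.replace(base.sim, n_links=150, n_residues=450,
                                n_linear_peptides=40, seed=2),
        method=dataclasses.replace(base.method, gradient_minutes=10.0))
    sets: dict[float, set] = {}
    for cv in CVS:
        cfg = dataclasses.replace(
            base, method=dataclasses.replace(base.method, cv_program=(cv,)))
        bundle = run_pipeline(cfg)
        sets[cv] = {(int(r["pos_a"]), int(r["pos_b"]))
                    for _, r in bundle.urps.iterrows()}
        print(f"CV {cv:+.0f} V: {len(sets[cv])} URPs")
    best_single = max(sets, key=lambda cv: len(sets[cv]))
    print(f"best single CV: {best_single:+.0f} V")

    regions = upset_regions(sets)
    combos = select_cv_combinations(sets, k=3)
    for crit, c in combos.items():
        print(f"{crit}: CVs {c.keys} union={c.union_size} "
              f"pairwise_overlap={c.pairwise_overlap} "
              f"common={c.common_size}")
    # transmission optima per charge, from the generator's model
    grid = np.arange(-90.0, -29.0, 1.0)
    optima = {z: float(grid[np.argmax([cv_transmission(z, cv, base.sim)
                                       for cv in grid])])
              for z in (1, 2, 3, 4, 5, 6)}
    print(f"transmission optima by charge: {optima}")
    OUT.mkdir(exist_ok=True)
    (OUT / "cv_optimization.json").write_text(json.dumps(dict(
        urps_per_cv={str(cv): len(s) for cv, s in sets.items()},
        best_single_cv=best_single,
        regions={"+".join(f"{k:+.0f}" for k in sig): n
                 for sig, n in regions.items()},
        combinations={crit: dict(cvs=list(c.keys), union=c.union_size,
                                 pairwise_overlap=c.pairwise_overlap,
                                 common=c.common_size)
                      for crit, c in combos.items()},
        transmission_optima=optima), indent=2, sort_keys=True))
    print(f"-> {OUT / 'cv_optimization.json'}")


if __name__ == "__main__":
    main()
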