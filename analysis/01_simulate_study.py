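#!/usr/bin/env python
"""Generate the synthetic study all later steps analyze.

Writes the small inputs (annotation, expression, labels, ground truth) to
results/data/.  Coverage tracks are regenerated from the seed by each
consumer instead of being stored: at per-nucleotide resolution they are
large, and the generator is deterministic.
"""

import os

from compscan.config import load_config
from compscan.pipeline import _write_simulated
from compscan.simulate import simulate_study

OUT = "results/data"


def main() -> None:
    cfg, warns = load_config(os.path.join(os.path.dirname(__file__), "study_config.yaml"))
    for w in warns:
        print("warning:", w)
    study = simulate_study(cfg["simulation"])
    os.makedirs(OUT, exist_ok=True)
    _write_simulated(study, OUT)
    n_x = len(study.annotation.on_arm("X"))
    n_bound = len(study.bound_genes)
    print(f"simulated {len(study.annotation)} genes ({n_x} on X), "
          f"{n_bound} MSL-bound, {len(study.has)} high-affinity sites")
    print(f"inputs written to {OUT}/")


if __name__ == "__main__":
    main()
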