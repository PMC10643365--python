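#!/usr/bin/env python
"""Invert every run by variational Laplace (one DCM per subject x task x
configuration) and summarise convergence."""

import json

from speechdcm import run_pipeline
from cohort_config import demo_config, RESULTS


def main():
    run_pipeline(demo_config(), stop_after="fit")
    fits = sorted((RESULTS / "fits").glob("*.json"))
    n_conv = 0
    f_values = []
    for path in fits:
        est = json.loads(path.read_text())
        n_conv += est["converged"]
        f_values.append(est["free_energy"])
    print(f"{len(fits)} inversions, {n_conv} converged")
    print(f"free energy: min {min(f_values):.1f}, "
          f"median {sorted(f_values)[len(f_values)//2]:.1f}, "
          f"max {max(f_values):.1f} nats")


if __name__ == "__main__":
    main()
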