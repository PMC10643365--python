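#!/usr/bin/env python
"""Generate the synthetic cohort: regional BOLD runs with known ground
truth, emulating the block design of the repetition experiment."""

import pandas as pd

from speechdcm import run_pipeline
from cohort_config import demo_config, RESULTS


def main():
    config = demo_config()
    run_pipeline(config, stop_after="simulate")
    truth = pd.read_csv(RESULTS / "cohort" / "ground_truth.csv")
    n_runs = len(truth)
    print(f"wrote {n_runs} runs under {RESULTS/'cohort'} "
          f"({config.cohort.n_subjects} subjects x "
          f"{len(config.cohort.tasks)} tasks x "
          f"{len(config.cohort.configurations)} configurations)")
    print("\nplanted archetype counts (per subject x task):")
    per_st = truth.drop_duplicates(["subject", "task"])
    print(per_st.groupby(["task", "archetype"]).size().unstack(fill_value=0))


if __name__ == "__main__":
    main()
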