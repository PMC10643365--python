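#!/usr/bin/env python
"""Prune each fitted model over the 256-model space by Bayesian model
reduction; report per-connection presence probabilities and
model-averaged rates."""

import pandas as pd

from speechdcm import run_pipeline
from cohort_config import demo_config, RESULTS


def main():
    run_pipeline(demo_config(), stop_after="reduce")
    red = pd.read_csv(RESULTS / "reduction.csv")
    red["connection"] = red.source + "->" + red.target
    print(f"{red[['subject','task','configuration']].drop_duplicates().shape[0]}"
          " models reduced over 256 nested alternatives each\n")
    print("fraction of fits reporting each connection (Pp > 0.75), "
          "and mean model-averaged rate when reported:")
    summary = red.groupby("connection").apply(
        lambda g: pd.Series({
            "frac_reported": (g.pp > 0.75).mean(),
            "mean_rate_when_reported": g.loc[g.pp > 0.75, "bma_mean_hz"].mean(),
        }), include_groups=False)
    print(summary.round(2).to_string())


if __name__ == "__main__":
    main()
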