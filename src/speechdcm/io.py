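"""Plain-text serialisation of the pipeline's artefacts.

Time series travel as TSV with a ``time_s`` column plus one column per
region; designs, network specifications and posterior estimates as JSON.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .model import (NetworkSpec, StimulusDesign, RegionTimeSeries)
from .invert import GaussianBelief, NoiseModel, PosteriorEstimate


def write_timeseries(ts: RegionTimeSeries, path: str | Path) -> None:
    t = (np.arange(1, ts.n_volumes + 1)) * ts.tr
    df = pd.DataFrame({"time_s": t})
    for i, label in enumerate(ts.region_labels):
        df[label] = ts.values[:, i]
    df.to_csv(path, sep="\t", index=False, float_format="%.10g")


def read_timeseries(path: str | Path) -> RegionTimeSeries:
    df = pd.read_csv(path, sep="\t")
    if "time_s" not in df.columns or df.shape[1] != 5:
        raise ValueError("expected columns: time_s plus four regions")
    t = df["time_s"].to_numpy()
    tr = float(np.diff(t).mean()) if t.size > 1 else float(t[0])
    labels = tuple(c for c in df.columns if c != "time_s")
    return RegionTimeSeries(df[list(labels)].to_numpy(float), tr, labels)


def write_design(design: StimulusDesign, path: str | Path) -> None:
    payload = {
        "block_onsets": design.block_onsets.tolist(),
        "block_durations": design.block_durations.tolist(),
        "tr": design.tr,
        "n_volumes": design.n_volumes,
        "microtime_bins_per_tr": design.microtime_bins_per_tr,
    }
    if design.event_onsets is not None:
        payload["event_onsets"] = np.asarray(design.event_onsets).tolist()
        payload["event_durations"] = np.asarray(design.event_durations).tolist()
    Path(path).write_text(json.dumps(payload, indent=1))


def read_design(path: str | Path) -> StimulusDesign:
    payload = json.loads(Path(path).read_text())
    return StimulusDesign(
        block_onsets=np.array(payload["block_onsets"]),
        block_durations=np.array(payload["block_durations"]),
        tr=payload["tr"],
        n_volumes=payload["n_volumes"],
        microtime_bins_per_tr=payload.get("microtime_bins_per_tr", 16),
        event_onsets=np.array(payload["event_onsets"])
        if "event_onsets" in payload else None,
        event_durations=np.array(payload["event_durations"])
        if "event_durations" in payload else None,
    )


def write_network(spec: NetworkSpec, path: str | Path) -> None:
    Path(path).write_text(json.dumps({
        "region_labels": list(spec.region_labels),
        "connection_mask": spec.connection_mask.astype(int).tolist(),
        "input_region": spec.input_region,
        "switchable_mask": spec.switchable_mask.astype(int).tolist(),
    }, indent=1))


def read_network(path: str | Path) -> NetworkSpec:
    payload = json.loads(Path(path).read_text())
    return NetworkSpec(
        region_labels=tuple(payload["region_labels"]),
        connection_mask=np.array(payload["connection_mask"], bool),
        input_region=payload["input_region"],
        switchable_mask=np.array(payload["switchable_mask"], bool),
    )


def write_posterior(est: PosteriorEstimate, path: str | Path) -> None:
    Path(path).write_text(json.dumps({
        "mean": est.belief.mean.tolist(),
        "cov": est.belief.cov.ravel().tolist(),
        "log_precision": est.noise.log_precision.tolist(),
        "free_energy": est.free_energy,
        "n_iterations": est.n_iterations,
        "converged": est.converged,
        "f_trace": list(est.f_trace),
    }))


def read_posterior(path: str | Path) -> PosteriorEstimate:
    payload = json.loads(Path(path).read_text())
    mean = np.array(payload["mean"])
    cov = np.array(payload["cov"]).reshape(mean.size, mean.size)
    return PosteriorEstimate(
        belief=GaussianBelief(mean, cov),
        noise=NoiseModel(np.array(payload["log_precision"])),
        free_energy=payload["free_energy"],
        n_iterations=payload["n_iterations"],
        converged=payload["converged"],
        f_trace=list(payload["f_trace"]),
    )
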