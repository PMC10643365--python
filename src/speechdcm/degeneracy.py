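"""Degeneracy taxonomy of fitted models and cohort summaries.

Each fitted model (one subject x task x subregional configuration) is
assigned to one of four groups by the presence of *excitatory* connections
onto M1, where "excitatory" means a positive (model-averaged) posterior
mean together with a presence probability above 0.75:

    A: both pOp -> M1 and pSTS -> M1 excitatory
    B: only pSTS -> M1
    C: only pOp -> M1
    D: neither

A model is consistent with the classical serial (neurological) account
exactly when it is Group C *and* pSTS -> pOp is excitatory
(pSTS -> pOp -> M1).  Within-subject variability is quantified as the
Shannon entropy (nats) of the empirical group-membership distribution over
configurations, per task.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "ConnectionVerdict", "GROUP_LABELS", "DegeneracyReport", "assign_group",
    "neurological_consistent", "membership_entropy", "summarise_cohort",
    "compare_group_distributions", "PP_THRESHOLD",
]

PP_THRESHOLD = 0.75
GROUP_LABELS = ("A", "B", "C", "D")


@dataclass(frozen=True)
class ConnectionVerdict:
    """Posterior summary of one extrinsic connection."""

    posterior_mean: float      # Hz
    presence_pp: float
    threshold: float = PP_THRESHOLD

    def __post_init__(self):
        if not 0.0 <= self.presence_pp <= 1.0:
            raise ValueError("presence probability must lie in [0, 1]")

    @property
    def excitatory(self) -> bool:
        """Strictly positive mean with Pp strictly above the threshold."""
        return self.posterior_mean > 0.0 and self.presence_pp > self.threshold


def assign_group(pop_to_m1: ConnectionVerdict,
                 psts_to_m1: ConnectionVerdict,
                 threshold: float = PP_THRESHOLD) -> str:
    """Group label from the two afferents of M1 (total function)."""
    pop = ConnectionVerdict(pop_to_m1.posterior_mean,
                            pop_to_m1.presence_pp, threshold).excitatory
    psts = ConnectionVerdict(psts_to_m1.posterior_mean,
                             psts_to_m1.presence_pp, threshold).excitatory
    if pop and psts:
        return "A"
    if psts:
        return "B"
    if pop:
        return "C"
    return "D"


def neurological_consistent(label: str,
                            psts_to_pop: ConnectionVerdict) -> bool:
    """True iff the model realises the serial pSTS -> pOp -> M1 route."""
    return label == "C" and psts_to_pop.excitatory


def membership_entropy(labels: Sequence[str]) -> float:
    """Shannon entropy (nats) of the empirical membership distribution."""
    labels = list(labels)
    if not labels:
        raise ValueError("at least one label required")
    _, counts = np.unique(labels, return_counts=True)
    p = counts / counts.sum()
    return float(-(p * np.log(p)).sum())


@dataclass
class DegeneracyReport:
    """Cohort-level degeneracy summary.

    ``labels``: long table (subject, task, configuration, label,
    consistent).  ``per_subject_task``: membership distribution and entropy
    per subject x task.  ``group_counts``: models per group per task x
    configuration.  Scalars: fraction of subjects assigned to >= 2 distinct
    groups (across everything they were fitted on), mean entropy per task,
    and the fraction of models consistent with the serial account.
    """

    labels: pd.DataFrame
    per_subject_task: pd.DataFrame
    group_counts: pd.DataFrame
    fraction_multi_group: float
    mean_entropy: dict[str, float]
    fraction_consistent: float


def summarise_cohort(labels: pd.DataFrame) -> DegeneracyReport:
    """Summarise a long table of group assignments.

    ``labels`` must have columns subject, task, configuration, label and
    (optionally) consistent.  Missing cells are reported by raising, never
    imputed: every subject must carry the same task x configuration grid.
    """
    required = {"subject", "task", "configuration", "label"}
    if not required.issubset(labels.columns):
        raise ValueError(f"labels table needs columns {sorted(required)}")
    if not labels["label"].isin(GROUP_LABELS).all():
        raise ValueError("labels must be A-D")
    grid = labels.groupby("subject")[["task", "configuration"]].apply(
        lambda g: frozenset(map(tuple, g.values)))
    if grid.nunique() != 1:
        raise ValueError("incomplete cohort: subjects cover different "
                         "task x configuration cells")

    rows = []
    for (subject, task), g in labels.groupby(["subject", "task"]):
        dist = {lab: 0.0 for lab in GROUP_LABELS}
        for lab, cnt in g["label"].value_counts().items():
            dist[lab] = cnt / len(g)
        rows.append({
            "subject": subject, "task": task,
            **{f"p_{lab}": dist[lab] for lab in GROUP_LABELS},
            "entropy_nats": membership_entropy(g["label"].tolist()),
            "n_groups": g["label"].nunique(),
        })
    per_subject_task = pd.DataFrame(rows)

    group_counts = (labels.groupby(["task", "configuration", "label"])
                    .size().unstack(fill_value=0)
                    .reindex(columns=GROUP_LABELS, fill_value=0))

    n_groups_overall = labels.groupby("subject")["label"].nunique()
    fraction_multi = float((n_groups_overall >= 2).mean())
    mean_entropy = {task: float(g["entropy_nats"].mean())
                    for task, g in per_subject_task.groupby("task")}
    if "consistent" in labels.columns:
        fraction_consistent = float(labels["consistent"].mean())
    else:
        fraction_consistent = float("nan")
    return DegeneracyReport(
        labels=labels.reset_index(drop=True),
        per_subject_task=per_subject_task,
        group_counts=group_counts,
        fraction_multi_group=fraction_multi,
        mean_entropy=mean_entropy,
        fraction_consistent=fraction_consistent,
    )


def compare_group_distributions(counts_task1: pd.DataFrame,
                                counts_task2: pd.DataFrame) -> pd.Series:
    """Rank-sum comparison of per-subject group counts between two tasks.

    Each input is a subjects x groups (A-D) table of model counts.  A
    two-sided Mann-Whitney-Wilcoxon test is run per group and Bonferroni
    corrected (x4, capped at 1).
    """
    c1 = counts_task1.reindex(columns=GROUP_LABELS)
    c2 = counts_task2.reindex(columns=GROUP_LABELS)
    if not c1.index.sort_values().equals(c2.index.sort_values()):
        raise ValueError("the two tasks must cover the same subjects")
    adjusted = {}
    for lab in GROUP_LABELS:
        x, y = c1[lab].to_numpy(float), c2[lab].to_numpy(float)
        if np.all(x == x[0]) and np.all(y == y[0]) and x[0] == y[0]:
            p = 1.0   # identical constant samples: no evidence of a shift
        else:
            p = stats.mannwhitneyu(x, y, alternative="two-sided").pvalue
        adjusted[lab] = min(1.0, 4.0 * float(p))
    return pd.Series(adjusted, name="p_adjusted")
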