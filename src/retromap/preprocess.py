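"""Presence filtering and fold-change computation.

Affymetrix-style detection calls drive two rules applied before any
statistics: a probe set is kept only if, in at least one condition group
of an experiment, it is called present on at least half of the chips
(``ceil(min_fraction * group_size)``); and a probe set that fails this
criterion in an experiment is assigned a fold change of exactly 1 there,
so it can never be called responsive in that experiment.
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd

from retromap.containers import ExpressionMatrix, PresenceMatrix


def _condition_groups(expr: ExpressionMatrix) -> list[pd.Index]:
    """Sample-id groups, one per (experiment, condition) pair."""
    groups = []
    for (_, _), sub in expr.samples.groupby(
        ["experiment", "condition"], sort=False
    ):
        groups.append(sub.index)
    return groups


def presence_filter(
    expr: ExpressionMatrix,
    calls: PresenceMatrix,
    min_fraction: float = 0.5,
) -> set[str]:
    """Genes retained by the detection-call filter.

    A gene is retained iff in at least one condition group (an
    experiment's control chips or its treatment chips) the number of
    present calls is at least ``ceil(min_fraction * group_size)`` — the
    "not called absent in at least half of the chips" rule.
    """
    calls.check_aligned(expr)
    if not 0 <= min_fraction <= 1:
        raise ValueError("min_fraction must be in [0, 1]")
    retained = np.zeros(len(expr.gene_ids), dtype=bool)
    for ids in _condition_groups(expr):
        need = math.ceil(min_fraction * len(ids))
        retained |= (calls.flags[ids].sum(axis=1) >= need).to_numpy()
    return set(expr.gene_ids[retained])


def _group_means(
    expr: ExpressionMatrix, experiment: str
) -> tuple[pd.Series, pd.Series]:
    ctrl = expr.condition_samples(experiment, "control")
    trt = expr.condition_samples(experiment, "treatment")
    if len(ctrl) == 0 or len(trt) == 0:
        raise ValueError(
            f"experiment {experiment!r} lacks a control or treatment group"
        )
    return expr.values[ctrl].mean(axis=1), expr.values[trt].mean(axis=1)


def fold_change(
    expr: ExpressionMatrix,
    calls: PresenceMatrix,
    gene: str,
    experiment: str,
    min_fraction: float = 0.5,
) -> float:
    """Treatment/control fold change (linear scale) for one gene.

    Computed as ``2 ** (mean treatment log2 - mean control log2)`` — the
    ratio of geometric means — and overridden to exactly 1 when the gene
    fails the presence criterion within the experiment.
    """
    if gene not in expr.gene_ids:
        raise KeyError(f"unknown gene: {gene!r}")
    return float(
        fold_change_table(expr, calls, experiment, min_fraction).loc[gene]
    )


def fold_change_table(
    expr: ExpressionMatrix,
    calls: PresenceMatrix,
    experiment: str,
    min_fraction: float = 0.5,
) -> pd.Series:
    """Per-gene linear fold changes for one experiment (absent rule applied)."""
    calls.check_aligned(expr)
    sub = expr.subset(experiment)
    sub_calls = PresenceMatrix(calls.flags[sub.values.columns])
    ctrl_mean, trt_mean = _group_means(sub, experiment)
    fc = np.power(2.0, trt_mean - ctrl_mean)
    retained = presence_filter(sub, sub_calls, min_fraction)
    fc[~sub.gene_ids.isin(retained)] = 1.0
    fc.name = experiment
    return fc
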