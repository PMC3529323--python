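"""Gene x experiment response matrix and recurrence counting.

A gene's evidence across the compendium is summarized by how often it is
called responsive in each experiment class (mitochondrial vs chloroplast
perturbations), irrespective of direction. Responsive sets ("changed in at
least k experiments of the class") and their set algebra underpin the
overlap analysis and marker classification.
"""

from __future__ import annotations

import numpy as np
import pandas as pd


def response_matrix(
    de_results: pd.DataFrame,
    experiment_classes: pd.Series | dict,
) -> tuple[pd.DataFrame, pd.Series]:
    """Pivot stacked per-experiment calls into a gene x experiment matrix.

    Parameters
    ----------
    de_results
        Output of :func:`retromap.diffcall.call_compendium` (MultiIndex
        gene_id/experiment with a ``direction`` column), or any frame with
        gene_id, experiment and direction columns.
    experiment_classes
        Mapping experiment -> class label (``mito``/``chloro``/...).

    Returns
    -------
    calls : DataFrame of int8 in {-1, 0, +1} (down / ns / up)
    classes : Series experiment -> class, aligned to the call columns
    """
    df = de_results.reset_index() if de_results.index.nlevels > 1 else de_results
    calls = (
        df.pivot(index="gene_id", columns="experiment", values="direction")
        .fillna(0)
        .astype(np.int8)
    )
    classes = pd.Series(dict(experiment_classes), name="perturbation_class")
    missing = [e for e in calls.columns if e not in classes.index]
    if missing:
        raise ValueError(f"experiments without a class label: {missing}")
    return calls, classes.loc[calls.columns]


def recurrence_counts(
    calls: pd.DataFrame,
    classes: pd.Series,
    consistent_direction: bool = False,
) -> pd.DataFrame:
    """Per-gene counts of responsive experiments in each class.

    Direction is ignored by default (a gene "significantly changed" up or
    down counts equally); with ``consistent_direction=True`` only calls
    matching the gene's majority sign within the class are counted, for
    sensitivity analyses.
    """
    classes = classes.loc[calls.columns]
    out = {}
    for cls in ("mito", "chloro"):
        cols = calls.columns[classes == cls]
        sub = calls[cols]
        if consistent_direction:
            majority = np.sign(sub.sum(axis=1))
            majority[majority == 0] = 1
            n = sub.eq(majority, axis=0).sum(axis=1)
        else:
            n = (sub != 0).sum(axis=1)
        out[f"n_{cls}"] = n.astype(int)
    counts = pd.DataFrame(out, index=calls.index)
    counts.index.name = "gene_id"
    return counts


def responsive_set(
    counts: pd.DataFrame, cls: str, min_experiments: int
) -> set[str]:
    """Genes responsive in at least ``min_experiments`` experiments of a class."""
    col = f"n_{cls}"
    if col not in counts.columns:
        raise ValueError(f"unknown experiment class: {cls!r}")
    if min_experiments < 1:
        raise ValueError("min_experiments must be >= 1")
    return set(counts.index[counts[col] >= min_experiments])


def set_algebra(a: set, b: set) -> dict[str, int]:
    """Cardinalities of two gene sets and their intersection/union."""
    inter = len(a & b)
    return {
        "n_a": len(a),
        "n_b": len(b),
        "n_intersection": inter,
        "n_union": len(a) + len(b) - inter,
    }
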