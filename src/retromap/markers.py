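"""Marker-gene classification from recurrence counts.

A gene is a *common* marker when it responds in at least ``common_min``
experiments of both classes; a *class-specific* marker when it responds
in at least ``specific_min_*`` experiments of its class but at most
``specific_max_other`` of the other. The defaults follow the published
rule set for a 14-mitochondrial / 13-chloroplast compendium: common at
>= 6 and >= 6, mito-specific at >= 7 with <= 1 chloroplast responses,
chloro-specific at >= 6 with <= 1 mitochondrial responses. Requiring
``specific_max_other < common_min`` makes the labels mutually exclusive.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

LABELS = ("common", "mito_specific", "chloro_specific", "none")


@dataclass(frozen=True)
class MarkerThresholds:
    common_min: int = 6
    specific_min_mito: int = 7
    specific_min_chloro: int = 6
    specific_max_other: int = 1

    def __post_init__(self) -> None:
        if min(self.common_min, self.specific_min_mito, self.specific_min_chloro) < 1:
            raise ValueError("marker thresholds must be >= 1")
        if self.specific_max_other < 0:
            raise ValueError("specific_max_other must be >= 0")
        if self.specific_max_other >= self.common_min:
            raise ValueError(
                "specific_max_other must be < common_min for disjoint labels"
            )


def classify_markers(
    counts: pd.DataFrame,
    thresholds: MarkerThresholds = MarkerThresholds(),
) -> pd.DataFrame:
    """Attach a marker label to every gene's recurrence counts.

    ``counts`` must have columns ``n_mito`` and ``n_chloro`` (see
    :func:`retromap.metacounts.recurrence_counts`). Returns a copy with a
    ``label`` column in {common, mito_specific, chloro_specific, none}.
    """
    t = thresholds
    nm, nc = counts["n_mito"], counts["n_chloro"]
    out = counts.copy()
    out["label"] = "none"
    out.loc[(nm >= t.specific_min_mito) & (nc <= t.specific_max_other), "label"] = (
        "mito_specific"
    )
    out.loc[(nc >= t.specific_min_chloro) & (nm <= t.specific_max_other), "label"] = (
        "chloro_specific"
    )
    # common takes precedence; disjoint from the specific labels whenever
    # specific_max_other < common_min
    out.loc[(nm >= t.common_min) & (nc >= t.common_min), "label"] = "common"
    return out


def marker_summary(
    records: pd.DataFrame, recurrence_ks: tuple[int, ...] = (4, 6)
) -> dict:
    """Tallies per marker label plus per-class >= k recurrence counts."""
    label_counts = {
        lab: int((records["label"] == lab).sum()) for lab in LABELS
    }
    recurrence = {
        f"n_{cls}_ge_{k}": int((records[f"n_{cls}"] >= k).sum())
        for cls in ("mito", "chloro")
        for k in recurrence_ks
    }
    return {"labels": label_counts, "recurrence": recurrence}
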