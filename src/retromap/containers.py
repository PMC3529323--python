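"""In-memory containers for expression compendia.

An :class:`ExpressionMatrix` holds normalized log2-scale intensities
(genes x samples) together with per-sample metadata: which perturbation
experiment the sample belongs to, the experiment class (``mito``,
``chloro``, ``mixed`` or ``other``), whether the sample is a control or a
treatment chip, and a replicate index. A :class:`PresenceMatrix` carries
the matching per-chip present/absent detection flags.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

VALID_CONDITIONS = frozenset({"control", "treatment"})

#: metadata columns required on every sample table
SAMPLE_COLUMNS = ("experiment", "perturbation_class", "condition", "replicate")


@dataclass
class ExpressionMatrix:
    """Normalized log2 intensities with sample metadata.

    Parameters
    ----------
    values
        DataFrame of shape (n_genes, n_samples); index are unique gene
        (probe-set) ids, columns are sample ids.
    samples
        DataFrame indexed by sample id with columns ``experiment``,
        ``perturbation_class``, ``condition`` (control/treatment) and
        ``replicate``.
    """

    values: pd.DataFrame
    samples: pd.DataFrame

    def __post_init__(self) -> None:
        if self.values.index.duplicated().any():
            raise ValueError("duplicate gene ids in expression matrix")
        missing = [c for c in SAMPLE_COLUMNS if c not in self.samples.columns]
        if missing:
            raise ValueError(f"sample metadata lacks columns: {missing}")
        if set(self.values.columns) != set(self.samples.index):
            raise ValueError("sample ids of values and metadata do not match")
        bad = set(self.samples["condition"]) - VALID_CONDITIONS
        if bad:
            raise ValueError(f"invalid condition labels: {sorted(bad)}")
        # keep metadata in column order of the value matrix
        self.samples = self.samples.loc[self.values.columns]

    @property
    def gene_ids(self) -> pd.Index:
        return self.values.index

    @property
    def experiments(self) -> list[str]:
        return list(dict.fromkeys(self.samples["experiment"]))

    def experiment_class(self, experiment: str) -> str:
        cls = self.samples.loc[
            self.samples["experiment"] == experiment, "perturbation_class"
        ].unique()
        if len(cls) != 1:
            raise ValueError(f"experiment {experiment!r} has ambiguous class {cls}")
        return str(cls[0])

    def subset(self, experiment: str) -> "ExpressionMatrix":
        """Return the sub-matrix of one perturbation experiment."""
        mask = self.samples["experiment"] == experiment
        if not mask.any():
            raise KeyError(f"unknown experiment: {experiment!r}")
        ids = self.samples.index[mask]
        return ExpressionMatrix(self.values[ids], self.samples.loc[ids])

    def condition_samples(self, experiment: str, condition: str) -> pd.Index:
        mask = (self.samples["experiment"] == experiment) & (
            self.samples["condition"] == condition
        )
        return self.samples.index[mask]

    def to_tsv(self, values_path: str | Path, samples_path: str | Path) -> None:
        self.values.to_csv(values_path, sep="\t", index_label="gene_id")
        self.samples.to_csv(samples_path, sep="\t", index_label="sample_id")

    @classmethod
    def from_tsv(
        cls, values_path: str | Path, samples_path: str | Path
    ) -> "ExpressionMatrix":
        values = pd.read_csv(values_path, sep="\t", index_col=0)
        samples = pd.read_csv(samples_path, sep="\t", index_col=0)
        return cls(values, samples)


@dataclass
class PresenceMatrix:
    """Boolean present/absent detection flags aligned to an expression matrix."""

    flags: pd.DataFrame  # True = present

    def __post_init__(self) -> None:
        self.flags = self.flags.astype(bool)

    def check_aligned(self, expr: ExpressionMatrix) -> None:
        if not (
            self.flags.index.equals(expr.values.index)
            and self.flags.columns.equals(expr.values.columns)
        ):
            raise ValueError("presence flags are not aligned with the expression matrix")

    def subset(self, expr: ExpressionMatrix, experiment: str) -> "PresenceMatrix":
        ids = expr.samples.index[expr.samples["experiment"] == experiment]
        return PresenceMatrix(self.flags[ids])

    def to_tsv(self, path: str | Path) -> None:
        self.flags.replace({True: "P", False: "A"}).to_csv(
            path, sep="\t", index_label="gene_id"
        )

    @classmethod
    def from_tsv(cls, path: str | Path) -> "PresenceMatrix":
        raw = pd.read_csv(path, sep="\t", index_col=0)
        return cls(raw == "P")

    @classmethod
    def all_present(cls, expr: ExpressionMatrix) -> "PresenceMatrix":
        return cls(
            pd.DataFrame(
                True, index=expr.values.index, columns=expr.values.columns
            )
        )


def read_gene_list(path: str | Path) -> pd.Series:
    """Read a gene list file: one id per line, optional TAB-separated label.

    Returns a Series mapping gene id -> label (empty string when the file
    has a single column).
    """
    ids, labels = [], []
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split("\t")
        ids.append(parts[0])
        labels.append(parts[1] if len(parts) > 1 else "")
    return pd.Series(labels, index=pd.Index(ids, name="gene_id"), name="label")


def write_gene_list(genes: pd.Series | list[str], path: str | Path) -> None:
    with open(path, "w") as fh:
        if isinstance(genes, pd.Series):
            for gid, lab in genes.items():
                fh.write(f"{gid}\t{lab}\n" if lab else f"{gid}\n")
        else:
            for gid in genes:
                fh.write(f"{gid}\n")
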