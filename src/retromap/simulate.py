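"""Synthetic multi-experiment compendia with planted ground truth.

The generator emulates the statistical structure of a compendium of
replicated organelle-perturbation microarray studies: a shared
stress-responsive gene block that responds in both mitochondrial and
chloroplast perturbations, organelle-specific blocks, non-responsive
background genes, replicate noise on the log2 scale, and random
present/absent detection calls. Planted truth (per-gene label, signed
per-experiment effects, compartment annotation) is returned alongside the
data so every downstream stage can be benchmarked against it.

Defaults mirror the published compendium scale: 14 mitochondrial and 13
chloroplast perturbation experiments with 3 replicates per condition, and
compartment annotation frequencies matching the ATH1 array's chloroplast
(2198/22810), mitochondrion (1178/22810) and peroxisome (287/22810)
probe-set proportions.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from retromap.containers import ExpressionMatrix, PresenceMatrix
from retromap.motifs import IUPAC, Motif, write_promoters_fasta

#: ATH1 probe-set fractions per compartment, used for the unbiased
#: annotation background
COMPARTMENT_BACKGROUND = {
    "chloroplast": 2198 / 22810,
    "mitochondrion": 1178 / 22810,
    "peroxisome": 287 / 22810,
}

GENE_LABELS = ("shared", "mito_specific", "chloro_specific", "background")


@dataclass
class SyntheticConfig:
    """Stated world of a synthetic compendium.

    Fractions partition genes into a shared-responsive block, two
    organelle-specific blocks and background; ``respond_prob`` is the
    chance a responsive gene is actually perturbed in any one experiment
    of its class; effects have magnitude ``effect_size_log2`` with a sign
    fixed per gene; replicate noise is normal on the log2 scale.
    """

    n_genes: int = 2000
    n_mito_experiments: int = 14
    n_chloro_experiments: int = 13
    n_mixed_experiments: int = 0
    n_replicates: int = 3
    frac_shared: float = 0.05
    frac_mito_specific: float = 0.05
    frac_chloro_specific: float = 0.05
    respond_prob: float = 0.7
    effect_size_log2: float = 2.0
    noise_sd_log2: float = 0.25
    absent_prob: float = 0.05
    frac_compartment_biased: float = 0.5
    baseline_mean_log2: float = 8.0
    baseline_sd_log2: float = 2.0
    random_sign_per_experiment: bool = False
    planted_absent_genes: int = 0
    seed: int = 0

    def validate(self) -> None:
        fracs = (
            self.frac_shared,
            self.frac_mito_specific,
            self.frac_chloro_specific,
            self.respond_prob,
            self.absent_prob,
            self.frac_compartment_biased,
        )
        if any(not 0 <= f <= 1 for f in fracs):
            raise ValueError("all fractions/probabilities must lie in [0, 1]")
        if self.frac_shared + self.frac_mito_specific + self.frac_chloro_specific > 1:
            raise ValueError("gene-label fractions sum to more than 1")
        if min(self.n_genes, self.n_replicates) < 1:
            raise ValueError("counts must be >= 1")
        if self.n_mito_experiments < 1 or self.n_chloro_experiments < 1:
            raise ValueError("need at least one experiment per class")
        if self.noise_sd_log2 <= 0:
            raise ValueError("noise_sd_log2 must be > 0")

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SyntheticConfig":
        return cls(**yaml.safe_load(Path(path).read_text()))


@dataclass
class PlantedTruth:
    """Ground truth planted by the generator.

    ``labels``: gene -> {shared, mito_specific, chloro_specific, background};
    ``effects``: gene x experiment signed log2 effects (0 everywhere for
    background genes); ``compartments``: gene -> annotation label ('' for
    unannotated); ``experiment_classes``: experiment -> class.
    """

    labels: pd.Series
    effects: pd.DataFrame
    compartments: pd.Series
    experiment_classes: pd.Series

    def genes_with_label(self, label: str) -> set[str]:
        return set(self.labels.index[self.labels == label])

    def compartment_sets(self) -> dict[str, set[str]]:
        return {
            c: set(self.compartments.index[self.compartments == c])
            for c in COMPARTMENT_BACKGROUND
        }


@dataclass
class Compendium:
    """A generated compendium: expression + presence + planted truth."""

    expression: ExpressionMatrix
    presence: PresenceMatrix
    truth: PlantedTruth

    @property
    def experiments(self) -> list[str]:
        return self.expression.experiments

    def write(self, outdir: str | Path) -> dict[str, Path]:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {
            "expression": outdir / "expression.tsv",
            "samples": outdir / "samples.tsv",
            "presence": outdir / "presence.tsv",
            "truth_labels": outdir / "truth_labels.tsv",
            "truth_effects": outdir / "truth_effects.tsv",
        }
        self.expression.to_tsv(paths["expression"], paths["samples"])
        self.presence.to_tsv(paths["presence"])
        pd.DataFrame(
            {
                "label": self.truth.labels,
                "compartment": self.truth.compartments,
            }
        ).to_csv(paths["truth_labels"], sep="\t", index_label="gene_id")
        self.truth.effects.to_csv(paths["truth_effects"], sep="\t", index_label="gene_id")
        return paths


def _assign_labels(config: SyntheticConfig, rng: np.random.Generator) -> pd.Series:
    n = config.n_genes
    n_shared = int(round(config.frac_shared * n))
    n_mito = int(round(config.frac_mito_specific * n))
    n_chloro = int(round(config.frac_chloro_specific * n))
    labels = np.array(["background"] * n, dtype=object)
    order = rng.permutation(n)
    labels[order[:n_shared]] = "shared"
    labels[order[n_shared : n_shared + n_mito]] = "mito_specific"
    labels[order[n_shared + n_mito : n_shared + n_mito + n_chloro]] = "chloro_specific"
    gene_ids = pd.Index([f"g{i:05d}" for i in range(n)], name="gene_id")
    return pd.Series(labels, index=gene_ids, name="label")


def _assign_compartments(
    labels: pd.Series, config: SyntheticConfig, rng: np.random.Generator
) -> pd.Series:
    comp = pd.Series("", index=labels.index, name="compartment", dtype=object)
    # class-specific genes biased toward the matching compartment
    for lab, target in (
        ("mito_specific", "mitochondrion"),
        ("chloro_specific", "chloroplast"),
    ):
        ids = labels.index[labels == lab]
        biased = rng.random(len(ids)) < config.frac_compartment_biased
        comp.loc[ids[biased]] = target
        rest = ids[~biased]
        comp.loc[rest] = _background_compartments(len(rest), rng)
    other = labels.index[labels.isin(["shared", "background"])]
    comp.loc[other] = _background_compartments(len(other), rng)
    return comp


def _background_compartments(n: int, rng: np.random.Generator) -> np.ndarray:
    names = list(COMPARTMENT_BACKGROUND) + [""]
    probs = list(COMPARTMENT_BACKGROUND.values())
    probs.append(1.0 - sum(probs))
    return rng.choice(names, size=n, p=probs)


def _experiment_table(config: SyntheticConfig) -> pd.Series:
    names, classes = [], []
    for cls, count in (
        ("mito", config.n_mito_experiments),
        ("chloro", config.n_chloro_experiments),
        ("mixed", config.n_mixed_experiments),
    ):
        for i in range(count):
            names.append(f"{cls}_{i + 1:02d}")
            classes.append(cls)
    return pd.Series(classes, index=pd.Index(names, name="experiment"))


_RESPONDING_LABELS = {
    "mito": ("shared", "mito_specific"),
    "chloro": ("shared", "chloro_specific"),
    "mixed": ("shared", "mito_specific", "chloro_specific"),
}


def generate_compendium(config: SyntheticConfig) -> Compendium:
    """Generate a replicated control/treatment compendium with planted truth.

    Reproducible bit-for-bit for a fixed config (including seed). Raises
    on invalid configs (e.g. label fractions summing above 1).
    """
    config.validate()
    rng = np.random.default_rng(config.seed)

    labels = _assign_labels(config, rng)
    compartments = _assign_compartments(labels, config, rng)
    gene_ids = labels.index
    n = len(gene_ids)
    signs = pd.Series(rng.choice([-1.0, 1.0], size=n), index=gene_ids)
    baseline = rng.normal(config.baseline_mean_log2, config.baseline_sd_log2, size=n)

    exp_classes = _experiment_table(config)
    effects = pd.DataFrame(0.0, index=gene_ids, columns=exp_classes.index)
    for exp, cls in exp_classes.items():
        responsive = labels.isin(_RESPONDING_LABELS[cls]).to_numpy()
        hit = responsive & (rng.random(n) < config.respond_prob)
        sign = (
            rng.choice([-1.0, 1.0], size=n)
            if config.random_sign_per_experiment
            else signs.to_numpy()
        )
        effects.loc[hit, exp] = sign[hit] * config.effect_size_log2

    values, flags, meta_rows = {}, {}, []
    n_rep = config.n_replicates
    for exp, cls in exp_classes.items():
        eff = effects[exp].to_numpy()
        for condition in ("control", "treatment"):
            mean = baseline + (eff if condition == "treatment" else 0.0)
            for rep in range(1, n_rep + 1):
                sid = f"{exp}_{condition[:4]}_{rep}"
                values[sid] = mean + rng.normal(0.0, config.noise_sd_log2, size=n)
                flags[sid] = rng.random(n) >= config.absent_prob
                meta_rows.append((sid, exp, cls, condition, rep))

    # planted-absent mode: force whole-compendium absence for the first k
    # background genes, exercising the fold-change-1 rule downstream
    if config.planted_absent_genes:
        bg_ids = labels.index[labels == "background"][: config.planted_absent_genes]
        pos = gene_ids.get_indexer(bg_ids)
        for sid in flags:
            flags[sid][pos] = False

    samples = pd.DataFrame(
        meta_rows,
        columns=["sample_id", "experiment", "perturbation_class", "condition", "replicate"],
    ).set_index("sample_id")
    expr = ExpressionMatrix(pd.DataFrame(values, index=gene_ids), samples)
    presence = PresenceMatrix(pd.DataFrame(flags, index=gene_ids))
    truth = PlantedTruth(labels, effects, compartments, exp_classes)
    return Compendium(expr, presence, truth)


# ---------------------------------------------------------------------------
# synthetic promoters


def _realize_motif(motif: Motif, rng: np.random.Generator) -> str:
    return "".join(rng.choice(list(IUPAC[c])) for c in motif.iupac)


def _plant_positions(
    k: int, motif_len: int, length: int, rng: np.random.Generator
) -> list[int]:
    """Non-overlapping start positions for k instances (best effort)."""
    chosen: list[int] = []
    candidates = rng.permutation(length - motif_len + 1)
    for pos in candidates:
        if all(abs(pos - q) >= motif_len for q in chosen):
            chosen.append(int(pos))
            if len(chosen) == k:
                break
    return chosen


def generate_promoters(
    n_foreground: int,
    n_background: int,
    motif: Motif | str,
    planted_rate_fg: float,
    planted_rate_bg: float,
    promoter_length: int = 1000,
    seed: int = 0,
    alphabet: str = "ACGT",
) -> tuple[dict[str, str], dict[str, str], pd.Series]:
    """Random promoter sets with Poisson-planted motif instances.

    Returns (foreground sequences, background sequences, true planted
    counts per promoter id). Foreground promoters are planted at rate
    ``planted_rate_fg`` instances per promoter, background at
    ``planted_rate_bg``. The background letters are drawn uniformly from
    ``alphabet`` (restricting it to letters incompatible with the motif
    makes spurious matches impossible, so a scanner must recover the
    planted counts exactly). The default length matches the 1 kb upstream
    regions conventionally used for promoter scans.
    """
    if isinstance(motif, str):
        motif = Motif("planted", motif)
    if planted_rate_fg < 0 or planted_rate_bg < 0:
        raise ValueError("planted rates must be >= 0")
    if len(motif) > promoter_length:
        raise ValueError("motif longer than the promoter length")
    rng = np.random.default_rng(seed)
    counts: dict[str, int] = {}

    def make_set(prefix: str, n_prom: int, rate: float) -> dict[str, str]:
        seqs = {}
        for i in range(n_prom):
            pid = f"{prefix}_{i + 1:04d}"
            seq = rng.choice(list(alphabet), size=promoter_length)
            k = int(rng.poisson(rate))
            placed = _plant_positions(k, len(motif), promoter_length, rng) if k else []
            for pos in placed:
                seq[pos : pos + len(motif)] = list(_realize_motif(motif, rng))
            seqs[pid] = "".join(seq)
            counts[pid] = len(placed)
        return seqs

    fg = make_set("fg", n_foreground, planted_rate_fg)
    bg = make_set("bg", n_background, planted_rate_bg)
    truth = pd.Series(counts, name="planted_count")
    truth.index.name = "promoter_id"
    return fg, bg, truth


def write_promoters(
    fg: dict[str, str], bg: dict[str, str], outdir: str | Path
) -> dict[str, Path]:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "foreground": outdir / "promoters_fg.fasta",
        "background": outdir / "promoters_bg.fasta",
    }
    write_promoters_fasta(fg, paths["foreground"])
    write_promoters_fasta(bg, paths["background"])
    return paths
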