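"""Stage orchestration: run the analysis end to end on disk artifacts.

Each stage reads the TSV/FASTA artifacts of its upstream stages from the
output directory and writes its own, so stages can be re-run selectively.
A manifest (JSON) records every written file with a SHA-256 checksum, the
configuration hash and the seed, making reruns verifiable: identical
configuration and seed reproduce byte-identical numeric artifacts.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import pandas as pd
import yaml

from retromap import __version__
from retromap.containers import ExpressionMatrix, PresenceMatrix
from retromap.diffcall import call_compendium
from retromap.enrichment import enrichment_test
from retromap.markers import MarkerThresholds, classify_markers, marker_summary
from retromap.metacounts import (
    recurrence_counts,
    response_matrix,
    responsive_set,
    set_algebra,
)
from retromap.cluster import ExperimentClusterer
from retromap.motifs import (
    DEFAULT_MOTIFS,
    motif_enrichment,
    read_motif_library,
    read_promoters_fasta,
    scan_promoters,
)
from retromap.simulate import SyntheticConfig, generate_compendium

STAGES = (
    "simulate",
    "preprocess",
    "diffcall",
    "metacounts",
    "enrich",
    "markers",
    "cluster",
    "motifs",
)

#: artifacts each stage requires from its upstream stages
_STAGE_INPUTS = {
    "preprocess": ("expression.tsv", "samples.tsv", "presence.tsv"),
    "diffcall": ("expression.tsv", "samples.tsv", "presence.tsv"),
    "metacounts": ("de_results.tsv", "samples.tsv"),
    "enrich": ("recurrence.tsv", "truth_labels.tsv"),
    "markers": ("recurrence.tsv",),
    "cluster": ("de_results.tsv", "recurrence.tsv"),
    "motifs": ("promoters_fg.fasta", "promoters_bg.fasta"),
}


@dataclass
class PipelineConfig:
    """Paths, thresholds and seeds for a pipeline run."""

    outdir: str = "retromap_out"
    synthetic: SyntheticConfig = field(default_factory=SyntheticConfig)
    fc_threshold: float = 2.0
    ppde_threshold: float = 0.95
    window: int = 101
    prior_df: int = 10
    min_fraction: float = 0.5
    min_recurrence: int = 4
    marker_thresholds: MarkerThresholds = field(default_factory=MarkerThresholds)
    n_clusters: int = 3
    enrichment_p: float = 0.05
    enrichment_min_ratio: float = 2.0
    motif_library: str | None = None
    promoter_motif: str = "TTGACY"
    promoter_rate_fg: float = 2.0
    promoter_rate_bg: float = 0.5
    seed: int = 0

    def config_hash(self) -> str:
        # outdir is a storage location, not a semantic setting
        plain = {k: v for k, v in self._as_plain().items() if k != "outdir"}
        blob = json.dumps(plain, sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]

    def _as_plain(self) -> dict:
        d = asdict(self)
        return d

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self._as_plain(), sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text())
        if "synthetic" in raw:
            raw["synthetic"] = SyntheticConfig(**raw["synthetic"])
        if "marker_thresholds" in raw:
            raw["marker_thresholds"] = MarkerThresholds(**raw["marker_thresholds"])
        return cls(**raw)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


class DependencyError(RuntimeError):
    pass


def _require(outdir: Path, stage: str) -> None:
    for name in _STAGE_INPUTS.get(stage, ()):
        if not (outdir / name).exists():
            raise DependencyError(
                f"stage {stage!r} needs missing artifact {name!r}; "
                "run its upstream stage first"
            )


def run(config: PipelineConfig, stages: list[str] | tuple[str, ...] = STAGES) -> dict:
    """Execute the requested stages in canonical order; return the manifest."""
    unknown = set(stages) - set(STAGES)
    if unknown:
        raise ValueError(f"unknown stages: {sorted(unknown)}")
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []

    for stage in [s for s in STAGES if s in stages]:
        _require(outdir, stage)
        written += _run_stage(stage, config, outdir)

    manifest = {
        "version": __version__,
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "stages": list(stages),
        "artifacts": {
            str(p.relative_to(outdir)): _sha256(p) for p in sorted(set(written))
        },
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest


def _run_stage(stage: str, config: PipelineConfig, outdir: Path) -> list[Path]:
    if stage == "simulate":
        sc = config.synthetic
        sc.seed = config.seed
        comp = generate_compendium(sc)
        paths = comp.write(outdir)
        sc.to_yaml(outdir / "synthetic_config.yaml")
        from retromap.simulate import generate_promoters, write_promoters

        fg, bg, planted = generate_promoters(
            n_foreground=30,
            n_background=100,
            motif=config.promoter_motif,
            planted_rate_fg=config.promoter_rate_fg,
            planted_rate_bg=config.promoter_rate_bg,
            seed=config.seed + 1,
        )
        ppaths = write_promoters(fg, bg, outdir)
        planted.to_csv(outdir / "promoters_planted.tsv", sep="\t")
        return list(paths.values()) + list(ppaths.values()) + [
            outdir / "synthetic_config.yaml",
            outdir / "promoters_planted.tsv",
        ]

    if stage == "preprocess":
        expr = ExpressionMatrix.from_tsv(outdir / "expression.tsv", outdir / "samples.tsv")
        presence = PresenceMatrix.from_tsv(outdir / "presence.tsv")
        from retromap.preprocess import presence_filter

        rows = []
        for exp in expr.experiments:
            sub = expr.subset(exp)
            sub_p = PresenceMatrix(presence.flags[sub.values.columns])
            kept = presence_filter(sub, sub_p, config.min_fraction)
            rows += [(g, exp) for g in sorted(kept)]
        pd.DataFrame(rows, columns=["gene_id", "experiment"]).to_csv(
            outdir / "retained.tsv", sep="\t", index=False
        )
        return [outdir / "retained.tsv"]

    if stage == "diffcall":
        expr = ExpressionMatrix.from_tsv(outdir / "expression.tsv", outdir / "samples.tsv")
        presence = PresenceMatrix.from_tsv(outdir / "presence.tsv")
        de = call_compendium(
            expr,
            presence,
            window=config.window,
            prior_df=config.prior_df,
            fc_threshold=config.fc_threshold,
            ppde_threshold=config.ppde_threshold,
            min_fraction=config.min_fraction,
        )
        de.to_csv(outdir / "de_results.tsv", sep="\t")
        return [outdir / "de_results.tsv"]

    if stage == "metacounts":
        de = pd.read_csv(
            outdir / "de_results.tsv", sep="\t", index_col=["gene_id", "experiment"]
        )
        samples = pd.read_csv(outdir / "samples.tsv", sep="\t", index_col=0)
        classes = (
            samples.drop_duplicates("experiment")
            .set_index("experiment")["perturbation_class"]
        )
        calls, cls = response_matrix(de, classes)
        calls.to_csv(outdir / "response_matrix.tsv", sep="\t")
        counts = recurrence_counts(calls, cls)
        counts.to_csv(outdir / "recurrence.tsv", sep="\t")
        a = responsive_set(counts, "mito", config.min_recurrence)
        b = responsive_set(counts, "chloro", config.min_recurrence)
        (outdir / "venn.json").write_text(json.dumps(set_algebra(a, b), indent=2))
        return [outdir / "response_matrix.tsv", outdir / "recurrence.tsv", outdir / "venn.json"]

    if stage == "enrich":
        counts = pd.read_csv(outdir / "recurrence.tsv", sep="\t", index_col=0)
        ann = pd.read_csv(outdir / "truth_labels.tsv", sep="\t", index_col=0)
        universe = set(counts.index)
        cats = {
            c: set(ann.index[ann["compartment"] == c])
            for c in ("chloroplast", "mitochondrion", "peroxisome")
        }
        rows = []
        for cls in ("mito", "chloro"):
            fg = responsive_set(counts, cls, config.min_recurrence)
            for cname, members in cats.items():
                res = enrichment_test(fg, members & universe, universe)
                rec = res.as_dict()
                rec.update(foreground=cls, category=cname)
                rows.append(rec)
        pd.DataFrame(rows).to_csv(outdir / "enrichment.tsv", sep="\t", index=False)
        return [outdir / "enrichment.tsv"]

    if stage == "markers":
        counts = pd.read_csv(outdir / "recurrence.tsv", sep="\t", index_col=0)
        records = classify_markers(counts, config.marker_thresholds)
        records.to_csv(outdir / "markers.tsv", sep="\t")
        (outdir / "marker_summary.json").write_text(
            json.dumps(marker_summary(records), indent=2)
        )
        return [outdir / "markers.tsv", outdir / "marker_summary.json"]

    if stage == "cluster":
        de = pd.read_csv(
            outdir / "de_results.tsv", sep="\t", index_col=["gene_id", "experiment"]
        )
        counts = pd.read_csv(outdir / "recurrence.tsv", sep="\t", index_col=0)
        pooled = sorted(
            responsive_set(counts, "mito", config.min_recurrence)
            | responsive_set(counts, "chloro", config.min_recurrence)
        )
        profiles = (
            de.reset_index()
            .pivot(index="experiment", columns="gene_id", values="log2_fc")
            .loc[:, pooled]
        )
        model = ExperimentClusterer(n_clusters=config.n_clusters).fit(profiles)
        (outdir / "experiments.nwk").write_text(model.newick_ + "\n")
        pd.Series(model.labels_, index=profiles.index, name="cluster").to_csv(
            outdir / "clusters.tsv", sep="\t"
        )
        return [outdir / "experiments.nwk", outdir / "clusters.tsv"]

    if stage == "motifs":
        motifs = (
            read_motif_library(config.motif_library)
            if config.motif_library
            else DEFAULT_MOTIFS
        )
        fg = read_promoters_fasta(outdir / "promoters_fg.fasta")
        bg = read_promoters_fasta(outdir / "promoters_bg.fasta")
        fg_table = scan_promoters(fg, motifs)
        bg_table = scan_promoters(bg, motifs)
        fg_table.counts.to_csv(outdir / "motif_counts_fg.tsv", sep="\t")
        bg_table.counts.to_csv(outdir / "motif_counts_bg.tsv", sep="\t")
        enr = motif_enrichment(fg_table, bg_table, mode="promoter_presence")
        enr.to_csv(outdir / "motif_enrichment.tsv", sep="\t")
        return [
            outdir / "motif_counts_fg.tsv",
            outdir / "motif_counts_bg.tsv",
            outdir / "motif_enrichment.tsv",
        ]

    raise ValueError(f"unknown stage: {stage!r}")
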