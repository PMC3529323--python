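# retromap

Meta-analysis of nuclear transcriptional responses to mitochondrial versus
chloroplast perturbations (retrograde signaling), built as a reusable,
tested pipeline.

When mitochondria or chloroplasts are stressed — by chemical inhibitors
(antimycin A, rotenone, norflurazon, lincomycin, ...) or by mutations in
organellar proteins — the organelles signal back to the nucleus and reshape
gene expression. Comparing many independent perturbation experiments lets
one ask: which responses are shared between the two organelles, which are
organelle-specific, and which genes are reliable *markers* of mitochondrial
or chloroplast dysfunction? `retromap` implements that comparison for
anyone analyzing a compendium of replicated expression experiments
(classically Affymetrix ATH1 microarrays), and ships a synthetic-compendium
generator with planted ground truth so that every stage can be benchmarked.

## The analysis

For each experiment (control vs treatment chips, replicated):

1. **Presence filter** — a probe set is kept if it is called present on at
   least `⌈f·n⌉` chips of some condition group (default f = 1/2); genes
   failing the filter get fold change 1 in that experiment.
2. **Regularized t statistic** (Cyber-T style) — the per-gene replicate
   variance σ̂²ᵍ is shrunk toward the mean variance σ̂²_bg of the `w`
   genes nearest in mean-expression rank:

       σ²_reg = (ν·σ̂²_bg + (n−1)·σ̂²ᵍ) / (ν + n − 1),   df = n₁+n₂−2+2ν

   with window w = 101 and prior weight ν = 10 by default.
3. **PPDE** — two-sided p-values are modeled as a beta-uniform mixture
   f(p) = π₀ + (1−π₀)·a·p^(a−1); the posterior probability of differential
   expression given P ≤ p is PPDE(p) = 1 − π₀p/F(p). A gene is *responsive*
   when its fold change is strictly more than twofold (either direction)
   and PPDE > 0.95.

Across the compendium, per-gene recurrence counts (how many mitochondrial /
chloroplast experiments called the gene) drive:

- **responsive sets** (≥ k experiments of a class; k = 4 or 6 classically)
  and their overlap, with expected chance overlap |A||B|/N and a
  hypergeometric tail p-value (plus a permutation cross-check);
- **compartment enrichment** of responsive sets against chloroplast /
  mitochondrion / peroxisome / transcription-factor annotation lists
  (observed, expected, obs/exp ratio, both tails);
- **marker classification**: *common* markers respond in ≥ 6 experiments
  of both classes; *specific* markers respond in ≥ 7 (mito) or ≥ 6
  (chloro) experiments of their class and ≤ 1 of the other;
- **experiment clustering**: average linkage (UPGMA) on 1 − Pearson
  distance between per-experiment log2-fold-change profiles, exported as
  Newick;
- **promoter-motif scanning**: occurrence counting of IUPAC consensus
  motifs (W-box, G-box/ABRE, GCC-box, Evening Element, I-box, ...) on both
  strands with palindrome de-duplication, and foreground-vs-background
  over-representation.

## Worked example

```python
import retromap as rm

cfg = rm.SyntheticConfig(seed=20)   # 2000 genes, 14 mito + 13 chloro experiments
comp = rm.generate_compendium(cfg)
de = rm.call_compendium(comp.expression, comp.presence)
calls, classes = rm.response_matrix(de, comp.truth.experiment_classes)
counts = rm.recurrence_counts(calls, classes)

mito = rm.responsive_set(counts, "mito", 4)
chloro = rm.responsive_set(counts, "chloro", 4)
print(rm.set_algebra(mito, chloro))
res = rm.enrichment_test(
    mito, comp.truth.compartment_sets()["mitochondrion"], set(counts.index))
print(f"obs={res.observed} exp={res.expected:.1f} ratio={res.ratio:.2f} p={res.p_over:.2e}")
print(rm.classify_markers(counts)["label"].value_counts().to_dict())
```

prints

```
{'n_a': 200, 'n_b': 200, 'n_intersection': 100, 'n_union': 300}
obs=64 exp=16.9 ratio=3.79 p=4.42e-25
{'none': 1709, 'common': 98, 'chloro_specific': 98, 'mito_specific': 95}
```

Reading: 200 genes are responsive in ≥ 4 mitochondrial experiments and 200
in ≥ 4 chloroplast experiments, sharing 100 (the planted shared stress
block); the mitochondrial responsive set contains 64 mitochondrion-annotated
genes against 16.9 expected by chance (3.8-fold enrichment, p ≈ 4e-25); and
marker classification recovers essentially all of the 100 planted genes per
category (98 common, 95 mito-specific, 98 chloro-specific).

The same pipeline runs from the shell on TSV/FASTA artifacts:

```
retromap --outdir out --seed 20 run-all     # or individual stages:
retromap --outdir out --seed 20 simulate
retromap --outdir out diffcall
```

## Acceptance script

`scripts/acceptance.py` recomputes, through the package's enrichment
machinery, the headline overlap and compartment-enrichment arithmetic for
the published set sizes (responsive-set sizes 720 and 606 in a universe of
22810 probe sets, the annotation category sizes, and the printed observed
counts): expected overlaps, obs/exp ratios, and the hypergeometric tail
probability of the observed 129-gene overlap.

```
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```
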