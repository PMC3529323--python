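# Methods

This note documents the statistical model behind each stage, the defaults
and why they were chosen, what the synthetic generator does and does not
emulate, and the numerical conventions.

## Differential-response calling

**Model.** Within one experiment, each gene has `n` control and `n`
treatment chips on the log2 scale. The replicate variance of a single gene
at microarray sample sizes (n = 2–4) is a poor estimate, so it is shrunk
toward a *local background*: genes are ranked by within-group mean
expression and the background variance is the running mean of sample
variances over a centered window of `window` genes (shrinking symmetrically
at the rank edges). The regularized variance is the convex combination

    var_reg = (prior_df · var_bg + (n − 1) · var_gene) / (prior_df + n − 1)

and the test statistic is the two-sample t on group means with the
regularized variances in the standard error and
`df = n1 + n2 − 2 + 2·prior_df`. Defaults `window = 101`, `prior_df = 10`
are the conventional settings of this Bayesian-regularization framework;
both are exposed. `prior_df = 0` reduces exactly to the ordinary pooled t
(verified to 1e-10 against an independent t-test implementation).

Groups need at least two replicates: with one replicate there is no
within-group variance anywhere, so the background window that the prior
shrinks toward is itself undefined.

**PPDE.** The two-sided p-values of one experiment are fitted with a
beta-uniform mixture, density `f(p) = π0 + (1−π0)·a·p^(a−1)`, `0 < a < 1`.
Fitting is direct likelihood maximization (L-BFGS-B) from a 3×2 grid of
starts (a ∈ {0.1, 0.3, 0.5}, π0 ∈ {0.5, 0.9}), tolerance 1e-8 — this is
deterministic and avoids EM stalling. The reported quantity is the
*cumulative* posterior

    PPDE(p) = P(DE | P ≤ p) = 1 − π0·p / F(p),
    F(p) = π0·p + (1−π0)·p^a,

which is monotone non-increasing in p and equals 1 − π0 at p = 1. At least
50 p-values are required for a stable fit.

**Calling rule.** `significant ⇔ max(FC, 1/FC) > 2 (strict) and
PPDE > 0.95 (strict)`. Fold changes are ratios of geometric means
(`2^(mean treatment log2 − mean control log2)`); an arithmetic-mean variant
was considered and rejected as the default because the data are modeled on
the log scale throughout. Genes failing the presence filter in an
experiment are assigned fold change exactly 1 there (hence never called),
with NaN statistics.

**Presence filter.** "Present on at least half of the chips of some
condition group" is implemented as `count ≥ ceil(min_fraction · n)` per
(experiment, condition) group, any single group sufficing; filtering is
per-experiment, since each study is normalized independently. The rule is
monotone: raising `min_fraction` never grows the retained set.

## Recurrence, markers, enrichment

Recurrence counts tally, per gene and experiment class, the experiments
that called the gene responsive in *either* direction; an optional
consistent-direction mode counts only the majority sign (sensitivity
analysis — published counts do not require directional consistency).

Marker thresholds default to the published rule set for a 14-mitochondrial
/ 13-chloroplast compendium: common at ≥ 6 and ≥ 6, mito-specific at ≥ 7
with ≤ 1 chloroplast calls, chloro-specific at ≥ 6 with ≤ 1 mitochondrial
calls. Requiring `specific_max_other < common_min` makes the three marker
labels provably disjoint; common takes precedence in the implementation,
which is a no-op under that constraint. The asymmetric specific minima
reflect the different class sizes (14 vs 13 experiments).

Enrichment uses the independence expectation `|A||B|/N` kept unrounded
internally (tables round only for display: 177/58.39 = 3.03, not 177/58),
the hypergeometric upper/lower tail for significance (one-sided Fisher
test; verified against exhaustive enumeration for all universes N ≤ 12),
and an optional permutation null (add-one-smoothed empirical tail over
random foregrounds) as a Monte-Carlo cross-check. The universe defaults to
the full annotation table (ATH1 analog: 22810 probe sets) and is
configurable. Category scanning retains categories with either tail
p < 0.05 and a ratio at least twofold in either direction.

## Experiment clustering

Experiments are points in the space of log2 fold changes over the pooled
responsive gene set; not-significant/absent entries contribute 0 (the
fold-change-1 rule), so all experiments share a complete feature space.
Distance is 1 − Pearson correlation (range [0, 2]; zero-variance profiles
are an error naming the item); linkage is average (UPGMA), the
Multiexperiment-Viewer default, deterministic with ties broken toward the
lowest pair index. Flat clusters come from cutting the tree at k clusters.

**Newick convention.** An internal node sits at depth equal to its merge
height; a branch length is parent height minus child height, leaves at
height 0. Two leaves merging at height h therefore serialize as
`(A:h,B:h);`, and leaf depth equals the root merge height (ultrametric).
Names containing spaces or Newick metacharacters are single-quoted.

## Promoter motifs

Motifs are IUPAC consensus strings (minimum length 4). An occurrence is a
distinct forward-coordinate start position matching the motif or (both
strands) its reverse complement; overlapping occurrences count, a
palindromic site counts once, and `N` in a sequence matches *no* motif
letter — the conservative choice that avoids inflating counts on masked
bases; a motif `N` is also unmatched by a sequence `N` for the same reason.
The shipped library (W-box TTGACY, T-box ACTTTG, G-box CACGTG, ABRE
ACGTGKC, Evening Element AAAATATCT, I-box GATAAG, GCC-box GCCGCC) uses
conventional consensus definitions from the plant cis-element literature;
tools differ on some of these, so the library is a declared, editable
input rather than ground truth, and published per-gene count tables are
not reproduction targets.

Enrichment modes: `promoter_presence` (hypergeometric on promoters
containing ≥ 1 occurrence, delegating to the enrichment module; requires
disjoint foreground/background ids) and `occurrence_rate` (one-sided
binomial test of total foreground occurrences against the background
per-position rate, add-one smoothed so an occurrence-free background still
defines a null rate).

## Synthetic compendia

The generator states a world emulating the structure of a
multi-study perturbation compendium:

- gene blocks: `frac_shared` respond in both classes, `frac_mito_specific`
  / `frac_chloro_specific` in one, remainder background (zero effect
  everywhere); block fractions of 5% each by default at 2000 genes;
- per experiment of a gene's class, the gene is perturbed with probability
  `respond_prob` (default 0.7 — published marker genes recur in roughly
  half to three-quarters of their class's experiments, not all);
- planted effects have magnitude exactly `effect_size_log2` (default 2,
  i.e. fourfold — strong responders of this literature) with a sign fixed
  per gene, since published markers respond consistently; an option
  randomizes the sign per experiment for robustness testing;
- replicate noise is i.i.d. normal on log2 scale (`noise_sd_log2 = 0.25`,
  a typical between-replicate spread for normalized arrays; baselines
  N(8, 2)); 3 replicates per condition, 14 + 13 experiments as in the
  compendium the defaults mirror;
- absent calls are i.i.d. Bernoulli per chip (`absent_prob = 0.05`); a
  planted-absent mode forces whole-compendium absence for chosen genes to
  exercise the fold-change-1 rule;
- compartment annotation: a fraction `frac_compartment_biased` (default
  0.5) of each class-specific block is annotated to the matching
  compartment; all other genes draw compartments at the ATH1 background
  rates (chloroplast 2198/22810, mitochondrion 1178/22810, peroxisome
  287/22810);
- an optional third experiment class `mixed` responds to both organelle
  blocks, giving three planted experiment groups for clustering
  benchmarks (the real compendium's tree shows three main groups, with
  some nominally mitochondrial treatments clustering with chloroplast
  ones).

Promoter generation plants Poisson-distributed, non-overlapping,
concretely realized instances of an IUPAC motif into random background
sequence (default 1 kb, the conventional upstream window); restricting the
background alphabet to letters incompatible with the motif makes spurious
matches impossible, so exact count recovery by the scanner is testable.

**What a green test does not establish.** The generator draws i.i.d.
normal noise with equal variance across genes and experiments; real
compendia have heavy-tailed noise, correlated genes, batch effects,
platform differences and probe-level artifacts, and real responsive genes
have graded, not fixed-magnitude, effects. Recovery rates on this world
are therefore upper bounds on real-data performance; the arithmetic checks
(overlap expectation, enrichment ratios, tail probabilities) are exact
regardless.

## Numerical conventions

- Zero pooled variance with unequal means: p is set to the smallest
  positive double rather than 0.
- p-values entering the mixture fit are clipped into (0, 1]; p = 0 is
  rejected as invalid input.
- Ratios are computed on unrounded expected values; display rounding is
  the caller's concern.
- All randomness flows through `numpy.random.default_rng(seed)`; identical
  configuration and seed reproduce byte-identical artifacts (checksummed
  in the pipeline manifest).

## Known limitations

- No probe-level normalization (MAS5/RMA) or CEL handling: inputs are
  normalized log2 matrices with detection calls.
- One replicate per condition is unsupported (see above).
- The beta-uniform mixture assumes p-values are uniform under the null;
  strongly discrete p-values (tiny replicate numbers) can bias π0.
- De novo motif discovery is out of scope; only known-motif counting.
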