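# Methods

## Consensus clustering

`run_consensus` implements the Monti resampling estimator. Per repetition
it draws ⌊pItem·n⌋ samples and ⌊pFeature·m⌋ features without replacement,
partitions the subsample with k-means (Euclidean distance, k-means++
seeding, 10 restarts by default), and accumulates two tallies per sample
pair: co-sampling and co-clustering. The consensus matrix is their
elementwise ratio; pairs never co-sampled are defined as 0 and excluded
from all CDF/PAC computations (with pItem = 0.8 and 50 reps the
probability of an unvisited pair is negligible, but the estimator must not
divide by zero). Defaults follow the subtyping protocol: maxK = 9,
reps = 50, pItem = 0.8, pFeature = 1. Per-rep RNG streams are spawned
from the master seed, so results are independent of execution order. A
rep in which k-means returns fewer than K nonempty clusters is retried
with a fresh restart and counted in the run record.

Final per-K labels come from average-linkage hierarchical clustering of
1 − consensus cut at K — standard consensus-clustering practice; the base
partitioner's labels are not reused because they exist only per
subsample. Clusters are renumbered by decreasing size so that C1 is
always the largest, making outputs stable across seeds.

## PAC model selection

PAC (proportion of ambiguous clustering) is CDF(x2) − CDF(x1) of the
pairwise consensus values, window (0.1, 0.9) — the standard ambiguity
interval. Lower is better; `select_best_k` takes the argmin over K with
ties resolved toward the smaller K. A perfectly stable partition has PAC
exactly 0.

PAC has a known failure mode worth stating: when planted clusters are
very unequal in size and far apart, coarse partitions (e.g. K = 2
isolating the dominant cluster) are themselves perfectly stable, PAC ties
at ~0 across several K and the tie-break picks the smallest. The
cluster-number-recovery tests therefore use the exchangeable planted
design (`balanced_design`: four equal subtypes, uniform baseline,
symmetric signature boosts), where no coarse merge is privileged and only
K = 4 is stable. This is a property of the selector, not of the
implementation.

## Disease ratios and subtype merging

Per-cluster counts are exact integers; the ratio columns AA/NC, CRC/NC
and (CRC+AA)/NC are kept as exact rationals (`fractions.Fraction`) and
displayed at 2 decimals with halves rounded away from zero
(8.235 → 8.24). A cluster with NC = 0 and diseased members has an
infinite ratio, ordered above every finite one; a cluster of controls
only has ratio 0.

`merge_clusters` bins clusters by (CRC+AA)/NC. With explicit breakpoints
a ratio exactly equal to a breakpoint joins the upper band. With a target
group count, breakpoints come from an exact O(n²g) dynamic program
minimizing within-group sum of squared deviations of log10-ratios
(Fisher's optimal 1-D partition; verified against exhaustive enumeration
in the tests); infinite-ratio clusters are forced into the top band.
Letters default to A, B, C, … from the highest ratio band down. The
shipped preset (breakpoints 3.9/7.0/9.5 with letter order B, C, A, D from
the top band down) reproduces the published naming convention of the
reference analysis, whose letters do not follow ratio order.

## Synthetic cohorts

`generate_cohort` draws Dirichlet-multinomial samples: per subtype the
baseline concentration vector (a 37-genus stool panel with realistic
baseline proportions, total concentration `precision`, default 40) has
its signature genera multiplied by `signature_boost` (default 50); counts
are multinomial at `depth` (default 10⁴) per sample. Subtype signature
genera: *Escherichia-Shigella* (A), *Streptococcus* (B), *Blautia* (C),
*Bacteroides* (D). Disease labels inside each subtype are assigned by
exact largest-remainder quotas of the subtype's disease probabilities and
shuffled by the seed: margins are exact by construction (at scale 1:
376 CRC / 363 AA / 175 NC over 914 samples) while label frequencies still
converge to the probabilities at any size. CRC samples optionally get a
mild (×2) concentration boost of CRC-associated genera so differential
and classifier stages carry signal; this is off-switchable
(`crc_boost=1`).

What the generator does *not* emulate: phylogenetic correlation between
genera, zero-inflation beyond the multinomial, depth variation across
samples, and batch effects. Passing tests therefore demonstrate that the
machinery recovers planted structure under a clean compositional model,
not that real cohorts cluster this way.

The trait table shipped by `default_trait_table` (gram stain, oxygen
requirement, beneficial/harmful role, CRC-association direction, biofilm
formation) is an illustrative synthetic fixture for exercising the
characteristic scores, not a curated literature resource; real analyses
should supply their own annotations.

## Differential screen

`lda_effect_size` is a two-stage LEfSe-style screen. Stage 1 keeps taxa
with Kruskal–Wallis p < alpha (default 0.05, raw p to mirror common
practice in this literature; BH-adjusted q is always reported alongside).
Stage 2 rescales relative abundances to [0, 10⁶] (the LEfSe convention
that makes the score-2 cutoff meaningful), and computes a bootstrap
effect: over 30 within-group resamplings, the largest between-group
difference of group means, averaged; the score is log10(max(|effect|, 1))
and taxa at or above the cutoff (default 2.0) are signed by the group
with the highest mean. With no subclass structure the one-against-all and
subclass modes of the original LEfSe collapse to this all-class form.
Groups with fewer than 3 samples are excluded with a warning.

`kruskal_wallis` wraps the tie-corrected midrank test; for n ≤ 12 an
exact permutation p-value is available by full enumeration of distinct
group assignments. All-equal inputs are a defined degenerate case
(H = 0, p = 1), not an error.

## Correlations and characteristics

Correlation "with a disease/subtype" is Spearman's rho between a quantity
and the group's 0/1 membership indicator (direction-equivalent to
rank-biserial correlation). The full table is always stored; the display
mask |r| > 0.14 and the star tiers (p ≤ 0.05 / 0.01 / 0.001) are applied
only at rendering.

The fifteen per-sample characteristics are computed from relative
abundances plus taxonomy and the trait table. Richness counts taxa with
at least one read. Enterotype defaults to the dominant-marker rule
(argmax relative abundance among *Prevotella*, *Bacteroides*,
*Ruminococcus*; alphabetical tie-break; `unknown` when all absent); a
cohort-level alternative (Jensen–Shannon divergence + partitioning around
medoids, k = 3, deterministic farthest-point seeding) is available via
`method="jsd"`. Firmicutes/Bacteroidetes is a phylum mass ratio (both
classical and current phylum names accepted), infinite when Bacteroidetes
is absent, missing when both are. Shannon diversity uses natural log.
Balance score is log10((beneficial + ε)/(harmful + ε)) with ε = 10⁻⁶;
oxidative tolerance is the content of aerobe/facultative taxa and biofilm
score the content of biofilm-annotated taxa. These last three have no
standard quantitative definition and are declared annotation-driven
surrogates, isolated entirely behind the trait table.

## Classifiers

Gradient-boosted trees (xgboost; 200 trees, depth 6, learning rate 0.1,
single thread, fixed seed) on genus relative abundances. Feature
selection is a two-group Kruskal–Wallis screen refit on the training
split only — the leakage-free reading; `screen_on_all=True` mirrors
designs that screen before splitting. The 80/20 split is stratified by
class with one child seed per task, shared across strata, so a stratum
containing the whole cohort reproduces the overall block exactly.
Discovery metrics are training resubstitution. A stratum smaller than
`min_test_total` (default 60, chosen so a 57-sample subtype is
discovery-only) or one where any class would contribute zero test samples
gets no test block. Positive class per task: CRC, AA, or CRC+AA, always
against NC.

## Pipeline and determinism

`run_pipeline` fans the master seed into per-stage child seeds by SHA-256
of "seed:stage", so enlarging one stage never reshuffles another. Stage
tables are written before the next stage runs; warnings are collected
into the JSON report. The pipeline is byte-identical across reruns with
the same config and seed.

## Problem sizes used in the checks

The automated checks run the clustering stages on scaled cohorts — the
balanced planted design at 4×50 samples with 15 reps for cluster-number
recovery (20 replicates), the study-shaped design at scale 0.25
(228 samples) with 50 reps for subtype recovery, and 200 null cohorts of
60 samples for Kruskal–Wallis calibration — sizes at which the planted
effects are comfortably detectable while the whole suite stays fast.

## Known limitations

- The Pearson chi-square on subtype × disease tables is validated against
  a Monte-Carlo permutation oracle; published analyses of this design
  sometimes print much larger statistics whose construction is not
  documented, and no attempt is made to reproduce those.
- PAC-based K selection inherits the tie-to-smallest behavior discussed
  above; on strongly unbalanced, well-separated data consider inspecting
  the whole PAC profile rather than trusting the argmin.
- NMDS ordination, compositional differential methods (ANCOM-style) and
  BIOM ingestion are out of scope.
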