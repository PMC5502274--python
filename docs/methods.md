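# Methods

This note documents the models, defaults and numerical choices behind
berrynet, what the synthetic-data generator does and does not emulate,
and the known limitations.

## Study design assumed

Two treatment arms — well-watered control (CT) and water deficit (WD) —
sampled at S developmental stages (default 5, labelled in days after
anthesis: 26, 53, 67, 81, 106) with R biological replicates per
treatment and stage (default 3). Transcripts arrive as a counts table
plus a log2-normalized companion; metabolites as replicate-level
concentrations; differential-expression (DE) calls per (gene, stage)
are an input produced upstream by a count-based test — this package
consumes them and never recomputes them. Promoters arrive pre-extracted
as FASTA (nominally 1 kb upstream of the 5′ UTR or TSS); shorter
sequences are accepted with a warning since real annotations truncate.

## Response profiles

The per-feature response statistic is
log2FC(s) = log2((mean_WD(s) + c) / (mean_CT(s) + c)) with arithmetic
replicate means. The pseudocount c defaults to 1.0 for counts and to
half the smallest positive observed value for metabolite
concentrations; applied symmetrically it makes the statistic
antisymmetric under swapping the treatment labels and finite on zero
cells. Metabolite significance per stage is a one-way fixed-effects
ANOVA (CT vs WD), which with two groups equals the squared
pooled-variance t-test; the degenerate case of zero within-group
variance is reported as p = 1 when the group means are equal and p = 0
otherwise — a documented convention, not an estimate. Heatmap ordering
clusters profiles with distance 1 − r (Pearson) under complete linkage;
rows are sorted lexicographically before linkage so ties break
deterministically, and zero-variance profiles (undefined correlation)
are set aside with a warning and appended after the ordered leaves. PCA
is the SVD of the centered (optionally unit-variance scaled) matrix;
scaling defaults to true for metabolites (heterogeneous units) and
false for variance-stabilized expression; component signs are fixed so
each component's largest-magnitude loading is positive.

## Co-expression modules

Dataset 1 ("co-response", WD modules) clusters the DE genes' log2FC
profiles over the S stages; dataset 2 ("development", DEV modules)
clusters the same genes' variance-stabilized values over all samples.

- **Soft power.** Unsigned adjacency |r|^β (signed: ((1+r)/2)^β). β is
  the smallest candidate (default 1–20) whose connectivity distribution
  fits scale-free topology with R² ≥ 0.8. The fit bins connectivities
  at their quantiles and regresses log10 bin density on log10 mean bin
  connectivity; a positive slope scores 0. When no candidate reaches
  the target and the best fit is essentially noise (R² < 0.1), the
  canonical sample-size default is used instead (9 for unsigned
  networks below 20 observations, 8 below 30, 7 below 40, else 6;
  doubled for signed networks): block-structured data with a handful of
  observations has no scale-free regime, and chasing the argmax of fit
  noise systematically picks β = 1, which flattens the topological
  overlap contrast. Fully degenerate inputs (fit undefined at every
  power, e.g. all |r| = 1) fall back to the smallest candidate with a
  warning.
- **TOM and tree cut.** TOM_ij = (Σ_u a_iu a_uj + a_ij) /
  (min(k_i, k_j) + 1 − a_ij), TOM_ii = 1. Modules come from
  average-linkage clustering of 1 − TOM. Because correlations over few
  points are inflated, the whole dendrogram can sit below any fixed
  absolute cut — a single static cut either returns one cluster or
  shatters everything. The cut used here is therefore a *search*: every
  merge height up to the `cut_height` ceiling (default 0.99) is tried
  as a static cut, and the one producing the most clusters of at least
  `min_module_size` members wins (ties toward the highest such cut, so
  modules are as inclusive as possible). Leftover features are then
  attached to the module with the highest mean topological overlap to
  its members (a PAM-like rescue stage, `pam_stage=True` by default,
  mirroring the hybrid tree-cut practice); when no module survives the
  cut, everything stays unassigned. This is a deliberate simplification
  of the full dynamic tree-cut algorithm: module counts on real data
  will not reproduce a particular published partition and are not a
  contract.
- **Eigengenes and merging.** A module eigengene is the first
  right-singular direction of the feature-standardized member matrix,
  unit norm, oriented to correlate nonnegatively with the mean member
  profile; var_explained is the first squared singular value over the
  total. Modules whose eigengenes differ by less than `merge_cut`
  (default 0.25) in 1 − r are merged iteratively, closest pair first,
  recomputing eigengenes after each merge.
- **Defaults.** Unsigned network, min_module_size 20 for co-response /
  30 for development, candidate powers 1–20, target R² 0.8, merge cut
  0.25. All exposed in configuration.

## Permutation p-values and thresholds

Empirical significance of a Pearson correlation shuffles one vector
n_perm times (default 1,000) and reports
p = (1 + #{|r_perm| ≥ |r_obs|}) / (n_perm + 1) — two-sided by absolute
value, never exactly zero, with ties counted as extreme. Permutation
streams are keyed by (run seed, CRC32 of the two feature ids), so
results are independent of evaluation order and reproducible under any
parallel schedule. Module–metabolite co-response and network edges are
screened at PCC > 0.8 (signed by default; absolute-value mode available
for repressor discovery) and empirical p < 0.01.

**Small-S limitation.** With S = 5 stages there are only 120 distinct
permutations. A perfectly correlated pair has true tail 1/120 ≈ 0.0083,
and the add-one estimator concentrates near (1 + n/120)/(n + 1) ≈
0.0093 — *below* 0.01 in expectation but close enough that sampling
noise at n_perm = 1,000 pushes roughly a third of perfect pairs over
the threshold. A PCC > 0.8 / p < 0.01 screen over 5-point profiles is
therefore intrinsically knife-edged: passing indicates a genuine strong
association, but a strong association is not guaranteed to pass any
single run. Profiles with exactly tied values are worse — each tie
contributes a permutation symmetry and multiplies the attainable p
floor — which is why the generator's default patterns use strictly
distinct, well-separated stage values. Tests and the acceptance script
treat per-pair passage as the probabilistic event it is and assert
aggregates (medians over seeds, null rates).

## Promoter-element enrichment

IUPAC 6–8-mers compile to character-class regular expressions wrapped
in a lookahead, so every start offset is counted and overlapping
matches are included; scanning is case-insensitive, and an `N` in the
*sequence* (unknown base) matches only a motif `N`. Both strands are
scanned by default (several canonical elements, e.g. CACGTG, are their
own reverse complement; strand handling is recorded in output
metadata). Enrichment per (module, motif) uses gene-level *presence*
(≥ 1 match), not match counts: k carriers among the n module genes
against K carriers among the N background genes, upper-tail
hypergeometric p, Benjamini–Hochberg FDR across all (module, motif)
pairs jointly, enriched at FDR < 0.01, score = −log10(FDR). The
background defaults to the clustered universe (DE genes with
promoters), not the whole genome: module enrichment is a statement
relative to the set that entered clustering. The bundled
`data/motifs.txt` is a small example catalog of drought- and
ripening-associated elements; real analyses should supply their own
catalog.

## Synthetic data generator

The generator is the package's validation instrument; its defaults are
the conditions under which the pipeline is tested.

- **Counts.** Gene baseline log2 means uniform on (3, 10); CT mean
  constant across stages; WD mean = CT mean × 2^(pattern[g, s] +
  N(0, noise_sd)) for module genes (noise_sd default 0.25), equal to CT
  for null genes. Counts are negative binomial parameterized by mean
  and a single global dispersion α (variance μ + αμ², default α = 0.1,
  a typical biological-replicate value). The variance-stabilized
  companion is log2(count / size_factor + 1) with median-of-ratios size
  factors (genes containing zeros excluded from the geometric-mean
  reference) — an explicit approximation to a proper variance-
  stabilizing transform, adequate here because downstream analysis uses
  correlations.
- **Default scenario.** Three 100-gene modules in a 1,000-gene
  universe with 5-stage patterns "late_up" (−0.4, 0.2, 1.0, 1.7, 2.3),
  "veraison_peak" (−0.5, 1.3, 2.2, 0.8, 0.1) and "harvest_spike"
  (0.6, −0.2, 0.2, −0.6, 2.0). The shapes are weakly mutually collinear
  (pairwise |r| ≤ 0.47) because an unsigned network identifies shape
  only up to sign, and their values are strictly distinct with gaps of
  at least 0.4 so that no permutation symmetry inflates the empirical-p
  floor (see above).
- **Metabolites.** A linked metabolite's log2FC profile is
  link_strength × (module mean pattern) + (1 − link_strength) ×
  N(0, 1) per stage; replicate concentrations are a lognormal baseline
  (1–1000 mg/kg scale) times 2^(profile + N(0, 0.15)), hence positive.
- **Promoters.** Random sequences at GC 0.35 (plant-promoter-like);
  each planted motif inserts one uniformly drawn concrete expansion at
  a random offset, forward strand only, in `carrier_fraction` of the
  target module's genes and `background_fraction` of all others
  (defaults 0.6 vs 0.05 in the demo).
- **DE table.** Derived from the planted truth: (gene, stage) pairs
  with |realized log2FC| ≥ 0.5 receive padj ~ U(1e-6, 0.04). The
  upstream DE test is out of scope by design, and deriving calls from
  truth keeps the DE universe exactly interpretable in recovery
  experiments.
- **What it does not emulate:** gene length and GC biases, library-size
  gradients, count outliers, batch effects, correlated noise between
  genes outside modules, metabolite detection limits and missingness,
  promoter composition heterogeneity (CpG islands, TATA structure), or
  any real genome's motif background. Passing the planted-recovery
  suites therefore demonstrates the *statistical machinery* is correct
  and calibrated, not that any particular biological dataset will yield
  comparable power.

Everything is a deterministic function of the configuration seed;
independent substreams per component (expression / metabolites /
promoters / DE) keep outputs stable when one component's parameters
change.

## Validation summary

The test suite checks each operation against an independent oracle:
hypergeometric tails against exact rational binomial-coefficient
summation; BH against a hand step-up; the motif scanner against
expand-and-substring-count; TOM against the hand-evaluated formula;
eigengenes and PCA against dense eigendecompositions; complete-linkage
clustering against exhaustive agglomeration; the permutation p against
exhaustive enumeration of all 120 permutations; ANOVA against t². At
pipeline level: planted-module recovery (median adjusted Rand index
≥ 0.8 over 20 seeds on the default scenario; measured ≈ 0.95),
planted-motif enrichment detection with null FDR control, null
module–metabolite screens firing in ≤ 5% of seeds, and byte-identical
re-runs. Problem sizes in the test and acceptance runs (1,000 genes,
100-seed enrichment loops, 10–20-seed recovery loops) were chosen so
the whole suite completes in a couple of minutes while leaving the
Monte-Carlo assertions comfortable margins.

## Known limitations

- The tree cut is a simplification of dynamic tree cutting; real-data
  module counts are configuration-sensitive.
- The scale-free criterion is uninformative on low-dimensional profile
  data; the sample-size fallback makes the choice explicit rather than
  principled.
- Empirical p-values over 5-point profiles have the hard floor
  discussed above; with more stages (or the per-member mode over
  samples) the screen sharpens considerably.
- The variance-stabilized companion is a log transform, not a fitted
  mean-variance stabilization.
- GO/annotation enrichment is provided only as the generic
  hypergeometric machinery; no ontology data ships with the package.
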