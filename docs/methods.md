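# Methods

This note documents the statistical models, the synthetic-data generative
model, the numerical choices, and the limitations of `cernet`.

## Differential expression

**Counts (mRNA, lncRNA).** Library composition is normalized by
median-of-ratios size factors: for each sample, the median over features
of the ratio of its count to the feature's geometric mean across samples,
computed over features positive in every sample. The test is a
negative-binomial Wald test on the normalized group means, written
in-house rather than wrapping a GLM framework:

- Per-feature dispersion α (variance μ + αμ²) is estimated by the method
  of moments from the pooled within-group variance, floored at 1e−8, and
  shrunk with weight 0.5 toward a mean–dispersion trend α(μ) = a + b/μ
  fitted by least squares across features. The shrinkage stabilizes the
  noisy per-feature moment estimate at small n.
- The log₂ fold change uses pseudocount 0.5 on the normalized group
  means; its standard error comes from the delta method with
  Var(mean) = (μ + αμ²)/n per group.
- The Wald statistic is referred to a **t distribution with n₁ + n₂ − 2
  degrees of freedom**. With moment dispersions at n = 10 per group the
  normal reference is anti-conservative; the t reference is the standard
  small-sample adjustment and brings the empirical type-I error to ~0.04
  at nominal .05 (verified by the null simulation in the acceptance
  suite). Features with zero standard error (constant rows) get p = 1.

**miRNA (TPM).** Small-RNA abundances arrive as tags-per-million, a
non-count scale, so the test is a two-sided Wilcoxon rank-sum with tie
correction; the fold change is log₂ of group mean TPM with pseudocount 1.

**Call rule.** `is_de ⇔ padj < α ∧ |log2fc| ≥ lfc_min` with defaults
α = .05 (BH-adjusted) and lfc_min = 2, for both tests. BH adjustment is
delegated to `statsmodels` behind a validated wrapper and checked in the
tests against a brute-force step-up oracle.

**Low-expression filter.** Features with mean abundance below
`min_mean` (default 1) are dropped before testing. The threshold is a
pipeline parameter; there is no canonical value for it, and results at
moderate thresholds are insensitive because the DE call already requires
large fold changes.

## Co-expression network

Pearson correlation across all samples of both groups (zero-variance
features dropped with a warning), soft-thresholded into an **unsigned**
adjacency a = |r|^β with zero diagonal; the sign of r is kept as edge
metadata so positive and negative co-expression partners remain
distinguishable. β is the smallest integer in 1..20 whose adjacency
yields a scale-free-topology fit R² ≥ 0.8, where the fit is a linear
regression of log₁₀ p(k) on log₁₀ k over 10 equal-width degree bins
(empty bins dropped, fewer than 3 occupied bins ⇒ R² = 0); if no power
qualifies, the conventional default 6 is used with a warning. Edges are
kept when a > 0.02 **strictly** and at least one endpoint is a lncRNA;
miRNAs are excluded from this network. Subnetwork extraction keeps edges
with at least one endpoint in a node set (typically the DE lncRNAs).

Pearson (not biweight midcorrelation) is the simplest defensible choice;
module detection and topological-overlap matrices are out of scope
because nothing downstream consumes them.

## miRNA target scanning

Sites are found by Smith–Waterman local alignment of the **reversed**
miRNA (3′→5′) against the transcript (5′→3′) under complementarity
scoring: Watson–Crick pair +5, G:U wobble +1, mismatch −3, gap open −9,
each additional gapped base −4. Contributions at miRNA positions 2–8
(5′→3′; the seed) are scaled ×4.0, and hits must reach score 140. These
constants are the scanner's defaults and fully configurable. U and T are
interchangeable in both sequences.

Non-overlapping hits are selected greedily by descending score (ties to
the leftmost start): each accepted hit splits its transcript segment in
two and the remaining segments are rescanned. Splitting (rather than
masking) guarantees that no later alignment can bridge across an
accepted site. The DP fill is numba-compiled; traceback is exact and
prefers diagonal moves on ties, which only selects among equal-score
alignment boundaries.

Seed classes follow the canonical definitions from the exact
Watson–Crick pattern at positions 2–8 plus the transcript adenine
opposite position 1: 8mer (2–8 perfect + A1), 7mer-m8 (2–8 perfect),
7mer-A1 (2–7 perfect + A1), 6mer (2–7 perfect), otherwise
alignment-only.

Thermodynamic (folding-energy) site filtering is deliberately **not**
modelled — it would require an RNA-folding engine and would break exact
oracle testability; a weighted-AU-content accessibility proxy
(`targets.au_content`) is provided but used nowhere by default. At
cutoff 140 the alignment score alone is permissive on random sequence
(~0.4 hits per 22-mer × 500 nt pair), which is precisely why the
database-whitelist criterion below matters.

**Interaction map.** A (miRNA, target) pair enters the map iff it has at
least one scan hit AND — when `require_whitelist` is set, the default —
it appears in the interaction whitelist (the local stand-in for curated
target databases). Evidence tags record whether support is scan-only or
scan+whitelist.

## ceRNA triplet inference

The candidate universe is restricted to DE features of all three
classes. For each DE lncRNA–mRNA pair sharing at least one mapped DE
miRNA, three Pearson correlations are computed on log₂(x+1) abundances
across **all samples of both groups** (the competition signature lives
at cohort level, not within groups): the triplet is admitted iff
r(miR,lnc) < 0, r(miR,mRNA) < 0 and r(lnc,mRNA) > 0, each with
two-sided p < α_corr (default .05; correlation p-values use the exact t
transform with df = n−2). "Correlated" is thus operationalized as sign
plus significance; a sign-only mode is a one-line parameter change
(α_corr = 1). No multiple-testing correction is applied across triplet
correlations by default; `bh_adjust` can be applied to the emitted
table when a corrected variant is wanted.

Triplets deduplicate into a tripartite network with only lncRNA–miRNA
and miRNA–mRNA edges (competition is mediated by the shared miRNA, so
direct lncRNA–mRNA edges would be redundant with criterion 4). Anchored
motifs are the triplets whose mRNA or lncRNA equals a designated anchor.

## Enrichment

Hypergeometric over-representation uses the upper tail P(X ≥ k) with the
universe equal to all tested PCGs, sets intersected with the universe,
and BH adjustment across sets. Preranked GSEA uses the weighted
Kolmogorov–Smirnov running sum with weight |score|¹ (hit steps
normalized by the summed hit weights, miss steps −1/(N−N_h)); ES is the
signed extremum. The null permutes gene labels (equivalently, random hit
positions of the same size) with a fixed seed; NES = ES divided by the
mean |null ES| of the same sign, and p is the same-sign empirical tail
frequency with a +1 continuity term. Ranking ties break by gene id so
results are reproducible.

## Synthetic cohort generative model

The generator emulates a two-group (healthy vs psoriasis) cohort at desk
scale. Per feature f and sample j with group indicator g_j ∈ {0,1}, the
log₂ latent mean is

    λ_fj = b_f + Δ_f · g_j + u_{block(f),j}      (background RNAs)

with baselines b_f ~ U(3, 9) (counts ≈ 8–512), planted effects
|Δ| ~ N(lfc_mean, lfc_sd) with random sign for a `de_fraction` of each
class, and block factors u ~ N(0, block_sd²) giving co-expression
structure among non-circuit RNAs. Each planted circuit (lncRNA, miRNA,
mRNA) receives coherent DE directions (lncRNA and mRNA together, miRNA
opposite) and two per-sample latent factors e, z ~ N(0, latent_sd²):

    λ_miR  += e
    λ_lnc  += −ρ·e + s·z        λ_mRNA += −ρ·e + s·z

with repression coefficient ρ (default 0.7) and sponge coupling
s = sponge_strength. In expectation corr(lnc, mRNA) > 0 and both
corr(miR, ·) < 0, with closed-form latent covariances because the model
is linear in log space. Counts are gamma-Poisson (NB) with a single
cohort-wide dispersion (default 0.1, variance μ + αμ²); miRNA counts are
converted to TPM by per-sample scaling to 10⁶.

Default study conditions: 300 mRNAs, 80 lncRNAs, 60 miRNAs, 50 samples
per group, de_fraction 0.1, lfc_mean 3, 10 circuits, sponge strength
0.8 — a desk-scale cohort whose DE effect sizes are scenario parameters,
not estimates of any real cohort.

**Stable miRNA tier.** Real small-RNA libraries are dominated by a few
ultra-abundant constitutive miRNAs. Without that mass, per-sample TPM
scaling on a small simulated miRNome redistributes the planted fold
changes (a 25%-DE miRNome shifted the observed |log2fc| of planted
miRNAs from 3 to ~1.7, below the call threshold — a compositionality
artifact, not a property of the test). The generator therefore reserves
`n_stable_mirna` (default 8) miRNAs as a high-abundance (b ~ U(10, 12)),
never-DE, never-circuit tier that anchors the TPM denominator, as in
real data.

**Sequences and whitelist.** Transcript sequences are uniform random
DNA (lncRNA full length 600 nt, 3′UTR 400 nt); mature miRNAs are random
22-mers. For every circuit, the exact reverse complement of the full
miRNA is written into its lncRNA and 3′UTR at random offsets
(`site_mode="seed"` plants only the 8-nt seed complement for harder
scenarios). The whitelist lists all planted pairs plus decoy pairs
(default half the planted count; configurable absolutely via
`n_decoys`) under a single source label, so the correlation filters —
not whitelist membership — must do the selection.

**What passing tests do not show.** The generator draws independent NB
counts given the latent means; it does not model library-size gradients,
batch effects, outlier samples, GC/length bias, isoform structure, or
miRNA-mediated *nonlinear* repression kinetics. Planted sites are exact
complements, so scanner recovery of them exercises coordinates and
scoring, not sensitivity to imperfect sites (seed-only recovery is
reported, not asserted). Recovery rates on this generator are therefore
upper bounds on real-data performance.

## Calibration checks and problem sizes

The acceptance suite fixes these scenarios (chosen to run in minutes on
one CPU):

- null type-I: 2000 NB features, 10 vs 10, dispersion 0.1 → raw-p
  rejection at .05 within [0.03, 0.07] for both tests;
- power: |log₂FC| = 3 at 20 vs 20 ≥ 0.9 (20 seeds);
- planted DE recovery at lfc_mean 3, n = 20: sensitivity ≥ 0.8,
  FDR ≤ 0.1 (20 seeds). The sensitivity bound is checked away from the
  fold-change boundary: with planted |log₂FC| exactly at the cut-off 2,
  the hard |log2fc| ≥ 2 rule censors about half of the estimates by
  symmetry, so no test can reach 0.8 there;
- end-to-end circuit recovery on the default cohort with 50 decoys:
  precision and recall ≥ 0.8 over 10 seeds, with a label-shuffle control
  collapsing recall to ~0;
- the null pass-rate check for the correlation filters uses a pure null
  cohort (de_fraction 0, block_sd 0): planted DE or block structure are
  genuine correlation signal and would correctly inflate the rate.

## Numerical and design notes

- Correlations are clipped to [−1, 1]; p-values at |r| = 1 underflow to
  0 via the guarded t transform.
- Group labels are ordered lexicographically (fold changes are
  group₂ vs group₁, e.g. psoriasis vs healthy), which makes every result
  invariant to sample order.
- All tabular output is sorted and written with a fixed column order;
  every stage's randomness (only GSEA permutations) flows from the
  config seed, so a fixed seed yields byte-identical result bundles.
- Degenerate inputs: empty transcript → no hits; constant feature →
  p = 1; anchor absent from the network → empty motif list with a
  warning; gene set disjoint from the ranked list → skipped with a
  warning; no feature positive in all samples → size-factor error
  advising filtering.

## Known limitations

- The NB Wald test is a documented stand-in for a full GLM framework:
  no covariates, no independent filtering, no outlier replacement.
- The scanner has no folding-energy or conservation filter, so
  scan-only evidence is weak by design and should be combined with the
  whitelist criterion.
- Co-expression module detection, Cytoscape export and raw-read
  processing (alignment, quantification) are out of scope; the pipeline
  starts from expression matrices.
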