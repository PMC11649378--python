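# Methods

`genarch` analyses the evolution of intron–exon gene architecture across
species without requiring orthology assignments. This note documents the
models and procedures it implements, the choices made where the design was
genuinely open, and what the synthetic-data tests do and do not establish.

## Gene-structure features

The unit of observation is the canonical transcript of each protein-coding
gene: the splice variant with the maximal summed CDS length (ties break on
the lexicographically smallest transcript id, so results never depend on
annotation file order). Because UTR annotation quality varies strongly
across genomes, each transcript is trimmed to its CDS span before anything
is measured: exons entirely outside `[min CDS start, max CDS end]` are
removed and exons straddling the boundary are clipped to it. Clipping
(rather than removing straddling exons outright) preserves the
coding-flanked portion of terminal exons and keeps the identity
`total_exon + total_intron = trimmed gene span` exact, which the test suite
asserts on every fixture.

Introns are the gaps between consecutive exons in 1-based inclusive
coordinates: the intron between exons ending at `e` and starting at `s`
spans `(e+1, s−1)` with length `s − e − 1`; a zero gap produces no intron
and is flagged as an annotation artifact. Per-gene features are the intron
count, the individual and total intron lengths, the total exon length, and
the **intron ratio** = total intron length / total exon length (0 for
intronless, i.e. single-exon, genes).

Species-level summaries average over *all* genes, intronless ones included
(a distribution export can exclude them via a flag). Two conventions
matter:

* `mean_intron_len` is the mean of the genome-wide pooled intron set, not
  a mean of per-gene means; long multi-intron genes therefore weigh more.
* log10 transforms are applied to the species-level means of every
  length/ratio feature — never to the intron count — because these means
  span orders of magnitude across taxa while intron counts do not.

Genome size is the sum of `##sequence-region` extents in the GFF3 header;
a duplicated region id is treated as an ambiguous assembly and rejected.
Genes whose transcripts sit on multiple sequences or mixed strands are
excluded with a warning.

## Tree conditioning

Dated trees carry node ages in Myr before present. Two conditioning steps
prepare a published timetree for comparative analysis:

* **Recent-pair collapsing.** Any cherry younger than 1 Myr is reduced to
  one uniformly chosen tip, re-applied until no such cherry remains, so
  clusters of more than two very recent tips also collapse to a single
  representative. The inequality is strict (a divergence at exactly the
  threshold survives) and the random choice is seeded.
* **Short-branch collapsing.** Internal branches shorter than 1 Myr are
  collapsed into polytomies. Branches are marked by their *original*
  lengths and then all marked nodes are spliced out, so stacked short
  branches merge into a single polytomy and the outcome is independent of
  processing order. Node ages are preserved; tip branches are never
  collapsed.

Branches are mapped to named clades (phyla, kingdoms) through MRCAs: a
branch belongs to a clade when its parent node descends from (or is) the
clade's MRCA; with nested clades the deepest matching anchor wins, and
unmatched branches are labelled `stem`.

## Rate-heterogeneous trait evolution (phylogenetic ridge regression)

Tip values `y` are regressed on the tree's **path matrix** `X`, where
`X[i,b]` is the length of branch `b` if it lies on the root-to-tip-`i`
path and 0 otherwise. Each branch gets its own rate `β_b` (trait units per
Myr); the state at any node is the root state plus the rate-weighted path
sum, so ancestral reconstruction is read directly off the fit and the
child−parent increment along a branch is exactly `β_b ℓ_b` (a telescoping
identity the tests assert). With 2n−2 branches and n tips the system is
heavily over-parameterized; the ridge penalty `λ Σ β_b²` makes it
identifiable and shrinks rates toward zero.

Numerical choices:

* The root state is estimated first as the GLS phylogenetic mean under BM
  covariance and held fixed; no external root prior is used.
* `λ` is selected by exact leave-one-out cross-validation of tip
  prediction error on a 40-point log grid spanning 1e−6…1e3. The LOO
  residual `e_i/(1−h_i)` is evaluated in a cancellation-free form (both
  numerator and denominator are O(λ) near the interpolation regime; the
  naive subtraction loses all precision there — the implementation is
  verified against brute-force refits).
* Rates are signed. Tree rescaling uses `ℓ'_b = |β_b| ℓ_b · Σℓ / Σ|β|ℓ`,
  conserving total tree length exactly: a branch changing fast in either
  direction becomes long, a zero-rate branch collapses to zero. A fit with
  all rates zero (constant trait) cannot be rescaled and raises.
* Polytomies need no special handling — the path-matrix formulation never
  resolves them.
* Transforms (log10 for ratios/lengths, identity for counts) are the
  caller's responsibility; the model is transform-agnostic.

The single-rate **Brownian-motion baseline** is fitted by ML (`σ̂² =
r'C⁻¹r/n` with the GLS root mean) and reconstructs ancestral states as the
conditional expectation of the joint Gaussian — verified against a dense
joint-covariance solve on small trees.

## Comparative inference

**PGLS** is generalized least squares with the BM covariance `C[i,j] =`
shared root-to-MRCA path length of the *working tree* — the dated tree for
a homogeneous-rate assumption, or the rate-rescaled tree, which is how
rate heterogeneity propagates into regression. σ² is ML (`RSS_gls/n`), not
REML, so log-likelihoods and AIC are comparable across fixed-effect
structures; the parameter count is the number of coefficients plus one for
σ². R² is defined against the GLS intercept-only fit; adjusted R² applies
the usual `(n−1)/(n−p)` correction. Collinear designs are rejected with
the offending columns named. The AIC comparison between a fit on the
rescaled tree and one on the dated tree is the model test for rate
heterogeneity.

The **phylogenetic ANOVA** compares the observed one-way F statistic with
F statistics of traits simulated under BM on the working tree (σ² and root
estimated from the data), with the add-one correction
`p = (1 + #{F_sim ≥ F_obs}) / (1 + n_sims)` so finite simulation never
yields p = 0. Multiple tests are corrected by Benjamini–Hochberg FDR.

## Ancestral-state uncertainty (perturbation protocol)

Point estimates come from the full-data ridge fit. The 95% band of each
internal node is the 2.5–97.5% empirical quantile range (type-7
interpolation) of its estimates across perturbed replicates. Each
replicate drops 20% of tips uniformly, exchanges the tree positions of 10%
of survivors in within-clade pairs (traits travel with the tip label), and
multiplies the ages of 10% of internal nodes by U(0.5, 1.5), clamped so a
parent always stays older than its children. The age-jitter magnitude is a
package choice — the protocol itself does not fix one — and is exposed in
the configuration.

Replicates whose selected penalty falls below a validity floor on the
normalized scale `λ′ = λ/(1+λ)` (default 0.9) are discarded as likely
degenerate optima, and perturbation continues until 100 valid replicates
accumulate (erroring after 20× that many attempts). A node is matched in a
replicate to the MRCA of its surviving descendant tips and skipped when
fewer than two survive; per-node replicate coverage is reported. Quantiles
are taken over the raw replicate estimates (not offsets from the point
estimate). The band is an uncertainty heuristic, not a confidence interval
with coverage guarantees: the point estimate is not guaranteed to fall
inside it, and — more fundamentally — every replicate's root estimate is
the GLS phylogenetic mean of a tip subsample, so the band quantifies
taxon-sampling and phylogeny uncertainty only. The error contributed by
the single realization of the evolutionary process along the root-adjacent
lineages is invariant under resampling of tips, positions or ages, so
against a *known simulation root* the band systematically undercovers
(and the undercoverage worsens as tips are added, because the band
narrows while the realization error does not shrink). The validation
suite measures this root-coverage rate directly on synthetic studies and
reports it as-is.

## Time-sliced trajectories

Reconstructed states are interpolated linearly along branches: with parent
age `t0`, child age `t1` and states `v0`, `v1`, the branch line is
`v(t) = m t + b`, `m = (v0 − v1)/(t0 − t1)`, `b = v0 − m t0`. This assumes
a constant rate of change within a branch and makes the trait readable at
any age, not only at nodes. Per-clade trajectories sample all of a clade's
living branches on an age grid anchored at the present (default spacing
5 Myr); both the per-slice median and mean are reported, since either is a
defensible summary and they can differ noticeably on skewed branch sets.
Zero-length branches are excluded from slicing; values at node ages agree
from both incident branches, so trajectories are continuous.

## KS-distance divergence trees

Whole-genome feature distributions of two species are compared with the
two-sample Kolmogorov–Smirnov statistic (0 = identical, 1 = disjoint
support). For the intron-length feature the pooled per-intron genome-wide
distribution is used by default (a per-gene-mean alternative is a flag);
per-gene intron ratios include intronless genes by default. The pairwise
matrix is mapped onto the fixed dated topology by ordinary (unweighted)
least squares over the tip-pair path equations — plain least squares is
used deliberately, not balanced minimum evolution, and negative solutions
are clamped to zero after solving (an NNLS mode is available). The two
branches of a bifurcating root are unidentifiable from distances and are
fitted as one merged edge whose length is split in proportion to the dated
branch lengths. Dividing KS lengths by dated lengths yields divergence
rates in KS units per Myr (×1000 for per-Byr) globally, per clade and per
branch; rates are undefined on zero-length dated branches.

## Synthetic data

The generator exists to exercise the whole pipeline against known truth:

* **Genomes.** Gene structures are drawn per gene: Bernoulli intronless
  status, exon count `2 + Poisson(mean−2)` for intron-bearing genes (so
  every such gene has ≥1 intron; a fixed count is available for exact
  arithmetic fixtures), log-normal exon and intron lengths (heavy-tailed
  like real intron-length distributions; an optional two-component
  log-normal mixture emulates genomes carrying two distinct intron
  populations). Genes are laid out without overlap across a configurable
  number of sequences, with `##sequence-region` headers sized to contain
  them. By default CDS and exon intervals coincide, so trimming is a no-op
  and expected summaries have closed forms; optional UTR decoration adds
  non-coding flanks and detached UTR exons (exercising trimming), and
  optional shorter-CDS second transcripts exercise canonical selection.
  The exact per-gene truth is retained, so extraction must reproduce the
  generator's summary exactly, and the same seed yields byte-identical
  GFF3.
* **Trees.** Pure-birth (Yule) topologies with exponential waiting times,
  rescaled to a chosen root age.
* **Traits.** Brownian motion along branches with optional per-clade σ²
  multipliers; every node state and branch multiplier is recorded.
* **Whole studies.** `build_study_fixture` evolves three species-level
  traits (log10 mean intron ratio, log10 mean intron length, mean intron
  count) by BM on one tree, then tunes each species' genome spec by
  log-normal mean matching so its *expected* extraction summary equals the
  simulated trait values; the implied mean exon length follows from the
  consistency constraint `ratio ≈ n_introns · intron_len / exon_len`, and
  infeasible trait combinations raise with that constraint spelled out.
  The matching is first-order (expectations, not ratio-of-sums corrections),
  which is adequate for the stochastic tolerances used in validation.

Default study conditions used by the validation suite: 16 species on a
500-Myr tree, 200 genes per genome, intronless fraction 0.15, trait
diffusion rates σ² = 2×10⁻⁴ per Myr for the log10 features and 2×10⁻³ for
the intron count, and a 5× rate multiplier on one root clade when a rate
shift is being probed. Calibration checks use 64-tip trees (ANOVA type-I
error, 500 runs of 199 null simulations) and 100-tip trees (σ² and PGLS
slope recovery over 100 replicates); these sizes keep every check
well-powered while the full suite runs in minutes.

### What the synthetic tests do not show

Generated genomes have clean, complete, well-formed annotations: no
missing genes, no fragmented assemblies, no mis-annotated UTRs beyond the
deliberate decorations, and no correlation between annotation quality and
taxonomy — all of which affect real comparative datasets. Trait evolution
is pure (shifted) Brownian motion, so passing recovery tests says the
estimators work under their own model assumptions, not that real gene
structure evolves that way. The KS tree step inherits whatever
non-additivity real distribution divergence has; the recovery test only
certifies the least-squares solver on additive inputs.

## Known limitations

* The ridge model's λ is selected by prediction error, which on data
  simulated without measurement noise tends to the shrinkage-heavy end of
  the grid; ancestral *contrasts* are then conservative even though the
  root estimate (a GLS mean) is unaffected.
* The perturbation CI is a resampling heuristic without formal coverage
  guarantees.
* Ordinary least squares on KS distances ignores the correlation and
  heteroscedasticity of shared-path distance errors; weighted variants are
  deliberately out of scope.
* The extraction step trusts the annotation: it measures annotated gene
  structure, not biological truth.
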