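# Methods

## The regression model

All cross-species models are phylogenetic generalized least squares (PGLS).
Under Brownian-motion trait evolution on a rooted, time-calibrated tree, the
covariance of trait values between species *i* and *j* is proportional to
their shared evolutionary history, `V_ij = depth of MRCA(i, j)` measured
from the root, with `V_ii` the root-to-leaf depth. A linear model
`y = Xβ + ε`, `ε ~ N(0, σ²V)` is then estimated by GLS:

    β̂ = (XᵀV⁻¹X)⁻¹ XᵀV⁻¹y

computed via Cholesky whitening (`L Lᵀ = V`; OLS on `L⁻¹X`, `L⁻¹y`).
Reported per coefficient: estimate, SE from `σ̂²(XᵀV⁻¹X)⁻¹` with the
unbiased `σ̂² = RSS_V/(n−k)`, two-sided p from a t distribution with `n−k`
df. `R²` is measured against the intercept-only GLS fit under the *same* V,
so fixed- and optimized-transform fits are comparable. The log-likelihood is
the Gaussian profile likelihood with σ² profiled
(`−(n/2)·log(2πσ̂²_ML) − ½log|V| − n/2`, `σ̂²_ML = RSS_V/n`).

### Pagel transforms

Strict Brownian motion is relaxed by three transforms, composed in the fixed
order **κ → δ → λ**:

| transform | acts on | default | bounds | meaning |
|---|---|---|---|---|
| κ | each branch length, `b → b^κ` | 1 | [1e−6, 3] | κ→0: punctuated (speciational) change; κ=1 gradual |
| δ | node depths, `d → d^δ` | 1 | [1e−6, 3] | δ>1 late acceleration, δ<1 early burst |
| λ | off-diagonal of V, `V_ij → λV_ij` (i≠j) | 1 | [0, 1] | phylogenetic signal; λ=0 is a star phylogeny |

Conventions for degenerate values: `0^x = 0` for x > 0 and `0^0 = 1`
(zero-length branches from polytomies survive κ; κ=0 equalizes all
branches). The δ transform is defined on node depths of an ultrametric tree;
the tree-level operation refuses non-ultrametric input, while inside the
composed covariance builder δ is applied elementwise to the (κ-transformed)
MRCA-depth matrix, which coincides with the tree operation at κ=1 and
mirrors the conventional composition otherwise. A root edge, if present, is
never transformed and never enters depths.

ML optimization maximizes the profile log-likelihood over (κ, λ, δ) jointly:
a deterministic 2×2×2 lattice over the bounding box plus the Brownian point
(1,1,1) is scored, and bounded L-BFGS-B refinement is run from the best
three starts. Estimates landing on a box bound are flagged (`at_bound`) —
an optimized δ printed exactly at its upper bound should be read as a
constrained estimate. If V loses positive definiteness (e.g. duplicate
depths at λ=0) a ridge of `1e−10·mean(diag V)` is added with a logged
warning, escalating ×100 up to 8 times before failing.

## Copy counting and normalization

Counts come from either source with identical downstream semantics:

* **Gene trees**: leaf labels `<species>_<int>` (configurable regex);
  a species absent from a gene's tree is *missing* (`found=False`), which is
  distinct from present-with-zero.
* **Ortholog records**: count = number of distinct confident ortholog ids
  per (gene, species); `found` is true wherever any record exists,
  confident or not.

Normalization is copies per found gene over a gene subset; `found=False`
pairs are excluded from numerator *and* denominator, never treated as zero —
the whole point of normalizing is that incomplete assemblies should not look
gene-poor. The denominator is computed per gene subset (TSG and OG
normalizations each count their own found genes); this is configurable, as
the alternative (all census genes as denominator) is equally defensible.
Genes with both TSG and OG roles are excluded from both tallies; mixed
role+fusion genes enter only in an opt-in `include_fusion_mixed` mode
(default off: strict pure-role counting). Z-scores use the sample SD (n−1)
and are computed over the full ingested species set, before any per-model
subsetting, so every model shares one scale; the TSG/OG ratio is reported
unstandardized.

The longevity quotient is in-sample: each species contributes to the
allometric fit that generates its own expectation, so mean log10(LQ) is
exactly 0 by OLS orthogonality. Out-of-sample LQs (refit excluding the
focal species) would differ; the in-sample convention matches comparative
practice and is what the tests assert.

## The synthetic study generator

The generator is the package's testbed: it produces complete studies with
the statistical structure the analysis assumes, at the scale of the real
data. Defaults (all in `SimConfig`):

* **Tree**: pure-birth (Yule) tree, `n_taxa = 60`, rescaled to unit
  root-to-tip depth. Branch-length units are therefore fractions of total
  tree depth; rates are per unit depth.
* **Genes**: 243 TSGs + 243 OGs (the pure-role census tallies), each
  starting at 2 copies at the root (the post-teleost-WGD baseline; absolute
  baseline is irrelevant to ratios) and evolving by a linear birth–death
  process with duplication = loss = 0.10 per copy per unit depth, simulated
  exactly per branch via Kendall's transition law (binomial extinction +
  negative-binomial offspring), truncated at 0.
* **Shared duplication pressure**: a Brownian log-rate modifier (sd 0.10
  per √unit-depth) tilts duplication against loss on every branch,
  identically for all genes, so whole lineages drift gene-rich or gene-poor.
  This — plus a WGD clade (4–10 species) whose counts double at the clade
  stem — is what couples TSG and OG counts across species. With these
  values the realized corr(norm_TSG, norm_OG) is ≈0.95 among non-WGD
  species (≈0.99 with the WGD clade included) and non-WGD normalized counts
  span ≈[1.7, 2.4] copies per gene, matching the near-proportional regime
  and the 1.5–2.2 range reported for real teleost genomes.
* **Missingness**: 5% of gene–species pairs are masked `found=False`
  (MCAR by default; a lineage-biased mode exists to stress normalization);
  17% of species lack lifespan (≈11/65, as in the real data).
* **Traits**: log10 body length is Brownian (mean 1.6 ≈ 40 cm, sd 0.45);
  log10 lifespan = 1.0 + 0.35·(log10 length − mean) + *s*·σ_resid·
  standardized(z_TSG − z_OG) + Brownian residual with σ_resid = 0.15 under
  the configured true (κ, λ, δ). The effect size *s* is in residual-SD
  units (default 1). Because z_TSG and z_OG are nearly collinear, the
  effect is invisible marginally and surfaces only jointly or via the
  ratio — the masked relationship by construction. Mass follows a cubic
  length allometry (for LQ only).

Every simulator is a pure function of the seed (substreams are derived by
CRC of the stage name, so stages are independently reproducible).

**What passing tests do not show about real data.** The generator draws
counts from the very birth–death/Brownian world the estimator assumes; real
copy-number variation includes assembly artefacts, annotation error,
non-Brownian trait evolution and correlated missingness that it does not
emulate. Detection rates and coverage measured here validate the *machinery*
(that the pipeline finds structure that is present and not structure that is
absent), not the biological effect sizes of any real dataset.

## Replicated experiments and problem sizes

* **Masking power**: 100 studies at default scale; the ratio term must fall
  below the run's Bonferroni threshold with a positive sign in ≥80% of
  replicates while each marginal count model stays nonsignificant in ≥70%;
  under a null (*s*=0) the ratio term rejects at α=0.05 at the nominal rate
  (binomial 95% band).
* **λ recovery**: 100 replicates × true λ ∈ {0, 0.5, 1} on 50-taxon trees;
  ML over λ with κ and δ held at their true value 1 — the standard
  phylogenetic-signal recovery design. Mean λ̂ lands within ±0.15 of truth
  and 95% slope CIs cover at 90–95%.

A known limitation, measured at 300 replicates: freeing all three transforms
jointly costs slope-CI calibration (coverage ≈0.89 at λ=0.5), the familiar
anticonservativeness of stacking ML-estimated covariance parameters at
n = 50. Joint optimization remains the default for data analysis (its
dominance and boundary behaviour are tested), but calibration claims are
made for the λ-recovery design.

## Other numerical and design choices

* Name canonicalization (lowercase, spaces→underscores) is applied to every
  species label at ingestion, since trees, counts and traits arrive from
  sources with inconsistent naming.
* Pruning keeps the root in place, collapses non-root unary nodes by
  summing branch lengths, and preserves all pairwise leaf path lengths and
  root-to-leaf depths exactly.
* The Bonferroni family size defaults to the number of non-diagnostic
  models actually fitted in the run; the marginal TSG-only/OG-only models
  are diagnostics (exhibits of masking), not hypothesis tests, and are
  excluded. A family size of 39 can be supplied to reproduce the
  main-plus-supplementary threshold 0.00128 of the original fish analysis.
* Ranking ties (after exact comparison of ratios) break lexicographically
  on species name and are flagged.
* Model failures inside the battery (e.g. too few complete cases) are
  recorded per model with their n; the battery never aborts.
* Out of scope: REML, Ornstein–Uhlenbeck models, phylogenetic logistic
  regression, measurement-error models, live database retrieval, and
  sequence-based homology inference.
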