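# Methods

This note documents the models, defaults and design choices behind
`gutassembly`, in the spirit of a package methods appendix.  Nothing here
states an empirical result that the test suite or `scripts/acceptance.py`
does not itself compute.

## Community-assembly null models

**βMNTD / βNTI.**  For each sample pair, βMNTD averages (abundance-
weighted by default) each taxon's patristic distance to its nearest
relative in the other sample, symmetrized over the two directions.  Shared
taxa contribute distance zero, so identical taxon sets give βMNTD = 0
regardless of abundances.  The null model is the *taxa-labels*
randomization: tip labels of the phylogeny are shuffled across the full
OTU pool observed in the table while the abundance matrix stays fixed.
One shuffle per null iteration is applied to every sample pair, so
iteration *i* is identical across pairs; 999 iterations by default (the
package's permutation convention throughout).  βNTI is the z-score of the
observed value against the per-pair null distribution (null SD with one
degree of freedom removed).  A pair is labelled *deterministic* iff
|βNTI| > 2 — the inequality is strict, so βNTI = 2.0 exactly is
stochastic.  Pairs whose null SD is zero (e.g. identical communities under
every shuffle) are left undefined, logged, and excluded from fraction
denominators.

**SES.MNTD** uses the same null for the within-sample mean nearest taxon
distance.  Abundance weighting defaults OFF for SES.MNTD and ON for
βMNTD/βNTI, matching the conventions of the standard R implementations of
these metrics; both are flags.  A sample that contains the entire pool is
shuffle-invariant in the unweighted case and its SES is exactly 0; any
other zero-SD null leaves SES undefined (NaN) rather than forcing a value.

**Niche optima and the correlogram.**  An OTU's niche optimum per nutrient
is the abundance-weighted mean of that nutrient over the samples the OTU
occurs in; optima therefore always lie inside the observed nutrient range.
Optimum vectors are z-standardized before the Euclidean OTU-by-OTU
distance (flag to disable) so nutrients on different scales contribute
comparably.  The Mantel correlogram bins phylogenetic distances into
equal-width classes (Sturges' rule on the number of pairs by default),
computes the negated Pearson correlation between niche distances and the
binary within-class indicator — positive values mean *similar niches at
that distance* — and tests each class by jointly permuting the taxa of the
niche matrix (two-sided on |r|, p = (b+1)/(n+1)).  Only classes up to the
one containing the median distance are tested by default (distant classes
of a correlogram are not interpretable); a flag tests all.  Multiple
testing uses the progressive Holm correction: class *c* reports the
Holm-adjusted value of its p-value within the family of classes 1..*c*.

## Diversity

Chao1 uses the bias-corrected form `S_obs + F1(F1−1)/(2(F2+1))`, defined
when doubletons are absent.  Shannon entropy is in nats by default (flag
for other bases).  Faith's PD sums the branch lengths of the minimal
subtree connecting the observed tips *including the path to the root*.
Rarefaction is a multivariate-hypergeometric draw to exact depth; samples
below depth are dropped and reported.  The default workflow rarefies
counts once (seeded, to the minimum sample total) for alpha/beta
diversity, and screens response shapes on unrarefied values; both choices
are flags.  PCoA double-centers −½D², reports all eigenvalues, assigns
coordinates only to positive-eigenvalue axes and excludes negative
eigenvalues from the proportion-explained denominator.

## Response-shape screen

Each feature is fit by OLS to `y = β0 + β1·x + β2·x²` with x the DSR
level.  Benjamini–Hochberg q-values are computed separately for the
quadratic-term family and for the slope family of an independent linear
refit, across all screened features.  Classification: if q(β2) ≤ α and the
vertex −β1/(2β2) lies strictly inside the observed DSR range, the label is
U (β2 > 0) or inverted-U (β2 < 0); otherwise positive/negative on
q(slope) ≤ α by sign; otherwise none.  The quadratic term takes precedence
because asymmetric bitonic responses also show significant slopes; the
vertex-in-range guard excludes significant-but-monotone quadratics.
Whether one classifies by term significance or by model comparison
(F-test/AIC) is a genuinely open choice; term significance with the vertex
guard is implemented because it yields the mutually exclusive five-way
labels the summary table needs.  α = 0.05 on q-values by default;
prevalence filtering defaults to 0 (no features excluded).  A constant
feature is classified `none` with p = 1 (a perfect intercept-only fit
carries no evidence for any term).

## Permutation statistics

PERMANOVA is one-way, via the Gower identity `SS_total = Σ_{i<j} d²/n` and
the analogous within-group sums; p-values permute group labels, one-sided
on pseudo-F.  Mantel correlates upper triangles (Pearson default,
Spearman optional) and permutes rows/columns of one matrix jointly,
two-sided on |r|.  All permutation p-values use (b+1)/(n+1).  Group
comparisons: one-way ANOVA omnibus, pairwise Welch t-tests with BH
adjustment, and an insert-and-absorb compact letter display (presentation
layer, not inference; letters are assigned in descending order of group
mean so they are invariant to group relabeling).

## Synthetic-data generator

The generator emulates the statistical structure of an eight-level
diet-manipulation study (default 8 DSR groups × 10 samples over a
983-taxon pool; every size is a parameter):

* **Tree**: pure-birth (Yule, rate 1) simulated forward in time, run one
  extra exponential waiting time past the n-th speciation so all tip
  branches are positive, then scaled to unit height.  Ultrametric by
  construction.
* **Traits**: Brownian motion down the tree (root 0, child = parent +
  N(0, bm_sd²·branch length)); bm_sd default 1 in trait units.  BM
  guarantees the short-distance phylogenetic signal the correlogram is
  meant to detect.
* **Nutrients and features**: mean response U / inverted-U (vertex at
  DSR 5 by default, where the study gradient turns) / linear / flat, plus
  Gaussian noise.  Default nutrient panel: glucose and resistant starch
  inverted-U, fiber/tannin/fat U, FOS increasing, crude protein flat, all
  with unit noise SD.
* **Communities**: per sample, `richness_per_sample` taxa are drawn
  without replacement — uniformly (neutral) or with weight
  `exp(−(trait − scaled_env)²/(2σ²))` (filtering), where the driving
  nutrient is z-scored and mapped onto the trait mean/SD and
  σ = `filter_strength` × SD(traits).  `filter_strength` is therefore in
  trait-SD units; 0.25 is strong filtering.  Weighted sampling uses the
  Gumbel-top-k scheme, which is exact for sequential sampling without
  replacement and numerically stable down to the σ → 0 limit (each sample
  then holds exactly the taxa nearest its environment).  Selected taxa get
  lognormal relative abundances (SD 1.0, the canonical microbiome
  abundance model) and a multinomial read draw (default 10,000
  reads/sample, a typical 16S depth; the depth any given study used is
  rarely decisive and is a parameter).

What the generator does **not** emulate: compositional artifacts of
relative-abundance sequencing, chimeras/contamination, overdispersed
(e.g. Dirichlet-multinomial) count noise, taxon co-occurrence networks,
and host-level covariates.  Passing tests therefore demonstrate that the
inference machinery recovers known assembly regimes and response shapes
under idealized sampling — not that it is robust to every artifact of real
amplicon data.

## Canonical study designs and problem sizes

The analysis drivers, the end-to-end tests and the acceptance script use
two fixed designs (module `gutassembly.study`), chosen as the package's
standard benchmark scale:

* *assembly design*: 100-taxon pool, 4 DSR groups (levels 1, 4, 5, 8 —
  picked so the inverted-U glucose driver takes four distinct values and
  the gradient is informative) × 5 samples, richness 30, depth 5,000,
  999 null randomizations.
* *screen design*: 8 levels × 10 samples, 40 features per shape,
  signal-to-noise ratio 4 (noise SD = SD of the noise-free response over
  the design ÷ 4).

## Numerical choices and degenerate inputs

* Patristic distances come from one postorder sweep with outer-sum merges;
  the matrix is cached per tree and validated symmetric.
* Distance matrices must be symmetric within 1e-12 with zero diagonal;
  they are exactly symmetrized on construction.
* Nearest-taxon minima need no tie-breaking; shared taxa contribute 0.
* The βNTI null pool is the *sorted* set of observed OTUs, making results
  invariant to OTU column order and sample order at a fixed seed.
* Trees must be rooted with branch lengths on every non-root edge;
  missing lengths are rejected rather than imputed (βMNTD and Faith's PD
  are undefined without them).
* Every random step takes an explicit integer seed; composite runs spawn
  sub-seeds via `numpy.random.SeedSequence`, so all outputs are
  bit-reproducible and CLI reruns are byte-identical (run logs contain no
  timestamps).

## Known limitations

One-way PERMANOVA only (no multi-factor or stratified designs, no
PERMDISP); no UniFrac; no Raup–Crick partitioning of the stochastic
fraction into dispersal vs drift; no GAM/segmented alternatives to the
quadratic screen; the correlogram tests classes independently rather than
fitting a spatial model.  These reflect the package's scope, not missing
fixes.
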