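# gutassembly

Phylogenetic community-assembly analysis of gut microbiota along a
dietary-species-richness (DSR) gradient.

Host diet shapes the gut microbiome, but *how* communities assemble along a
dietary gradient — by deterministic habitat filtering or by stochastic
draws from the species pool — is not visible from composition alone.  This
package implements the nearest-taxon family of phylogenetic null models
that answers that question, together with the surrounding analyses a
diet-manipulation microbiome study needs: diversity metrics, ordination,
dose–response shape screening and permutational statistics.  It is aimed at
microbial ecologists who have an OTU table, a rooted phylogeny and
per-sample diet/nutrient metadata.

## The model

For a sample pair (k, m) with within-sample relative abundances *f* and
patristic distances *d(i, j)*, the between-community mean nearest taxon
distance is

    βMNTD(k,m) = ½ [ Σᵢ f_ik · min_{j∈m} d(i,j) + Σⱼ f_jm · min_{i∈k} d(j,i) ]

The null model shuffles the phylogeny's tip labels across the full observed
OTU pool (999 randomizations), holding abundances fixed.  The z-score of
observed βMNTD against this null is the **β nearest taxon index**:

    βNTI = (βMNTD_obs − mean(βMNTD_null)) / sd(βMNTD_null)

|βNTI| > 2 marks a pair as deterministically assembled (phylogenetic
clustering if βNTI < −2, overdispersion if βNTI > 2); |βNTI| ≤ 2 marks it
stochastic.  Per-group deterministic/stochastic fractions are computed over
within-group pairs.  The same null yields the within-sample **SES.MNTD**.

Reading ecology out of phylogeny requires phylogenetic signal at short
distances.  The package computes each OTU's **niche optimum** (the
abundance-weighted mean of each nutrient over the samples it occupies),
Euclidean distances between optimum vectors, and a **Mantel correlogram**
of niche distance against phylogenetic distance with permutation tests and
progressive Holm correction.

Around this core: rarefaction, alpha diversity (observed OTUs, Chao1,
Shannon, Faith's PD), Bray-Curtis/PCoA, group-similarity z-scores,
Firmicutes/Bacteroidetes ratios, a quadratic/linear response-shape screen
(U / inverted-U / positive / negative / none with BH-FDR), one-way
PERMANOVA, Mantel tests and compact-letter group comparisons.

Because real diet-manipulation data need not be at hand, the package ships
a fully seeded synthetic-study generator (`gutassembly.synthetic`): Yule
trees, Brownian-motion niche traits, nutrient variables with prescribed
DSR responses, and communities assembled neutrally or by habitat
filtering — so every inference has a known ground truth.

## Worked example

The numbered drivers under `analysis/` run the whole study on synthetic
data (seed 1 by default):

```
python analysis/01_simulate.py
python analysis/03_assembly.py
```

prints

```
[neutral] short-class Mantel r=0.022 (p=0.139); mean SES.MNTD=0.06; |bNTI|>2 in 3.2% of 190 pairs
[filtering] short-class Mantel r=0.071 (p=0.001); mean SES.MNTD=-2.17; |bNTI|>2 in 60.0% of 190 pairs
```

Read: under neutral assembly there is no short-distance phylogenetic
signal, SES.MNTD sits at its null expectation and only ~3% of sample pairs
(consistent with the 5% a z-threshold of 2 implies) exceed |βNTI| = 2 —
stochastic assembly.  Under habitat filtering the correlogram's shortest
distance class is significantly positive (niche similarity tracks
relatedness), communities are phylogenetically clustered (SES.MNTD ≈ −2.2)
and 60% of pairs are deterministic.  `analysis/05_stats.py` closes the
loop:

```
[filtering] PERMANOVA F=6.74, R2=0.56, p=0.001; strongest nutrient: glucose (r=0.87, p=0.001)
```

glucose is exactly the nutrient the generator used to filter taxa.  The
shape screen (`analysis/04_shapes.py`) classifies 200 features with known
responses at 99% accuracy and recovers the bitonic turning point at DSR
5.01 (generated at 5).

The same functionality is available as a CLI
(`gutassembly generate|diversity|assembly|shapes|stats`), with `--seed`
making every output table byte-reproducible.

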