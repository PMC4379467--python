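# Methods

## Statistical model

Per-gene association is an analysis of covariance fitted as one ordinary
least-squares model per gene, `y = b0 + b1*age + b2*I(male) + e`, with age
continuous in years and sex an indicator (reference level female; the
choice of reference does not affect p-values). Each coefficient is tested
with a two-sided t test on n − 3 residual degrees of freedom, which for a
single term equals the partial F test. The fit is joint, not sequential, so
covariate order is irrelevant. All genes share one design matrix, so the
fits are vectorised (one matrix product per cohort); this is numerically
identical to per-gene OLS (checked against statsmodels to 12 digits in the
test suite). Genes with zero expression variance are skipped with a
warning; a single-sex or constant-age design raises an error naming the
deficient covariate.

Multiple testing is controlled by the Benjamini–Hochberg step-up procedure,
`q_(i) = min_{j>=i} m p_(j)/j` clipped at 1, applied within one cohort and
one covariate at a time — each (cohort, covariate) pair is its own p-value
family, because cohorts are analysed independently and then merged.
Significance is conjunctive: raw p < 0.001 (strict) **and** q ≤ 0.05. Both
constraints are exposed as parameters.

Direction of an age association is the sign of the Spearman correlation of
expression with age. Spearman p-values use the t approximation on n − 2 df
for n > 9 and exact permutation enumeration for n ≤ 9, where the
approximation is poor. By default the ANCOVA alone gates set membership and
rho supplies only the direction; a `gate="both"` mode additionally requires
the correlation to pass the same p/q thresholds.

Merging across cohorts takes the union of significant (gene, covariate)
pairs. If cohorts disagree on direction, the cohort with the larger effect
wins (|rho| for age; |b2| for sex, mirroring the age rule); an exact tie
yields direction 0 with a warning. The merge is idempotent and invariant to
cohort order.

Gene-class enrichment (e.g. RBPs vs transcription factors) is a two-sided
Fisher exact test on the 2×2 table (associated vs not) × (class A vs B); the
two classes are explicit arguments since several constructions are
plausible. Sex contrasts for selected genes are two-sided Mann–Whitney U
tests with per-sex medians.

Age-binned summaries use half-open bins `[0,20), [20,40), ...` with the
last bin closed at 120 years. Direction subgroups are clustered by
average-linkage agglomerative clustering on 1 − Pearson correlation of row
z-scores, cut to k clusters; rows are processed in lexicographic gene order
so labels are deterministic, and constant rows (not z-scorable) go to a
residual cluster 0.

## Network analysis

The interactome is an undirected simple graph over gene symbols (self-loops
dropped, unordered duplicates collapsed; BioGRID Tab 2 rows are filtered to
one organism). The observed network is the subgraph induced by the
associated genes, dropping nodes left without edges — which is why an
88-gene set can yield a 47-node network.

Centrality conventions:

- **degree** — edge count;
- **betweenness** — raw Brandes pair-dependency counts (unordered pairs
  counted once, endpoints excluded), via networkx; dependencies accumulate
  only along realised shortest paths, so no disconnected-pair convention
  applies here. Edge betweenness is the analogous per-edge count.
- **closeness** — (|V|−1) / Σ d(v,u), with a disconnected pair assigned
  distance |V| − 1 (one less than the node count). Implemented in the
  package because standard closeness implementations use a different
  disconnected convention.
- **clustering coefficient** — edges among neighbours over C(k,2), defined
  as 0 for degree < 2 so every node enters pooled distributions (the
  alternative, excluding such nodes from medians, would shift null medians
  upward; the chosen convention keeps observed and null samples comparable).

Before any comparison, each measure is divided by its maximum within its
own network (per-network max-normalization); an all-zero vector is left
unchanged with a warning.

The null model is **edge subsampling**, not degree-preserving rewiring:
each of the 100 control networks is x edges drawn uniformly without
replacement from the non-associated interactome, with nodes induced by the
sampled edges. Normalized node values are pooled across the 100 members and
compared to the observed network's by a two-sided Mann–Whitney U (exact
enumeration when both sides are ≤ 50 and tie-free, otherwise the normal
approximation with tie correction — pooled sides are always large, matching
the extreme p-values such comparisons produce). Pooling, rather than
comparing per-network medians, yields a single p per measure; a per-network
summary can be derived from the stored members.

## Cross-species concordance

Human calls are transferred through a one-to-one ortholog map (ambiguous
mappings dropped). A rodent gene's trend over the ordered stage series is
the sign of the Spearman correlation of expression with stage order,
thresholded at |rho| ≥ 0.5 (four ranks can only realise rho values spaced
0.2 apart, so 0.5 separates "clearly monotone" from noise; the threshold is
a parameter). The enrichment universe defaults to mapped orthologs with a
determinate (non-zero) trend — the smallest defensible universe; using all
mapped orthologs is selectable and gives smaller p-values. The upper-tail
hypergeometric probability is reported as a raw float plus a display string
that renders values below 2.2e-16 as the bound "< 2.2e-16" rather than a
literal zero.

qPCR fold changes use ddCt with the arithmetic-mean-of-reference
convention: per replicate dCt = Ct_target − Ct_housekeeping, ddCt against
the mean dCt of the reference timepoint, fold = 2^(−ddCt), summarised as
mean ± SEM (sample SD / √replicates) per timepoint.

## Preprocessing

Two protocols. `three_step` (single-colour arrays): per-array normexp
background correction with offset 50, quantile normalization between
arrays, log2. `quantile_only` (already-summarized bead arrays): quantile
normalization, with log2 applied only when the matrix maximum exceeds 100
(a heuristic for "looks unlogged"; the source protocol for such data is
silent on the log step).

normexp models observed intensity as X = B + S with B ~ N(mu, sigma²) and S
exponential with mean alpha; the corrected value is the posterior mean
E[S | X = x] + offset, evaluated through log-pdf/log-cdf so the Mills-ratio
term stays finite for arbitrarily negative standardized residuals, and is
strictly positive. Parameters are fitted per array by method of moments
(alpha = (m3/2)^(1/3), mu = mean − alpha, sigma² = max(var − alpha², eps)),
a closed-form, robust alternative to the MLE variant used by microarray
suites. Caveat: when sigma ≪ alpha the background SD is ill-conditioned
(sigma² is a difference of near-equal large terms), so sigma estimates are
only order-of-magnitude there — the correction itself is insensitive to
this, since the posterior mean is dominated by mu and alpha in that regime.
When the third central moment is non-positive the convolution fit is
infeasible and a conservative fallback (mu = min, sigma = SD/10,
alpha = mean − min) is used with a warning.

Quantile normalization maps each value to the row-wise mean of the sorted
columns at its within-column rank; ties receive the mean of the tied
reference values (average-rank convention), keeping the map deterministic.
Matrices must be complete — probe summarization upstream (rule: keep the
highest-mean probe per gene) must not leave missing values.

## Synthetic data

The generator emulates the structure the analysis assumes, with ground
truth for recovery tests:

- **Cohorts** — n_genes=1344 genes (the size of a curated human RBP
  catalogue) × n_samples=150 (between the two liver cohorts' 149 and 206);
  ages uniform on [1, 85] years (the union of the cohorts' reported
  ranges); sexes Bernoulli with male fraction 0.6. Expression is baseline
  N(8, 2²) (log2 microarray scale) plus age_effect·age plus
  sex_effect·I(male) plus N(0, 1) noise. 6.5% of genes carry an age slope
  of ±0.05 log2-units/yr (60% positive — liver age associations skew
  upward) and 3.3% a sex shift of ±0.5 — fractions matching 88/1344 and
  45/1344, effect sizes chosen once as typical log2 microarray magnitudes
  (a 0.05/yr slope spans ~4 log2 units over the age range; the shift is
  half the noise SD).
- **Interactome** — a planted module: Erdős–Rényi edge probability
  p_in = 0.3 among associated genes over p_out = 0.02 elsewhere
  (500 background genes), reproducing the qualitative observation that
  associated genes form a denser, more clustered module than background.
- **Stage series** — one column per stage age (default weeks 2, 6, 21,
  104); a gene's values are age_effect × stage age plus N(0, 0.25) noise,
  so trend signs match planted slopes when noise is small.

All generators are pure functions of their arguments and a seed
(numpy `default_rng`), so identical inputs give byte-identical TSVs. What
the generator does **not** emulate: probe-level array noise, batch effects,
count-based RNA-seq noise, correlated gene modules in expression,
age–sex confounding, or realistic degree distributions (the background is
Erdős–Rényi, not scale-free). Passing recovery tests therefore demonstrate
correctness of the statistical machinery under the model's own
assumptions, not field performance on real cohorts.

## Problem sizes and numerical choices

Calibration checks pool ten 5000-gene null cohorts (50,000 null genes), so
the 3-SD binomial check on the sub-0.001 fraction has adequate power for
its own size; recovery checks use twenty two-cohort studies of 1000 genes.
The planted-module network contrast uses 20 seeds with 100-member
ensembles over degree and clustering coefficient (the two measures that are
cheap per member), and the full four-measure comparison runs once in the
default study. The betweenness/edge-betweenness implementations are
verified exactly against exhaustive simple-path enumeration on 200 random
graphs of ≤ 8 nodes, BH against a naive O(m²) reference, and Fisher /
hypergeometric tails against exact rational enumeration for margins ≤ 12.

Pipeline runs derive per-stage child seeds from the single global seed via
`numpy.random.SeedSequence`, and all TSV output uses a fixed float format,
so a rerun with the same configuration is byte-identical (asserted in the
test suite).

## Known limitations

- The ANCOVA assumes linear age trends and homoscedastic Gaussian noise;
  strongly non-linear trajectories will be found only insofar as they have
  a monotone component (the Spearman direction call is more robust).
- The edge-subsampled null preserves edge count but neither degree sequence
  nor connectivity; it answers "is the observed subnetwork denser/more
  clustered than a random same-size slice of the rest of the interactome",
  not "than a degree-matched rewiring".
- The quantile_only log2 heuristic (max > 100) can mis-fire on unusual
  scales; pass already-logged data or use the explicit steps if in doubt.
- Probe→gene summarization, platform annotation and download clients are
  out of scope; users supply complete matrices.
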