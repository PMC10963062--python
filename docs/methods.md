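# Methods

This note documents the statistical procedures implemented in `micoval`,
the defaults they use, and the choices made where the methods literature
leaves room.

## Preprocessing

Abundance tables (taxa or KO/pathway × samples; counts or relative) pass
through three predefined steps before analysis:

1. **Prevalence filter.** A feature is removed when it is zero in
   *strictly more than* 80% of samples (`max_missing_fraction = 0.80`).
   Zeros are treated as missing: abundance tables encode absence as 0,
   and low-prevalence features contribute mostly ties and false
   discoveries. A feature zero in exactly 80% of samples is retained.
2. **Zero imputation.** Remaining zeros are replaced by one tenth of the
   smallest positive value in the table. The minimum is global by
   default (a single detection-limit proxy for the whole table); a
   per-feature variant is available (`per_feature=True`). Positive
   entries are never modified.
3. **Total-sum scaling.** Each sample is divided by its total, giving
   relative abundances that sum to 1 (within 1e-9).

Median-of-ratios normalization (size factor = median over
everywhere-positive features of count / geometric mean) and rarefaction
(multivariate-hypergeometric subsampling to a common depth, seed
recorded) are available for count tables as alternatives. Filtering is
applied at the analysis rank, i.e. after taxonomic collapsing, so that
rare OTUs belonging to a common genus are not discarded prematurely.

Jaccard distances are computed on the *pre-imputation* table: imputation
replaces zeros with small positives and would destroy presence/absence
information.

## Diversity

Shannon entropy uses the natural log (ecology convention; a log2 flag
exists). Simpson is reported in its Gini–Simpson form 1 − Σp², so larger
values mean more diversity for both indices. Alpha diversity is computed
on TSS relative abundances. The Firmicutes/Bacteroidetes ratio requires
a phylum-rank table and matches the configured phylum names exactly — no
synonym mapping ("Bacteroidota" is not silently treated as
"Bacteroidetes"), because rank names are nomenclature-version-specific
and silent matching would hide a real data problem.

Bray–Curtis (abundance) and Jaccard (presence/absence) distances feed
classical PCoA (double-centered squared-distance eigendecomposition;
negative eigenvalues are dropped and their summed magnitude reported)
and non-metric MDS (SMACOF majorization of Kruskal stress-1, 20 seeded
restarts, best stress kept). Group separation is tested with ANOSIM:
R = (mean between-group rank − mean within-group rank)/(M/2) over the
M = n(n−1)/2 pairwise distances, with the permutation p-value
(1 + #{R\* ≥ R})/(B + 1), B = 999 by default and the seed recorded in
the output. The in-package PCoA and ANOSIM are cross-checked against
scikit-bio in the test suite.

## Differential abundance

Kruskal–Wallis (tie-corrected, chi-square p) is the default per-feature
test; constant features get H = 0, p = 1 and a flag rather than an
error. The two-group Wilcoxon rank-sum test uses the exact null
distribution whenever both groups have ≤25 samples and no ties; tied
small samples (combined n ≤ 12) fall back to full enumeration of
labelings under the symmetric two-sided criterion |U − mn/2| ≥
|U_obs − mn/2| (this makes p = 1 exact for identical multisets);
everything else uses the tie-corrected normal approximation with
continuity correction.

Fold changes are log2 ratios of arithmetic group means of TSS
abundances, defined because zero imputation precedes them. Significance
defaults to raw p < 0.05 per comparison — mirroring common practice in
the web-based tools this package is patterned on — with
Benjamini–Hochberg FDR available via `use_fdr`.

### LDA effect size

The LEfSe-style scorer is single-level (two classes, no
subclass/one-against-all stage): features passing a Kruskal–Wallis gate
at α = 0.05 enter 30 bootstrapped two-class LDAs on 2/3 of each group,
after scaling relative abundances to parts-per-million. The per-feature
effect is the bootstrap mean of (|w_f|·Δ + |Δ_f|)/2, where w is the unit
LDA direction, Δ the class separation along it and Δ_f the raw class
mean difference of the feature; the reported score is log10 of that
effect, floored at 1 before the log (the LEfSe scale convention, which
is why the conventional gate is log10(LDA) > 2, i.e. an effect of ~100
ppm). A pathway or taxon counts as LEfSe-significant only when
log10(LDA) > 2 *and* p < 0.05, both strict.

## Consistency scoring

CS = (n1 − n2)/N with n1/n2 the significant increases/decreases of a
feature across comparisons. The default denominator is the number of
*significant* comparisons (n1 + n2); `denominator="total"` divides by
all comparisons in which the feature was evaluated. Under the default, a
feature significant in a single comparison trivially has |CS| = 1 —
the selection rule (significant in ≥3 comparisons AND |CS| strictly
\> 0.6) exists precisely to gate those out. Features absent from a
comparison's table reduce its n_total but never count toward n1/n2.

WCS = Σ log2FC / Σ |log2FC| over significant comparisons. The up/down
coefficient is interpreted as the sign already carried by the signed
log2FC; a reading that multiplies an explicit ±1 coefficient by the
*signed* fold change would make the score identically 1 and carry no
information, so the implemented convention is the only non-degenerate
one. Exports carry a `wcs_convention` field naming it.

Stratified (cross-phenotype / cross-intervention) validation recomputes
CS independently within each stratum and reports features passing the
selection rule in ≥1 stratum, with a concordance flag set when all
selected strata agree in sign.

## Co-abundance networks

Per group, nodes are the 30 most abundant taxa by within-group mean
relative abundance (name-tie-broken); edges are Spearman correlations
(average ranks for ties) with |ρ| ≥ 0.3 and BH q < 0.05 over all
candidate pairs. Neither threshold comes from a published derivation;
both follow common microbiome co-occurrence practice and are config
keys. One figure caption in the genre uses the top 50 taxa where the
accompanying text says 30; `top_n` is configurable and defaults to 30.
Negative correlations are kept as signed edges; communities (greedy
modularity maximization, chosen over Louvain for determinism without
seed juggling) and centralities use absolute weights. Closeness is
(|component|−1)/Σ within-component path lengths; betweenness is
normalized; eigenvector centrality is the nonnegative L2-normalized
principal eigenvector of the absolute-weight adjacency (on a
disconnected graph it concentrates on the dominant component, which is
the intended reading of "core" taxa). Network properties between groups
are compared per property with the two-sided Wilcoxon rank-sum test.

## Synthetic cohorts

The simulator emulates a curated multi-study collection. A global
baseline composition is drawn once per seed from a sorted log-normal
(σ = 1.25) abundance spectrum over 60 taxa; each project resamples its
own baseline from Dirichlet(200 × base), mimicking between-study batch
effects. Per sample, a composition is drawn from Dirichlet(50 × project
baseline) — moderate overdispersion — and counts are multinomial at
negative-binomial library sizes (mean 20,000, dispersion 5). Case-group
baselines multiply planted taxa by 2^(sign·|log2FC|) and renormalize.
Default cohort sizes are 6 projects × 20 samples per group. Taxa carry
seeded lineages over five phyla (including Firmicutes and Bacteroidetes)
so collapsing and the F/B ratio are exercisable end to end.

**Closure spillover and mass-balanced planting.** Because compositions
are renormalized after planting, an unbalanced planted set shifts every
unplanted taxon by the inverse total mass change — consistently across
projects — so null taxa would masquerade as consistent biomarkers. The
`mass_balanced_effects` helper chooses the up-regulated set so that
up_mass = down_mass/2^log2FC, cancelling the spillover in expectation;
residual per-project jitter is direction-random and is filtered by the
CS gate. Benchmarks that plant effects in relative-abundance space face
this closure problem generically; balancing is the standard remedy.

What the simulator does *not* model: phylogenetically correlated
effects, taxon-taxon interactions (beyond compositional closure),
covariate structure (age, sex, sequencing platform), or zero-inflation
beyond what Dirichlet-multinomial sampling induces. Passing tests
demonstrate correctness of the machinery and calibration under this
generative model, not performance on any particular real cohort.

## Calibration results exercised by the test suite

The acceptance tests (seeded, re-runnable) check, at the problem sizes
noted:

- per-feature Kruskal–Wallis type-I error within [0.03, 0.07] at
  α = 0.05 over 500 null Dirichlet-multinomial cohorts (20 taxa,
  10 + 10 samples, depth 5,000);
- ANOSIM type-I error within the same band over 500 null cohorts
  (30 taxa, 8 + 8 samples, 199 permutations per dataset — the
  permutation grid contains 0.05 exactly, and the machinery is identical
  to the 999-permutation default);
- exact Wilcoxon p equal to full enumeration for every tie-free
  arrangement with m + n ≤ 10;
- end-to-end planted-biomarker recovery across 20 replicates of
  6 projects (|log2FC| = 1.5, 20 per group, mass-balanced 4-up/4-down
  planting): sensitivity ≥ 0.9, null pass rate ≤ 0.01 under the
  "≥3 comparisons, |CS| > 0.6" rule;
- a 16-fold planted shift clearing log10(LDA) > 2 in ≥95 of 100 seeded
  runs, with identical-across-groups features never scored.

## Known limitations

- Vote counting ignores per-comparison precision; a formal
  random-effects pool would weight by standard error. That is a
  deliberate non-goal: the scores are meant to be readable and
  assumption-light.
- The LDA effect size is a re-derivation of the LEfSe recipe, not a
  wrapper around the original implementation; subclass structure is not
  supported.
- ANCOM-BC- and DESeq2-style model-based differential tests are not
  implemented; precomputed functional tables are accepted instead of
  running PICRUSt2/HUMAnN-style prediction.
- UniFrac distances (tree-dependent) and PERMANOVA are out of scope.
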