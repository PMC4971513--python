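# Methods

`mbstats` implements the statistical core of a tissue-microbiome association
study: given an OTU count table, a rooted phylogeny, a taxonomy, and
per-sample metadata, it quantifies within-sample diversity, phylogeny-aware
between-sample dissimilarity, community-level association with a trait under
covariate adjustment, per-taxon differential abundance, and
microbiota-based classification, alongside the contingency-table statistics
of a two-group clinical cohort. This note records the models, the defaults
and why, and the choices made where the design was genuinely open.

## Rarefaction and alpha diversity

Unequal sequencing effort is handled by rarefying every sample to a common
depth (default 20,000 reads) by sampling reads without replacement — a
multivariate hypergeometric draw per sample, so rarefied counts never exceed
the originals and the expected rarefied count of feature *i* is
`depth·nᵢ/N`. Samples below the target depth are dropped and reported, not
up-sampled. Rarefaction is performed once per analysis at a recorded seed
rather than averaged over draws; this keeps every downstream artifact
reproducible from the manifest. Alpha diversity is summarized as observed
OTU richness and the Shannon index `H = −Σ pᵢ ln pᵢ` (natural log), and
group effects on alpha are assessed by OLS with a Wald test, with sequencing
depth and batch available as covariates.

## UniFrac and ordination

Both UniFrac variants are computed from a branch × sample decomposition of
the rooted tree. For a branch *b* of length `l_b`, let `p_b` be the summed
relative abundance of leaves below it. Unweighted UniFrac is the unique
branch length (branches whose descendant leaves are present in exactly one
community) over the union branch length; weighted UniFrac is
`Σ l_b |p₁ᵦ − p₂ᵦ| / Σ l_b (p₁ᵦ + p₂ᵦ)` — the normalized variant, bounded
to [0, 1], matching the GUniFrac convention; a flag disables the
normalization. Identity of indiscernibles and symmetry are asserted;
triangle inequality is not (UniFrac variants need not satisfy it).

Ordination is classical metric scaling: eigendecomposition of
`−½·J·D²·J`. Negative eigenvalues — expected for non-Euclidean
dissimilarities — are excluded from coordinates and from the
percent-explained denominator (no Cailliez/Lingoes correction). Each axis is
oriented so that its largest-magnitude coordinate is positive, making output
independent of the eigensolver's sign conventions.

## Kernel association test

Community-trait association uses a kernel score test in the MiRKAT family.
The distance matrix is Gower-centered, `K = −½·J·D²·J`, and projected onto
the PSD cone by zeroing negative eigenvalues; for Euclidean distances this
recovers the centered Gram matrix exactly, so the kernel test and PCoA see
the same geometry. The null model regresses the trait on covariates only
(OLS for continuous traits, logistic for binary), and the score statistic is
`Q = rᵀKr` on the null residuals. Significance comes from residual
permutation (Freedman–Lane style), `p = (1 + #{Q* ≥ Q}) / (1 + B)`, rather
than the asymptotic mixture-of-chi-squares tail: at cohort sizes of a few
dozen samples the permutation reference is assumption-light and its
anticipated discreteness (`p ≥ 1/(B+1)`) is explicit. Batch effects that are
encoded as covariates are absorbed by the null model; the type-I error of
the adjusted test on batch-confounded nulls is checked empirically in the
acceptance suite (nominal within [0.03, 0.07] at α = 0.05 over 500
simulated cohorts of 28 samples).

The paired-tissue test compares the mean within-subject breast–skin
distance to the mean between-subject breast–skin distance, permuting which
skin sample belongs to which subject; the p-value is one-sided for the
within < between alternative, since the scientific question is whether
paired tissues are more similar.

## Differential abundance

Counts are aggregated to a taxonomic rank by summation (unclassified
lineages pool under their deepest named parent, so depth is conserved),
filtered by prevalence ≥ 10% AND maximum relative abundance ≥ 0.2% —
the stricter reading of the two-threshold rule, both thresholds exposed —
and tested per feature: the outcome is the square root of the relative
abundance (damps outliers, keeps zeros at zero), the model is linear with
covariates plus group, the statistic is the partial F for the group term,
and the null distribution comes from 1,000 Freedman–Lane residual
permutations shared across features. Ties count as exceedances
(conservative). No multiple-testing correction is applied by default —
results are nominal p < 0.05, flagged as unadjusted — with an optional
Benjamini–Hochberg column. Functional (pathway) tables are tested by the
identical machinery after row normalization.

Degenerate outcomes are defined explicitly: a feature with no residual
variation under the null model has F = 0 and p = 1; a varying feature fit
perfectly by the full model has F = ∞.

## Classification protocol

Tissue discrimination is a paired comparison of a random forest (500 trees,
√p features per split — the classic defaults; scikit-learn provides the
forest, the protocol is bespoke) against a constant majority-class
predictor. Each of 100 bootstrap replicates draws a training set with
replacement and evaluates both predictors on the out-of-bag samples;
degenerate replicates (empty out-of-bag, single-class training set) are
redrawn and counted. The two error columns are compared with a Friedman
rank test treating replicates as blocks — implemented in-package with
average-rank tie handling and the standard tie correction because SciPy
declines k = 2 treatments.

**Known limitation (anticonservatism).** Bootstrap replicates all reuse the
single observed dataset, so they are not independent blocks: any spurious
pattern in one noise dataset biases every replicate the same way, and the
Friedman p-value under label-noise data concentrates near zero with a
random sign of the difference. The protocol therefore demonstrates effect
direction and magnitude (error medians), but its p-value should not be read
as calibrated; the acceptance suite carries a deliberately failing
uniformity check documenting this.

## Cohort statistics

Conventions are fixed by exact agreement with printed two-group cohort
tables: Pearson chi-square without Yates continuity correction (nominal
variables); Cochran–Armitage trend with integer scores 1..r and variance
`(R/N)(1−R/N)[Σnᵢsᵢ² − (Σnᵢsᵢ)²/N]` — no finite-population `N/(N−1)`
factor (ordinal variables); Wilcoxon rank-sum, exact by enumeration for
combined n ≤ 20 without ties, otherwise normal approximation with tie
correction and no continuity correction (continuous variables). With two
categories the trend Z² coincides with the Pearson chi-square under these
conventions, which the suite asserts on random tables.

## Synthetic data generator

The generator emulates the structure the analysis assumes: ~33 subjects ×
up to four sample types (breast tissue, skin tissue, skin swab, buccal
swab), two sequencing batches randomized with equal disease-state
representation, ~1,460 OTUs with a log-normal rank-abundance baseline
(log-SD 2.0) dominated by Bacteroidetes/Firmicutes/Proteobacteria/
Actinobacteria, and per-sample depths log-normal around a median of
126,764 reads clipped to [28,549, 335,363].

Per sample, `log π` stacks: baseline + sample-type offset (per-OTU
log-normal, SD 1.0) + batch offset (SD 0.3) + a subject-level random effect
shared across a subject's samples + per-sample noise + a disease log
fold-change (default ln 4) on a designated differential set, drawn from the
rarest baseline quintile by default to mirror signal concentrated in rare
lineages. The within-subject correlation ρ (default 0.5) splits the total
log-abundance noise SD (0.7) into subject-level variance `ρ·σ²` and sample-
level `(1−ρ)·σ²`. The composition is `Dirichlet(θ·π)` with θ = 200 and
counts are multinomial at the drawn depth. Taxonomy is assigned by nested
clade cuts of a simulated pure-birth tree (exponential branch lengths), so
rank aggregation respects phylogeny.

The noise split (σ = 0.7, θ = 200) puts most overdispersion in the explicit
log-normal component with mild Dirichlet-multinomial compounding; it gives
≈2-fold typical between-sample fluctuation per taxon, under which 8-fold
planted shifts on filter-surviving features are detectable at n = 15 vs 13
(power ≈ 0.83) while rarest-quintile shifts remain below the detection
floor — the same contrast (membership signal without abundance signal) the
pipeline is designed to resolve.

What the generator does not emulate: sequence-level artifacts (chimeras,
primer bias), taxonomy misassignment, true ecological covariance networks
among taxa, zero-inflation beyond what the compound model induces, and any
real effect sizes — so passing tests demonstrate the statistical machinery
under the assumed model, not biological conclusions about real tissue.

## Problem sizes in the checked runs

The acceptance suite uses 500 simulated cohorts (n = 28, 200 OTUs, 999
permutations) for kernel-test calibration, one 1,460-OTU cohort for F-test
null uniformity (≥500 filtered features, 1,000 permutations), 200 cohorts
for power, 50 random 8-leaf communities (all 1,225 pairs, both UniFrac
variants) against the branch-enumeration oracle, 100 bootstrap replicates
for the classifier protocol, and 20 random rarefaction fixtures × 400
Monte-Carlo draws against the hypergeometric closed form.
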