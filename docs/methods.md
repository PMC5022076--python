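# Methods

`neurocourse` re-creates, as a tested pipeline, a family of analyses used to
characterize transcriptomic time courses of neuronal differentiation
(SH-SY5Y-style designs: 7 time points at days in vitro 0, 1, 3, 5, 7, 9, 11,
three biological replicates, Illumina-style summary intensities with
detection p-values). This note records the models, the parameters that
matter, the numerical choices, and what the synthetic benchmark does and
does not establish.

## Pre-processing

Signals are log2-transformed and quantile-normalized: every sample column is
mapped onto the across-column mean of sorted log2 values, preserving
within-column ranks. Ties within a column receive the mean of the reference
values across their rank span, which makes the transform deterministic and
idempotent. Multi-probe genes are collapsed to the probe with the highest
variance across all samples (ties broken by lexicographically smallest probe
ID); probes without a gene annotation are dropped with a logged count.

The analysis universe (the "expressed transcriptome") is the set of genes
with detection p < `alpha_detect` (default 0.05) in **every** sample — the
strictest reading of "detected in all replicates"; the full annotated
platform remains the reference universe for enrichment. Sample QC clusters
samples on 1 − Pearson correlation over the `n_top_variance` (default 2000)
most variable genes with average linkage; a sample is flagged when its first
merge height exceeds median + 3·IQR of all first-merge heights. The flagging
rule is ours — it simply needs to be explicit to be testable.

## Differential expression

Each gene and each time point t is fitted against the baseline with a linear
model of expression on the dichotomized time indicator plus a random
intercept per biological replicate. Because the design is balanced and
paired (every replicate measured at both time points), the REML variance
components are the classical ANOVA estimators and the fit has closed form,
which makes it vectorizable across all genes:

- when the replicate variance estimate is positive, the fixed effect is the
  mean of paired replicate differences with SE = sqrt(var(d)/R), tested
  against Student t with R − 1 df;
- when the replicate mean square does not exceed the residual mean square,
  the variance component is truncated at zero and the model degenerates to
  OLS — the two-sample pooled-variance t-test with 2R − 2 df.

We use the t reference rather than a normal (Wald) reference in both
branches: with R = 3 the variance estimates carry 2–4 df and a normal
reference is badly anticonservative; with the t reference null p-values are
uniform (verified by simulation with a Kolmogorov–Smirnov check). A unit
test cross-checks effect and SE against `statsmodels` MixedLM. Genes with
identical values in both groups get effect 0 and p 1 by convention.

Multiple testing uses Benjamini–Hochberg step-up with the denominator fixed
to the size of the expressed universe, so the correction honours the full
number of tests even if individual genes were skipped. Up/down calls use
q < 0.05 with the sign of the effect; a gene may be up at one time point and
down at another. Nominally significant counts (p < 0.05, uncorrected) are
reported per contrast but never enter the call sets.

## DTW dynamics

A gene's trajectory is its replicate-mean log2 fold change versus baseline
(length = number of time points, first entry 0). Its dynamic-time-warping
distance to the flat zero trajectory uses absolute-difference local cost and
the symmetric unit-weight step pattern (match/insert/delete), with both
endpoints aligned; the statistic is the unnormalized accumulated cost. An
exhaustive warping-path enumeration on short series serves as the oracle in
tests.

The null model perturbs flat trajectories with Gaussian noise at several SD
levels (`noise_levels`, default 0.1–0.5; `n_noise` = 100 rows per level) and
regresses DTW distance on SD by OLS. The calibration returns the slope, the
intercept b0, its upper 95% boundary u0 = b0 + 1.96·SE(b0), and the
zero-anchored threshold 2·u0. Because DTW distance is positively homogeneous
in the noise scale, the intercept of this regression converges to zero as the
noise matrix grows; a threshold anchored at the intercept alone therefore
cannot control false positives on noisy data. The pipeline instead evaluates
the fitted line at the experiment's own trajectory-noise SD (estimated from
within-time-point replicate scatter: sd = sqrt(2·s²/R)) and thresholds at
twice the upper 95% confidence boundary of that predicted null distance.
This retains the linear noise model and the "twice the upper boundary" rule
while anchoring it where the data live; on pure-null simulations the dynamic
fraction stays below 5%.

Dynamic genes are clustered by k-means (Euclidean distance on unscaled
trajectories, `kmeans_n_init` = 50 starts, k = 1..`k_max` = 12). The cluster
count maximizes the second difference of the within-cluster sum-of-squares
curve — an automated stand-in for the visual elbow; it favours the sharpest
bend, so for hierarchically separated shape families it can sit below the
finest planted structure. Clusters are numbered by descending mean final
fold change.

## Reproducibility-selected ICA

For each candidate component count (2–8), FastICA is run `n_iter` = 250
times from independent random starts on the expressed genes × samples
matrix (PCA whitening to the component count). Runs are kept only if they
converge; the tolerance is deliberately tight (1e-6, 400 iterations)
because reproducibility is only meaningful between runs that reached a
fixed point — with a loose tolerance, over-extracted counts "converge" at
arbitrary early-stopping points and appear spuriously stable. Components
are matched to a reference run by optimal one-to-one assignment on absolute
load correlation and sign-aligned; the consensus load is the first
principal component of the aligned run-load matrix, z-scored; per-component
reproducibility is the mean correlation of run loads with the consensus.

The selected count is the largest whose components all exceed the
reproducibility cutoff (0.999), among counts with at least half of their
runs convergent (an ensemble that mostly fails to converge carries no
evidence). Absence of a passing count is a valid outcome and is reported
with the full table. Genes with |z-scored consensus load| > 3 are component
members. Note that under the default synthetic conditions the planted
temporal shapes are strongly collinear in the 21-sample space, the ICA
problem has several near-equivalent optima, and no count reaches 0.999 —
the pipeline then reports the table and no component calls, which is the
intended behaviour rather than a failure; count recovery is demonstrated
under identifiable conditions in the test suite.

## Signed co-expression network

Adjacency a_ij = ((1 + cor_ij)/2)^β with Pearson correlation across all
samples; β is either fixed or chosen as the smallest grid value whose
connectivity distribution fits a scale-free law with R² ≥ 0.8 (log–log
regression of binned frequency on connectivity), falling back to the best
fit with a warning. The topological overlap matrix is

    TOM_ij = (Σ_{u≠i,j} a_iu·a_uj + a_ij) / (min(k_i, k_j) + 1 − a_ij)

with k_i the connectivity excluding the diagonal. Modules come from
average-linkage clustering of 1 − TOM with a static cut
(`cut_height` = 0.99); clusters under `min_module_size` (default 30) stay
unassigned (grey) and surviving modules are named by the size-ordered color
palette convention. The static cut (vs. dynamic tree cutting) was chosen for
reproducibility: two parameters, both in the config. Module eigengenes are
the sign-oriented first principal component of the standardized module
submatrix, plus the same computed on per-time fold changes. Genes whose
expression is constant (including to within floating-point residue,
sd ≤ 1e-10) are dropped before correlation.

Hub metrics: Connectivity = row sum of the adjacency (the verbatim "sum of
weighted correlation" definition, i.e., adjacency-based, not TOM-based);
Degree and Betweenness are computed on the unweighted graph linking genes
with Spearman ρ strictly above 0.90; betweenness is the unnormalized
shortest-path count with equal-length paths split fractionally. Top-10% hub
sets take ceil(0.10·n) genes per metric, ties broken by gene ID.

## Enrichment

Fisher's exact test on the 2×2 table of list × cluster membership against
the full platform universe; two-sided by default (the emulated analyses
report both over- and under-representation), with one-sided modes available.
The sample odds ratio uses a Haldane 0.5 correction only when a cell is
zero; log odds ratios are natural logs. Grids of lists × clusters are
BH-corrected over exactly (#lists × #clusters) tests, with reporting at
FDR < 0.1 and significance tiers at 0.05/0.01.

Rank–rank hypergeometric overlap (RRHO) ranks two signed score vectors,
then computes one-sided hypergeometric enrichment of the overlap between
top-k prefixes on a fixed bin grid (default 200 genes per bin), returning
the −log10 p matrix (threshold-set formulation).

DAG-aware term enrichment implements the bottom-up *elim* decorrelation:
terms are processed leaves-first; when a term is significant at `go_p_cut`
(default 0.01), its annotated study genes are removed from all ancestors'
annotations before those are tested. The weighted variant of
child–parent decorrelation (where child scores down-weight rather than
remove genes) is intentionally not implemented; elim is the documented
simplification.

## Synthetic data generator

The generator emulates the differentiation experiment's design: 7×3 samples,
probe-level linear-scale intensities (2^log2), detection p-values, ~30%
multi-probe genes (second probe with attenuated dynamics, so variance-based
collapse picks the primary), a background stratum (~44%, detection
p ≥ 0.05 somewhere, mirroring ~11.4k expressed of ~20.3k annotated genes),
planted monotone-up/down (linear in time index, amplitude `effect_size` = 2
log2 units), transient (discretized Gaussian bump peaking mid-course,
anchored at 0), latent-factor modules (loadings U(0.9, 1.1) on smooth
distinct latent shapes, carved out of the flat class), residual noise
(SD 0.25) and replicate offsets (SD 0.1). Risk lists are sampled with a
deterministic in-class count solved from the requested odds ratio, keeping
all four table cells positive so the planted OR is finite and estimable.

Baseline intensities are drawn in disjoint strata (background < flat <
up/transient < down < modules), with down-regulated genes starting high and
descending through the band where up/transient genes start, and with a
population of *unannotated scaffold probes* (20% of the gene count, static,
spanning the dynamic range — real chips carry a large unannotated probe
fraction, which the collapse step drops). This layout has one purpose: to
make quantile normalization information-preserving in the noiseless limit.
Quantile normalization transmits a gene's signal only through its rank
trajectory; a gene that crosses nothing is flattened, and a gene passed by
its own descending/rising cohort is inverted. The strata guarantee that
every dynamic gene exchanges ranks against stable reference material while
flat and background genes are never traversed. That is what makes exact
zero-noise recovery (DEX set, dynamic set, module partition) achievable as
a design property. At realistic noise the strata are immaterial — noise
dominates local rank order.

What the generator does **not** emulate: bead-level summarization, batch or
hybridization effects, probe cross-hybridization, heavy-tailed intensity
distributions, correlated noise across genes, or per-gene amplitude
variation within a trajectory class (class amplitudes are exact by design so
the zero-noise limit is checkable). Passing tests therefore show the
pipeline's statistics are implemented correctly and behave as designed under
controlled signal/noise — not that the defaults are tuned for any particular
real dataset.

## Problem sizes and determinism

Default pipeline scale is 2 000 genes (≈1 100 expressed), chosen so a full
run (including the 7×250-run ICA scan) completes in about a minute on one
CPU; the test suite uses 300–5 000-gene simulations per property. One master
seed is expanded into independent per-stage seeds (simulation, DTW null,
k-means, ICA, risk lists); identical config + seed reproduces byte-identical
reports.

## Known limitations

- The quantile-normalization rank-frontier effect is intrinsic: on real
  data, genes at the extreme intensity ranks can have shrunken or distorted
  normalized trajectories.
- The elbow rule (max second difference of the scree curve) prefers the
  sharpest bend; nested shape families can be cut coarser than the planted
  truth.
- The per-gene reading of the DTW noise model (one regression per gene) is
  approximated by a single global regression evaluated at the experiment's
  estimated noise SD; per-gene noise SDs can be passed as the regressor if
  needed.
- ICA component membership (|z| > 3) assumes approximately normal bulk
  loads; with very sparse components the z-scoring is conservative.
- Static tree cut does not merge close modules by eigengene correlation;
  module counts on real data will differ from dynamic-tree-cut workflows.
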