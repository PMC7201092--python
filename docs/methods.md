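# Methods

## The analysis

A ceRNA (competing endogenous RNA) network connects transcripts that
co-regulate each other by competing for a shared miRNA pool. The pipeline
builds these networks in two stages. First, a **target-share backbone**: for
each pair of genes with sponge potential (total miRNA site count ≥ 6), the
overlap of their miRNA sets is scored with the upper-tail hypergeometric
probability P(X ≥ k) over the miRNA universe (by default, the miRNAs present
in the supplied table), and pairs are kept at Benjamini–Hochberg q < 0.05.
The overlap is tested on site *presence*, not counts, and BH is applied once
across all tested pairs of a build. Second, per condition, backbone edges are
retained when the sample Pearson correlation of the two genes — computed on
log2(value + 1); positive correlations only — reaches the condition's
cutoff. Constant-expression genes are excluded with a warning. Genes enter
the analysis when expressed ≥ 1 (FPM scale) in strictly more than 80 % of all
samples.

### Correlation significance and the equal-significance cutoff

The two-tailed p-value of a sample correlation r at sample size N uses
Student's t with df = N − 2 and t = r·√(df/(1 − r²)); |r| = 1 maps to p = 0.
`equivalent_cutoff(r_ref, n_ref, n_target)` returns the smallest grid value
c ∈ {0, step, …, 1} (step 0.01, two-decimal cutoffs) whose two-tailed p at
n_target is ≤ that of r_ref at n_ref. Under this definition the significance
of r = 0.6 at N = 77 is p = 8.07·10⁻⁹ (log₁₀ p = −8.09) and the matched
cutoff at N = 20 is **0.93**. A published two-decimal account of this same
mapping reports 10^−8.2 and 0.91; those printed values are reproducible only
if the t distribution is given df = N rather than the stated df = N − 2. We
follow the stated definition; the discrepancy is inherent to the source, not
to the scan.

### Spectral comparison and cutoff calibration

Networks are compared by the eigenvalue distribution of the normalized
Laplacian N = D^(−1/2) L D^(−1/2), with entries 1 on the diagonal,
−1/√(deg_i·deg_j) for adjacent pairs, 0 otherwise. Eigenvalues lie in [0, 2];
0 appears once per connected component. Degree-0 nodes are dropped before the
decomposition — their all-zero rows would pad the spectrum with zeros that
depend only on node-universe bookkeeping. Eigenvalues come from a symmetric
solver, are sorted ascending, and are clipped to [0, 2] at tolerance 1e−8.
Similarity is the two-sample two-sided Kolmogorov–Smirnov test on the two
eigenvalue multisets (full multisets, not binned densities), with the
asymptotic p-value; identical networks give statistic 0, p = 1, and a higher
p means more similar topology.

Calibration builds the target group's network at every cutoff in
{0, 0.01, …, 1}, compares each against the reference network, and selects the
cutoff with maximal KS p. Exact ties are broken by average clustering
coefficient closest to the reference's, then by the smaller cutoff; both
tie-break quantities are stored in the returned grid so the selection is
reproducible from the artifact alone. Empty-network cutoffs record NaN.

Two caveats of the KS-on-spectra score, visible in the calibration grids and
documented as limitations: (i) the comparison is shape-based and does not
penalize network size directly, so moderately inflated networks can score
well; (ii) its power falls with the number of eigenvalues, so very high
cutoffs that shrink the target network to a small stable core can receive
optimistically high p-values. In the synthetic experiments below, the
selected cutoff for an under-sampled group therefore lands anywhere above
the reference value, occasionally deep above it; the clustering-coefficient
column of the grid is the practical cross-check.

### Downstream statistics

Recurrent 3′US (3′-UTR shortening) genes are those called in strictly more
than 20 % of a group's tumor samples. 3′US ceRNA partners are the union of
network neighbors of the 3′US genes, minus the 3′US genes themselves. The
housekeeping (HK) sponge analysis extracts, per condition network, the
subnetwork of edges with ≥ 1 endpoint in the HK set, scores the two focal
subnetworks with the KS spectral similarity, and compares against 200
matched nulls: per repetition, the same number of edges is drawn without
replacement from each network's edges touching *no* HK gene. The empirical p
uses the add-one estimator (1 + #{null p ≥ focal p})/(reps + 1), so it is
never zero and is bounded below by 1/201 ≈ 0.005 at 200 repetitions. The
degree ratio of a gene is the fraction of its normal-network neighbors
retained in the tumor network (tumor-only gains are ignored). Fold change is
log2 of tumor over normal means with pseudocount 1. Unnamed two-group
comparisons use the two-sided Mann–Whitney test — exact when both samples
are ≤ 25 and tie-free, asymptotic with tie correction otherwise. Gene-set
overlap and over-representation reuse the hypergeometric kernel with BH
adjustment across a collection. In *backbone-only* mode (too few replicates
to estimate co-expression, e.g. knockdown experiments with duplicate
samples), `classify_network_genes` labels backbone genes directly as 3′US
genes, 3′US ceRNA partners, or unconnected, cross-tabulated with HK /
tumor-associated / transcription-factor annotations.

## The synthetic generator

Real inputs are paired tumor/normal RNA-seq expression for two subtype
groups of unequal size, a curated gene × miRNA target-site table, gene-class
lists, and per-sample APA calls produced externally. The generator emulates
the statistical structure the analysis assumes:

- miRNAs are partitioned into blocks; each gene targets a subset of one
  block's miRNAs, so miRNA sharing is block-local and nothing overlaps
  across blocks.
- Per sample, latent miRNA activities a_m ~ N(0, 1) repress their targets:
  x_gs = baseline_g − scale_g · Σ_m site_gm · a_ms + ε_gs, floored at 0,
  with baseline_g log-normal (median ≈ e⁴ ≈ 55, FPM-like) and scale_g set so
  the miRNA-driven component has a per-gene signal SD. Genes sharing miRNAs
  are thereby positively co-expressed.
- **Regulation-strength heterogeneity**: each ordinary gene's signal SD is
  drawn uniformly from `signal_strength_range` (default 0.3–0.85 of
  `signal_sd` = 2.0, against noise SD 1.0). Most target-share pairs are then
  weakly-to-moderately co-expressed — the reservoir whose estimation noise
  inflates small-sample networks, which is the phenomenon the calibration
  exists to correct. Without this heterogeneity the backbone contains only
  strongly co-expressed pairs and the inflation effect disappears.
- **Housekeeping sponges**: a configurable HK fraction receives high total
  site counts (≥ 6 by construction; default 8–20), a fixed stable signal SD
  (1.2) and a smaller noise SD (0.4 < 1.0), giving lower total variance and
  more reproducible correlations. Optionally (`hk_dedicated_blocks`) HK
  genes occupy their own miRNA block(s) with full-block support and evenly
  spread counts: their pairwise correlations are then uniformly high and the
  sponge community forms a stable near-clique conserved across groups.
- **Planted 3′US**: a set of non-HK genes concentrated in half the open
  blocks loses all effective target sites in tumor; every non-3′US gene
  sharing a miRNA with one of them ("partner") is shifted down by
  `repression_effect` (default 5) with per-sample variability
  `repression_sd` (default 2), reflecting variable APA penetrance across
  tumors. The variability also attenuates partners' tumor co-expression, so
  partners lose network neighbors in tumor — the planted degree-ratio
  effect. Per-sample APA calls mark each planted gene 3′US in a tumor
  sample with probability 0.6, over a 1 % background of spurious 3′US/3′UL
  calls.
- **Group divergence** (`group_divergence`, default 0): a fraction of
  non-HK genes have their regulation strengths independently redrawn in
  group B, de-synchronizing non-HK crosstalk between the groups while the
  HK core stays shared — the planted structure behind the focal-vs-null
  subnetwork comparison.

Determinism: one `numpy` Generator seeded from `seed` drives every draw, so
identical configurations are bit-identical. The generator does **not**
emulate: read-level noise, normalization artifacts, miRNA expression
dynamics, APA site choice within a 3′-UTR (site loss is all-or-none),
within-pair tumor/normal correlation, or negative co-expression. Passing
tests therefore demonstrate the pipeline's behavior under its own modeling
assumptions, not performance on real RNA-seq.

## Problem sizes and experiment configurations

The test suite runs three named synthetic designs, all chosen as scaled-down
analogs of a 77-vs-20-pair two-subtype study:

- *calibration design*: 400 genes, 96 miRNAs in 12 blocks (2 dedicated to a
  10 % HK community), strengths 0.15–0.85, groups of 75/75 and 20/20
  samples. Across seeds the calibrated small-group cutoff exceeds the 0.6
  reference (selections typically 0.61–0.80), and a 100-repetition
  subsampling experiment at sizes 20 vs 75 shows mean edge-count inflation
  around 1.5–1.9×.
- *planted-APA design*: 400 genes, 48 miRNAs in 6 mixed blocks, so HK genes
  appear among the 3′US partners; used for the fold-change and
  degree-ratio direction checks.
- *synchronized-sponge design* (`synchronized_sponge_config`): 600 genes,
  64 miRNAs in 8 blocks with one dedicated HK block (30 HK genes, site
  totals 16–24), strengths 0.5–0.95, group divergence 0.9, equal 75/75
  groups. The HK subnetworks are then identical between groups (KS statistic
  0) and beat all 200 matched nulls (empirical p = 1/201).

These sizes keep the full suite under a minute of compute while preserving
every qualitative effect; the matrices and networks are one to two orders of
magnitude smaller than a real cohort's.

## Numerical and interface choices

- Hypergeometric tails via `scipy.stats.hypergeom.sf`; BH via
  `statsmodels`; KS via `scipy.stats.ks_2samp(method="asymp")`; graphs and
  clustering coefficients via `networkx` (the normalized Laplacian is
  assembled directly and checked against `networkx` in the tests).
- The correlation p-value is computed from the t formula rather than
  delegated, since the calibration machinery needs it at arbitrary (r, N);
  `scipy.stats.pearsonr` serves as an independent oracle in the tests.
- All writers emit lexicographically sorted rows; expression TSVs use
  `%.17g` and are read back with round-trip float parsing, so write → read
  is lossless and identical runs are byte-identical. The run manifest
  records the configuration, child seeds (one global seed fanned out per
  stage via `SeedSequence`), headline results, and SHA-256 checksums of
  every artifact.
- Pipeline stages that cannot be computed on a given dataset (e.g. the
  matched-null comparison when HK-incident edges outnumber the rest, which
  violates the null-sampling precondition) are recorded in the manifest as
  degenerate with a reason, rather than aborting the run.
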