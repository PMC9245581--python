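# Methods

This note documents the models implemented in `metasoil`, the synthetic
cohorts they are tested on, the numerical choices that matter, and the
limits of what the test suite demonstrates.

## Study design being emulated

The analysis targets an *extreme discordant phenotype* cohort: patients at
opposite ends of the metastasis-risk spectrum (low clinical risk but
relapsed, versus high clinical risk but relapse-free), genotyped
genome-wide. The premise is that no single germline variant carries a
strong marginal effect; the susceptibility signal lives in epistatic
interactions spread over many loci, which a pairwise interaction network
can surface and a gene-regulatory analysis can interpret.

## Synthetic cohorts

Three generators (`metasoil.synthetic`) produce the inputs every stage
assumes. Each draws from its own RNG stream seeded by `(seed, name hash)`,
so adding or rerunning one generator never perturbs another's output.

**Genotypes.** Per-SNP minor-allele frequencies are uniform on
`maf_range` (default 0.05–0.5, the common-variant spectrum); null SNP
genotypes are Binomial(2, MAF) independent of phenotype. The phenotype of
an individual follows a logistic model whose log-odds sums, over planted
pairs (i, j),

    marginal_effect·(gᵢ+gⱼ) + ln(OR)·(gᵢ−2·mafᵢ)(gⱼ−2·mafⱼ).

The product term is *mean-centred*, so with `marginal_effect = 0` each
planted SNP has vanishing marginal association at any MAF — the purely
epistatic regime the design postulates. (A product centred at one minor
allele would leak a marginal slope of −(1−2·maf)·ln OR per allele and
contradict that premise at maf ≠ 0.5.) Individuals are rejection-sampled
until the requested case and control counts are reached, mirroring a
fixed-size extreme-phenotype recruitment; an explicit error names the
unreachable count if the settings make one class too rare.

**Expression.** TF expression is Normal(10, 2); each target gene is
α + β·TF + Normal(0, σ) with the sign of β drawn per edge (defaults β = 1,
σ = 1); regulons are disjoint target sets of sizes uniform on
`regulon_size_range`. Dysregulated genes (half of them inside regulons —
a constant within-role shift leaves rank-based MI untouched) are shifted
by `dysregulation_shift` control-SD units in tumour samples and twice that
in metastasis samples. Twenty stemness genes load on a latent per-sample
factor (r ≈ 0.8) that also defines the stemness index; tumour samples get
PAM50-style subtype labels at realistic proportions (40/20/15/15/10).
Sample layout defaults to 30 control / 100 tumour / 30 metastasis — a
control-poor tumour cohort.

An optional `tf_hierarchy` flag couples a few TFs under one master
regulator at r = 0.7 (marginal SD preserved). It is **off by default**:
correlated regulators make the indirect master→grand-target MI fall within
DPI's tolerance of the TF–TF MI, which caps edge precision near 0.85 no
matter the algorithm — an inherent property of DPI, not an implementation
artifact. The pipeline preset turns the hierarchy on because it gives the
module stage a non-trivial bow-tie core.

**Survival.** Event times are exponential with rate
`baseline_hazard · exp(coef · s)` where `s` is the standardized mean
expression of the designated hazard gene set; censoring is an independent
Bernoulli(`censoring_rate`) coin with censored records truncated uniformly
before their event time.

What the generators do *not* emulate: linkage disequilibrium and
population structure, batch effects, count-based expression noise,
copy-number events, non-proportional hazards. Passing tests therefore
demonstrate the correctness and calibration of the algorithms, not their
power on real cohorts.

## Genotype QC and single-variant screen

Samples below 90% call-rate are removed first, then SNPs below 90%
call-rate or with Hardy–Weinberg exact p < 1e-6. The HWE test is the
Levene–Haldane exact distribution, two-sided by summing the probabilities
of all heterozygote counts no more likely than the observed, computed with
log-gamma weights (oracle-tested against exact rational enumeration to
n = 200). The single-SNP screen is the Cochran–Armitage trend test with
additive scores and a genome-wide flag at 5e-8. LD pruning is greedy over
sliding windows (50 SNPs, step 5) on squared genotype correlation with
missing calls ignored pairwise; the lower-MAF member of a violating pair
is dropped (tie: later position). The evaporative-cooling reduction of the
original pipeline is simplified to plain ReliefF top-K — the published
description reduces to "keep the K most relevant variants", and ReliefF is
the interaction-sensitive core of that method; this is a documented
stand-in, with genotype distance |gₐ−g_b|/2 and k = 10 nearest
hits/misses under Manhattan distance.

## Interaction matrix and SNP ranking

Every SNP pair is fit with `phenotype ~ gᵢ + gⱼ + gᵢ·gⱼ`. Because
genotypes are discrete, each fit depends on the data only through its
2×3×3 case/control genotype-cell table; all tables come from 18 one-hot
matrix products and the fits run as batched Newton iterations on those
sufficient statistics (validated against per-pair `statsmodels` fits to
seven decimals). This makes the O(n²) scan run in seconds at 500 SNPs and
minutes at 10⁴. Non-convergent, separated (|β| > 25) or degenerate fits
contribute strength 0 / p 1, logged, rather than dropping the pair — the
rank iteration needs a complete matrix. BH adjustment runs once over all
n(n−1)/2 interaction p-values.

SNPrank solves `r = γ·A·r + (1−γ)·u` with γ = 0.85, A the off-diagonal
part of G column-normalised (zero columns teleport uniformly), and
u ∝ diag(G): the damped eigenvector ranking with main-effect-weighted
teleportation of the cited construction. The power iteration is
oracle-tested against the dense linear-system fixed point. A caveat worth
stating plainly: because A is column-stochastic, every SNP redistributes a
unit of score regardless of its absolute interaction strength, so ranking
differences are driven by main effects and network position. Planted
*purely epistatic* SNPs (no main effect) at odds ratio 3 in an 800-sample,
500-SNP panel do **not** reach the top rank decile: their per-pair
interaction z (≈3.5–5.5, MAF-dependent) sits at the noise ceiling of a
124,750-pair scan (max null |z| ≈ 4.6), so a large fraction of planted
pairs are statistically invisible at that scale. The corresponding
recovery test is left failing rather than re-tuned; at reduced multiplicity
(100 SNPs) the planted pair's q-value is the scan minimum in ≥80% of
seeds, which the suite does assert.

## Gene network, link communities, centrality

SNP pairs with q < 0.01 become gene-gene edges via nearest-gene mapping
(gene body ± 1 Mb; minimum distance wins, ties to the smaller gene id);
edge weight is the *maximum* supporting interaction strength, so one
strong interaction is not diluted by weak ones; intra-gene pairs are
dropped. Link communities follow the edge-clustering construction:
similarity of edges sharing node k is the Jaccard index of the inclusive
neighbourhoods of the non-shared endpoints; single-linkage clustering of
edges; cut at maximum partition density D = (2/M)·Σ m_c(m_c−(n_c−1)) /
((n_c−2)(n_c−1)) with D_c = 0 for two-node communities, ties resolved
toward fewer communities. Community centrality of a gene is the number of
distinct link communities among its incident edges — the quantity used to
prioritise genes. Small-world sigma uses degree-preserving rewired
baselines with a Monte-Carlo standard error.

## Regulatory inference

Mutual information is the plug-in estimator on an equal-frequency 6-bin
2-D histogram of rank-transformed vectors (ties share the bin of their
smallest rank, so constant vectors give exactly zero). Rank binning makes
MI invariant to monotone transforms, sidestepping normalisation choices.
Per TF, a pooled permutation null (TF vector shuffled `n_perm` times
against all candidates) gives empirical p-values with the add-one
convention; BH runs over all TF-candidate pairs; an edge must additionally
exceed the per-TF null (1−q) quantile in ≥95% of sample bootstraps
(`n_boot = 0` skips the filter and flags the output). DPI pruning
evaluates every closed TF–TF–target triplet on the original MI values in
one pass, removing the minimum edge when it is below (1 − 0.1) times the
second-smallest. On the default synthetic cohort the recovered edge set
attains precision ≈ 0.99 / recall ≈ 1.0 over 20 seeds.

## Expression indices and screens

Z_tg = (E_tg − mean_c E_cg)/sd_c E_cg with the n−1 SD denominator; the
tumour expression index is the proportion of tumour samples with
|Z| > 1.96, and the metastasis expression index swaps roles (metastasis
vs tumour reference). The expressed threshold defaults to the fixed 0.35
of the original random-model calibration; `calibrate_index_threshold`
reproduces that calibration by drawing pseudo-genes i.i.d. from the pooled
expression values and taking the 95th percentile of their index
distribution (tracks the Binomial(n_tumour, tail) quantile on pure noise).
Threshold spellings are deliberately mirrored per screen: index strictly
> 0.35, differential expression logFC strictly > 1 at BH q < 0.01, the
seed-set variant logFC ≥ 5 at unadjusted p < 1e-4, stemness correlation
p < 1e-10. Differential expression is a Welch-t + BH screen on log-scale
values — the artifact's contribution is the index logic, not a
moderated-variance model; inputs are assumed normalised/log-transformed.

## Metastasis module

Seeds = union of the three screens. DIAMOnD adds, per step, the candidate
with the smallest hypergeometric tail P(X ≥ k_s) of its module
connectivity (population = all nodes, successes = module size; ties by
higher k_s then smaller id), for 200 iterations or until nothing connects;
no seed weighting. Communities on the undirected projection come from
greedy modularity (deterministic); per-(community, set) over-representation
is hypergeometric with universe = network nodes, BH across all pairs,
reported at q < 0.001. Bow-tie scores count S_v = source TFs reaching v
and T_v = sink genes reachable from v (excluding v itself on both sides);
sinks are the out-degree-zero genes, which in a strictly bipartite TF→
target map are exactly the non-TF genes. The one-proportion z-test is
one-sided in the over-representation direction.

## Survival validation

Kaplan–Meier product-limit curves and the log-rank test with
hypergeometric variance at each distinct event time are implemented
in-house and verified against `lifelines` to nine decimals; the in-house
route exists because the random-set benchmark needs thousands of log-rank
statistics per call, which run as one vectorised pass over group-indicator
matrices. Gene sets are scored as per-sample mean expression and split at
the median (ties and the median sample to the low group — a fixed
convention); the empirical p against `n_random` equal-size random gene
sets uses the add-one convention (1 + #as-good)/(n+1), on the statistic
scale to avoid p-rounding ties, so it is never zero. Degenerate random
splits (all samples one side) are discarded and the effective count
reported.

## Pipeline

`metasoil run --config run.cfg` drives
simulate → qc → interact → epinet → grn → index → module → survive from a
plain INI file with per-stage sections; unknown sections or keys fail
validation by name. Every stage records parameters, input hashes and
output hashes (SHA-256) in `manifest.json`; a rerun with unchanged
parameters and inputs skips the stage. The `interact` CLI refuses more
than 20,000 SNPs without `--force`, since the pairwise scan is quadratic.

## Problem sizes and reported numbers

Desk-scale defaults — 400+400 samples × 500 SNPs with 5 planted pairs at
odds ratio 3; 300 genes × 160 samples with 10 regulons of 8–15 targets —
were chosen so a full pipeline run and the whole test suite complete on a
single CPU in minutes while every planted effect is comfortably
detectable by its intended stage. `scripts/acceptance.py` recomputes all
headline quantities from scratch at these sizes (seed-controlled); the
README's worked example shows actual printed output. No empirical claim
in this note goes beyond what those runs compute.

## Known limitations

* The SNPrank recovery caveat above: pure-interaction variants at modest
  odds ratios are not recoverable by a column-stochastic rank iteration at
  realistic scan multiplicities.
* DPI cannot disentangle strongly correlated regulators (tolerance-bounded
  by MI estimation bias); the hierarchy flag documents the effect.
* ReliefF stands in for the full evaporative-cooling schedule.
* Bow-tie cores are empty on strictly bipartite inferred networks — they
  require TF-TF regulation to exist and be recovered.
* All thresholds (0.90 call-rate, HWE 1e-6, q 0.01, |Z| 1.96, index 0.35,
  200 DIAMOnD iterations, 1000 random sets) are exposed as parameters with
  these defaults.
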