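# Methods

## Model and assumptions

Each gene's local regulatory network is a Bayesian network over typed
nodes (phenotype *p*, mRNA *e*, DNAm sites *m*, H3K9ac peaks *h*, anchor
SNPs *g*, composite covariates *C*). The observational model is Gaussian:
node values are treated as jointly normal given the DAG, which is why all
non-genetic node values are rank-inverse-normal transformed before
structure learning and why the BGe score (a conjugate normal–Wishart
marginal likelihood) is the default. The causal content comes entirely
from constraints, not the likelihood: BGe is score-equivalent, so without
the mask, i→j and j→i would be indistinguishable within a Markov
equivalence class. SNP nodes are roots by construction (dosage precedes
molecular state), each anchor SNP may parent only the variables it anchors
plus the phenotype, and covariate nodes are roots feeding only their own
variable. Those asymmetries, plus v-structures involving anchors and
covariates, are what orient the molecular edges.

Key structural conventions:

* exactly one mRNA node and at most one phenotype node per network;
* marks enter a gene's network only when they are significantly
  expression-associated (eQTM/eQTH, dual gene/peak-level FDR) **and**
  carry a cis-QTL of their own; the gene itself must have a cis-eQTL
  (`require_eqtl=True`, relaxable);
* when one SNP is the best cis-variant of several variables (common in
  simulation, where the mQTL also tags expression), it becomes a single
  node allowed to parent all of them — duplicating the dosage would make
  the Gaussian scatter singular;
* one covariate node per molecular variable, matching the composite
  definition C_j = Σ_i w_ij F_i (a single weighted combination of that
  layer's hidden factors per variable).

## Scoring

BGe hyperparameters: α_mu = 1, α_w = p + 2 (p = number of nodes), prior
scatter T = α_mu (α_w − p − 1)/(α_mu + 1) · I, prior mean 0. With
unit-variance (quantile-normalized) data this makes the prior predictive
covariance the identity. Subset marginals are computed from the posterior
scatter matrix R = T + S + (α_mu n/(α_mu + n)) x̄x̄ᵀ via log-determinants
and multivariate gamma functions, cached per subset, so family scores
during MCMC are dictionary lookups. A Gaussian-BIC score is available
(`score="bic"`) for users who prefer a consistent non-Bayesian criterion;
it is not score-equivalent at finite n.

## Sampler

Structure MCMC over mask-respecting DAGs with a uniform structure prior.
Proposal mixture per step: 1/15 REV (new-edge reversal), and the remaining
14/15 split evenly between a pair toggle (uniform over mask-allowed
ordered pairs; delete if present, add if absent, stay if the addition
closes a cycle — symmetric, Hastings ratio 1) and a plain reversal of a
uniform existing edge (edge count invariant, ratio 1). The REV move picks
an existing edge i→j, orphans both endpoints, samples a new parent set for
i constrained to contain j from the Boltzmann distribution over enumerated
acyclic parent sets, then a free parent set for j, and accepts with the
partition-function ratio (|E(G)|/|E(G̃)|) · Z₁Z₂ / (Z₃Z₄); all family
weights cancel. Every proposal is checked for acyclicity and mask
compliance. Defaults follow the reference protocol: 75,000 steps, first
10% discarded, edge frequencies tallied at every retained step without
thinning (implemented as presence intervals, so tallying is O(changes)).
A master seed expands into independent per-(gene, context) streams, so
per-gene results are reproducible regardless of batch composition.

The exhaustive oracle enumerates all mask-respecting DAGs (recursion over
per-child parent sets with incremental cycle pruning), refuses more than
6 maskable nodes or oversized product spaces, and marginalizes edges
exactly with log-sum-exp. Sampler and oracle share the same scorer object,
so agreement tests compare only the sampling, never the score.

## Consensus and relations

Per unordered pair the consensus keeps the most frequent of
{i→j, j→i, independent}, with f_ind = 1 − f_ij − f_ji; any tie at the top
(within 1e−9) resolves to independence. Because pairs are decided
marginally the result can contain a cycle; the lowest-frequency edge of
each cycle is dropped (with a warning) until the digraph is acyclic.
Mark-vs-mRNA relations use directed-path reachability; gene-vs-phenotype
calls use the direct e→p edge for "upstream" and path reachability for
"downstream" — the only reading under which the three labels partition
genes, and deliberately asymmetric. Cross-phenotype consensus keeps a
(source, reference) pair when one identical label appears in at least
`min_support` (default 3) of the phenotype-specific networks; a pair can
never emit two labels because only the modal label is considered.

## Mapping

Cis-windows are symmetric about the feature anchor (TSS for genes, peak
center for marks), 1-based inclusive, truncated at position 1: 50 kb for
eQTLs and haQTLs, 5 kb for mQTLs, 1 Mb for expression-associated marks.
Feature-level significance is the min-p permutation test: only the
feature vector is permuted (preserving LD among candidates), empirical
p = (1 + #{permutation best ≥ observed best})/(n_perm + 1), n_perm = 1,000
by default. Across features, BH step-up q-values at FDR 0.05;
expression-associated marks must pass FDR 0.05 at both the peak level
(BH over all gene–peak pairs) and the gene level (BH over gene-level
permutation p). Missing dosages are mean-imputed per SNP; monomorphic
candidates are dropped; features with zero candidates are reported with
empty results rather than silently removed. Best-SNP selection is
deterministic: smallest nominal p, ties broken by genomic position then
identifier. Storey's π0 is the #{p > λ}/(m(1−λ)) estimate over
λ ∈ {0.05, …, 0.90}, extrapolated with a cubic smoothing spline to the
largest λ and clipped to [0, 1]; π1 = 1 − π0.

## Preprocessing

* Beta→M: M = log2(β/(1−β)), with β clipped into [ε, 1−ε], ε = 1e−6.
* Quantile normalization: per-feature rank-inverse-normal transform with
  offset (r − 0.5)/n and average ranks for ties; constant features map to
  zero with a warning.
* Residualization: ordinary least squares with an always-included
  intercept; rank deficiency is an error naming the collinear covariates.
* Hidden factors: truncated SVD of the feature-standardized matrix,
  factors ordered by explained variance. This is a variance-capturing
  factor model in the role PEER plays on real cohorts; any factorization
  producing factors F and weights w satisfies the downstream contract.
* Sample outliers: d_i = 1 − mean Spearman correlation of sample i with
  all other samples, flagged outside median quartiles ± 1.5 IQR. The
  connectivity-based d_i is this package's concrete choice of outlier
  statistic; the IQR flag rule is the fixed convention.

### Cis-aware composite covariates

The composite covariate of variable j should be exactly the combination of
hidden factors that enters j's structural equation. Estimating the weights
by regressing j on the factors alone also absorbs any factor signal
mediated through j's local regulators (for expression: its marks' factor
loadings scaled by the cascade effect). Conditioning on such a
contaminated composite either leaves part of the confounding channel open
or, worse, fakes the v-structures that orient edges. The default
(`composite_mode="cis_aware"`) therefore regresses each variable on its
layer's factors jointly with its candidate local regulators — the anchor
SNP dosages, plus the SNP-associated marks in the case of the mRNA node —
and uses only the factor coefficients. Candidate *targets* are never
partialled out: conditioning a variable's loading estimate on its putative
downstream nodes reintroduces the same distortion in reverse. The plain
composite (`"model"`) remains available.

## Synthetic data

The generator emulates the study design: biallelic SNP dosages under
Hardy–Weinberg equilibrium with MAF uniform on (0.05, 0.5]; molecular
layers and phenotype generated by linear structural equations over a
user-specified acyclic template; shared hidden factors loading on every
molecular node (N(0,1) loadings scaled by `factor_strength`) to emulate
batch/cell-composition confounding; DNAm emitted both on the latent scale
and as Beta = logistic(latent) to exercise the Beta→M transform. Defaults
are the reference study condition: n = 400 samples, effects 0.7 on every
template edge, noise SD 0.5, template g_m → m1 → e → p plus an unrelated
SNP-anchored H3K9ac peak (so upstream, downstream and independent truths
all exist), two hidden factors at strength 0.3, four phenotype contexts
that share the structural role and differ only in noise (emulating several
related phenotypes measured on one cohort).

Parents enter the structural equations standardized: SNP dosages are
z-scored, continuous parents are rank-inverse-normal standardized. The
second choice makes the cascade linear-Gaussian *exactly on the scale the
network model sees* after its own quantile normalization (the INT of a
monotone transform of x equals the INT of x), so conditional independences
in the generator survive normalization. With plain z-scored parents, the
INT of a strongly SNP-driven (trimodal) mediator would distort the
conditional independence between anchor and outcome and inject spurious
direct edges — an interaction worth knowing about when applying the model
to variables with large-effect discrete causes.

Each gene receives its own phenotype realization per context. A single
shared trait influenced by 50 genes at standardized effect 0.7 each is
arithmetically impossible, so the generator treats genes as independent
cascades measured on common samples (sharing the hidden factors); for a
1-gene, 1-context dataset this reduces to the single phenotype vector.

Coordinates place each gene 3 Mb apart with marks and anchor SNPs inside
the mapping windows (mQTL SNP 1 kb from its site, site ~17 kb from the
TSS, H3K9ac peak ~45 kb upstream), so windowing behaves as on real
annotations.

What the generator does **not** emulate: linkage disequilibrium among
SNPs, realistic genome-wide feature counts, count-type noise (RNA-seq,
ChIP-seq), nonlinear or interaction effects, case–control phenotypes.
Passing tests therefore demonstrate correctness of the machinery and
calibration under the stated generative model, not performance on any
real cohort.

## Enrichment

Gene-model categories: promoter = TSS ± 3 kb (symmetric in genomic
coordinates), downstream = 3 kb past the TED in the transcription
direction, gene body = the non-promoter part of [TSS, TED], intergenic
elsewhere; marks are assigned by their center position, with precedence
promoter > gene body > downstream across overlapping models (the promoter
is the focal category). Category enrichment uses Fisher's exact test
(two-sided by default, one-sided available); gene-set enrichment uses the
upper-tail hypergeometric test with terms intersected with the background
and the dual significance rule q < 0.05 AND overlap > 2. The label
permutation null shuffles relation labels across features (10,000 times by
default) and compares the median per-label statistic, with the
(1 + k)/(n_perm + 1) floor.

## Validation studies and problem sizes

`lrnkit.validation` holds the studies both the test suite and
`scripts/acceptance.py` run: 20 random ≤5-node node sets (n = 300,
75,000-step chains) against exhaustive enumeration with a ±0.05 per-edge
tolerance; one 50-gene, 4-context cohort at the default generator
conditions for edge precision/recall (computed over non-covariate nodes —
the true DAG does not encode factor loadings as edges) and relation-label
agreement; a 500-feature, n = 200, 1,000-permutation mapping cohort for
null calibration (KS uniformity) and empirical FDR on a 10% signal
mixture; and 10,000-p-value mixtures for π1. These sizes were chosen as
the smallest at which the quantities of interest are measured with
adequate Monte-Carlo resolution.

## Known limitations

* Composite covariates require a reasonably sized layer: with only ~10
  features per omics layer, the SVD factor estimates are dominated by the
  features themselves and edge orientations degrade noticeably (the
  validation cohorts use 50 features per layer).
* Networks are single-gene; no information is shared across genes, and
  trans effects are out of scope.
* The consensus is a marginal-per-pair summary; its post-hoc cycle
  breaking is a repair, not part of the probability model.
* The Gaussian likelihood treats the discrete dosage node as continuous;
  with three genotype classes and moderate effects this is benign, but it
  is an approximation.
* The eligibility rule conditions on mapping outcomes (significance at
  FDR 0.05), so gene sets entering network inference are selected, not
  random samples.
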