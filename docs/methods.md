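# Methods

## Protocol model

The package implements a three-stage client–server protocol for assigning
samples held by multiple researchers to population clusters without sharing
genotypes.

**Shared PCA model.** Genotypes are minor-allele dosage matrices
(samples × SNPs, entries 0/1/2, `NA` for missing). The server standardizes
its public panel per SNP (mean 0, population-variance 1; missing entries
mean-filled first) and computes the thin SVD `Z = PΔQᵀ`. The model shipped
to researchers consists of the top-*d* right singular vectors `Q`, the
per-SNP standardization means and scales, and one sensitivity per
component. Shipping the standardization parameters inside the model is
essential: clients must standardize with the *panel's* statistics, not
their own, for their projections to live in the same coordinate system.
Each column of `Q` is sign-fixed so its largest-magnitude entry is
positive; the SVD sign is otherwise arbitrary and the protocol needs
serialized models to be deterministic. A client's factor scores are
`F = Z_std Q`; a missing dosage standardizes to 0, i.e. is imputed at the
panel mean without using any client-side statistic.

Projection is computed row by row rather than as one matrix–matrix
product: blocked GEMM rounds differently depending on the batch size, and
a sample's shared coordinates must not depend on who else was projected in
the same batch (the no-noise aggregation invariant is bit-exact equality
with the pooled projection). The panel's own factor scores inside model
training use the same kernel so the sensitivities match what clients
reproduce.

**Local differential privacy.** The sensitivity of component *j* is
estimated as the range `s_j = max_i F_ij − min_i F_ij` of the panel's
factor scores. With total budget ε split evenly across the *d* released
components, each coordinate of component *j* receives i.i.d.
`Laplace(0, λ_j)` noise with `λ_j = s_j/(ε/d) = s_j·d/ε`. `ε = inf` is an
explicit no-noise sentinel used only for benchmarking; it returns the
scores bit-exactly. Noise is drawn from fresh OS entropy unless an
explicit seed is passed (experiments pass seeds; a deployment must not).
Sample identifiers are pseudonymized with plain SHA-256 (64-char lowercase
hex); an optional salt is supported but off by default — unsalted digests
of guessable identifiers are dictionary-attackable, which deployments
should weigh.

**Server aggregation.** Payloads are row-concatenated in the order given,
tagged by source (the same pseudonym may legitimately appear under two
sources). k-means uses k-means++ initialization, 10 restarts, a 300
iteration cap and tolerance 1e-6 on centroid movement; cluster labels are
canonicalized by decreasing size so reports are stable across runs. The
WCSS curve is the best-of-restarts inertia for each k, with an additional
warm start from the previous k's centroids plus the farthest point — this
makes the curve provably non-increasing in k, which the elbow rule
requires. The elbow normalizes both axes to [0, 1] and picks the k with
maximum perpendicular distance to the chord joining the curve's endpoints,
ties toward smaller k; flat or exactly linear curves fall back to the
smallest scanned k with a warning.

The curve is scanned from k = 1 (up to min(10, n_t − 1)) even though the
protocol never reports fewer than 2 clusters: the chord rule cannot select
an endpoint of the scanned range, so starting at k = 2 would make a
two-population federation undetectable. The selected k is floored at 2.

**Evaluation.** Utility is scored against either the generator's
population labels or a centralized benchmark (PCA + k-means on the pooled
raw data — the partition the protocol tries to approximate). Predicted and
reference partitions are matched one-to-one by the Hungarian algorithm on
the contingency table; accuracy is the matched agreement fraction;
precision and recall are computed per cluster from the matched overlap and
averaged weighted by true cluster size (unmatched reference clusters score
0; an empty matched predicted cluster scores precision 1 only if its
reference cluster is empty too).

## Membership-inference evaluation

**Euclidean-distance attack.** The honest-but-curious server holds a
victim's raw genome and the released payload. It projects the victim
noise-free through the same trained model and computes the minimum
Euclidean distance to the released points. The decision threshold γ is the
⌊fpr·|G|⌋-th smallest minimum distance over a control set G of known
non-members (the minimum itself when that index is 0), so at most a
fraction fpr of controls fall strictly below γ; power is the fraction of
true members strictly below γ. Default |G| = |H| = 100. Both attack sets
are projected without noise — the attacker has raw genomes, only the
defender's release is perturbed.

**LRT baseline.** The risk of releasing GWAS-style summary statistics is
quantified by the log-likelihood ratio over the first *l* released SNPs,
contrasting the dataset's allele frequencies `a_s` with reference
frequencies `pop_s` at the target's genotype `z`. The default treats the
diploid genotype as two Bernoulli alleles, `z·log(a/pop) +
(2−z)·log((1−a)/(1−pop))`; a `verbatim` mode applies the single-term form
`z·log(a/pop) + (1−z)·log((1−a)/(1−pop))` with `z ∈ {0,1,2}` directly,
which weights the second term negatively for homozygous-minor genotypes —
both conventions circulate in the summary-statistics attack literature, so
both are provided and the saner one is the default. Frequencies are
clamped to `[1/(2n+1), 1 − 1/(2n+1)]` before logs. The decision threshold
is the upper fpr-quantile of control statistics; `l = 0` yields power 0
with a warning. In simulations the reference frequencies are the
generator's true population frequencies; with real data the user supplies
them.

## Synthetic cohorts

The Balding–Nichols generator draws, per SNP, an ancestral frequency
`q ~ Uniform(0.05, 0.5)`, population frequencies
`q_k ~ Beta(q(1−F_ST)/F_ST, (1−q)(1−F_ST)/F_ST)` (mean q, variance
`F_ST·q(1−q)`), and dosages `Binomial(2, q_k)`. Defaults — 3 populations,
50 samples each, 2000 SNPs, F_ST = 0.1 — produce clearly separated
clusters in the top two PCs, comparable in difficulty to continental-scale
human structure on a few thousand independent SNPs. One RNG stream per
call, seeded from the config, makes every cohort bit-reproducible. An
optional missing-data rate supports QC testing; no missingness by default.

What the generator does *not* emulate: linkage disequilibrium (SNPs are
independent), realistic site-frequency spectra, admixed individuals, and
hierarchical population relationships (all populations diverge
symmetrically from one ancestral pool). The last point matters for
interpretation: real continental populations separate hierarchically along
the leading PCs, whereas K symmetric Balding–Nichols populations span a
(K−1)-dimensional simplex of which d = 2 components capture only a slice.
Passing tests on these cohorts demonstrates the protocol's mechanics and
calibration, not performance on any particular real panel.

A consequence worth stating explicitly: in the five-population benchmark
design the public panel is sized so that every population — including the
two held by the researchers — keeps roughly equal panel representation
after the researcher draws. A panel in which the researchers' populations
are nearly absent yields top-2 PCs that ignore exactly the axis separating
those populations, and the federation cannot succeed regardless of noise.
This mirrors the protocol's stated requirement that the public panel
represent the populations observed locally.

## Numerical and procedural choices

- Per-SNP QC before training: drop SNPs with MAF < 0.01 or missing rate
  > 5% (computed over non-missing genotypes); the server's post-QC SNP
  list is the ordered set all parties agree on, and clients restrict their
  matrices to it.
- Minor-allele orientation in VCF input is decided per SNP from the file
  itself (ALT frequency ≤ 0.5 keeps ALT counts, otherwise dosage = 2 −
  ALT count; ties count ALT). Multi-allelic records are skipped with a
  warning; SNP identity is the VCF ID, falling back to CHROM:POS.
- Model and payload files round-trip bit-exactly (floats serialized at
  full precision; `epsilon` stored as the string "inf" for the sentinel).
- Experiment replication derives every stage's seed as
  SHA-256(master seed, stage name, indices) mod 2³¹, so adding stages
  never perturbs existing streams and any single number is reproducible
  in isolation.
- Evaluation designs in `fedstrat.designs` use cohort sizes that keep each
  design between a fraction of a second and half a minute on one CPU:
  2000 SNPs for the clustering designs, 800–1000 for the attack designs,
  100 replicates for replicate-averaged quantities.

## Known limitations

The range-based sensitivity makes the noise scale proportional to the full
spread of the panel's factor scores. When the panel spans the same
populations the researchers hold — which the protocol requires for
utility — that spread is at least the between-population separation, so
the per-coordinate noise at budget ε is at least `d/ε` times the
separation. Both quantities grow as √(#SNPs), so the ratio is invariant to
panel size. At practical budgets (ε ≤ 5, d = 2) the Laplace noise
therefore dominates the cluster structure: elbow selection drifts upward
(k = 4 is the modal choice on three-population federations across
ε ∈ {1, 3, 5}) and per-sample cluster assignment degrades well below
noise-free accuracy. The privacy side of the evaluation is unaffected —
attack power is computed against the same noisy release, rises smoothly
with ε, is roughly halved when both researchers hold the same two
populations, and reaches 1 at ε = ∞ — but users should treat the utility
of finite-ε releases under this calibration with caution. The range
estimator is also not a worst-case sensitivity: it bounds the projection
change only for genotypes inside the panel's convex hull along each
component, so the ε-LDP guarantee is heuristic for out-of-panel
individuals.
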