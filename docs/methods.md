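# Methods notes

This note documents the models behind each module, the defaults that
matter, the synthetic-data assumptions, and the numerical choices made
where the design was genuinely open.

## Genotype model and synthetic panels

Microsatellite genotypes are diploid allele-size pairs; missing copies are
unified internally to the sentinel `0` regardless of the source dialect
(Genepop `000`, STRUCTURE `-9`).

The generator uses a two-level Dirichlet drift model. Each locus carries
4–12 alleles with broken-stick ancestral frequencies. A species' frequency
vector is drawn from Dirichlet(p_ancestral · (1−F)/F) — the
Balding–Nichols parameterisation, where a single drift parameter F
controls the expected differentiation. Populations drift from their
species the same way with a much smaller F.

- `DEFAULT_DIVERGENCE_F = 0.25`, frozen from a Monte-Carlo calibration
  (`scripts/calibrate_divergence.py`): over 20 seeds, two 30-sample
  species panels at the default 12 loci give a mean Weir–Cockerham θ of
  0.249 (sd 0.034), i.e. two species differentiated at the strong end of
  the microsatellite range.
- `DEFAULT_WITHIN_SPECIES_F = 0.015` keeps within-species θ in the low
  single digits of percent.

The default study design has 14 populations and 237 individuals: three
allopatric *I. elegans* populations (52 individuals) and two allopatric
*I. graellsii* populations (29) that carry the reference flag, two
parapatric populations (24) and seven sympatric introgressed populations
(132). Introgressed populations are mixtures of pedigree classes; the
default sympatric recipe (45% 1EB, 25% F1, 15% 2EB, 8% 1GB, 4% 3EB,
3% pure) has an expected elegans ancestry of ≈0.68, which places the modal
posterior admixture bin of sympatric individuals in the intermediate
74–56% band — the regime in which hybrid classification is actually
interesting. Hybrid individuals are generated by per-copy lineage coin
flips: with unlinked loci, a gamete from class C carries elegans lineage
at each locus independently with probability equal to C's expected
ancestry, which is exact for the pedigree recursion used.

What the generator does **not** emulate: mutation (no stepwise model),
linkage, null alleles and allele dropout, selection, and spatially
explicit gene flow. Tests passing on this fixture therefore demonstrate
correct inference under idealized HWE/linkage-equilibrium pedigree
mixtures, not robustness to those artefacts.

## Differentiation statistics

Weir–Cockerham θ sums the a (among-population), b (among-individual) and c
(within-individual) variance components over alleles and loci and reports
Σa / Σ(a+b+c). Negative estimates are reported as computed, matching the
estimator's convention; loci monomorphic or undersampled (any population
with <2 typed individuals) contribute zeros. Jost's D uses the
Nei–Chesser-corrected Hs and Ht with harmonic-mean sample sizes
(Ht_est = Ht + Hs_est/(2·ñ·r)) and averages D over loci. Note the
corrected estimator assumes independent population samples: feeding it two
copies of the *same* sample biases D slightly negative, which is visible
in tests as a small negative value rather than exactly 0.

Confidence intervals are percentile bootstrap (2.5/97.5) over loci,
1,000 replicates by default. Percentile rather than bias-corrected was
chosen because the locus-resampling distribution is already centred on the
point estimate for ratio estimators of this form and keeps the CI
monotone in the locus set.

## Linkage disequilibrium exact tests

For one locus pair in one population the statistic is the G
log-likelihood-ratio of the single-locus-genotype × single-locus-genotype
contingency table. The null is explored by the Diaconis–Sturmfels swap
chain over tables with fixed margins, Metropolis-weighted by the
hypergeometric 1/Π x_ij!; since margins are fixed, Σ x log x is tracked
incrementally as the G-equivalent statistic. p is the post-dememorization
fraction of visited tables at least as extreme, with batch-mean standard
errors. Defaults follow the conventional settings (dememorization 1,000;
100 batches of 1,000 iterations); the inner loop is numba-compiled, so a
66-pair region scan over several populations runs in seconds. Chains much
shorter than ~10⁴ samples bias p low near the observed table; the
calibration suite pins the type-I rate at α = 0.05 within [0.02, 0.08].

Regions combine per-population p-values by Fisher's method rather than
pooling genotypes, because pooling would confound between-population
structure with within-population LD. Raw α = 0.05 counts are reported
with a Bonferroni column alongside.

## Supervised admixture

The model is the standard two-cluster admixture mixture. Per sweep:

1. each allele copy's cluster origin z ~ Categorical(q_i,k · p_k,l,a);
2. q_i ~ Dirichlet(α + per-cluster copy counts) for query individuals;
   reference-flagged individuals are pinned at q = 1 for their species'
   cluster and contribute fixed counts to that cluster's frequencies;
3. p_k,l ~ Dirichlet(prior + counts), with prior λ = 1 (independent
   model) or p_ancestral·(1−F_k)/F_k (correlated F-model, the default);
   ancestral frequencies are fixed at pooled empirical counts;
4. α by Metropolis random walk (uniform prior on (0, 10)); each F_k by
   Metropolis with a Gamma prior of mean 0.01 and sd 0.05.

Cluster 1 is anchored to the reference species with the alphabetically
first label, so Q1 is elegans membership without any post-hoc label
alignment; with references pinned, label switching cannot occur. Credible
intervals are posterior quantiles of the sampled q (90% mass by default).
Convergence is summarised by a Geweke-style z on the log-likelihood trace
(plain-variance version; adequate for the trace lengths used). The model
evidence used by the ΔK criterion is mean(L) − var(L)/2.

Desk defaults are 5,000 burn-in + 20,000 sweeps (tens of seconds at the
fixture's size); the field-standard 50,000 + 100,000 is a config change.
Estimated Q1 for deep backcrosses sits ~0.02–0.04 above/below the
pedigree expectation toward the nearer pure cluster, and F1 estimates
shrink toward the data-dominant side when the query panel is heavily
unbalanced — the pedigree-recovery guarantee (±0.08) is stated for the
balanced seven-class panel.

## Hybrid classification

Admixture proportions are binned after rounding to integer percent
(floor(100q + 0.5)), which makes the printed bins ≥75 / 74–56 / 55–50 /
49–26 / ≤25 tile 0–100 exactly. Class ranges from the simulated panel use
2.5/97.5% quantiles rather than raw extremes (extremes grow with class n);
classes under 5 individuals are flagged. Two group presets exist: the
verbal rule (≥75% elegans backcrosses, 50–55% central F1/first-backcross
band, ≤25% graellsii backcrosses, with unassigned gaps between) and a
quantile preset keying three contiguous bands to the F1 class's quantile
range. Multi-class ambiguity is resolved by the highest Gaussian-KDE
density of the class's simulated Q1 at the individual's value; values
outside all ranges are labelled `unassigned`, never raised.

## Maximum-entropy niche model

Features are the background-standardized linear and quadratic terms of
each variable ("auto features" reduced to the closed-form subset that
keeps the problem convex at three variables; hinge/product features are
out of scope). The raw distribution is q(x) ∝ exp(λ·f(x)) over a uniform
background sample (default 10,000 cells, or all cells on smaller
landscapes). λ minimizes the negative mean presence log-likelihood plus
the L1 penalty β·Σ_j s_j|λ_j| with s_j = presence-sd of feature j divided
by √m (m = deduplicated presence cells) — the √m scaling mirrors standard
maxent practice and keeps β values of 1–3 meaningful: an unscaled
presence-sd penalty at β = 1 zeroes every weight on standardized features.
The convex objective is solved by L-BFGS-B on the positive/negative weight
split (tolerance 10⁻⁵, 500 iterations max; non-convergence flags the
model). Presences are deduplicated per cell. The logistic display output
is τ·e^H·q / (1 − τ + τ·e^H·q) with entropy H of q and prevalence τ.

AUC is the rank-based (Mann–Whitney) presence-vs-background probability,
ties counting ½. Because the raw model is selected by rank AUC and τ is a
monotone output rescale, the (τ, β) grid effectively selects over β; the
grid report records this, and ties resolve to smaller β then smaller τ.
This is a documented limitation: a threshold-based metric would be needed
for τ to matter.

## Overlap statistics and randomization tests

D and I are computed on raw (not logistic) surfaces renormalized over the
compared cell set — they are defined on probability surfaces, and the
logistic transform is a monotone display map that would distort both. The
identity test pools the two occurrence sets and repartitions them into the
original sizes, refitting both models per pseudoreplicate (100 by
default); p = (1 + #{null ≤ observed})/(n + 1), one-tailed low, α = 0.01.
The background similarity test redraws the second group's points uniformly
from its background region — by default the occurrences' bounding box
expanded by 10% per side, since real background extents are a user choice
— and is two-tailed at α = 0.05: observed overlap below the α/2 null
quantile is divergence, above 1 − α/2 conservatism. Both directions
(swap x and y) are computed by calling the test twice. All fits within a
test share one background sample, so null variation reflects occurrence
resampling only.

The synthetic occurrence scenarios (`identical`, `displaced` with optima
4 climatic SD apart, `background_driven` with identical responses in
disjoint regions) reproduce the three qualitative regimes the tests must
distinguish, and the calibration suite checks the identity test's type-I
rate against its binomial band.

## Problem sizes and determinism

Defaults were chosen so a full pipeline run (admixture at desk MCMC
settings, 1,000 bootstrap replicates, full LD chains, 100 niche
pseudoreplicates) completes in minutes on one CPU, and the test suite in
about two. Every stochastic component takes an explicit seed; the
pipeline derives per-stage seeds from one global seed and records them in
the run manifest, making reruns byte-identical and any stage reproducible
in isolation.

## Known limitations

- The admixture model implements the pinned-reference simplification of
  supervised clustering (no migration-prior leak terms) and omits
  LOCPRIOR/linkage models.
- The F-model's ancestral frequencies are fixed at pooled counts rather
  than sampled.
- Maxent-lite's feature set is linear+quadratic only; responses more
  complex than bell-shaped curves are out of reach by design.
- Jost's D and θ assume independent population samples; duplicated
  samples show the small negative bias noted above.
- Coordinates are treated as planar in raster units for niche analyses
  and as lon/lat only for the Mantel great-circle distances.
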