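# Methods

`aimkit` re-implements, as a tested pipeline on synthetic data, the
computational core of a honey-bee population-genomics analysis: identity-by-
descent (IBD) kinship between haploid drones, genotype quality control and
LD pruning, PCA-based genetic–geographic correlation analysis, random-forest
selection of a 96-SNP ancestry-informative-marker (AIM) panel with an
empirical random-panel null, and a backcross hybrid simulator used to
stress-test that panel.  This note documents the models, the defaults and
the design choices, and states what the synthetic data do and do not show.

## Genotype model and QC

Genotypes are stored as a samples × variants matrix of alternate-allele
counts with per-sample ploidy (1 for drones, 2 for simulated hybrids) and a
`MISSING` sentinel.  Drones are haploid, so a diploid-style heterozygous
call in a drone is a genotyping artifact: at read time it increments a
per-variant het counter and is stored as missing.  Site QC removes variants
with het fraction > 1%, missingness > 5% or ≥ 4 observed alleles; sample QC
drops samples with call rate < 90%.  Upstream variant-caller annotation
filters (SOR, FS, MQ, QUAL, QD) are applied only when the corresponding
fields are present, and skipped with a notice otherwise.

LD pruning follows the PLINK `indep-pairwise` scheme: minor-allele-frequency
filter first (MAF ≥ 1%), then windows of `window_n` SNPs per chromosome
(default 1749) advancing by ⌈window_n·(1−overlap)⌉ with 10% overlap; within
a window, each pair of dosage-fraction columns with squared Pearson
correlation above the threshold (0.30; 0.13 for AIM candidates) loses its
lower-MAF member, with ties resolved against the later variant.  Which
member PLINK drops is not specified by the upstream description, so the
lower-MAF rule is pinned here and checked against an O(n²) within-window
oracle in the tests.  Window size stays SNP-count-based on synthetic data
(the genomic-span interpretation only matters at real SNP densities).

## The IBD HMM

Kinship between two haploid genomes is estimated with a two-state hidden
Markov model (states IBD / DBD, i.e. identical or distinct by descent),
following the structure of the haploid IBD-segment HMM originally developed
for malaria parasites and re-parameterised for *Apis mellifera*: 16
chromosomes, recombination rate ρ = 9.04 × 10⁻⁷ per bp per generation.
With stationary IBD fraction f and generation parameter k, the transition
probability across an inter-site gap of d bp is

    a_ij(d) = δ_ij·e^(−kρd) + (1 − e^(−kρd))·π_j,   π = (f, 1−f).

Emissions use a genotype error rate ε (default 0.001): with population alt
frequency p and e(a|t) = 1−ε if a = t else ε, the DBD state emits
m(a₁)·m(a₂) with m(a) = Σ_t p_t e(a|t), and the IBD state emits
Σ_t p_t e(a₁|t) e(a₂|t).  Sites missing in either sample are skipped but
their gap still accrues; chromosomes are independent (the chain restarts
from π at each chromosome start, since whether the original tool
concatenates chromosomes is not documented).

f and k are fitted by Baum–Welch EM (default 5 iterations, tolerance 10⁻³):
f is updated to the mean posterior IBD occupancy, and k to the expected
state-switch count divided by ρ times the total inter-site gap length.  The
exact k update of the original tool may differ in constants; the quantity
validated here is f recovery, not k.  The reported kinship statistic,
`f_viterbi`, is the fraction of informative sites assigned to IBD on the
Viterbi path (the "fraction of sites IBD" convention); the posterior mean
is reported alongside.  Numerics use a scaled forward–backward recursion
(per-site normalization); the contract, enforced by test, is relative
log-likelihood error < 10⁻⁹ against exhaustive path enumeration on ≤ 12-site
toys.

Accuracy depends on marker density relative to IBD tract length.  Sibling
drones (gametes of one queen) switch IBD status at rate 2ρ, giving ~550 kb
tracts; at the 20 k-site panels used for validation (~11 kb spacing) the
mean `f_viterbi` recovers 50/25/12.5% within a fraction of a percentage
point, while panels sparser than roughly one SNP per 50 kb visibly
underestimate short-tract sharing.  Pairs with fewer than 50 informative
sites are flagged low-confidence.

Families are connected components of the kinship graph thresholded at 0.30;
one sample per family is retained (best call rate, ties by id).  Close-kin
reporting lists pairs above a 0.10 cutoff with great-circle distances.

## Synthetic populations

The generator produces the statistical structure the analyses assume, not a
demographic reconstruction.  Allele frequencies follow the Balding–Nichols
model: ancestral frequencies p ~ Uniform(0.05, 0.95); each lineage (ALG, M,
C) draws Beta(p(1−F)/F, (1−p)(1−F)/F) with F = 0.12, and two Algerian
sub-populations (ALG_W, ALG_E) drift from ALG with F = 0.02.  Under this
hierarchy the pairwise Hudson Fst between two lineages converges to F
itself (numerator E[(p₁−p₂)²] = 2Fp(1−p) against denominator 2p(1−p)),
which the tests verify within ±20%.  F = 0.12 per lineage was chosen once
so that a PCA of the pooled sample reproduces clearly separated lineage
clusters with PC1 splitting ALG from Europe — the qualitative structure the
downstream analyses require; it is deliberately a strong-differentiation
regime.

Each ALG sample carries an eastern-ancestry weight that is logistic in its
longitude (slope 2 per degree by default, midpoint at the centre of the
sampling range), and draws genotypes from the mixture frequency
w·p_E + (1−w)·p_W, producing the within-Algeria West–East cline.  Altitude
is anti-correlated with latitude (target r = −0.6).  Default sample sizes
mirror the study layout: 82/50/118 ALG/M/C training and 20/13/30 test
samples.  The genome is 16 chromosomes of 14 Mb each; missingness and
haploid het artifacts are injected at configurable rates.

Ground-truth relatives come in two modes.  Pedigree mode simulates a
diploid queen and returns meiosis gametes (Poisson crossovers at ρ, no
interference), so sibling drones share 50% in expectation.  Tract mode
copies exponential-length tracts (mean 2 Mb, chosen so the HMM sees
multi-segment sharing at the default genome size) between two independent
genomes until exactly the target fraction 2^−degree of the genome is
covered, trimming the final tract, and returns the exact site mask.

What the generator does **not** emulate: linkage disequilibrium within
populations (sites are independent given frequencies), mutation, selection,
realistic bee mating biology (polyandry, csd), genotyping error beyond the
symmetric artifact/missingness model, and realistic chromosome-length
variation (real assembly lengths can be supplied).  Passing tests therefore
demonstrate correctness of the algorithms under their own assumptions and
calibrated recovery of planted signal — not performance on real data, where
differentiation, LD and error structure differ.

## Structure and geography

PCA uses the standard population-genetics normalization (column centring by
mean dosage, scaling by √(p̄(1−p̄)), mean-imputation of missing calls — the
data are silent on imputation so the common smartpca-like behaviour is
used) followed by SVD; eigenvalues are validated against a dense
eigendecomposition.  Genetic distance between samples is the Euclidean
distance on the top two PCs with the PC1 coordinate difference weighted by
λ₁/λ₂.  The verbal definition admits weighting the squared term instead;
the coordinate-difference placement is the default and the alternative is
exposed as `weight_on="squared"`.  Geographic distance is the haversine
great-circle distance on a 6371-km sphere.  Correlation tables report
Pearson r with two-sided p from the t transform (n−2 df) and 5/1/0.1%
significance stars; pairwise-distance correlations use naive Pearson p over
all pairs, deliberately ignoring pair non-independence to match the
original analysis convention.  The two-cluster W/E assignment is k-means on
PC1 (50 seeded restarts) with the lower-mean-longitude cluster labelled W —
a PC-based proxy for a model-based admixture clustering, justified by the
observation that the two-way clustering is captured by PC1.

## AIM panel selection

Candidates are sites with no missing genotype in any sample (both splits,
so panels are scorable on test data) pruned at r² ≤ 0.13.  Ranking trains
`RandomForestClassifier` (scikit-learn defaults, 100 trees, explicit seeds)
100 times per split criterion (Gini / entropy) and per lineage setting
(ALG vs M on the 82+50 samples, ALG vs C on the 82+118), recording impurity
importances.  Two ranking methods share those fits: frequency of appearance
in each run's top-96 importance list (ties by mean importance, then index),
or mean importance (ties by index) — crossed with the two criteria this
gives configurations GI1, GI2, EN1, EN2.  Each panel is the union of the
top 48 SNPs per setting; when the lists overlap, both rankings advance
alternately (M first) past rank 48 until 96 unique SNPs are collected (the
fill rule is unstated upstream and pinned here).  Panels are compared by
PCA of the panel-restricted test samples: mean plain-Euclidean pair
distance on the top two PCs within ALG versus between ALG and M∪C, and the
panel maximizing the between/within ratio wins (the original choice was
made by visual inspection; the ratio formalizes it, with ties broken in
configuration order).  The winner is benchmarked against panels of 96
randomly drawn candidates, each scored by repeated classification
(accuracy, min P(ALG) over ALG test samples, max P(ALG) over non-ALG); the
test suite uses a reduced null (50 panels × 5 runs) and requires the
selected panel to sit at or above the 95th percentile of the null on each
parameter — with only five runs per null panel the per-panel summaries are
noisy, so demanding strict dominance over every panel would test the noise,
not the panel.

## Hybrid simulation and experiments

Haploid drones serve directly as gametes: an F1 is one European plus one
Algerian haplotype; BC(n+1) combines a meiosis gamete of a BC(n) (or F1)
with a fresh Algerian haplotype, so expected European ancestry is 2^−(n+1).
Parent pairs are drawn without replacement from all unique combinations,
40 matings per cross type × 2 lineages × 2 splits = 640 hybrids, with
train-split hybrids descending only from training samples.  Classifier
features are dosage fractions (haploid {0,1}, diploid {0,½,1}) so originals
and hybrids share one encoding; no genotyping error is added to hybrids.
Experiment A trains on originals only and reports per-generation P(ALG)
distributions for test hybrids; experiment B adds the 320 train-split
hybrids labelled non-Algerian; experiment C repeats B with all candidate
SNPs instead of the panel.

## Pipeline, seeds and problem sizes

The pipeline (simulate → QC → prune → kinship/family filter → structure →
AIM selection → null → hybrids) fans a single master seed into per-stage
seeds via `(master·1009 + stage_offset) mod 2³¹` and writes a manifest of
per-output SHA-256 checksums; a re-run with the same configuration
reproduces the manifest byte-identically, and `resume` skips stages whose
outputs still match their checksums.

Problem sizes are scaled to desk use: validation suites use 5 000-SNP
panels for the selection pipeline (yielding ≈ 4 900 candidates), 20 000
sites for IBD recovery (40 pairs per relationship degree), and a reduced
random-panel null; the demo pipeline configuration is smaller still.  These
sizes were chosen as the smallest at which the measured quantities are
stable (marker density above the IBD-sparsity threshold noted earlier, and
panel selection saturated at 100% held-out accuracy).

## Known limitations

- The HMM's k estimates are reported but not calibrated; only f is.
- `f_viterbi` is biased downward when marker spacing approaches the IBD
  tract length (quantified above).
- The random-forest probability for intermediate (hybrid) dosage profiles
  depends on split-threshold placement between the binary parental feature
  values; absolute P(ALG) levels for hybrids are therefore
  encoding-dependent even though the generational ordering is robust.
- Two-cluster assignment assumes the leading PC captures the cline; it will
  mislabel structure where PC1 reflects something else (e.g. families).
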