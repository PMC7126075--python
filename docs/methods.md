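# Methods

## Model

Muscle essential-amino-acid (AA_ESS) carbon is treated as a two-source
mixture. For each amino acid *a*, diet treatment *t*, and mouse *i*:

δ_muscle = (1 − p)·δ_diet(t, a) + p·δ_microbe(t, a) + ε,  ε ~ N(0, σ²)

with p the fraction of that amino acid's carbon supplied by microbial de
novo synthesis from dietary carbohydrate and (1 − p) the fraction routed
intact from dietary protein. The estimator is the inverse,
p̂ = (δ_muscle − δ_diet)/(δ_microbe − δ_diet). The model assumes muscle is
at isotopic steady state with the diet, that exactly two carbon pathways
contribute (lipid carbon is ignored, consistent with a low-fat
semi-purified diet), and that pathway end members are homogeneous within a
treatment.

### End members

*Dietary routing.* δ_diet(t, a) is the concentration-weighted δ¹³C of
amino acid *a* in the diet's protein: casein and corn protein are mixed in
proportion to (protein mass per g diet) × (g of *a* per g protein). On
high-protein diets this is essentially casein (−26.5‰); on the 9%-protein
diet ~43% of dietary protein comes from cornmeal, pulling δ_diet toward
the C₄ value and shrinking the end-member separation from ~14.2‰ to
7–11‰ depending on the amino acid. Routing is assumed isotopically
neutral (trophic discrimination 0‰); a per-amino-acid routing offset is
exposed in `dietary_aa_delta` for sensitivity analysis.

*Microbial synthesis.* δ_microbe(t, a) is the mass-weighted δ¹³C of the
dietary carbohydrate pool (sucrose at −12.2‰ plus the non-protein mass of
cornmeal at −12.0‰, ≈ −12.1‰ in every diet) plus a per-compound
fractionation offset Δ(a) for bacterial biosynthesis. The shipped offsets
default to 0‰ — explicitly a placeholder meaning "end member = substrate
pool" — because culture-derived offsets are study-specific; they are a
required config input for real analyses.

### Estimation policy

Raw p̂ can fall outside [0,1] under measurement noise; values are clipped
to [0,1] for reporting and preserved raw for diagnostics, with the number
clipped in each direction recorded. Treatment summaries are mean ± SE
(sample SD/√n) over mice, computed after clipping by default
(`clip_order="average_then_clip"` switches the order; at the study's
noise level the two differ only when truth is near a boundary). With one
mouse the SE is reported as NaN, never 0. Estimation is refused when
|δ_microbe − δ_diet| < 1‰ (≈2× a typical compound-specific measurement
SD): below that separation the fraction is effectively unidentifiable and
silently returning a quotient would be misleading.

### Derivatization correction

Reagent carbon is removed by a two-pool mass balance, calibrated per
amino acid from standards of known δ¹³C run through the same chemistry
(the calibrated "added-carbon δ" absorbs any reaction fractionation).
Calibration and correction are exact inverses; the correction is linear
in the measured value with slope (n_AA+n_add)/n_AA, which also amplifies
measurement noise by that factor. Added-carbon counts depend on the
derivative chosen and are config-exposed per amino acid; the defaults are
labelled placeholders. All algebra is done on the ‰ scale; the error of
the linear-in-δ approximation is ≪0.01‰ at natural abundance.

## Supply and demand

Net supply of each amino acid, as % of dry food, is
protein fraction × concentration in protein × ileal digestibility ×
(1 − mucosal catabolism) × 100. Mucosal-catabolism defaults are the
first-pass splanchnic fractions measured in non-ruminant mammals on
casein diets: Ile 0.30, Leu 0.40, Val 0.40, Phe 0.45, Lys 0.50, Thr 0.60
(threonine is heavily consumed for mucin synthesis); Asp is assigned 0.90
to reflect near-complete first-pass extraction of dietary aspartate.
Digestibility (0.91 uniform) and demand tables (requirements for rapidly
growing mice, % of dry food) are literature-typical placeholders —
the module validates completeness of user tables rather than asserting
study values. Supply:demand ratios are classified deficit/balanced/surplus
with a balanced band of [0.9, 1.1]. The experiment ration is simply
daily ration × days (defaults 3 g/day × 120 days).

## Community statistics

Counts are total-sum-scaled to proportions before Bray–Curtis
(d = Σ|x−y|/Σ(x+y)); rarefaction is not implemented. ANOSIM uses Clarke's
statistic R = (r̄_between − r̄_within)/(n(n−1)/4) on midranks of all
pairwise dissimilarities, tested by label permutation with
p = (1 + #{R* ≥ R})/(1 + n_perm). PCoA is Gower double-centering plus
eigendecomposition; negative eigenvalues are reported and their axes
dropped by default, with a Lingoes additive correction available. The
db-RDA regresses the per-sample amino-acid δ¹³C matrix (response, the
default direction; config-switchable) on the smallest set of leading PCoA
axes explaining ≥80% of positive-eigenvalue variance, capped at n−2;
significance is a pseudo-F permutation test on rows of the response, and
an AIC in the Gaussian least-squares form is reported for comparability
but never used for selection. Spearman correlations use midranks with a
two-sided permutation test. Permutation counts default to 1000 for
analysis runs; calibration simulations in the tests and acceptance script
use 199 permutations per dataset so that hundreds of null datasets fit in
a routine run (at α = 0.05 and 199 permutations the null rejection
probability is exactly 10/200 = 0.05, so the calibration check is
unaffected).

## Synthetic data

The generator defines the study conditions all tests run under: four
diets (40P:40C, 21P:45C, 12P:55C, 9P:75C; sucrose fixed at 36% of diet
mass, cornmeal 10% protein by weight, casein −26.5‰ / sucrose −12.2‰ /
cornmeal −12.0‰), six mice per treatment for isotopes and five for ceca,
Gaussian measurement noise with SD 0.5‰ (typical compound-specific
precision; the emulated study does not print per-amino-acid SDs).
Ground-truth microbial fractions default to the published estimates the
pipeline is meant to recover: Val 0.60 and Ile 0.40 on the low-protein
diet, Phe 0.04 there, Thr/Lys 0.03–0.04 on the high-protein diets rising
several-fold by 12% protein. Communities are Dirichlet-multinomial:
expected phylum mixtures per treatment (Firmicutes 0.825 and 0.662 on the
two low-protein diets, ~0.46–0.50 on the high-protein ones, minor phyla
making up the remainder), split within phylum over OTUs by a geometric
rank-abundance series (ratio 0.8; Firmicutes get 6× more OTUs than
Bacteroidetes), then per-sample Dirichlet(α = 80 × expected) proportions
and a multinomial at depth 20 000. Isotope and OTU artifacts draw from
independent seeded streams derived from the design seed, so each is
reproducible in isolation.

What the generator does **not** emulate: amplicon/primer bias, chimeras,
variable sequencing depth, overdispersion beyond the single Dirichlet
concentration, inter-individual variation in the true mixing fraction,
non-Gaussian isotope error, or any real coupling between a sample's
community and its isotope values beyond the shared treatment effect.
Passing tests therefore demonstrate the estimators' correctness and
calibration under the stated model, not robustness to those real-data
features.

## Numerical and design choices

- Mass-fraction sums are validated to 1 ± 10⁻⁶; degenerate inputs
  (protein-free or carbohydrate-free diets, all-zero samples, <2 groups,
  constant vectors, n ≤ m+1 regressions) raise with named subjects rather
  than propagating NaN.
- The eigendecomposition symmetrizes its input and treats eigenvalues
  below max(|λ|)·10⁻¹² as zero; PCoA reconstruction of Euclidean
  matrices is accurate to <10⁻⁸.
- Permutation p-values use the add-one estimator, so p = 0 is impossible
  and the smallest attainable p is 1/(1+n_perm).
- Rank-deficient predictor matrices in the RDA are truncated to their
  rank with the retained axis count reported.
- The pipeline stamps every output table with a SHA-256 hash of the
  scientific config (output directory excluded, so relocated reruns are
  byte-identical); stages whose inputs are absent are skipped with a
  logged notice.

## Problem sizes

Monte-Carlo checks use 500 replicate experiments for mixing-model
recovery (bias ≤ 0.01 at truth 0.4), 500 (tests) / 300 (acceptance
script) null datasets at 199 permutations for type-I calibration, and
60 runs for db-RDA power. At n = 6 mice the exact coverage of the
mean ± 1 SE interval under Gaussian noise is P(|t₅| ≤ 1) ≈ 0.637 rather
than the asymptotic 0.683; the coverage check tests against the exact
value.

## Known limitations

- With zero default fractionation offsets the microbial end member is the
  carbohydrate pool itself; real offsets of a few ‰ would shift estimated
  fractions by roughly Δ/separation (~7–25% relative), so study-specific
  offsets matter more on the low-protein diet where separation is small.
- Clipping before averaging biases treatment means upward when the true
  fraction is near 0 (visible for Phe/Thr/Lys at high protein); the raw
  fractions are retained precisely so this can be audited.
- The db-RDA treats PCoA axes as fixed predictors; uncertainty from the
  ordination itself is not propagated.
- No hierarchical model: mice are independent, treatments unpooled,
  matching the design it reproduces.
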