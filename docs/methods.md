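# Methods

This note documents the models behind `gnis`, the defaults and why they were
chosen, the numerical conventions, and what the synthetic-data checks do and
do not demonstrate about real data.

## 1. Data model

A dataset is a dosage matrix (individuals × biallelic loci, values 0/1/2
copies of the alternate allele, −1 for a missing call) with aligned metadata:
per locus a contig ID, a position within the contig and an optional
reproducibility score from technical replicates; per individual a sex and
planar capture coordinates in metres. Coordinates must be pre-projected: the
package performs no geodesy, and all distances are Euclidean. Genotypes are
stored as dosage because it makes every estimator closed-form (He, MAF and
IR are functions of column sums).

## 2. Synthetic populations

The generator emulates a continuous, fully sampled population with three
controllable properties: mean expected heterozygosity, a population-level
heterozygote deficit, and fine-scale isolation by distance (IBD).

**Allele frequencies.** Global per-locus frequencies are drawn from a
symmetric Beta(a, a). For p ~ Beta(a, a), E[2p(1−p)] = 0.5 − 1/(2(2a+1)),
which is inverted exactly for the target He (default 0.28 → a ≈ 0.64, a
U-shaped spectrum with many rare variants). Only the mean heterozygosity is
calibrated; the full shape of the real spectrum is unknown, which matters
for one check (§7).

**Spatial structure.** Each locus receives an independent perturbation field
on the logit scale: a weighted sum of 30 Gaussian radial kernels with random
centres, bandwidth `ibd_range` (metres), standardised across the sampled
individuals to mean 0 and sd `ibd_sigma`. Local allele frequency at a
location is logistic(logit(p) + field). The mechanism is a cheap stand-in
for a Gaussian-process draw — O(n · kernels) per locus — and only the
induced distance-decaying genotype correlation is contractual.
`ibd_sigma = 0` (or `ibd_range = 0`) disables structure entirely and is the
null condition used in calibration tests.

**Amplitude default.** Spatially varying local frequencies inflate the
population-level F_IS by a Wahlund term ≈ p(1−p)·σ² per locus (≈ 0.013 at
the default He). The default `ibd_sigma = 0.3` keeps this term comfortably
inside the ±0.03 recovery contract for F_IS while remaining easily
detectable by the autocorrelation machinery at thousands of loci. Stronger
structure (σ ≈ 0.8–1.0) is used in tests that need saturating detection
power; those populations intentionally have F_IS above the generator target.

**Genotypes.** Given local frequency p and inbreeding F (default 0.125),
genotypes are drawn from P(hom ref) = Fq + (1−F)q², P(het) = (1−F)2pq,
P(hom alt) = Fp + (1−F)p². F is a single population-wide constant: the
generator does not produce the among-individual inbreeding variance seen in
real populations (see §8).

**Bookkeeping.** Loci are spread over contigs (every contig gets one locus,
the surplus is assigned at random) with unique ordered positions, so the
secondary-SNP filter has real work to do; reproducibility scores are
Uniform(0.95, 1) with a 5% tail drawn below threshold. Everything is
deterministic given the spec seed.

## 3. Quality control

Four locus filters, applied in the order reproducibility → call rate → MAF →
secondary-SNP removal: reproducibility ≥ 0.95 (inclusive; loci without a
score pass with a warning), call rate > 0.70 and MAF > 0.01 (both strict,
following the convention of the QC they reproduce), then one locus per
contig (smallest position, ties by locus ID). MAF and call rate are always
computed on the observed genotypes of the dataset as it stands, so the same
pipeline re-run on a degraded dataset responds to the degradation — this is
what produces locus loss (and a small composition bias, §7) in simulated
gNIS data. Filters never remove individuals and never edit genotype calls;
the pipeline is idempotent.

## 4. gNIS degradation

**Fixed panel.** The reduced panel (default 1300 loci) is drawn uniformly
*once per experiment* from the complete **filtered** dataset and reused for
every replicate; re-drawing panels would add between-replicate variance from
panel informativeness, which the study design deliberately excludes.

**Spatial thinning.** To mimic spatially explicit field sampling, n_keep
random points are drawn inside the convex hull of capture coordinates
(rejection sampling; a jittered-grid "regular" mode is available) and each
point claims its nearest not-yet-selected individual. Retained individuals
therefore track the areal distribution of locations rather than local
abundance. With a degenerate hull (collinear coordinates) the function falls
back to uniform random subsampling with a warning.

**Call-rate calibration.** Expected per-locus call rates are drawn from a
normal(mean, sd) truncated to [min, max], then iteratively moment-corrected
(affine rescale, re-truncate, ≤100 iterations, inner tolerances 1e-4 on the
mean and 5e-4 on the sd) so the realized mean is within 0.005 and the
realized sd within 0.01 of the profile; finally one locus is pinned to the
minimum and one to the maximum so the profile's extremes are honoured
exactly. The generating distribution behind the published four moments is
unknown; the truncated normal is the minimal mechanism honouring all four,
and the correction loop makes the match contractual rather than asymptotic.
The default profile is the aged-scat calibration (0.43, 1.00, 0.62, 0.13).

**Degradation.** Locus j keeps each genotype independently with probability
rate_j, on top of any existing missingness (calls are never restored and
never altered). Every replicate draws fresh calibration and knockout
randomness, so a locus is not degraded the same way twice.

**Seed hierarchy.** The design's master seed spawns one child per
(size index, replicate index) via SeedSequence spawn keys; each child splits
into independent streams for thinning, calibration and knockout. Any
replicate is reproducible in isolation and results are independent of
execution order.

## 5. Estimators

He, Ho and Shannon's I are per-locus quantities on observed allele
frequencies, averaged over loci with data; the reported "spread" is the sd
across loci divided by √n_loci (the convention behind "0.284 ± 0.002"-style
values — whether such values are SE or SD across loci is ambiguous in the
field, so the computation is documented here and the field named neutrally).
He uses plain 2p(1−p); the 2n/(2n−1) small-sample correction is available
but off by default, matching the dialect of the standard tooling.
F_IS = (He − Ho)/He is formed from the multilocus means, not averaged
per-locus ratios. IR uses cohort allele frequencies including the focal
individual (the standard dialect; leave-one-out is an option). Individuals
with no typed loci get NaN and are dropped pairwise from correlations.

## 6. Spatial autocorrelation

Pairwise squared genetic distance is the codominant metric (0 / 1 / 4 per
locus), summed over loci typed in both individuals and rescaled by
(total loci / shared loci). The rescaling direction matters: it extrapolates
the shared-locus sum up to the full panel, so that heavily missing pairs are
not artificially close (the alternative reading — multiplying by the shared
fraction — would do the opposite). Pairs sharing no locus are excluded with
a warning and mean-imputed only inside the double-centering step.

The distance matrix is Gower-centered (c = −½ J D² J) and the per-class
coefficient is r_h = Σ c_xy / Σ (c_xx + c_yy)/2 over pairs in the class.
Distance classes are half-open [k·w, (k+1)·w) tiling [0, max); defaults
250 m to 3500 m; zero-distance pairs fall in the first class. Two
uncertainty measures are computed: a 95% CI from 999 bootstrap resamples of
pairs within each class, and a 95% null band from 999 permutations of
individual coordinates (which permutes class membership while genetic
similarity stays attached to individuals). "Positive structure" in a class
means r > 0 with the bootstrap CI lower bound above zero; the permutation
band is reported alongside but is not the default detection rule, since the
published detection convention is bootstrap-based. Under the null the
expected r is slightly negative (a −1/(n−1)-type offset), which the
permutation band reflects.

## 7. The experiment and its checks

The engine runs the full grid (default: panel 1300; sizes 40–420 step 20;
100 replicates; scat profile), measures every replicate, and summarises per
size: bias (mean − truth) and precision (sd across replicates) for He, I and
F_IS; the mean Pearson correlation between replicate and truth IR over
shared individuals; and the fraction of replicates with positive structure
in the 0–250 m and 250–500 m classes, with the smallest size whose rate
exceeds 95%. Replicates whose filtered dataset has zero loci are recorded
as failed and excluded with accounting. Rows stream to disk and interrupted
runs resume.

The automated checks run desk-scale versions chosen once: estimator
exactness against literal loop oracles at 1e-10; calibration of the
aged-scat profile at 1300 loci; F_IS recovery over 20 seeds at 400
individuals × 2000 loci; false-positive calibration of the structure test
over 200 no-IBD populations (100 × 300); a detection-power curve on a
200-individual strong-IBD population (panel 600, sizes 40–200, 25
replicates, 999 bootstraps); and the direction of the He bias over 50
replicates at near-complete sampling on the default population.

One directional check deserves a caveat. Degradation-induced re-filtering
removes only low-MAF (hence low-He) loci, so replicate He should overshoot
the truth on average. The mechanism is present — every MAF-step casualty in
simulated replicates has truth-He ≈ 0.02–0.03 — but with the symmetric Beta
spectrum only ~0–3 of ~1300 panel loci sit close enough to the MAF threshold
to be lost per replicate, an expected bias of ≈ +0.002 against per-replicate
noise of ≈ 0.007 (random call-rate locus loss) plus a fixed offset from the
once-drawn panel (sd ≈ 0.004). A 50-replicate sign test at these numbers has
essentially no power, and its outcome is dominated by the panel draw. A
spectrum with more mass near the MAF boundary — which real
reduced-representation data plausibly has — would make the effect much
larger; the spectrum here is calibrated only to mean He, so this check
documents the direction of the mechanism, not its real-data magnitude.

## 8. Limitations

- **Homogeneous inbreeding.** All synthetic individuals share one F, so
  among-individual IR variation is mostly sampling noise (IR range ≈
  0.09–0.19 versus −0.33–0.43 in real data of comparable mean). Replicate-
  vs-truth IR correlations are therefore strongly attenuated (≈ 0.2 at the
  default settings); on real data with genuine inbreeding variance they
  would be substantially higher. Detection *rates* and diversity biases are
  unaffected.
- **No genotyping error.** Degradation only removes calls; allelic dropout
  (heterozygotes miscalled homozygous) and false alleles are not simulated,
  so homozygosity-based measures are, if anything, optimistic.
- **No linkage disequilibrium** beyond shared-contig bookkeeping, no
  pedigrees, no demography, no sex-biased dispersal: sex-stratified
  correlograms are supported as a grouping, but in synthetic data the sexes
  are exchangeable by construction.
- **Frequency spectrum** calibrated to mean He only (see §7).
- The spatial field is a kernel-sum surrogate, not a true Gaussian process;
  its correlation length is approximate and edge effects reduce the field's
  variance near the hull boundary.
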