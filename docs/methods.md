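# Methods

This note documents the models, parameter choices and numerical conventions
behind `nigcmr`, and what the synthetic-data tests do and do not establish.

## The data-generating model

The generator (`nigcmr.simulate`) produces everything downstream modules
consume, under the assumptions the analysis itself makes.

**Population and movement.**  A two-sex population starts with `n_females` +
`n_males` animals, all on-site.  Between consecutive primary sampling
occasions (PSOs; one spring or fall field session) each animal survives with
sex-specific probability φ (apparent survival: death and permanent
emigration are confounded, as usual).  Survivors move by a Markovian
temporary-emigration process: an on-site animal leaves with γ″, an off-site
animal stays away with γ′.  Recruits (default 0, i.e. a demographically
closed population apart from deaths) enter on-site between PSOs.

**Capture.**  Within a PSO of `sso_per_pso` secondary occasions (SSOs; one
sampling day each), an on-site animal is captured per day with p until its
first capture of the session and with c afterwards.  "Capture" means a fecal
sample that yields a genotype; p ≠ c is a statistical device (there is no
physical trap response), and both are season- and sex-specific.

**Misidentification.**  Each capture is attributed to the animal's true
genotype with probability α; otherwise it creates a *ghost* — a fabricated
genotype drawn from a reserved allele namespace so that it can collide with
nothing.  Ghosts therefore appear exactly once, the standard
misidentification assumption (errors create singletons).

**Replicate-level errors.**  Every capture event becomes one sample with R
(default 3) PCR replicates per locus.  Per replicate-locus, independently: a
heterozygote loses one allele uniformly at random with `dropout_rate`
(homozygotes cannot drop out — the operational definition of allelic
dropout); a novel allele replaces one allele with `false_allele_rate`; the
whole replicate fails with `missing_replicate_rate`.  The Y-linked sex
marker amplifies per replicate with 1 − `sry_dropout` in males and never in
females.

**Default values.**  Where the monitored population's published estimates
exist they are the defaults: φ_f = 0.90, φ_m = 0.76, γ″ = 0.05, γ′ = 0.77,
and the (sex, season) grids for p (0.17–0.26), c (0.21–0.44) and α
(0.77–0.95).  The per-locus allele-frequency spectra reproduce the published
panel's allele counts (3, 5, 7, 2, 6, 3, 5) and heterozygosities
(H_E ≈ 0.14–0.64).  `missing_replicate_rate` = 0.15 matches the observed
across-years missing share (≈ 0.14).  The per-replicate error rates have no
published counterparts (only consensus-level proxies are reported), so they
are stated choices: `dropout_rate` = 0.02 (the observed false-homozygote
share among consensus-heterozygote replicates is ≈ 0.7–2.1%, and at small
rates the two quantities nearly coincide), `false_allele_rate` = 0.002
(false alleles are rare after consensus filtering), `sry_dropout` = 0.25
(all-replicate marker failure then affects d³ ≈ 1.6% of male samples, the
order of the observed false-female share).  Ten PSOs alternate
spring/fall with five SSOs each (sessions spanned at most eleven days, with
repeat surveys a few days apart).  Two qualitative pattern loci with 12
distinguishable classes each stand in for electropherogram peak-pattern
scoring; 12 classes makes them strongly but not perfectly discriminating,
mirroring their role of resolving genotypes identical at the seven scored
loci.  One sample is emitted per capture event; multiple same-day samples
of one animal would collapse to the same binary detection anyway.

**What the generator does not emulate.**  Per-sample DNA-quality
heterogeneity: replicate failures are independent, whereas real missingness
concentrates in bad samples.  The multilocus 6-of-7 acceptance filter
therefore removes more simulated samples (≈ 50–70% at the default missing
rate) than the field study's 20.5%.  Rates are also season-constant unless
configured otherwise, there is no spatial structure, and pellet age/diet
effects on DNA quality appear only implicitly through the error-rate
settings.  Passing tests consequently show that the estimators recover the
processes they model, not that field data meet those assumptions.

## Consensus calling and error rates

The multi-tube rules are exactly the acceptance table of the monitoring
protocol: homozygote iff all R replicates amplified and agree; heterozygote
iff ≥ 2 replicates agree and ≤ 2 distinct alleles occur across the
non-missing replicates (for R > 3 the same wording generalises; the
homozygote rule still demands all R present — a deliberate, conservative
choice).  The false-homozygote rate uses per-replicate counting: homozygous
non-missing replicates over all non-missing replicates within sample/locus
combinations whose consensus is heterozygous (the published rates are
phrased per consensus-heterozygote replicate).  Group SEs are standard
errors of per-sample proportions.

## Individual identification

Accepted genotypes are grouped by single-linkage under the ≤ 2 mismatched
alleles rule, with pattern loci contributing 2 mismatches when classes
differ, processed in sorted-sample order so the partition is reproducible
and order-free.  Dedicated matching software scores pairwise similarity
with its own machinery; the operative published rule is the mismatch
threshold, which is what is implemented.  Two guards: at least 5 comparable
loci are required to merge (sparse genotypes never chain), and undefined
distances count as non-matches.  Borderline merges (distance 1–2) remain in
the membership table for review.  Sex conflicts resolve male-ward: the
Y-marker can only drop out, so female-called samples in a male cluster are
reclassified and counted as false females.  Individual ids are assigned in
order of first detection.

## Population genetics

H_E uses the unbiased small-sample form (2n/(2n−1))(1 − Σp²); PIC, P_ID and
P_IDsib use plug-in frequencies; across-loci identity probabilities multiply
per-locus values.  The null-allele column is the Chakraborty estimator
(H_E − H_O)/(H_E + H_O); the published panel table used a different,
homozygote-frequency-based iterative estimator, so that column is
deliberately not comparable.  Hardy–Weinberg: Monte-Carlo exact test —
alleles permuted among genotypes, tables compared by Levene's conditional
probability, p = (1 + #{permuted ≤ observed}) / (1 + n_mc) with n_mc = 10⁴
by default and a fixed seed.

## The mark-recapture likelihood

The published analysis fit a robust design with misidentification in
closed-source software; the likelihood itself is never printed.  `nigcmr`
commits to the following composite likelihood (documented here and in
`nigcmr/cmr/likelihood.py`, validated by the α = 1 reduction, the
Lincoln–Petersen closed form and simulation recovery):

1. **Closed misID component per (PSO, sex).**  On-site animals form a
   Poisson superpopulation with intensity Λ = f0/P0, P0 being the
   probability of no recorded capture in the session, so f0 keeps its MARK
   meaning (expected on-site-but-undetected animals) and N̂ = (estimated
   real detected) + f0̂.  Recorded captures are the thinned capture process
   (p·α before the first recorded capture of the session, c·α after — the
   behavioural switch keys on *recorded* captures, which keeps the thinning
   exact); every capture spawns a ghost with 1 − α instead of a record.
   Poisson thinning renders the count of each observable class independent:
   multi-detection genotypes contribute log(Λσ(ω)) for their within-session
   history ω; study-wide singletons contribute the mixture
   log(Λ(σ₁(j)·S_out + G(j))), where σ₁(j) is the one-record history, G(j)
   the per-animal expected ghost yield at day j, and S_out the open-model
   probability that a real animal on-site in this session is detected in no
   other session.  S_out is what separates a once-caught animal from a
   ghost: without it, every singleton can be explained by a slightly lower
   p and α is not identified.
2. **Open component.**  Each multi-detection genotype, conditional on its
   first detection, follows a three-state hidden Markov chain (on-site,
   temporary emigrant, dead) across PSOs with emissions p* = 1 − P0 (on-site
   and detected) and P0 (on-site, not detected); off-site and dead emit no
   detections.  Evaluated by forward recursion, vectorised over the unique
   detection patterns.

Detection indicators after first capture enter both components, as in the
classical robust-design factorisation; the product is a composite
likelihood, not an exact joint density, so Hessian-based SEs are
approximate.  Simulation recovery at the defaults (100 replicates, 10 × 8
occasions, ~100 animals) shows per-parameter 95%-CI coverage of roughly
0.9–1.0 for φ, p, c and α.  Singleton genotypes enter only the closed
component; their cross-session absence is used through S_out but their
open-chain likelihood is not otherwise modelled.  The before-session part
of S_out conditions on presence since the first PSO, matching the
generator's closed-recruitment default.

**Parameterisation.**  Families φ, γ′, γ″ (per between-PSO interval), p, c
(per SSO), α, f0 (per PSO), each structured as constant / by sex / by
season / by sex-season / fixed, on the logit link (log for f0).  Two
extensions: `by_sso` gives p one value per secondary occasion (shared over
sessions and sexes) and `equal_p` ties c to p; together they reproduce the
classical two-occasion Lincoln–Petersen estimate (N̂ = n₁n₂/m₂) exactly,
which fixes the abundance scale of the closed component.  Interval-level
season uses the season of the departure PSO.  A sex absent from the data
contributes no parameters.  K counts free link-scale parameters and
reproduces the published model set's counts (e.g. 18 for the full
sex-season model, 16 for its no-movement variant with γ′ = 1, γ″ = 0).

**Fitting and model selection.**  L-BFGS-B from deterministic starts (all
probabilities 0.3, f0 at half the mean detected count per cell; two fixed
±0.5 link-scale perturbations as extra starts), ftol 10⁻¹⁰.  SEs from the
numerical Hessian by delta method; all CIs are Wald intervals on the link
scale (the profile alternative does not pay for itself at these sample
sizes, and the averaging convention below is Wald-based anyway).  AICc uses
n_eff = total detection events (the closed-model convention; the
number-of-histories alternative is a flag).  Ranking: ΔAICc, relative model
likelihood exp(−Δ/2), normalised weights.  Averaging: weights renormalised
over the supported models (model likelihood > 0.2 and weight > 0.05, with
fall-back to the best model), estimates and SEs averaged as weighted means
— the simple weighted-mean SE convention, with the unconditional
(between-model variance) form available as a flag.  Derived: N̂ per
(PSO, sex) adds f0̂ to the ghost-discounted detected count (each singleton
weighted by its posterior real probability σ₁S_out/(σ₁S_out + G));
density = ΣN̂/area; sex ratio = N̂_M/N̂_F.

**Degenerate inputs.**  Histories with zero detections are rejected;
empty (PSO, sex) cells contribute only their normalising term; non-finite
likelihood evaluations return a large penalty; a singular Hessian falls
back to a pseudo-inverse and flags the fit.

## Species assignment

Genotypes become an individuals × alleles 0/1/2 count matrix; missing loci
are mean-imputed (listwise deletion is the switchable alternative); the
joint panel + query matrix is centred and decomposed by SVD; group
centroids on PC1–2 come from labelled panel rows only (≥ 2 species with ≥ 5
members required) and queries take the nearest centroid (Euclidean).  This
mechanises the visual reading of a PCA scatter; admixture-model assignment
and hybrid-class inference are out of scope, and discordance with other
methods is reported, not adjudicated.

## Problem sizes used in the test suite

Test simulations use populations of 28–120 animals over 4–10 sessions —
small enough for the full suite to run in a few minutes, large enough for
the 3σ calibration checks and the 100-replicate coverage study to bind.
The Hardy–Weinberg null-uniformity check runs 60 replicates at n_mc = 500;
exhaustive consensus checks cover all 7³ three-replicate combinations over
three alleles.
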