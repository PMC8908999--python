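# Methods

`peridmi` re-creates, on fully synthetic data, a diffusion-microstructure
analysis of the T2-hyperintense zone that surrounds contrast-enhancing
brain tumors: the peritumoral edema of metastases is predominantly
vasogenic (free-water rich), while the corresponding zone of glioblastoma
(GBM) additionally harbors infiltrating tumor. The package therefore has
two arms that meet at a common patient-table schema: a voxel-level
imaging arm (signal model → estimator → ROI normalization) and a
patient-level statistics arm (cohort emulator → ANCOVA / correlation /
ROC battery).

## Signal model

Each white-matter voxel is a three-compartment mixture,

S(b, g) = S₀ · [ v_i · exp(−b·D_i·(g·u)²)
              + v_e · exp(−b·(D_e⊥ + (D_e∥ − D_e⊥)(g·u)²))
              + v_f · exp(−b·D_f) ],

with volume fractions (v_i, v_e, v_f) on the unit simplex: a zero-radius
**stick** (intra-axonal water, diffusivity D_i along the axon direction
u), an axially symmetric **zeppelin** (extra-axonal cellular water,
D_e∥ ≥ D_e⊥), and an isotropic **ball** (free water / CSF, D_f fixed at
3.0 μm²/ms, body temperature). b is in ms/μm² (1.0 ≡ 1000 s/mm²),
diffusivities in μm²/ms. There is no exchange, no compartmental
T2 difference, and a single fiber orientation per voxel.

The orientation average (spherical mean / powder average) of each
compartment has a closed form; for the stick,
⟨E⟩ = √(π/(4bD_i))·erf(√(bD_i)), and the zeppelin factors into
exp(−b·D_e⊥) times the stick form of its anisotropy Δ = D_e∥ − D_e⊥
(with a series switch below bΔ = 10⁻⁶ for continuity). These means are
the rotation-invariant features the estimator consumes, which is why
orientation dispersion need not be simulated: any dispersion distribution
leaves the spherical mean unchanged.

Magnitude-MR noise is Rician: S ← √((S+ε₁)² + ε₂²), ε ~ N(0, σ²),
σ = S₀/SNR with SNR quoted at b = 0.

## Acquisition scheme

The default synthetic protocol is one b = 0 volume plus two 30-direction
shells at b = 1.0 and 2.0 ms/μm², directions laid out by electrostatic
repulsion (antipodally symmetric energy, seeded and deterministic). Two
nonzero shells are the minimum that renders three compartments
identifiable; the scheme is a placeholder for a clinical protocol and is
fully configurable through FSL-style bval/bvec files.

## Estimator

The fraction estimator is a posterior-mean surrogate obtained by
simulated regression ("Bayesian estimation by supervised learning"):

1. draw n = 20 000 parameter sets from the prior — fractions uniform on
   the simplex; D_i ~ U(1.5, 2.5); D_e∥ ~ U(1.0, 2.0);
   D_e⊥/D_e∥ ~ U(0.2, 0.6); orientations uniform on the sphere;
   training SNR ~ U(20, 50);
2. simulate each voxel's signal under the scheme with Rician noise;
3. reduce to per-shell powder means normalized by the b = 0 mean
   (2 features for the default scheme);
4. least-squares fit a full degree-3 polynomial map from features to the
   generating fractions.

The fitted map approximates E[v | features] marginalized over the
diffusivity, orientation and noise priors. Predictions are clipped to
[0, 1] and renormalized to sum to one, so the simplex constraint holds
everywhere by construction.

**Why this diffusivity prior.** With only two shell features, a very wide
diffusivity prior makes the inverse problem non-identifiable: different
(fractions, diffusivities) pairs produce identical features, and the
posterior mean is pulled far from the true fractions. We measured this
directly — under a prior spanning D_i ∈ [1.0, 2.5], D_e∥ ∈ [0.5, 2.5],
ratio ∈ [0.1, 1.0], even a kernel estimate of the exact posterior mean
deviates from the canonical-diffusivity inversion by more than 0.1 per
fraction in ~35% of voxels. The shipped prior (±25% around the canonical
white-matter values D_i = 2.0, D_e∥ = 1.5, D_e⊥/D_e∥ ≈ 0.33) restores
identifiability (≥ 90% oracle agreement, RMSE ≤ 0.09 per fraction at
SNR = 30) while still marginalizing realistic biological variation. The
trade-off is explicit: voxels whose true diffusivities fall outside the
prior will be biased toward it.

**Verification oracle.** An exhaustive grid search over the fraction
simplex (step 0.02) at the canonical diffusivities, minimizing the
sum-of-squares misfit of the analytic spherical-mean features, is kept as
an independent cross-check; it shares no code path with the regression
beyond the feature definition. On noise-free canonical voxels it recovers
fractions to ~0.02 (grid resolution plus the ≲5·10⁻³ error of a
30-direction powder average relative to the exact spherical mean).

## Phantom

A synthetic "patient" is a concentric spherical geometry on a 32³ grid of
2 mm voxels: enhancing core (8 mm radius), perilesional T2 rim (10 mm
thick), remaining brain sphere as normal-appearing white matter (NAWM).
Zone mean fractions — NAWM (0.45, 0.45, 0.10); GBM rim (0.25, 0.40,
0.35); metastasis rim (0.15, 0.30, 0.55); core (0.10, 0.50, 0.40) — are
*declared stand-ins*: the emulated study reports only NAWM-normalized
ratios, so these absolutes are chosen to reproduce the direction and
rough size of the published ratio contrasts, not measured values.
Per-voxel jitter is Dirichlet with concentration 100·3·mean (coefficient
of variation a few percent); diffusivities are canonical; orientations
random. Default SNR 30.

What a green phantom test establishes: the estimation → ROI → ratio chain
preserves a configured free-water contrast under realistic noise. What it
does not: that real perilesional tissue has these absolute fractions, or
that the chain is robust to anatomy, partial-volume mixing at zone
boundaries, crossing fibers, or preprocessing artifacts — none of which
are simulated.

## ROI metrics

NAWM is constructed by exclusion (white matter ∧ ¬T2-ROI ∧ ¬core). Each
map is reduced by the arithmetic mean over a mask, and the reported
metric is the ratio mean(ROI)/mean(NAWM) — "ratio of means", one of the
two conventions compatible with per-patient normalization; it removes any
global multiplicative factor exactly. ROI volume is voxel count × voxel
volume (ml). Empty masks and zero NAWM means raise errors rather than
propagating silent zeros. Identical ROI and reference masks are permitted
(the self-normalization degenerate case, ratio ≡ 1); in normal use the
NAWM construction guarantees disjointness.

## Cohort emulator

Patient-level data are drawn directly at the published group summaries
(n = 19 GBM / 17 metastasis): normalized V-intra / V-extra / V-CSF and
T2-lesion volume get log-normal marginals — positive, right-skewed,
consistent with a study that reports medians and IQRs — parameterized
exactly by median m and IQR: μ = ln m, σ = asinh(IQR/2m)/z₀.₇₅. Age is
normal (mean/SD as published). Dependence is a Gaussian copula over
(age, volume, v_intra, v_extra, v_csf) with two nonzero links per group:
(V-CSF, volume) and (age, V-CSF). Latent correlations are moment-matched
in closed form — for two log-normals ρ = ln(1 + r√((e^{σ₁²}−1)(e^{σ₂²}−1)))/(σ₁σ₂),
for normal–log-normal ρ = r√(e^{σ²}−1)/σ — so the *observed* Pearson
correlations converge to the configured targets. Direct latent imposition
was rejected after measurement: at the published volume spread
(σ_log ≈ 1.2 for metastasis T2 volume) it would distort the
(V-CSF, volume) correlation by ≈ 0.16.

Limitation worth stating: at n = 19/17 the V-extra group contrast
(medians 0.88 vs 0.81 against IQRs 0.30/0.18) is weak by construction —
the sample-median ordering holds in only ~83% of simulated cohorts. This
mirrors the emulated study, where V-extra was the weakest effect
(p = 0.024, AUC 0.663); the V-CSF and V-intra orderings hold in ≥ 95% and
≈ 96% of cohorts respectively.

## Statistics

* **ANCOVA** — OLS of the metric on a group indicator plus lesion volume;
  the group term is tested by the nested-model F (df = (1, n−3) for two
  groups); Bonferroni over m = 3 metrics. The published "F (1,1)"
  denominator df is treated as a typographical artifact. With a pure-noise
  covariate the test is exactly calibrated (measured type-I error 0.046
  at α = 0.05 over 500 null cohorts of n = 36).
* **Pearson correlation** — product-moment r, two-sided t-based p (n−2 df).
* **Mann–Whitney U** — exact permutation null with midranks for combined
  n ≤ 12 (handles ties; p = P(|U−μ| ≥ |U_obs−μ|) by full enumeration),
  tie-corrected normal approximation otherwise.
* **ROC** — candidate cutpoints are midpoints between consecutive
  distinct scores plus ±∞ sentinels; the classification direction ("≥" or
  "≤" predicts the positive class) is chosen by the better attainable
  sensitivity+specificity; AUC is the trapezoid over the empirical curve
  (points ordered by FPR, ties by TPR, which credits tied scores by ½ and
  makes the trapezoid identical to the Mann–Whitney pair count); the
  optimal cutpoint maximizes sensitivity+specificity ("equally weighted",
  the Youden criterion), smallest candidate winning ties for determinism.

## Reproducibility and numerics

All randomness descends from one integer seed, split per module through
SHA-256-hashed stream names into `numpy` SeedSequences (child seeds
< 2³¹). Identical seeds give byte-identical cohort tables and CSV
outputs. Numerical guards: stick-mean series expansion below
b·D = 10⁻⁶; clip-and-renormalize with a 1/3-fallback for degenerate
all-zero predictions; Cholesky feasibility check of the latent
correlation matrix with the offending pair named on failure.

## Known limitations

* Absolute phantom fractions and the acquisition protocol are declared
  stand-ins, not published values.
* The regression estimator is a surrogate for full Bayesian inversion;
  its prior is intentionally narrow (see above) and voxels outside it are
  biased toward it.
* Normalized-ratio estimates are attenuated relative to ground truth
  (estimator shrinkage affects ROI and NAWM asymmetrically); the group
  *contrast* survives, absolute ratios should not be read as calibrated.
* The cohort emulator reproduces printed summaries (medians, IQRs, two
  correlations, group sizes) — not the unpublished joint distribution of
  the real patients; marginal shapes are an assumption.
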