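# Methods

## Signal model and apparent q-space metrics

All metrics are computed from a single shell at b ≈ 1,000 s/mm² under the
mono-exponential radial model: for every unit direction u the normalized
attenuation is E(q·u) = exp(−4π²τq²·D(u)), where D(u) = −ln(S(u)/S₀)/b is the
apparent diffusivity sampled at the shell and τ is an effective diffusion
time.  The model is what makes single-shell estimation possible; it is a good
description of brain tissue up to b ≈ 2,000 s/mm², and all outputs must be
read as *apparent* values tied to the acquired shell.  With it, the EAP
integrals reduce to angular averages of powers of D:

| metric | definition | reduction | units |
|---|---|---|---|
| RTOP | ∫ E(q) dq | (4πτ)^−3/2 ⟨D^−3/2⟩ₛ | mm⁻³ |
| RTPP | ∫ E(q·e₁) dq | (4πτ D(e₁))^−1/2 | mm⁻¹ |
| RTAP | ∫\_{⊥e₁} E dq | (4πτ)^−1 ⟨D^−1⟩\_eq | mm⁻² |
| Υ^γ | ∫ ‖q‖^γ E dq | 2π Γ((γ+3)/2) (4π²τ)^−(γ+3)/2 ⟨D^−(γ+3)/2⟩ₛ | mm^−(3+γ) |

qMSD = Υ², Υ^1/2 ("U12") is the half-order moment, and Υ⁰ ≡ RTOP (asserted
in tests to 1e−12).  The anisotropy indices are power fractions of the SH
expansion: t = √(1 − c₀₀²/Σc²) on the attenuation profile (APA) or on D(u)
(DiA), optionally rescaled by σ\_ε(t) = t^{3ε}/(1 − 3t^ε + 3t^{2ε}).  The
exact anisotropy construction varies across the apparent-metrics literature;
we expose both the raw index and the rescaled one (ε = 0.4, enabled by
default) because only the monotone cross-group behavior matters downstream.

### Numerical engine

Spherical functions are expanded in a real, symmetric, orthonormal SH basis
(even l ≤ 6, 28 coefficients; modified-real construction; coefficients
ordered by l then m = −l…l).  Fits are penalized least squares,
c = (BᵀB + λR)⁻¹Bᵀy with R = diag(l²(l+1)²) and λ = 0.006 — the common
Laplace–Beltrami smoothing convention.  Angular means come from c₀₀; the
equatorial mean in RTAP uses the Funk–Hecke identity
⟨f⟩\_eq(e) = Σ P_l(0) c\_{lm} Y\_{lm}(e), which is exact for band-limited
series and equals the K-point great-circle quadrature for K > L (K = 64 kept
for cross-checks).  The principal direction e₁ is taken from the
ordinary-least-squares log-linear tensor fit (not the SH maximum): it is
deterministic, cheap, and consistent with the RTPP↔AD pairing.

We fit the SH series to the required *power* of D (transform-then-fit)
rather than transforming a fitted series: the closed forms need spherical
means of powers, and fitting the transformed samples makes that mean an
ordinary LS estimate without negative-lobe artifacts.

Guard rails: ADC clipped to [1e−5, 1e−2] mm²/s before negative powers (clip
count reported as QC); signal clipped to [1e−6·S₀, S₀] before logs; tensor
eigenvalues floored at 1e−7 mm²/s; voxels with S₀ ≤ 0 flagged invalid (NaN
scalars).

### Known accuracy limits

Measured against brute-force numerical integration of the mono-exponential
q-space integrals on dense radial × angular grids, over randomized tensor
voxels with FA ≤ 0.9 at the default L = 6, λ = 0.006, 61 directions:

- spherical-mean metrics are accurate to ≲0.5% (RTOP) and ≲0.8% (Υ^1/2);
  qMSD, whose transform D^−5/2 is the spikiest, reaches ~2% at the
  extreme-FA corner;
- RTPP carries a ~1.2% negative bias on D(e₁) from the λ-shrinkage of the
  l ≥ 2 content at the pole;
- RTAP is the least accurate: the order-6 truncation of D⁻¹ is amplified by
  the alternating Funk–Hecke weights, giving ~2% at FA ≈ 0.3 and up to ~20%
  at FA ≈ 0.9 (8% even with λ = 0).

These biases are intrinsic to the estimator, scale-consistent (the exact
power-law scaling RTOP → c^−3/2·RTOP etc. under D → c·D holds to 1e−10), and
shared by any implementation of this algorithm; group contrasts, which are
what the pipeline tests, are unaffected by a systematic multiplicative bias.
The isotropic closed forms hold to 1e−10.

## Synthetic data

### Voxel model

Two compartments: a zeppelin (axially symmetric tensor, diffusivities
d∥ ≥ d⊥, axis μ) with volume fraction f, plus isotropic free water,
S(b,u) = f·exp(−b(d⊥ + (d∥−d⊥)(uᵀμ)²)) + (1−f)·exp(−b·D₀).  Defaults are
textbook healthy white matter: d∥ = 1.7e−3, d⊥ = 0.3e−3, D₀ = 3.0e−3 mm²/s
(free water at body temperature).  The acquisition is 1 b=0 plus 61
directions at b = 1,000 s/mm²; the direction table is a deterministic
electrostatic-repulsion set, fixed across subjects and cohorts like a real
vendor table.

### Constant-FA / constant-MD families

For the signal experiment, d∥ is fixed and d⊥ is root-found per f ∈ [0.3, 1]
so that the tensor *fitted from the mixture signal* keeps FA (or MD)
constant (tolerance 1e−4, verified by re-fitting).  Feasibility constrains
the reference point: with 30–70% free water at D₀ = 3.0e−3, the fitted FA
cannot exceed ≈0.49 and the fitted MD cannot fall below ≈1.6e−3 at f = 0.3.
We therefore run both families at d∥ = 2.0e−3 with reference d⊥ = 0.9e−3
(constant-FA, FA ≈ 0.46) and d⊥ = 1.5e−3 (constant-MD).  Two structural
consequences, both verified: at constant FA the tensor shape is fixed, so
RTAP ∝ 1/MD and its normalized curve mirrors MD's (we compare against the
mirrored curve); at constant MD, free water being faster than any feasible
zeppelin forces d⊥ → 0 as f → 0.3, so all anisotropy indices strictly
*decrease* with f, with DiA tracking FA closely and the three indices moving
in a common direction.

### Cohorts

A cohort is three groups (HC/EM/CM by default) of subjects sharing a block
atlas: 12 cuboid regions (configurable to 48) tiled over a small grid, each
with a one-voxel-thick core plane as the "skeleton".  Per subject and
region, parameters are baseline + group offset (the injected effect) +
subject-level offset jitter (Gaussian, SD = 10% of the offset) + biological
variability of the zeppelin fraction (Gaussian on f, SD f\_sigma = 0.07).
The biological term is essential: without it a null group's between-subject
variance is only measurement noise, any injected offset has an effect size
of several pooled SDs, and significance would never depend on the sample
size.  f\_sigma = 0.07 puts the standard −0.05 f-offset at Cohen's d ≈ 0.7 —
the medium-to-large regime clinical migraine studies report — giving ≈0.9
power at n = 50 and a sub-majority subsample rejection rate at n = 10.
Magnitude (Rician) noise is added at a stated b=0 SNR (default 30).
Generation is fully deterministic given the cohort seed.

What the generator does *not* emulate: head geometry, registration error,
crossing fibers (single zeppelin only), spatially correlated noise, and
atlas misalignment.  Green tests on this cohort therefore certify the
statistics pipeline and metric behavior under the stated variance model, not
robustness to real-data artifacts.

## Group statistics

Per subject, ROI and metric: restrict to ROI ∩ skeleton, compute the 2nd and
98th percentile of those values (linear-interpolation quantiles), and
average the values strictly inside the bounds (ties fall back to the
inclusive window; constant data returns the constant).  Bounds are computed
per ROI; a switch for global-skeleton bounds exists.  ROI id 0 is the
whole-skeleton ("full WM") pseudo-ROI.  Group comparisons are equal-variance
two-tailed t-tests (df = nₐ+n_b−2) with Cohen's D on the pooled SD, at
α = 0.05 and deliberately *no* multiple-comparison correction (the design
probes each measure separately; an FDR switch exists, default off).  The
Pearson chi-square (no continuity correction) is included for contingency
tables and reproduces the published gender × group example (χ² = 2.74).

## Resampling and stability

From the full N down to 10 subjects per group in steps of 5, B subsamples
are drawn per size *without replacement* (distinct-subject subsets are the
only reading under which thousands of "different subsamples" of reduced size
make sense; a with-replacement mode exists).  The per-subsample seed derives
from (base seed, size, iteration), so any single draw is reconstructible.
Only tests significant on the full sample are re-tested (configurable); a
test is robustly significant at size n when ≥ ⌈B/2⌉ subsamples reject
(2,501 of 5,001 at the reference B; 251 of 501 at the reduced B used in the
shipped experiments).  Stability is the CQV per group × ROI × metric,
summarized as the median over subsamples with a 2.5–97.5 percentile
interval; at n = N all subsamples coincide and the interval has zero width
(asserted).

A selection subtlety documented here because it shapes expectations: a test
that is significant on the full sample by chance is reproduced by
construction in subsamples of nearly full size, so the null-cohort claim "no
test reaches the majority criterion" is only meaningful at strongly reduced
sizes; the shipped checks evaluate it at n = 10, where the expected |t| of a
chance finding shrinks by √(n/N).

## Problem sizes of the shipped experiments

The validation experiments are sized for a laptop-class single-core run:
type-I calibration uses 500 replicate null cohorts of 3×50 subjects on a
compact atlas (12 regions of 2×2×2 voxels); effect recovery uses 20 cohort
seeds of 50+51 subjects on 3×3×3-voxel regions with B = 501 subsamples per
size.  Region size enters only the per-subject averaging, not the
subject-level test statistics, so the small atlases do not change the
calibration being tested.
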