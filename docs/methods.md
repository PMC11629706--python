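# Methods

## Setting and model

`mrgj` performs two-sample Mendelian randomization from GWAS summary
statistics: the SNP–exposure associations come from one cohort (a continuous
microbial-abundance trait) and the SNP–outcome associations from another (a
binary disease analysed on the log-odds scale).  The instrumental-variable
assumptions are the usual three: relevance (the SNP is associated with the
exposure), independence (no confounding of the SNP–outcome relation), and
exclusion (the SNP affects the outcome only through the exposure).  The
estimators differ in how they relax exclusion: IVW assumes it for all
instruments, MR-Egger replaces it with InSIDE (instrument strength
independent of direct effects), the weighted median requires a valid
majority of weight, and the mode estimators require only a valid plurality.

## Instrument selection

Selection runs in a fixed, logged order: exposure p-value threshold →
greedy LD clumping → harmonization → confounder-list exclusion → per-SNP
F filtering.  Defaults (all exposed in config):

| parameter | default | meaning |
|---|---|---|
| `pval_threshold` | 1e-5 | exposure significance cutoff (1e-8/5e-8 selectable for a stricter genome-wide screen) |
| `clump_r2` | 0.001 | max pairwise r² between retained instruments |
| `clump_kb` | 10,000 | clumping distance window (kb) |
| `f_min` | 10 | per-SNP F must exceed this |
| `palindrome_eaf_margin` | 0.08 | palindromic SNPs kept only if both EAFs are outside 0.5 ± margin |

Clumping greedily picks the smallest-p remaining SNP as index and removes
same-chromosome neighbours within the window at or above the r² threshold.
Ties on p are broken by (chromosome, position, variant_id), so the result
is independent of input order.  Distance is |pos₁ − pos₂| ≤ window; SNPs on
different chromosomes are never clumped together.

Instrument strength uses R² = 2·EAF·(1−EAF)·β² per SNP, and
F = R²(N−1−i)/[(1−R²)·i] with i regressors.  Per-SNP filtering evaluates
each SNP at i = 1; once a set holds i ≥ 10 instruments, its set-level R²
(used for set F and the Steiger test) sums the normalized per-SNP form
R²/(R² + N·SE²·…) that discounts estimation noise.  Set-level R² sums
per-SNP values, which is exact for LD-independent instruments; N entering
set-level F is the mean exposure sample size across instruments.

## Harmonization

Outcome records are rewritten onto the exposure's effect allele: identical
allele pairs pass through; swapped pairs negate the outcome beta and
complement its EAF; strand-complement pairs are complemented first.
Palindromic SNPs (A/T, C/G) cannot be strand-resolved from alleles, so they
are kept only when both EAFs are outside the ambiguity margin *and* agree
on the minor allele after any allele-order swap; otherwise they are dropped
with reason `palindromic_ambiguous` (also whenever outcome EAF is missing).
This is deliberately conservative: a genuinely strand-flipped palindrome
whose frequencies disagree is dropped, never "corrected".  Harmonization is
involution-safe (re-harmonizing output changes nothing), and the Wald ratio
is invariant to which allele is called the effect allele.

## Estimators

With θ̂ⱼ = β̂ᵧⱼ/β̂ₓⱼ and first-order SE σᵧⱼ/|β̂ₓⱼ| (no second-order delta
term), weights wⱼ = se(θ̂ⱼ)⁻²:

* **IVW** — weighted mean of ratios; algebraically identical to WLS of β̂ᵧ
  on β̂ₓ through the origin with weights σᵧ⁻².  Default multiplicative
  random effects inflate the fixed-effects SE by √max(1, Q/(J−1)) — a
  conservative choice under heterogeneity that never narrows the interval;
  fixed effects by flag.  Normal p-values.
* **MR-Egger** — SNPs oriented to β̂ₓ ≥ 0, then WLS with intercept, weights
  σᵧ⁻², SEs inflated by √max(1, Q_E/(J−2)), t p-values with J−2 df (the
  t reference guards the intercept test at small J, its known fragility).
  The fit is delegated to statsmodels WLS; tests verify it against directly
  solved weighted normal equations.
* **Weighted median** — sort θ̂, form cumulative mid-weights
  sⱼ = Σ_{k≤j}p_k − pⱼ/2, interpolate to s = 0.5.
* **Modes** — normal-kernel density argmax over a 512-point grid spanning
  [min θ̂ − 3h, max θ̂ + 3h], bandwidth h = φ·0.9·min(sd, IQR/1.349)·J^(−1/5),
  φ = 1 by default; uniform weights (simple) or wⱼ (weighted).  If all
  ratios coincide the common value is returned with zero SE and a warning.

Median and mode SEs come from a parametric bootstrap that redraws each
ratio from N(θ̂ⱼ, se(θ̂ⱼ)²) — ratio-level rather than per-beta resampling,
equivalent to first order — with n_boot = 1000 and a fixed default seed
(20241126) recorded in output metadata.

## Sensitivity suite

Cochran's Q = Σwⱼ(θ̂ⱼ − β̂)² with J−1 df for IVW (J−2, residual-based, for
Egger); the Egger intercept test reads p > 0.05 as no directional
pleiotropy detected; leave-one-out recomputes IVW without each SNP and
flags a SNP as influential if its removal flips the estimate's sign or
moves the p-value across 0.05 (both triggers reported separately).  The
Steiger test sums instrument R² on each side — for the binary outcome the
observed-scale approximation r² = z²/(z² + n) per SNP, which needs neither
outcome EAF nor case fraction — and compares Fisher-transformed √R² values
with variances 1/(n−3), two-sided.  Total (not effective) outcome n is used
by default and is an explicit argument.

## Synthetic-data generator

The generator emulates the *summary statistics* of a microbiome MR design,
not individual-level data.  Per SNP: maf ~ U(maf_range); SNP–exposure
effect γⱼ ~ N(gamma_mean, gamma_sd); direct (pleiotropic) outcome effect
αⱼ = 0 (none), N(0, sd_alpha) (balanced), or N(mean_alpha, sd_alpha)
(directional), applied to a configurable fraction of SNPs; when InSIDE is
violated, αⱼ gains a +0.5·(γⱼ − γ̄) term correlating it with instrument
strength.  True outcome effect Γⱼ = β_causal·γⱼ + αⱼ.  Observed betas add
normal noise with the closed-form SEs of standardized-genotype regression,
se_x = 1/√(2·maf·(1−maf)·n_exp) and se_y = 1/√(2·maf·(1−maf)·n_out·cf·(1−cf));
binary-outcome effects are drawn directly on the log-odds scale with this
effective-n inflation rather than via logistic sampling of individuals.
LD is block-diagonal by construction with positions placed so blocks fall
inside/outside one clumping window.  Allele records receive configurable
palindrome and strand-flip fractions to exercise harmonization.  One master
seed drives an independent substream per SNP, so growing the panel never
perturbs earlier draws; `noise_scale` exists purely as a validation hook
(0 = noiseless limit).

Defaults mirror the emulated study's sample sizes — exposure n = 18,340,
outcome 1,086 cases / 147,221 controls (n = 148,307) — and place
instruments in the strong-instrument, strength-heterogeneous regime:
γ ~ N(0.30, 0.08), giving per-SNP F in the hundreds and I²_GX ≈ 0.98.
This is a deliberate design choice: the calibration studies are meant to
measure the estimators where their consistency conditions hold.  At the
weak-instrument end (per-SNP F near the conventional cutoff of 10–25),
two documented attenuations dominate instead: IVW shrinks toward the null
by roughly se_x²/(γ² + se_x²), and the Egger slope by 1 − I²_GX, with the
lost effect surfacing in its intercept.  A subtler effect also appears:
SNPs whose estimated γ̂ is negative get re-oriented, which reflects their
direct effects αⱼ and — because low-|γ̂| SNPs carry maximal intercept
leverage — biases the mean Egger intercept several-fold more than the flip
probability alone suggests.  The defaults keep P(γ̂ < 0) ≈ 10⁻⁴ so this is
negligible; all regimes remain reachable through config.

What the generator does **not** emulate: LD-correlated summary noise
within blocks (block members have correlated r² but independent noise —
sufficient for exercising clumping, not for realistic conditional
analyses), microbiome abundance distributions (only their GWAS summaries),
sample overlap between cohorts, population stratification, and
total-variance bookkeeping across SNPs (per-SNP effects are standardized
marginally, so a large panel's summed R² can be unrealistically high).
Passing calibration therefore demonstrates correctness of the estimators
under their stated assumptions, not robustness to these real-data
complications.

## Calibration scenarios

The calibration module fixes study-scale sizes (n_exp = 18,000,
n_out = 148,000, case fraction 1,086/148,307, 50 instruments, no
palindromes or strand flips so every simulated SNP survives to estimation):
recovery and coverage at β = 0.5; type-I error and Q calibration at β = 0
over 2,000 replicates; Egger recovery under directional pleiotropy with
mean α = 0.1, sd 0.08 (InSIDE held); and median robustness with 40% of
SNPs invalid at mean α = 0.8 — a magnitude chosen so the invalid ratios
separate cleanly from the valid cluster, which is the regime the weighted
median's breakdown guarantee speaks to (at small α the invalid cluster
hides inside the ratio noise and no estimator can distinguish it).
Replicate seeds derive from one master seed.  These sizes complete in
about half a minute on one CPU; they are the package's standing problem
sizes for validation.

## Published-row audit

The original cohort downloads are not redistributable, so `mrgj.reported`
ships the published per-exposure IVW rows (p, OR, 95% CI, Egger intercept,
Q, Steiger verdict) and audits their internal Wald consistency:
se = ln(OR)/Φ⁻¹(1 − p/2), CI = exp(ln OR ∓ 1.959964·se).  20 of the 21
rows reproduce their printed CI within 0.03 (print rounding); the
"L-histidine degradation I" pathway row does not (recomputed 1.10–1.89
against printed 1.07–1.93), an apparent print inconsistency in the source
table, pinned as such in the tests.

## Numerical and degenerate-case choices

Floats are written with 17 significant digits and re-read with round-trip
parsing, so file round trips are lossless and repeated runs byte-identical
(no timestamps anywhere in outputs).  LD matrices tolerate asymmetry up to
1e-8 (symmetrized by averaging), reject worse.  A single-instrument IVW
degenerates to the Wald ratio with a warning; estimators needing spread
(Egger with collinear exposures, modes with identical ratios) error or
return the degenerate value explicitly rather than guessing.  p-values
below double precision are clamped to the smallest positive double so
validation (p > 0) is preserved.  Exposures ending with fewer than two
instruments are reported as `insufficient_instruments`, never silently
dropped, and one exposure's failure cannot affect another's results.
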