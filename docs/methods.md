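# Methods

## Signal model and fitting

Each voxel's diffusion-weighted magnitude signal is modelled as

    S(b) = S(0) · exp[ −(b · DDC)^α ],   DDC in mm²/s,  α ∈ (0, 1]

The product b·DDC is dimensionless, so the fit is equivariant under
rescaling of the b axis (b → k·b implies DDC → DDC/k with α unchanged) and
invariant to overall signal amplitude — two properties the test suite
asserts directly.

**S(0) handling.** The model normalizes by the measured b = 0 signal, so
S(0) is fixed, not estimated: the fit minimizes
Σ_b (S(b)/S(0) − exp[−(b·DDC)^α])² over (DDC, α) only. A free-S0 mode
(`FitSettings(free_s0=True)`) adds a multiplicative amplitude parameter for
sensitivity checks; on noiseless data both modes recover the truth.

**Optimizer.** Bounded trust-region-reflective least squares
(`scipy.optimize.least_squares`) with the analytic Jacobian. At b = 0 the
model is identically 1 with zero gradient; the partials are set to 0 there
to avoid the 0^(α−1) singularity. Defaults:

| setting | value | rationale |
|---|---|---|
| DDC bounds | [1e−6, 1e−2] mm²/s | brackets physiological brain diffusivity with margin |
| α bounds | [0.01, 1.0] | α > 1 is outside the model's domain; 0 is singular |
| DDC init | log-linear ADC (clipped into bounds) | the α = 1 special case is an excellent starting point |
| α init | 0.8 | interior, near typical tumor values |
| tolerances | 1e−10 (ftol/xtol/gtol) | noiseless roundtrips to ≤ 1e−5 relative error |
| max function evals | 500 | never reached on well-posed voxels |

Voxels with S(0) ≤ 0 are degenerate: they are removed from the fit mask,
counted in the log, and carry NaN in every output map. A parameter landing
within 1e−9 of a bound sets the `at_bound` flag (a constant signal, for
example, drives DDC to its lower bound).

**Two subsets, four maps.** The acquisition's 22 b values (0–5,000 s/mm²)
are fitted twice: once restricted to b ≤ 1,500 s/mm² (15 values, the
clinical range) and once over the full range. A subset must retain at least
4 b values — two parameters plus slack — or selection fails. Residuals are
unweighted by default; NEX-proportional weights are available
(`nex_weighting=True`) but the default mirrors the plain least-squares
convention. No Rician-floor correction or high-b truncation is applied by
default; at the simulated noise levels the floor only matters for
near-zero-signal voxels, and the option is a config switch rather than a
default behaviour.

## Synthetic phantoms

The phantom is a rectangular tissue block (background margin of one-eighth
of each dimension) split along x into three compartments with distinct
uniform parameter ranges:

| class | DDC (10⁻³ mm²/s) | α | fraction |
|---|---|---|---|
| normal-appearing | 0.7–0.9 | 0.85–0.95 | 0.50 |
| low-grade-like | 1.1–1.5 | 0.72–0.85 | 0.25 |
| high-grade-like | 0.7–1.1 | 0.50–0.68 | 0.25 |

High-grade-like tissue has the lowest α (greatest intravoxel heterogeneity)
and lower DDC than the low-grade-like compartment (denser cellularity
restricting diffusion); normal tissue sits near mono-exponential decay.
S(0) is uniform in 80–120 arbitrary units; background has S(0) = 0. The
default grid uses 1.875 mm in-plane pixels (24 cm field of view at 128×128)
and 4 mm slices; tests use smaller matrices at the same pixel size.

**Noise.** Magnitude (Rician) noise: each sample becomes
√((s + n₁)² + n₂²) with n₁, n₂ zero-mean Gaussians of scale σ₀/√NEX(b).
The default NEX schedule rises with diffusion weighting — 1 for b ≤ 600,
2 to 1,500, 3 to 3,000, 4 above — emulating protocols that average more
excitations where signal is weakest. Zero-signal voxels then follow a
Rayleigh distribution with mean σ·√(π/2), which the suite checks against
the simulated background at b = 5,000.

**Randomness.** Everything descends from one root seed through named
substreams (`SeedSequence(seed, spawn_key=(k,))` with a fixed name→k table:
truth 0, noise 1, targets 2, cohort 3, fields 4, reader 5), so any stage
can be re-run bit-identically in isolation.

## Synthetic specimen cohorts

Each biopsy target yields one specimen whose pathology indices are driven
by the mean (DDC, α) of the phantom truth inside the measurement ROI:

    pMIB-1 (%)            = clip(β₀ + β₁ · DDC·10³ + ε,  0, 100)
    CD34-MVD (vessels/mm²) = max(γ₀ + γ₁ · α + ε′, 0)

with ε, ε′ Gaussian. Defaults β₀ = 28, β₁ = −15, σ = 6 and γ₀ = 70,
γ₁ = −60, σ′ = 8 give proliferation indices of a few to ~20 % and vascular
densities of ~15–40 vessels/mm², and produce median cohort-level Spearman
correlations near −0.4 (DDC vs pMIB-1) and −0.55 (α vs CD34-MVD) at n = 32
— the moderate negative-association regime such biopsy studies report. The
negative slopes encode the expected biology: proliferative tumor restricts
diffusion, and dense microvasculature raises intravoxel heterogeneity
(lowers α).

WHO grade (II/III/IV) comes from two fixed thresholds on a latent
malignancy score z(−α) + z(−DDC), standardized within the cohort. The
default thresholds (−1.90, 1.65) are the pooled 18.75 % / 75 % quantiles of
that score over 60 independently simulated cohorts, so a default 32-specimen
cohort averages 6 grade-II, 18 grade-III and 8 grade-IV specimens, the mix
typical of biopsy series weighted toward high-grade disease.

Field-level measurements add the microscope's sampling noise: per-field
CD34 vessel counts are Poisson with mean MVD × field area (default
0.5 mm², a ×200 high-power field), and per-field MIB-1 positive fractions
are Beta-distributed with the specimen's mean and concentration 100. One
specimen per default cohort is generated without MIB-1 staining, so the
correlation table exercises per-row N bookkeeping (31 vs 32).

**What the synthetic studies do not show.** The phantom has no anatomical
shape, no partial-volume mixing at tissue boundaries, no T2/EPI contrast
effects or geometric distortion, and no registration or brain-shift error
between the coordinate on which the ROI is centered and the tissue actually
sampled. The pathology link is linear with additive noise, whereas real
links are unknown and possibly nonlinear. Passing tests therefore
demonstrate correctness of the computational chain and calibration of the
statistics — not clinical validity of the parameter–pathology associations.

## ROI extraction

The measurement ROI is an in-plane square centered on the recorded biopsy
coordinate. The side length (1–20 px) minimizes the difference between the
realized area and the 90–120 mm² target; because no integer square on the
1.875 mm DWI grid lands inside that window exactly (5 px → 87.9 mm²,
6 px → 126.6 mm²), a realized area within [85, 130] mm² is accepted with a
logged warning. Even side lengths center with the offset toward lower
indices. An ROI that would extend outside the volume is an error, never
silently clipped. ROIs are placed directly on the parameter-map grid; the
cross-grid resampling a scanner workflow would need (anatomical →
diffusion space) is out of scope since phantoms share one grid.

ROI means exclude NaN (unfitted) voxels and report the missing count. Two
readers are simulated — reader 2 duplicates reader 1 with additive Gaussian
jitter, per-parameter scales since DDC (~10⁻³) and α (~1) differ by three
orders of magnitude — and the per-target mean across readers feeds the
correlation analysis.

## Pathology indices

CD34-MVD is the pooled ratio Σ vessel counts / Σ field areas (vessels/mm²),
which is invariant to subdividing fields — the property the suite checks —
and differs from the mean of per-field densities when areas are unequal.
pMIB-1 is the mean per-field positive fraction × 100. The alternative
literal reading (raw positive-cell count per field) is available as
`pmib1(fields, mode="cells_per_field")` but is unbounded and not used by
default. Specimens with 3–20 fields are standard; counts outside that range
warn but are processed.

## Statistics

**Spearman's rho** is the Pearson correlation of midranks, which handles
the heavy ties of an ordinal grade variable. Significance uses the
t-approximation t = |ρ|·√((n−2)/(1−ρ²)) on n−2 degrees of freedom,
two-tailed — the method general statistics packages apply at these sample
sizes. Against the exhaustive permutation null at n = 6 the approximation
is within 0.02 of the exact two-tailed tail wherever the exact p ≤ 0.10;
at larger p the discrete null is too coarse for tighter agreement (worst
absolute deviation 0.048 over all 720 rank configurations). |ρ| = 1 returns
p = 0 with an exact-monotone flag. Correlation strength is binned on |ρ|:
≤ 0.40 little/fair, (0.40, 0.75] moderate/good, > 0.75 very good/excellent.

**ICC(2,1)** — two-way random effects, absolute agreement, single rater —
is computed from the mean squares of the subjects × raters layout:
(MSR − MSE) / (MSR + (k−1)·MSE + k·(MSC − MSE)/n). Identical raters give
exactly 1; independent raters center on 0. Agreement bins: < 0.40 poor,
0.40–0.60 moderate, 0.61–0.80 good, > 0.80 excellent. The implementation is
cross-checked against pingouin's ICC table in the suite.

**The correlation table** crosses the four SEM parameters with pMIB-1,
CD34-MVD and WHO grade (12 cells); pMIB-1 rows use only specimens with the
stain available, so their N can differ from the others. No multiple-testing
correction is applied across the 12 cells, and the report says so.

## Problem sizes

The suite fits phantoms up to 32³ voxels (≈ 14k tissue voxels × 2 subsets)
and draws 200 cohort replicates for sign-recovery checks; the acceptance
script uses the same sizes. These are large enough for the noiseless
roundtrip and Monte-Carlo bounds asserted, while keeping a full run in the
minutes range on a single core.

## Known limitations

- The vendor software used in scanner workflows does not disclose its
  bounds, initialization, or S0 handling; numerical agreement with any
  particular workstation's maps is not guaranteed.
- The Rician noise model assumes single-coil magnitude reconstruction;
  modern multi-coil reconstructions have different (noncentral-chi) noise.
- The ROI tolerance rule for discrete grids is this package's own
  convention; published studies rarely state how a continuous area window
  was realized on a pixel grid.
- WHO grading here is a deterministic function of the latent score;
  real grading has inter-observer variability the generator does not model.
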