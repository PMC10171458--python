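# semdwi

Stretched-exponential model (SEM) analysis of multi-b-value diffusion-weighted
MRI, with the radiology–pathology correlation layer used in biopsy-matched
glioma studies.

## The problem

Conventional diffusion MRI summarizes each voxel by a single apparent
diffusion coefficient (ADC), assuming mono-exponential signal decay. In
heterogeneous tissue such as glioma the decay is not mono-exponential: a
voxel contains a continuous distribution of diffusion environments. The
stretched-exponential model captures this with two parameters,

    S(b) / S(0) = exp[ −(b · DDC)^α ]

where **DDC** (distributed diffusion coefficient, mm²/s) is an ADC-like mean
intravoxel diffusion rate and **α ∈ (0, 1]** is the heterogeneity index —
α = 1 recovers mono-exponential decay, lower α means broader intravoxel
heterogeneity. Fitting the model over two b-value ranges (0–1,500 and
0–5,000 s/mm²) yields four parametric maps: DDC₁₅₀₀, α₁₅₀₀, DDC₅₀₀₀, α₅₀₀₀.

The package implements the full analysis chain for relating these maps to
histopathology at biopsy-verified coordinates:

1. **`synthetic_data`** — digital phantoms with known (DDC, α) ground truth
   on a 22-b-value acquisition (0–5,000 s/mm², NEX 1–4 rising with b,
   128×128 matrix geometry, 4 mm slices) with Rician magnitude noise, plus
   synthetic specimen cohorts whose pathology indices are monotonically
   linked to the local truth;
2. **`sem_fit`** — voxelwise bounded nonlinear least-squares fitting over
   both b-value subsets;
3. **`roi_extraction`** — square 90–120 mm² ROIs centered on recorded
   biopsy coordinates, with two-reader averaging;
4. **`pathology_quant`** — specimen-level CD34 microvascular density
   (pooled vessel count / total field area) and the MIB-1/Ki-67
   proliferation index (mean per-field positive percentage) from 3–20
   microscope fields per specimen;
5. **`correlation_stats`** — two-tailed Spearman correlations (midranks,
   t-approximation significance), ICC(2,1) inter-reader agreement, strength
   classification, and a formatted report table.

It is intended for imaging scientists who want a tested, reproducible
reference implementation of this pipeline — since patient data of this kind
are rarely shareable, every stage can be exercised end-to-end on synthetic
inputs with known truth.

## Worked example

```python
from semdwi import (BValueScheme, sem_signal, fit_voxel, spearman_pvalue,
                    make_phantom, make_biopsy_targets, make_specimen_cohort)

# significance of a rank correlation of -0.437 over 32 specimens
print(spearman_pvalue(-0.437, 32))
# 0.01238888053930021

# fit one voxel's noiseless stretched-exponential decay
scheme = BValueScheme.default()                    # the 22 b values, 0-5000
sig = sem_signal(100.0, 0.9e-3, 0.72, scheme.b_values)
r = fit_voxel(sig, scheme)
print(f"DDC = {r.ddc:.6g} mm^2/s, alpha = {r.alpha:.4f}, rss = {r.rss:.3g}")
# DDC = 0.0009 mm^2/s, alpha = 0.7200, rss = 2.78e-32

# a synthetic specimen cohort driven by local phantom truth
truth, dwi = make_phantom((32, 32, 6), seed=42)
targets = make_biopsy_targets(truth, n_targets=8, n_patients=6, seed=42)
for s in make_specimen_cohort(truth, targets, seed=42)[:3]:
    print(f"{s.specimen_id}: grade {s.who_grade}, "
          f"CD34-MVD = {s.cd34_mvd:.1f} vessels/mm^2, pMIB-1 = {s.pmib1:.2f}%")
# spec_000: grade 3, CD34-MVD = 29.7 vessels/mm^2, pMIB-1 = 10.48%
# spec_001: grade 3, CD34-MVD = 26.8 vessels/mm^2, pMIB-1 = 21.37%
# spec_002: grade 4, CD34-MVD = 37.8 vessels/mm^2, pMIB-1 = 3.19%
```

The first number is the two-tailed significance of a moderate negative rank
correlation at a 32-specimen sample size; the voxel fit recovers the exact
simulated (DDC, α) with a residual at machine precision; the cohort rows
show specimen-level pathology indices generated from the phantom's local
diffusion truth.

The same pipeline is available from the shell:

```bash
semdwi e2e --seed 7 --out run/     # simulate -> fit -> extract -> correlate
```

which prints a report table (rows pMIB-1 / CD34-MVD / WHO grades, columns
the four SEM parameters, cells rho / p / N with significance markers) and
writes `specimens.csv`, `correlations.csv`, `report.txt` and a run log.

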