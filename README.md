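# curtainkit

Simulation and analysis of single-molecule DNA-curtain experiments on UV
damage recognition, plus the protein–DNA binding equilibria that accompany
them.

## The scientific problem

In global-genome nucleotide excision repair, the UV-DDB heterodimer
(DDB1–DDB2) locates cyclobutane pyrimidine dimers (CPDs) among ~3×10⁹ bp
of undamaged genome, assisted by the damage sensor XPC-RAD23B. DNA-curtain
experiments watch individual quantum-dot-labeled proteins on flow-stretched
λ-DNA (48,502 bp) carrying a 3×CPD cassette at 33,513–33,630 bp, at roughly
1 kbp/pixel and a 600 s observation window. `curtainkit` packages the entire
quantitative pipeline behind such a study — with a synthetic-data generator
standing in for the microscope and the gel scanner, so every stage is
verifiable at desk scale:

- **1D diffusion** (`curtainkit.diffusion`): time-averaged MSD curves,
  MSD(t) = 2Dt + 2σ²loc, with a GLS-weighted short-lag fit; pooled
  displacement Gaussians (Brownian motion ⇒ center at 0); the
  sliding-vs-hopping call from the salt dependence of D; and the
  theoretical ceiling for rotation-coupled sliding,
  D_max = k_BT / {6πηR [1 + (4/3)(2π/p)²R² + (2π/p)²R²_OC]}.
- **Lesion search** (`curtainkit.lesion_search`): classification of lesion
  engagement (direct 3D collision vs arrival by 1D diffusion), bypass
  counting, the recognition efficiency
  Σ_b [1/(b+1)] · n_b/n_total · 100 (%), binomial standard deviations for
  mode fractions, and residence times right-censored by the observation
  window — both the conventional ("naive") histogram fit and the censored
  maximum-likelihood estimator τ̂ = Σ durations / #uncensored.
- **Position statistics** (`curtainkit.position_stats`): binding-position
  histograms with 70% percentile-bootstrap intervals, single-Gaussian peak
  fits with flat baseline, per-kbp lesion enrichment, binding-enhancement
  folds, and the genome lesion-burden arithmetic.
- **Equilibria** (`curtainkit.equilibria`): depletion-corrected single-site
  isotherms C = (S − √(S² − 4PD))/2 with S = P + D + K_d (DNA at 4–10 nM is
  comparable to K_d, so no Langmuir shortcut), EMSA K_d fitting, SPR
  steady-state fits RU(C) = RU_max·C/(K_d + C), and a coupled mass-action
  solver for the UV-DDB·XPC-RAD23B (UX) complex that makes the
  "complex loads UV-DDB onto DNA" model quantitative.
- **Kymographs** (`curtainkit.kymotrack`): rendering (Gaussian PSF, Poisson
  photons) and tracking (4σ Poisson detection, sub-pixel Gaussian fits,
  greedy nearest-neighbor linking).
- **FRAP** (`curtainkit.frap`): pre-bleach normalization, recovery at a
  fixed time, two-sample comparisons.

Fitting operations are scikit-learn-style estimators
(`MSDDiffusionEstimator`, `KdFitter`, `SprSteadyStateFitter`,
`GaussianPeakFitter`, `ResidenceTimeFitter`) and compose with sklearn
tooling; module functions are thin wrappers over them.

## Worked example

```bash
curtainkit report --seed 42 --out results/
```

runs the full simulate → analyze pipeline (50 sliding tracks, a 100-molecule
lesion-search experiment, a 300-event curtain snapshot, a noisy EMSA
ladder) and prints:

```json
{
  "diffusion": {
    "D_um2_s": 0.0253, "se_um2_s": 0.0007,
    "intercept_kbp2": 0.506,
    "displacement_center_kbp": -0.006
  },
  "search": {
    "fraction_direct": 0.19, "fraction_direct_sd": 0.039,
    "efficiency_percent": 95.3,
    "tau_naive_s": 746, "tau_mle_s": 976
  },
  "positions": {"peak_center_kbp": 33.52, "enrichment_fold": 23.3},
  "titration": {"kd_nM": 5.10, "kd_se_nM": 0.18}
}
```

Reading the numbers: the MSD fit recovers the generating diffusion
coefficient 0.025 μm²/s and an intercept ≈ 2σ²loc = 0.5 kbp²; the
displacement Gaussian centers at zero (Brownian sliding, no flow); 19% of
molecules bound the lesion directly; the bypass-weighted recognition
efficiency is ~95%; the censored-MLE residence time (976 s) sits above the
naive histogram fit (746 s), which is biased low because arrivals spread
through the 600-s window truncate long dwells; the binding-position peak
falls at the CPD cassette (33.5 kbp); and the fitted K_d matches the
generator's 5 nM UV-DDB/CPD affinity.

The same stages are available as `curtainkit simulate ...`,
`curtainkit analyze ...` and `curtainkit fit ...` subcommands over
TSV/JSON/YAML files, or directly as library calls.

## Acceptance script

```bash
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

recomputes, from freshly generated synthetic data, the fitted UV-DDB/CPD
and XPC-RAD23B/undamaged dissociation constants (median over 100 noisy
8-point titrations), the Gaussian center of a simulated curtain
binding-position histogram, and the empirical coverage of the 70%
percentile-bootstrap interval, and writes them as JSON keyed by target id.
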