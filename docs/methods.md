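# Methods

This note records the models implemented in `curtainkit`, their
assumptions, the defaults that matter, and the numerical choices that were
genuinely open.

## Coordinate and unit conventions

Positions are kbp from the barrier-tethered DNA end (0-based); times in
seconds; concentrations in nM. The λ genome is fixed at 48,502 bp and the
3×CPD cassette at 33,513–33,630 bp. Diffusion coefficients are reported in
μm²/s and converted to sequence units through the flow-stretch extension
factor e = 0.272 μm/kbp (≈80% of the 0.34 nm/bp B-form contour):
D_kbp² = D_μm² / e². The extension and the frame interval (default 0.1 s)
are not fixed by the source experiments and are exposed as configuration.

All randomness flows from one integer seed through named substreams
(SHA-256 of the stream labels → `numpy.random.SeedSequence` spawn key), so
adding a stage never perturbs another stage's draws and every generator is
bit-reproducible.

## Synthetic data: what it emulates and what it does not

`simulate_sliding_trajectory` draws per-frame displacements with variance
2·D·Δt, reflects at the DNA ends, and adds independent Gaussian
localization noise (default σ_loc = 0.5 kbp, half the ~1 kbp/pixel
resolution). `simulate_search_experiment` mixes a direct-binding population
(probability 0.19, the observed fraction without XPC-RAD23B) with
diffusive arrivals whose bypass counts are geometric with per-pass capture
probability q = 0.885 — chosen so the closed-form efficiency
−q·ln q/(1−q) equals the observed ≈94% — and exponential dwells
(mean 900 s, a plausible true value above the 600 s window, so censoring
is material) right-censored at the window. The *fast* mode draws these
quantities from their distributions and renders stylized tracks (for
testing statistics); the *explicit* mode integrates a real Brownian path
and applies per-pass capture to actual window crossings (for testing the
classifier). Ground-truth labels in explicit mode follow the observable
convention: an arrest is labeled *diffusion* only if the molecule had been
more than one pixel away from the lesion window beforehand, since
sub-pixel excursions are invisible at this resolution.

Not emulated: Qdot photophysics (blinking/bleaching), flow distortion,
multi-molecule crowding on one DNA, and any kinetics of protein exchange.
A green test therefore establishes correctness of the estimators under the
stated statistical model, not robustness to those instrument effects.

## MSD fitting and the diffusion estimate

The time-averaged MSD uses all overlapping ordered pairs per lag
(maximizes data at curtain track lengths). The linear fit
MSD = 2D·t + c runs over lag indices 1–10 by default (short lags avoid
reflecting-boundary and censoring bias) with weights n_pairs/k²: the
variance of the overlapping-pair estimator grows roughly as k²/n_pairs(k),
so these are GLS-approximate weights. The intercept estimates 2σ²_loc. D
is clipped at zero. Pooled results carry a bootstrap-over-tracks standard
error (1,000 resamples) because per-track D distributions are broad.

At the default noise level (σ_loc = 0.5 kbp, D·Δt = 0.0034 kbp²) a single
300-frame track carries limited information: the information bound puts
the per-track relative error near 16–20%, so individual estimates scatter
accordingly. The *population* estimate — the median of per-track D, or the
pooled-MSD fit — recovers the generating 0.025 μm²/s within a few percent,
and that is the quantity the recovery tests certify.

The displacement-Gaussian fit bins pooled displacements symmetrically
about their mean and falls back to the moment estimate (mean, sd) when the
least-squares solution is degenerate (sub-bin spike, flatter than the data
range, or off-histogram center — possible for discrete or bimodal inputs);
the fallback preserves the symmetry property that exactly symmetric data
yield the symmetry point.

The sliding/hopping call regresses D on NaCl concentration (weights
1/se²). Hopping requires a positive slope at 95% confidence *and* a fitted
relative increase above 25% across the range; sliding requires the
converse; anything else is inconclusive. The 25% threshold is not from any
measurement — it is a documented, configurable package choice.

The rotation-coupled ceiling D_max = k_BT/{6πηR[1 + (4/3)(2π/p)²R² +
(2π/p)²R²_OC]} takes the particle radius R, axis offset R_OC and helical
pitch p (default 3.57 nm) as explicit inputs; the hydrodynamic parameters
behind any particular published number are not guessed. Defaults: 23 °C,
η = 0.933 mPa·s (water at 23 °C).

## Lesion-search classification and residence times

*Arrest* is a contiguous run of ≥ 20 s (configurable; no operational
definition exists in the source experiments) within 1 kbp of the lesion
window padded to one pixel. Positions are rolling-median filtered (5
frames) first so isolated localization outliers do not split runs, and
within a qualifying run the arrest is dated from the first frame at which
the particle sits inside the padded window for ≥80% of the following
20 s — otherwise a molecule lingering near the lesion before engaging
would be dated from band entry. *Direct* means arrest within the first 2
frames of the track; *diffusion* requires having visited > 1 kbp outside
the window before arrest; *none* is never arrested. Bypasses are
enter–exit transits of the padded window before arrest. Arrests shorter
than the 20 s criterion (e.g. in the last seconds of the window) are
undetectable in principle; they dominate the few-percent disagreement with
explicit-simulation ground truth.

Residence times: the *naive* method least-squares fits a·e^(−t/τ) to the
histogram of uncensored dwells. Because molecules arrive throughout the
movie, each event has its own observation cap; discarding censored events
thins long-dwell bins preferentially, so the naive τ is biased low
whenever τ is comparable to the window — the implementation reproduces
that conventional procedure deliberately. The *mle* method is the censored
exponential maximum-likelihood estimator τ̂ = Σ(all observed
durations)/#uncensored with se τ̂/√#uncensored; when every event is
censored only the lower bound Σ durations is identified and the result is
flagged. Naive is the default for reproducing published-style numbers,
MLE for inference.

## Position histograms and peak fits

Histograms use 1-kbp bins (one pixel) over [0, L]. Per-bin confidence
intervals are percentile bootstrap at 70% (15th/85th percentiles), the
level used throughout; the bootstrap resamples positions with replacement,
implemented by drawing multinomial(n, observed bin proportions) — exactly
the position bootstrap projected onto bins, and much faster. The interval
is clamped to bracket the observed count. Peak fits are least-squares
single Gaussians with a flat baseline absorbing uniform nonspecific
binding (toggleable; a strict single Gaussian is biased by background).
Lesion enrichment compares per-kbp densities inside the [32, 36] kbp
window against the rest of the molecule.

## Binding equilibria

DNA totals (4–10 nM) are comparable to the dissociation constants, so all
isotherms use the exact depletion quadratic (Hill coefficient fixed at 1).
The coupled UX model solves U + X ⇌ UX, U + D ⇌ UD, X + D ⇌ XD,
UX + D ⇌ UXD (optionally UD + U ⇌ U2D for the 2× band) by trust-region
least squares on log free concentrations, to mass-balance residual
< 10⁻⁹; an independent test oracle reduces the same system to one root in
free DNA. Defaults encode the measured hierarchy — K_d(U·CPD) = 5 nM,
K_d(U·und) = 26 nM, K_d(X·CPD) = 7 nM, K_d(X·und) = 9 nM. The
protein–protein K_d is experimentally only bounded as tight ("minimal
dissociation" by SPR) and defaults to 1 nM; the UX complex binds DNA with
its tighter subunit's K_d for that substrate (policy configurable to any
number). The enhancement fold is defined as the experiment measures it —
DNA-bound U with the partner present over without — so in the weak-complex
limit it tends to 1 only when DNA is in excess; at comparable totals,
plain competition for DNA drives it slightly below 1. The equilibrium
model reproduces the end-state asymmetry (X loads U, U does not load X);
order-of-addition effects and sub-stoichiometric recycling are kinetic
phenomena outside its reach, deliberately.

## Kymograph rendering and tracking

Rendering integrates a Gaussian PSF over pixels (error-function
differences), adds uniform background, and applies Poisson noise.
Detection thresholds at background + 4√background (Poisson 4σ); sub-pixel
localization is a least-squares 1D Gaussian on a 7-pixel window with ties
broken toward the lower pixel index; linking is greedy nearest-neighbor
with a hard maximum jump (default 3 px) and single-frame gap closing —
appropriate for the single-particle, low-density curtain regime, and
validated only against synthetic ground truth.

## FRAP

Traces are normalized to the mean pre-bleach intensity (≥3 pre-bleach
frames required) and compared by the interpolated recovery at 120 s;
traces shorter than the query time raise rather than extrapolate (the
1-minute acquisition of the emulated assay cannot support a 120-s
statistic; synthetic traces are simply generated longer). Group
comparisons default to the equal-variance two-sample t-test, with Welch
available.

## Known limitations

- The arrest criterion, direct-vs-diffusion boundary and sliding/hopping
  threshold are package definitions, stated above, not inferred from data.
- Recognition-efficiency and residence-time results inherit the event
  classifications; mislabeled short arrests propagate.
- The equilibrium solver addresses end states only.
- Bootstrap intervals are percentile (not BCa); their finite-count
  coverage is certified empirically (~70% at nominal 70%) rather than
  theoretically.
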