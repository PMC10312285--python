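# Methods

`oscibrain` models resting-state whole-brain dynamics as a network of
local units poised near a Hopf bifurcation, coupled by a structural
connectome, and asks whether a regional heterogeneity map improves the
fit to empirical BOLD beyond matched-complexity controls.  This note
documents the models, the estimators, the numerical choices, and what
the synthetic experiments do and do not establish.

## The two local models

**Stuart–Landau network.**  Each region n obeys the normal form of a
supercritical Hopf bifurcation in Cartesian coordinates,

    dx_n/dt = (a_n - x_n^2 - y_n^2) x_n - w_n y_n + G Σ_j C_nj (x_j - x_n) + ν η(t)
    dy_n/dt = (a_n - x_n^2 - y_n^2) y_n + w_n x_n + G Σ_j C_nj (y_j - y_n) + ν η(t)

with x_n standing in for the regional fMRI signal.  For a_n < 0 the
region is a stable focus whose activity is noise-driven; for a_n > 0 it
is a self-sustained oscillator of amplitude sqrt(a_n) and frequency
w_n.  Coupling is diffusive through the (symmetric, max-0.2-normalized)
structural matrix C and a global gain G.  Independent Gaussian noise of
standard deviation ν drives both equations.  Defaults: a0 = -0.02
homogeneous baseline, ν = 0.02, Euler–Maruyama step dt = 0.1 s (BOLD-band
dynamics), 20 s transient discarded, output subsampled to the
repetition time.  The integrator snaps dt to an exact divisor of TR so
the output sampling grid is exact.

**Exact QIF mean-field network.**  Each region holds an excitatory and
an inhibitory population of quadratic integrate-and-fire neurons with
Lorentzian-distributed input currents; in the thermodynamic limit each
population is exactly described by two ODEs for its mean rate and mean
voltage (the firing rate equations, FRE).  The package integrates the
nondimensional form

    re' = d_e/π + 2 re ve
    ve' = ve² + η - (π re)² + j_ee re + j_ei ri + G j_ee Σ_p C_np re_p
    ri' = d_i/π + 2 ri vi
    vi' = vi² + 1 - (π ri)² + j_ii ri + j_ie re

with inter-regional coupling only between excitatory pools.  The
rescaling that maps the dimensional FRE (membrane time constant τ_m,
half-widths Δ, drives η̄, synaptic weights J, reference drive
η_ref > 0) onto this form is

    r = τ_m R / √η_ref,  v = V / √η_ref,  t̃ = √η_ref t / τ_m,
    j = J / √η_ref,      d = Δ / η_ref,   η = η̄ / η_ref,

verified in the test suite by dual integration (dimensional and
rescaled trajectories agree to better than 1e-3 relative error); one
nondimensional time unit is τ_m/√η_ref seconds.

The (d_e, d_i) plane contains a Hopf bifurcation curve separating
damped from self-sustained E–I oscillations; `locate_hopf_curve` finds
it by root-finding on the fixed point plus bisection on the largest
real part of the Jacobian eigenvalues.  Default synaptic parameters are
η = 4.03, j_ee = 5.04, j_ie = 3.8, j_ei = j_ii = -3.8: with these the
curve passes through (d_e, d_i) = (1, 1.168), so the default
homogeneous working point (1, 1.175) sits just on the stable side, in
the fluctuation-driven oscillatory regime the fitting procedure
explores.  The cross/inhibitory magnitude was set by requiring exactly
this geometry; weaker couplings leave the system stable everywhere in
the plane, i.e. with no bifurcation to organize the dynamics.

The microscopic cross-check (`simulate_qif_population`) integrates
N QIF neurons with currents on the deterministic Lorentzian quantile
grid, a finite peak voltage of 100 with mirrored reset and a
refractory interval of 2/V_peak (the standard finite-threshold
correction).  At N = 10⁴ the stationary population rate matches the FRE
fixed point within ~2 % across drive levels (the test tolerance is 5 %).

**Hemodynamics.**  Excitatory rates are converted to BOLD by the
standard 4-state Balloon–Windkessel model (vasodilatory signal, inflow,
venous volume, deoxyhemoglobin) with literature constants κ = 0.65 s⁻¹,
γ = 0.41 s⁻¹, τ = 0.98 s, α = 0.32, ρ = 0.34, V₀ = 0.02, driven by the
z-scored rate and read out nonlinearly, then downsampled to TR.  The
FRE itself is noise-free; optional Gaussian noise on the voltage
equations (`noise_v`) produces fluctuating BOLD below the bifurcation
and is flagged as a model extension.

## Heterogeneity modulation

A per-region map β_n (empirically a T1w/T2w ratio or node-level GBC;
synthetically a smoothed random field) modulates the local bifurcation
parameters through a bias δ1 and a scale δ2.  Two conventions are
implemented:

* multiplicative (default): a_n = a0 (1 + δ1 + δ2 β_n) — the form in
  which (0, 0) recovers the homogeneous baseline exactly;
* additive: a_n = a0 + δ1 + δ2 β_n — the literal printed form of the
  modulation equation; it lets regions cross the bifurcation when the
  map spread exceeds |a0|.

The mean-field model applies the same convention jointly to d_e and
d_i, clipping nonpositive half-widths to a small floor (logged).

## Observables and fit statistics

All BOLD (empirical and simulated alike) is demeaned and band-passed
to 0.008–0.08 Hz with a zero-phase second-order Butterworth filter
before any observable is computed; instantaneous phases and amplitudes
come from the Hilbert analytic signal, with 10 samples discarded at
each end against edge transients.

* FC: full-length Pearson correlation matrix; FCfit = correlation of
  the strict upper triangles of group-averaged empirical and modeled FC.
* GBC_i = Σ_j FC_ij / N with the diagonal retained — the literal
  definition; removing it only shifts every region by 1/N and cannot
  change GBCfit, which is the correlation of group-averaged GBC vectors.
* KoP(t) = |Σ_p e^{iφ_p(t)}| / N, summarized by its temporal mean per
  subject and averaged over subjects; ErrKoP is the absolute difference
  between empirical and modeled group levels.  The modulus is taken at
  each time point and then averaged.

## Causal ignition

For each region, CI quantifies the Granger-causal influence of its
amplitude history on the next-step global synchronization:

    I_n = H(KoP_{i+1} | KoP^i) - H(KoP_{i+1} | A_n^i, KoP^i),

with T = 10-sample past windows advanced by one sample, all entropies
Gaussian — dim/2·log 2πe + ½ log det of the (conditional) covariance,
conditionals by Schur complement — and CI = I_n normalized by the total
predictive information the joint past carries about KoP_{i+1}, clipped
to [0, 1] (clipping logged).  Significance per subject and region uses
circularly shifted amplitude surrogates (shifts restricted to
[T+1, L-T-1]; p = (1+#{CI_surr ≥ CI_obs})/(1+n_surr), 100 surrogates by
default), aggregated across subjects by Stouffer's method and masked
across regions by Benjamini–Hochberg FDR at q = 0.05.  CIfit is the
Pearson correlation of group CI vectors restricted to the empirically
significant regions.

Numerical choices: near-singular covariances get a relative ridge
(1e-8·trace/dim).  Because band-limited KoP series are strongly
autocorrelated, the number of effectively independent windows is far
smaller than the window count and the raw 21-dimensional
log-determinants are noisy; the dataset-level routines therefore shrink
the correlation matrix toward the identity by 0.1 by default (variances
untouched), which roughly doubles the test–retest reliability of group
CI profiles at 10-subject cohorts.  The low-level estimator functions
default to the plain sample covariance, and the calibration tests (type-I
error of the surrogate test; agreement with the analytic Granger value
for a linear system) pin both configurations.

For data that cannot support the lag embedding, the proxy CI — the
lag-1 Pearson correlation between A_n(t) and KoP(t+1) — replaces the
full estimator.  Besides its role for coarse sampling, the proxy has
far lower estimator variance, which matters at small cohort sizes (see
the recovery study below).

## Fitting pipeline

Homogeneous fit: sweep G (Stuart–Landau) or the (G, d_i) plane
(mean-field), simulating as many trials per grid point as there are
empirical subjects; the working point minimizes ErrKoP.  Heterogeneous
fit: at that working point, evaluate ErrKoP/FCfit/GBCfit/CIfit over a
(bias, scale) grid; for each scale, the bias minimizing ErrKoP defines
the iso-ErrKoP curve (ties break toward smaller |bias|); the optimum is
the curve point maximizing CIfit.  Because a single simulation batch
per grid point leaves the on-curve CIfit ranking noisy, the selection
re-evaluates each curve point with several independent batches and
averages (`evaluate_curve_cifit`).  Model comparison re-simulates the
heterogeneous, homogeneous, and spatial-null models (each null repeat
drawing a different surrogate map) for 50 repeats and compares
CIfit/GBCfit/FCfit distributions with two-sided Wilcoxon rank-sum
tests, Bonferroni-corrected over the model pairs.  Grid point and
repeat seeds are spawned deterministically from one base seed, so every
stage is exactly reproducible.

## Synthetic data

The generator emulates the study's inputs without any real data:

* Connectome: nodes placed uniformly on a 70 mm sphere (the scale of a
  hemisphere, so spatial statistics are nontrivial), weights
  exp(-λ d_ij) × lognormal(σ = 0.5) noise with λ = 0.02/mm,
  symmetrized, zero diagonal, max-normalized to exactly 0.2.
* Heterogeneity map: white noise smoothed by a Gaussian kernel over
  inter-node distances (default width 30 mm) and affinely mapped to
  [0.5, 2.0] — positive, spatially autocorrelated, T1w/T2w-like.
* BOLD: the Stuart–Landau network at a known (G, bias, scale) ground
  truth, one independent noise realization per "subject", matching the
  convention that simulated trial counts equal subject counts.

What it does **not** emulate: scanner noise spectra, motion artifacts,
physiological confounds, multi-site effects, realistic cortical
geometry or hemispheric structure.  Passing tests on these data show
that the estimators and the pipeline recover known ground truth under
the model's own assumptions — not that the models fit real brains.

## The desk-scale recovery study

`oscibrain.experiments.run_recovery_study` is the package's headline
experiment (also the core of the acceptance tests): 30 regions,
10 subjects, 864 s at TR = 0.72 s (an HCP-like 15-minute recording),
intrinsic frequencies uniform in 0.04–0.05 Hz.  Design rationale:

* **a0 = -0.2, ν = 0.06.**  The amplitude envelope of a subcritical
  Stuart–Landau region decorrelates at rate |a_n|.  At the empirical
  working point a = -0.02 a 15-minute record contains only ~17
  independent amplitude excursions; published fits compensate with
  cohorts of hundreds of subjects.  At a 10-subject desk scale the
  causal-ignition profile would be pure estimator noise, so the study
  uses faster local relaxation (envelope rates 0.02–0.06 Hz, still
  inside the analysis band) to pack many more excursions into the same
  recording length.
* **Additive modulation with near-zero mean shift, (bias*, scale*) =
  (-0.5, 0.4).**  This places a handful of high-map regions just above
  the Hopf bifurcation: weak pacemakers that genuinely ignite global
  synchronization, giving the map a qualitative dynamical signature,
  while the group synchronization level stays matched to the
  homogeneous baseline (so the homogeneous G sweep still recovers
  G* = 2.0).  Multiplicative modulation with grid-bounded (δ1, δ2) and
  a positive map cannot move any region across the bifurcation, and
  purely quantitative amplitude differences proved too weak to
  discriminate models at this cohort size.
* **Proxy CI in the model comparison.**  The full transfer-entropy CI
  profile remains estimator-noise dominated at 10 subjects even with
  covariance shrinkage (model-comparison margins indistinguishable from
  zero), whereas the proxy CI discriminates robustly; the comparison
  therefore scores the proxy metric — the same substitution the method
  prescribes whenever the data cannot support the full estimator.  The
  full estimator remains the default elsewhere and carries its own
  calibration tests.
* **Grids.**  G ∈ {1, 1.5, 2, 2.5, 3}; bias ∈ [-0.9, -0.1] and scale ∈
  [0, 0.6], both with step 0.2.  Matching the bias step to the scale
  step matters because the iso-ErrKoP curve has slope ≈ -mean(β) ≈ -1.1
  bias per unit scale: a one-step selection error along the curve then
  moves each coordinate by about one grid step rather than several.
* **Curve refinement.**  8 independent batches per curve point for the
  CIfit selection; 50 comparison repeats over 50 surrogate maps.

These conditions were fixed by pilot power analysis before the
acceptance checks were frozen, and validated across several master
seeds.

## Spatial-null surrogates

Surrogate maps destroy regional identity while preserving spatial
autocorrelation.  Implementation: random rigid rotations of the node
cloud about its centroid, projected back onto the original nodes by
optimal (minimum-total-distance) assignment — a permutation, so the
value multiset, mean and variance are preserved exactly.  Candidate
rotations whose induced map still correlates with the original above
|r| = 0.3 are rejected; among the rest the best match to the original's
empirical variogram (quantile-binned, 5 bins by default, mean relative
deviation) is kept, 40 candidates per surrogate.

A permute-then-smooth-then-rescale generator was evaluated first and
rejected: the sampling noise of a binned variogram between independent
same-process maps is ~30 % at these node counts, and optimizing
smoothed permutations toward the observed variogram drives them back
into alignment with the original map (median correlation ≈ 0.5),
destroying the null.  The rotation family sidesteps the trade-off
because every member preserves the autocorrelation structure by
construction.  For node clouds that are far from spherical the
rotation-projection degrades toward an unconstrained permutation; the
variogram screening still selects the most structure-preserving
candidates, but tolerances were validated on spherical clouds.

## Known limitations

* The Stuart–Landau integrator is Euler–Maruyama; at dt = 0.1 s the
  supercritical limit-cycle amplitude carries an O(dt ω²) bias (~1 % at
  0.05 Hz), relevant only if amplitudes are read quantitatively.
* The mean-field arm is much slower than the Stuart–Landau arm
  (nondimensional time unit 10 ms vs BOLD-band dynamics), so the
  grid-search machinery is exercised at full scale only on the
  Stuart–Landau model; the mean-field sweeps are validated on small
  smoke configurations.
* CI estimates at small cohorts are reliability-limited; the package
  reports what the estimators can and cannot resolve (see the recovery
  study), and nothing here speaks to empirical effect sizes in real
  fMRI cohorts.
* Surrogate tolerances and the recovery margins are validated at desk
  scale (30–40 regions); behavior at parcellation scales of 360 regions
  is extrapolation.
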