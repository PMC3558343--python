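# Methods

## Model

Probe-level log2 expression along one chromosome × strand is modelled as

    Y = X B + E,    E_i(t) ~ N(0, σ²) iid,

with `Y` (N arrays × T probes), `X` (N × q) the design matrix, and row m of
`B` the effect function β_m(t) of genomic probe index t. Probes are assumed
(approximately) equally spaced; each chromosome × strand is an independent
signal. After the orthonormal discrete wavelet transform `D = Y Wᵀ`, the
working model per coefficient (scale j, location k) is

    D(j,k) | β*(j,k) ~ MVN(X β*(j,k), I σ²(j,k)),
    β*_m(j,k) | τ_m(j,k) ~ N(0, τ_m(j,k) σ²(j,k)).

The normal prior on the wavelet coefficients of the effect functions
produces ridge-type shrinkage: with an orthonormal design (X″ᵀX″ = I_q) the
posterior mean of β*_m is τ/(1+τ) times the least-squares coefficient and its
variance is σ²τ/(1+τ). Back-transforming the posterior means gives denoised
effect functions; because the inverse DWT is linear and posteriors are
independent across (j,k), pointwise variances are obtained by propagating
the coefficient variances through the squared synthesis weights. The error
covariance is restricted to I·σ²(j,k) in the wavelet domain; probe-domain
correlation is represented implicitly through scale-dependent σ².

## Designs

* **Two-group**: intercept plus ±1 dummy coding; the fitted between-group
  difference is twice the second effect function. The coding gives
  XᵀX = diag(N, N) for balanced groups.
* **Time-course**: orthogonal polynomials of the design time points, built
  by QR decomposition of the Vandermonde matrix of centered times, so
  unbalanced and non-equidistant layouts are handled uniformly. The
  unnormalized coding rescales each orthonormal column by its
  smallest-magnitude nonzero entry, which reproduces the classical integer
  contrast tables on balanced equidistant designs ((1,1,1), (−1,0,1),
  (1,−2,1) with XᵀX = diag(3,2,6)); the fitted model always uses the
  normalized coding, and coefficients are mapped back through the stored
  column scales, so this rescaling is presentational only.
* **Helmert contrasts** for unordered factors: contrast j is −1 on the
  first j groups and +j on group j+1, giving XᵀX =
  diag(N, Σ_{i≤2}N_i, 2Σ_{i≤3}N_i, …). Orthogonality (and hence the
  diagonal form) requires balanced group sizes; unbalanced factors should
  be fitted through the QR route instead.
* **Circadian**: first-harmonic Fourier coding [1, sin(2πt/P), cos(2πt/P)]
  with explicit period P; full-cycle equally spaced designs give
  XᵀX = diag(N, N/2, N/2) (equal to diag(N, q, q) when there are exactly two
  replicates per time point). Higher harmonics are out of scope.
* **Custom / multi-factor**: any full-column-rank matrix is QR-decomposed
  (X = X_orth · X_tri, positive diagonal of X_tri for backend-independent
  reproducibility); the model is fitted on X_orth and posteriors are mapped
  back by X_tri⁻¹, with covariance X_tri⁻¹ V X_tri⁻ᵀ. Rank deficiency is
  reported with the offending column.

Normalization divides each column by its norm, recording the scales so every
effect is always reported on the original coding (e.g. the linear time
effect at probe t is β̂₁(t) × ψ₁(time)).

## Estimation

Hyperparameters are estimated by marginal maximum likelihood. With
P = X″X″ᵀ (a rank-q projection), the marginal at one coefficient is
D ~ N(0, σ²(I + τP)), and one Gauss–Seidel sweep is

    σ² ← (‖D‖² − τ/(1+τ)·‖X″ᵀD‖²) / N
    τ  ← ( ‖X″ᵀD‖² / (q σ²) − 1 )₊

This is exact coordinate ascent on the marginal likelihood, and the fixed
point matches a dense two-dimensional grid search (tested). The subtraction
of 1 in the τ update enforces the moment identity E‖X″ᵀD‖² = qσ²(1+τ).
Per-effect smoothing uses the columnwise analogue with c_m = (XᵀX)_mm:
the effective shrinkage parameter is t_m = τ_m c_m with moment estimate
(c_m b_m²/σ² − 1)₊.

**Pooling.** By default τ and σ² are shared by all locations k within a
scale j (level-wise empirical Bayes). With only N (often ≤ 6) observations
per coefficient, fully local plug-in estimates are so variable that the
resulting posteriors are overconfident — in null simulations roughly 2–3 %
of probes were called at δ = 0.2 — whereas level-wise sharing calibrates the
null to essentially zero false regions while leaving effect recovery
unbiased. The fully local fixed point (`pool="none"`) remains available and
is the form all per-coefficient primitives and oracle tests use.

Numerical choices: σ² is floored at 1e−12 (noise-free inputs would otherwise
drive τ̂ → ∞ through a zero denominator); convergence is declared when the
maximum relative hyperparameter change drops below 1e−6 (default), with a
budget of 100 sweeps; non-convergence is recorded on the fit, not fatal.
Initialization: σ² from the per-location OLS residual variance, τ from one
application of the moment estimator. `smoothing="none"` disables shrinkage
entirely (posterior = OLS), which is used for oracle comparisons.

## Wavelet transform

Haar by default — the hierarchical model treats coefficients generically,
and Haar keeps worked examples hand-checkable; any orthogonal Daubechies
family is available. Signals whose length is not a power of two are extended
by symmetric reflection to the next power of two; the periodized transform
is then exactly orthonormal, and the synthetic positions are dropped on
inversion and excluded from inference and region calling. Decomposition
depth defaults to the full log2 of the padded length. Large genomic gaps
between probes are not modelled at the transform level; region calling
handles them through its gap rule.

## Inference

Four modes, gated by the fitted design: `compare` (fitted mean difference of
two groups/time points — any replicated design), `means` (fitted per-group
expression, for annotation-free transcript discovery), `effects` (a single
polynomial coefficient function, time designs only), `circadian` (the
amplitude A(t) = √(β_sin² + β_cos²), Fourier designs only).

For linear effect combinations the posterior of F(t) = fᵀβ(t) is normal with
variance from the independent per-effect posteriors (orthonormal designs) or
the triangular-mapped covariance (QR designs). Overexpression calls use the
local false-call probability P(F(t) < δ | Y) = Φ((δ−mean)/sd);
underexpression uses P(F(t) > −δ | Y); both directions are reported
separately, plus a two-sided minimum. Zero posterior sd is treated as a
point mass.

The amplitude depends non-linearly on its components, so its tail is
approximated by Monte Carlo: draw n_sim pairs from the component posteriors,
form A_sim(t), and use the proportion of draws below δ. In the
equal-variance case this matches the noncentral-χ²₂ closed form (tested at
3 binomial standard errors).

**Bayesian FDR.** Significance is declared by the direct-posterior-
probability rule: sort local probabilities ascending and keep the largest
prefix whose running mean stays ≤ α (default 0.05). The declared set is
implemented as a threshold set — probes with identical local probabilities
enter or leave together — which coincides with the plain prefix rule
whenever probabilities are distinct and avoids arbitrarily admitting a few
certain-false probes when many point-mass posteriors are present. Thresholds
δ default to |log2 1.2| for differential calls and log2 1.1 for circadian
amplitude; `means` mode has no defensible default and requires an explicit
δ (an empirical-quantile helper can be built from the track, but that is a
convenience, not a calibrated procedure).

## Regions

Runs of significant probes are merged across insignificant gaps of at most
`max_gap_bp`, measured from the end (start + probe length) of the last
significant probe to the start of the next; the default is twice the median
probe spacing. Runs with fewer than `min_probes` (default 4) significant
probes are dropped. A region spans from its first probe start to its last
probe start plus the probe length. Coordinates are 0-based half-open
internally and in BED output; GFF3 output is 1-based closed. Strands are
never merged.

Annotation mapping retains genes whose basepair overlap with called regions
reaches `min_overlap_fraction` (default 15 %) of the gene length,
strand-aware by default. Unannotated-region extraction keeps called regions
of at least `min_length_bp` (default 200) with zero overlap with the
annotation padded by `exclusion_margin_bp` (default 500) on both sides — the
padding operationalizes "near a gene or its promoter"; by default a gene on
either strand excludes a region (set `stranded=True` to allow antisense
candidates).

## Synthetic data

The generator draws from exactly the working model: equally spaced probes
(35 bp spacing, 25 bp probes by default), a baseline level (6.0 log2 units)
plus boxcar bumps on chosen effect columns, and iid Gaussian noise
(σ = 0.3 by default, the scale of replicate variability in log2 intensity
data; study conditions use 3+3 arrays for two-group runs and a planted
1.0-log2 difference over 128 of 1024 probes). Bump amplitudes are specified
as the natural effect per role — the between-group difference for
`group_diff` (the ±1-coded coefficient is half of it), the amplitude A with
a phase for circadian `amplitude`, the raw column coefficient otherwise.
Optional half-cosine tapers probe boundary-localization behaviour; an AR(1)
noise flag exists for robustness experiments only.

What passing tests do and do not show: the generator matches the model's
assumptions (iid Gaussian noise, exactly piecewise-constant effects, no
probe-affinity or GC effects, no spatial artifacts, no cross-hybridizing
probes), so simulation results certify the correctness and calibration of
the machinery under its own assumptions, not its robustness on real arrays;
real-data preprocessing (CEL import, normalization, probe remapping) is out
of scope and delegated to array-platform tooling.

Benchmark problem sizes (T = 1024, N = 6, 20–50 replicates) are the
package's standard quick-calibration settings; all seeds are explicit.

## Known limitations

* Helmert designs must be balanced to retain estimation orthogonality.
* Plug-in empirical-Bayes posteriors ignore hyperparameter uncertainty;
  level-wise pooling mitigates but does not remove this.
* Common smoothing with scale pooling shrinks all coefficients of a scale
  equally, which can over-smooth very sparse signals on long chromosomes;
  use `pool="none"` (spatially adaptive, less calibrated) in that regime.
* One Fourier harmonic only; heteroscedastic per-array variances, covariates
  varying along the genome, heavy-tailed priors and MCMC are non-goals.
* The probe-equal-spacing assumption is not checked at the transform level;
  chromosomes with very uneven probe density should be split beforehand.
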