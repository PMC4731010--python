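# Methods

This note documents the models, the parameter choices behind the
package's defaults, the numerical decisions, and what the synthetic-data
based tests do and do not establish.

## Equilibrium crosstalk model

The core object is the equilibrium transcription rate of an
AHL-responsive promoter read out ratiometrically in relative promoter
units (RPU).  Two receiver proteins (LuxR, LasR) bind two signals
(3OC6HSL, 3OC12HSL) with association constants `KR6, KR12, KS6, KS12`
(1/nM); signal-bound monomers dimerize; dimers bind the promoter with
constants `KGR, KGS`; the promoter transcribes at `a0` when free and at
`a1R` / `a1S` when bound by a LuxR- / LasR-derived dimer.  Intracellular
receiver abundances enter as `r` and `s`, expressed relative to
constitutive expression from the weak pCat promoter — `r = 1` *defines*
the unit, which also resolves the exact confounding of `(KGR, r)`: only
`KGR·r²` is observable, so `KGR` is calibrated at pCat-level expression.

Two renderings of this model exist:

* **Closed form** (`simplified_rate`): the algebraic expression obtained
  when the growth-dilution of molecular complexes is neglected, with
  occupancy weights `W = KG·level²·(K6ⁿC6ⁿ + K12ⁿC12ⁿ)/(1 + K6C6 +
  K12C12)ⁿ` per receiver arm.  All inference and optimization uses this
  form.
* **Full mass-action network** (`full_equilibrium_rate`): 15 species
  (free receivers, monomer–signal complexes, dimers, free and bound
  promoter) with one common binding forward rate `kf` and reverse rates
  `kf/K` — only equilibrium ratios are identifiable from equilibrium
  data, so the forward timescale is a convention.  Zero-order production
  of receivers and promoter balances dilution at rate γ, which forces
  total promoter to `production/γ` at steady state.  The network
  realizes cooperativity `n = 2` mechanistically (dimerization), so it
  refuses other values of `n`.

The steady state is found by collapsing the network exactly onto the
three free species (R, S, G) — every complex satisfies a closed-form
balance given those three — and root-finding the three conservation
relations in log-space, followed by verification of the full 15-species
residual (scaled max-norm below 1e-10 relative to the dominant flux).  A
stiff-integration + polish fallback exists but is not normally reached.

**Regime of agreement.**  The closed form neglects (i) dilution of
complexes relative to their unbinding (`kf/K ≫ γ`), (ii) sequestration
of receiver monomers into dimers and promoter complexes, and (iii)
promoter-bound regulator relative to total regulator.  The defaults
(γ = 1e-4/min, kf = 10/(nM·min), dimerization constant 1e-4/nM, total
promoter 0.01 nM, receiver scale 10 nM per pCat unit) keep all three
corrections ≲1%, and the oracle test verifies closed-form agreement
within 5% over a 10×10 log-grid of doses spanning 0.1 nM – 25 µM for 20
random parameter sets.  When the promoter pool is made comparable to the
receiver pool the two models genuinely diverge (sequestration), which is
a property of the chemistry, not a solver artifact.

**Cooperativity `n`.**  The machinery treats `n` as an inferable shared
parameter with prior support (0.5, 4), and the standard fitting plan
leaves it free; the mass-action oracle pins it at 2.  In recovery tests
the posterior concentrates tightly at the generating value 2.

## Reference parameter regime

Appendix-level parameter tables are not reproduced here; instead
`defaults.py` defines a self-consistent regime chosen to exhibit the
system's characteristic magnitudes: wild-type pLux responding maximally
at ~10 RPU under weak receiver expression with ~0.7 RPU residual genetic
crosstalk; LuxR ~10²-fold selective for 3OC6HSL; LasR ~10⁶-fold
selective for 3OC12HSL; pLux76 with >10-fold reduced LuxR affinity and
LasR affinity set to zero; pLas81 with ~10-fold increased LasR affinity
and ~100-fold reduced LuxR affinity.  These serve as generating truths
for recovery tests and as the fitted-regime inputs to the optimizer and
simulator; absolute values are the package's own calibration and are
documented as unanchored to any measured table.

## Ratiometric activity extraction

ρ = deYFP/deCFP is estimated as the ratio of the two channels'
accumulation rates over an analysis window, each rate fitted by OLS
against time.  Regressing one noisy fluorescence channel directly on the
other was rejected: noise in the regressor attenuates the slope
(errors-in-variables), visibly biasing ρ at realistic noise.  Time is
noise-free, so per-channel slopes are unbiased and their ratio is exact
under local linearity.

Standard errors combine the two slopes' heteroscedasticity-robust (HC3)
variances by the delta method — multiplicative measurement noise makes
residual variance grow with the signal, which homoscedastic OLS errors
understate — and carry a t/z small-sample factor so that ±2·stderr
approximates a 95% interval at window sizes of a few dozen points.

The window is the most linear stretch of the expected accumulation
shape, found by maximizing regression R² over sliding windows of one
third of the series.  The shape is taken from the integrated OD channel
when present (and from a lightly smoothed reference channel otherwise):
integrated OD shares the reference's shape (both integrate growth
capacity) but its noise is independent of the fluorescence channels.
Selecting the window on the raw reference trace conditions the window on
the very noise the regression must average over and measurably biases ρ;
this was observed directly in calibration runs.  Calibration on 200
noisy synthetic wells lands 97–99% of estimates within 2 stderr of
truth across seeds.

## Inference

Likelihood: Gaussian on replicate-mean ρ with per-point standard
deviation `max(sd/√n, 0.1·|prediction|, 1e-3)`.  The 10% multiplicative
floor absorbs between-day variability that within-plate replicate
scatter understates; it makes posteriors mildly conservative, which is
the right direction for coverage statements.  Priors are log10-uniform
over broad ranges (association constants 1e-6–1e2 /nM, rates 1e-3–1e4
RPU, levels 1e-2–1e2).

Sampling: affine-invariant ensemble with 4×(free-parameter count)
walkers (minimum 16), initialized in a small ball around a multi-start
Nelder–Mead MAP estimate.  Moves are a 0.8/0.2 mixture of
differential-evolution and DE-snooker proposals — plain stretch moves
mix poorly along the curved `(KG, a1)` and `(K, n)` ridges of this
posterior.  At least half of each chain, and never fewer than 1,000
steps, is discarded as warmup; the retained flattened sample is thinned
to the requested 5,000 draws.  Chains are bit-reproducible given a seed;
split-R̂ and effective sample size are attached to every posterior.

Identifiability is managed by staging: promoter/receiver constants are
fitted jointly across single-receiver and double-receiver ratiometric
devices spanning *multiple expression levels* (weak pCat, strong
pLlacO1) — the level contrast is what separates `KG` from `a1`, and
recovery degrades to a ridge without it; receiver levels (r, s) of new
two-channel devices are then inferred as a 2-parameter posterior with
promoter constants held fixed.  The arabinose→level transfer is fitted
as a monotone saturating Hill curve through per-arabinose 1-D level
posteriors, with an uncertainty band propagated by bootstrap over those
posteriors.

## Receiver-level optimization

The signal-to-crosstalk objective is evaluated at 100 nM of one signal
at a time (the other at zero), on a log-spaced (r, s) grid (levels span
orders of magnitude), with Nelder–Mead polish in log space that never
returns less than the best grid point.  Degenerate objectives (no
LasR-dependent term anywhere) are reported as unidentifiable in that
axis rather than returning an arbitrary arg-max.  Model outputs are used
raw (not basal-subtracted); with basal subtraction the crosstalk terms
can hit exact zero and the objective diverges — the code reports ±inf
with a flag in that case.

## Spatial lattice model

Each grid square of the printed membrane is one well-mixed population:
cells cannot cross the hydrophobic boundary, signals can.  Capacity
follows a per-square Gompertz curve `K·exp(−exp(−k_g(t−t_i)))` (defaults
K = 1, k_g = 0.008/min, t_i = 400 min for membrane growth; a faster
curve for liquid culture).  Reporters accumulate as activity × capacity;
mRFP1 is proportional to capacity by construction and serves as the
normalization channel.  Synthases (LuxI, LasI) are tracked as
per-capacity expression with first-order turnover δ = 0.01/min; constant
turnover (rather than growth-coupled dilution) is required for the
relay loop to possess a genuine off steady state after growth stops.
Signals obey production `k_syn·synthase·capacity`, first-order decay,
and nearest-neighbour exchange `D/h²` with no-flux boundaries (explicit
Euler, dt capped at 0.1× the stability limit, at which point profiles
are converged to well under 1% against 4×-finer references; with zero
production and decay the scheme conserves mass to machine precision).
The optimized receiver's YFP channel uses a Hill refit of the pLas81
response at the device's levels; all other transfer functions use the
closed-form model.

Effective-parameter defaults (D6 = 0.045, D12 = 0.0315 mm²/min;
k_syn = 0.008 nM/(RPU·capacity·min); k_deg6 = 0.01, k_deg12 =
0.0075/min; 3 mm pitch) were chosen once, by a coarse scan, to place the
model in the regime the membrane experiments exhibit simultaneously:
sender gradients decaying over a few squares; relay stripes propagating
a plated signal sequentially; a supra-threshold homogeneous feedback
loop (bifurcation threshold ≈ 0.32 in production-scale units, so scale 1
is supercritical); a checkerboard of relay populations that stays off
over a 2,000-min experiment unless seeded with a co-localized 50:50
mixed-population block, from which activation spreads.  The
discrimination between the induced and uninduced checkerboard is a
*kinetic* one — signal localization (λ = √(D/h²/k_deg) < 1 square) makes
the co-localized mixture ignite fast while the spatially alternating
loop's ignition time exceeds the horizon — not a difference in
steady-state stability.  These values are order-of-magnitude plausible
(D is close to small-molecule mobility in agar) but are not anchored to
measured tables; conclusions that depend on their precise values should
be re-fitted to real trajectories via `fit_gompertz` and the inference
module.

One known edge: a terminal stripe whose receiving channel is the
stiffer pLux76 (EC50 ≈ 400 nM at device levels) receives signal from
only one side and can sit just below the 0.5 activation-fraction
threshold; interior stripes and pLas81-terminated layouts activate
robustly.  The stripe presets therefore use five stripes, terminating on
the sensitive channel.

## Synthetic data

The plate generator emulates the fluorometer designs: 10-min cadence
over 1,000 min, dose ladders 10 nM–25 µM (plus a zero-dose point),
arabinose 0–8 mM, three replicates, and blank wells.  Fluorescence is
`gain × activity × ∫capacity` with lognormal multiplicative noise
(CV 3% per read — typical of ratiometric plate assays) and additive
Gaussian background (mean 50, sd 2 a.u.); the error model is an artifact
choice, made once.  The grid generator overlays lognormal noise (CV 10%)
on the deterministic lattice trajectories.  Ground-truth records
accompany every dataset, and generated files round-trip losslessly
through the package's readers.

What passing tests show: the estimators and samplers are calibrated and
unbiased *under this generative model*, and the spatial model reproduces
the qualitative membrane phenomenology.  What they do not show: real
plates have day effects, spectral bleed-through, maturation delays and
evaporation; real membranes have agar reservoirs, anisotropy and signal
loss to the bulk.  None of these are modelled; the likelihood's 10%
floor and the lumped effective transport parameters are where such
effects would be absorbed when fitting real data.

## Numerical conventions

Concentrations are nM throughout (µM config values converted at parse
time); time is minutes; rates are RPU.  Dose-response tables flag
single-replicate standard deviations as undefined (NaN), never zero.
Simulations are seed-free and bit-reproducible; generators and samplers
take explicit seeds.  Window selection, grid arg-max ties, and stripe
activation all break ties deterministically toward the earlier index.
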