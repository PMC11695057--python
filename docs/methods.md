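# Methods

`bindfit` models equilibrium and kinetic binding of a soluble ligand to a
membrane receptor, in the regime where reactant depletion matters: total
concentrations of ligand and receptor are comparable to the dissociation
constants, so "free ≈ total" shortcuts are invalid and all isotherms are
solved at exact mass action. Concentrations are nM and biosensor signal
is nm interference shift throughout the library; file schemas carry the
unit in the column name.

## Equilibrium models

**Ligand-depletion isotherm.** For a binary interaction with site total
A, receptor total R and constant K_A, the bound-site fraction is the
quadratic root

    Y0 = (A + K_A + R − sqrt((A + K_A + R)² − 4AR)) / (2A),

which is exact at any depletion level. The expression `(−A−K_A−R)²`
sometimes seen for the discriminant is evaluated as `(A+K_A+R)²`
(identical value). At the default bead-assay composition (A = 64 nM
sites — 32 nM of a disulfide-linked dimeric ligand with two independent
sites, see `dimer_to_sites` — R = 50 nM, K_A = 10.4 nM) Y0 ≈ 0.568,
i.e. roughly half the ligand is bound in the absence of competitor.
Protomer-level cooperativity between the two sites of a dimer is not
modelled.

**Fully competitive three-species system.** `wang_competition_curve`
evaluates the classical trigonometric root of the cubic governing one
species bound competitively by two others:

    h = K_A + K_B + A + X − R
    k = K_B(A−R) + K_A(X−R) + K_A·K_B
    l = −K_A·K_B·R
    t = arccos[(−2h³ + 9hk − 27l) / (2√((h²−3k)³))]
    Y = (2√(h²−3k)·cos(t/3) − h) / (3K_A + 2√(h²−3k)·cos(t/3) − h)

In this parameterisation the species at total concentration R is the
shared one: ligand sites (A, K_A) and competitor (X, K_B) both bind it,
and Y is the receptor-bound fraction of ligand sites. The quantity
`(2√(h²−3k)cos(t/3) − h)/3` is the free concentration of the shared
species, so Y = p/(K_A + p). Note this topology differs from the
alternative in which the competitor binds the *ligand*; the two
coincide at X = 0 and in the no-depletion limit but can differ by a few
parts in 10³ at bead-assay depletion levels. The closed form above is
the model used for all "competitive" fits; its exact boundary role for
the affinity-shift family is discussed below.

*Numerics.* The trig evaluation suffers catastrophic cancellation when
the free shared species is orders of magnitude below the totals
(2√(h²−3k)cos(t/3) ≈ h). The closed-form value is therefore used as a
seed and polished by vectorized Newton iteration on the monotone
mass-action balance p(1 + A/(K_A+p) + X/(K_B+p)) = R, giving
machine-precision results across A, R ∈ [1, 500] nM,
K ∈ [0.1, 10⁴] nM, X up to 1 mM (verified against a derivative-free
bisection oracle to better than 1e−12 relative). arccos arguments
within 1e−9 of ±1 are clamped; larger excursions raise, since they
indicate invalid parameters rather than round-off.

**Allosteric ternary-complex model (ATCM).** For a modulator that binds
the ligand and *weakens* (rather than blocks) receptor binding, the
species are L, LR (K_A), LC (K_B) and LRC, with receptor binding
competitor-bound ligand at α·K_A; detailed balance then fixes the
competitor's affinity for LR at α·K_B. A single cooperativity factor
α > 1 encodes negative cooperativity. Y counts sites in LR + LRC.
Limits built into the model: Y(0) is the depletion isotherm; as
x → ∞ the curve plateaus at the isotherm with K_A → α·K_A (non-zero for
finite α), which is the signature that distinguishes an affinity shift
from full competition; α = 1 makes the modulator silent. The paper-gap
here is real: the underlying study reports only that an
"affinity-shift" description fits better, without printing its
equations, and the ATCM is the minimal standard model producing that
phenotype — a documented assumption of this package.

*Numerics.* For each x the free-ligand balance is solved by bracketed
Brent iteration on [0, A] (relative tolerance 1e−12); given free
ligand, the receptor balance reduces to a quadratic solved in closed
form with the numerically stable root, and free competitor follows
explicitly. The α → ∞ boundary of the ATCM is the competitive system in
which receptor and competitor share the *ligand*; it therefore matches
the trigonometric closed form exactly only when depletion is
negligible. Model comparison remains valid at depletion because the
inter-topology gap (~2e−3 in fraction units) is far below the assay
noise (0.03–0.05).

**Hill curve.** `hill_binding` uses B_max·cʰ/(cʰ + K_Dʰ), so the
reported K_D is the half-saturation concentration for every Hill slope
h. **Cheng-Prusoff**: K_i = IC50/(1 + L/K_D), exact only without
depletion; the package's own tests demonstrate the inflation of
converted K_i at bead-assay depletion levels.

## Biosensor kinetics

The 1:1 Langmuir model: association R(t) = R_eq(1 − e^(−K_obs t)) with
K_obs = K_on·C + K_off and R_eq = B_max·C/(C + K_D); dissociation
r₀·e^(−K_off t). The estimation procedure mirrors standard biolayer
interferometry practice:

1. **Preprocessing** — subtract the parallel receptor-free reference
   sensor (interpolated onto the trace grid), optional Savitzky-Golay
   smoothing (default window 11 points, order 3; off in most tests so
   fits see the raw model), then re-zero on the mean of the final 10 s
   of baseline.
2. **K_obs per trace** — least-squares `plateau·(1 − e^(−k t))` on the
   association phase, initialised from a log-linear regression of the
   early rise; R² reported.
3. **K_on** — ordinary least squares of K_obs against concentration
   (≥ 3 distinct concentrations); the slope is K_on with its standard
   error; the intercept is reported as a cross-check against K_off but
   deliberately *not* constrained to it (two-source procedure).
4. **K_off** — per-trace one-phase decay fits; fits with R² ≤ 0.8 are
   excluded (low-concentration traces carry too little signal), and the
   mean ± SEM over survivors is the headline value, with the exclusion
   count always reported.
5. **Kinetic K_D** = K_off/K_on, SEM propagated in quadrature from the
   relative SEMs.
6. **Single-concentration traces** — a joint association-then-
   dissociation fit sharing kon, koff, B_max, with the dissociation
   amplitude pinned to the association model's value at the phase
   boundary (signal continuity). Parameters are optimised in log space.

Internal consistency (tested): noiseless families recover kon/koff to
1e−6, and the steady-state K_D fitted from the same family's exponential
plateaus equals K_off/K_on to 1e−6. The "plateau" entering steady-state
fits is the fitted exponential plateau by default (a terminal-window
average is trivially substitutable by the caller); the fitted plateau is
exact even when low-concentration associations do not visibly saturate.

## Estimation layer

**Steady-state fits** use all replicate points jointly for point
estimates; when ≥ 2 replicates exist each replicate is also fit
separately and the across-replicate SEM is the headline uncertainty
(falling back to asymptotic errors if per-replicate fits fail). A
fitted B_max more than 1/0.6 times the top-concentration signal is
flagged as extrapolated.

**IC50** fits a descending logistic with bottom fixed at 0 and slope
fixed at 1 by default (both releasable); the data must span the
transition (points above 75% and below 25% of the zero-competitor
level). IC50 is optimised as log10(IC50).

**Competition fits** hold A, R, K_A fixed at their known design values
and estimate K_B (and α) in log space, seeded by a coarse log-grid scan.
95% CIs use a seeded parametric bootstrap (default 1000 resamples;
Gaussian noise at the fitted residual SD added to the fitted curve,
each resample refit, percentile bounds). The bootstrap was chosen
because a resampling CI is assumption-light for a 1-2 parameter
nonlinear fit on a 6-point grid; the choice is recorded in the result
metadata. Empirical coverage at the displacement design (K_B = 1.06 µM
truth, 5-percentage-point noise, triplicate) is ≥ 85% over 200
simulated repeats with 200 resamples each — the scaled-down resample
count used in the test suite and acceptance script to keep runtimes in
minutes; point estimates are unaffected.

**Model comparison** treats the competitive model as the boundary of the
affinity-shift family and combines the extra-sum-of-squares F-test
(df = 1, n − 2) with AICc; the verdict is the model both criteria favor,
else "ambiguous". When the two SSRs differ by less than a numerical
floor (n·(1e−7·scale)²), the data cannot separate the models and the
verdict is "ambiguous" regardless.

## Synthetic data

The generator reproduces the study designs: kinetic families on a
3.16-fold (half-log) analyte ladder (3.2, 10, 32, 100 nM) with 60 s
baseline / 300 s association / 600 s dissociation at 5 Hz and trace
amplitude 0.8 nm (a typical specific-binding response when sensors are
loaded to a 1.5-2.5 nm shift); steady-state ladders 0.1-100 nM;
competition grids 0, 0.1, 0.4, 1.6, 25, 100 µM in triplicate. Default
truths are the measured constants (kon 1.9e−4 nM⁻¹s⁻¹, koff 1.4e−3 s⁻¹,
K_A 10.4 nM, competitor K_B 200 nM or 1060 nM depending on scenario).

Noise is additive homoscedastic Gaussian (SD 2% of amplitude for
traces, 3% for saturation series, 3-5 percentage points for competition
replicates, matching the replicate scatter typical of these assays); a
signal-proportional mode exists. Optional linear drift is shared between
trace and reference, emulating buffer mismatch removable by reference
subtraction. Not emulated: sensor-jump artifacts between phases,
mass-transport limitation, heterogeneous ligand density, or western-blot
quantification nonlinearity — so passing round-trip tests demonstrates
estimator correctness under the stated noise model, not robustness to
instrument pathologies.

All generation is deterministic given the design and seed; the design
(including truth and seed) is written to a sidecar JSON next to every
simulated CSV.

## Degenerate inputs and tie-breaks

Zero receptor gives Y ≡ 0 without touching the cubic; constant-zero
traces, missing phases, unspanned IC50 transitions, all-filtered K_off
sets and undisplaceable competition data raise typed errors rather than
returning numbers. Bootstrap percentile intervals are widened by a
relative 1e−9 when a pathological resample distribution would otherwise
exclude the point estimate, preserving the CI invariant. Fits are
deterministic given data; every stochastic step (generation, bootstrap)
takes an explicit seed.

## Known limitations

- Single-site 1:1 kinetics only; no bivalent-analyte or
  mass-transport-limited models, and no global multi-concentration
  surface fitting beyond the K_obs line.
- The two competition topologies (competitor on receptor vs competitor
  on ligand) are distinguishable in principle at strong depletion but
  are treated as interchangeable for model comparison, where their gap
  is far below assay noise.
- No four-species equilibria (two simultaneous competitors).
- The ATCM is an assumption standing in for an unpublished functional
  form; α is identifiable only when the data resolve the plateau.
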