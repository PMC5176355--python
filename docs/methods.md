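# Methods

This note documents the models, conventions and numerical choices behind
`gdtox`, and what the synthetic-data tests do and do not demonstrate.

## Sequestration equilibrium

The central object is a hub enzyme binding each of several partner enzymes
in an independent 1:1 complex. Assumptions, stated explicitly because they
matter for interpretation:

- **Independent sites.** Partners neither compete for a shared hub surface
  nor bind each other; each pair has its own dissociation constant. The
  multi-partner solver couples them only through depletion of free hub.
- **Closed system at equilibrium.** Total concentrations are conserved; no
  synthesis, degradation, or kinetics. Time-resolved association/
  dissociation, higher-order stoichiometries, crowding and activity
  coefficients are out of scope.

**Pairwise (closed form).** The complex concentration is the smaller root
of the conservation quadratic, evaluated as
`c = 2 D P / (s + sqrt(s^2 - 4 D P))`, `s = D + P + K`. This form avoids
the catastrophic cancellation of the textbook `(s - sqrt(...))/2` when
`4DP << s^2`, which is precisely the weak-binding, trace-abundance regime
the model is used in (nM proteins, µM constants).

**Competitive (N partners).** Free hub `h` solves
`h + Σ_i h P_i/(K_i + h) = H_T`. The left side is strictly increasing, so
the root in `[0, H_T]` is unique; Brent's method is run with relative
tolerance 1e-12 and an absolute floor of `H_T * 1e-16` so that even roots
many orders of magnitude below `H_T` (strongly bound hub) are resolved to
machine precision. Tests verify mass conservation to 1e-9 relative and
agreement with both the pairwise quadratic and an independent damped
fixed-point oracle on random systems.

**Units.** Everything internal is mol/L. Copies-per-cell conversion uses a
default cytoplasmic volume of 1.66 fL, the value consistent with 50
copies ≈ 5×10⁻⁸ M; it is a parameter everywhere it appears. Percentages
are rounded half-up when printed; unrounded fractions are always available.

**Sensitivity.** With the benchmark abundances (hub 5×10⁻⁸ M, partner
2×10⁻⁷ M) the basal bound fractions are 6.2% (hub) and 1.5% (partner) at
K_D = 3.0 µM, and 94.3% of partner is bound at 1000-fold hub excess. A
constant reported to one significant figure leaves real slack: the rounded
integers 5%/1% are reproduced exactly at K_D ≈ 4 µM, and 96% bound at
K_D ≈ 2 µM. The acceptance suite performs this scan explicitly rather than
pretending the one-digit constant pins the percentages.

## Binding (SPR)

Reference-cell subtraction interpolates the control onto the sample time
grid (linear; an error if the grids do not overlap). The equilibrium
readout is the response at the time point nearest 100 s after injection
(configurable). Isotherm fits use unweighted nonlinear least squares of
`RU = Rmax c/(c + KD)` with both parameters log-transformed to stay
positive; standard errors are back-transformed by the delta method. A
weighted option exists but is off by default since the readouts carry no
stated per-point errors. Dissociation tails are fitted globally —
one shared off-rate, one amplitude per curve — by bounded least squares.
The 100-s readout convention reports an *apparent* equilibrium constant; no
kinetic correction for curves short of steady state is attempted.

## Kinetics

Michaelis–Menten fits are log-parameterized NLS; `kcat = Vmax/[E]` and
`efficiency = kcat/KM` is an exact identity in the result object. Substrate
grids that do not straddle the fitted K_M set a `degenerate_span` flag
instead of failing. Duplicate substrate concentrations are used as
replicates. Modulation profiles divide each parameter by its zero-modulator
reference with first-order error propagation. The IC50 fit is a
four-parameter logistic with free Hill slope bounded in (0, 10]; the fitted
curve passes through `(top+bottom)/2` at `x = IC50` by construction, and
the fit is equivariant under affine rescaling of the signal axis.
Absorbance-to-rate conversion constants (e.g. NADPH at 340 nm) are left to
the caller: all modulation statements are about normalized ratios, which
such constants cancel out of.

## Growth and fitness

Growth curves are fitted with the modified Gompertz model — the
conventional default among the Gompertz/logistic/Richards family — on
`y = ln(OD)` with the inoculum level `ln(OD0)` estimated as a nuisance
baseline. Anchoring `y` at the first observed point instead would force the
model through zero at `t = 0` and biases µ noticeably for slow growers, so
the baseline is always fitted. Optional blank (medium background)
subtraction precedes the log transform. A series whose log-range is below
0.05 is declared flat: µ = 0 with a warning. µ is reported in h⁻¹, lag in
h. Recovery on synthetic curves: within 2% (median) at 1% multiplicative
OD noise across µ ∈ [0.1, 1.5] h⁻¹.

The abundance–fitness relation uses two branches with the normalization
reference always an explicit argument (no-inducer culture for
overexpression; empty-plasmid strain for metabolite-linked growth):

- depletion: saturating `f(a) = F_max a/(a + K_f)`;
- overexpression: decreasing 4PL in log10 abundance with `predict()` for
  arbitrary abundances.

**Ortholog significance.** The expected growth at an ortholog's abundance
is read off the fitted overexpression curve and assigned a 3% relative
standard deviation. The comparison with observed replicates is an unpaired
two-sample t-test in which the expectation side is represented by `n`
pseudo-replicates (default 3) drawn from `N(prediction, 0.03·prediction)`
with an explicit RNG. Treating the prediction instead as a summary-statistic
"sample" makes the test severely conservative (type-I ≈ 0.01 at α = 0.05);
the pseudo-replicate formulation is literally an unpaired t-test and is
exactly calibrated under the null, which the test suite verifies to
0.05 ± 0.02 over 2000 trials. The cost is a small stochastic component in
the p-value; pass a fixed seed for reproducibility.

**Rank correlation.** Spearman's ρ with an exact permutation p-value for
n ≤ 8 (full enumeration of rank orderings) and the t-approximation above.
Sidedness is an explicit flag. Note the combinatorics: a strictly monotone
series of five points has exact two-sided p = 2/5! ≈ 0.0167; six points
give 2/720 ≈ 0.0028. Ties receive average ranks; constant input returns
ρ = 0 with a warning.

**Rescue factor.** `(µ(hub+X) − µ(hub+empty)) − (µ(X) − µ(empty))`:
invariant under a constant shift of all four rates, so it isolates the
interaction benefit of co-expressing X from X's own toxicity.

## Co-IP interactome

A protein is called an interactor when its mean spectral count over sample
runs strictly exceeds its mean over pooled control runs. Conventions the
input format makes explicit: a protein missing from a run counts as zero;
all control runs are pooled into one mean (per-control-type analysis is a
matter of subsetting the table); averages run over all runs, detected or
not; no multiple-testing correction is applied by the caller, matching
standard practice for this simple background-subtraction rule. Dataset-level
enrichment is a paired t-test across proteins of (sample mean, control
mean); a constant nonzero shift (zero-variance differences) returns p = 0
with a warning instead of NaN, and identical means return p = 1.
Replicate agreement reports all pairwise Pearson correlations among sample
runs, flagging constant runs as degenerate.

## Metabolomics

Fold changes are `log2(mean strain area / mean control area)` per
metabolite (arithmetic mean by default, geometric optional). Metabolites
undetected in the control are excluded and listed rather than producing
infinities; sporadic zero areas elsewhere are floored at half the
metabolite's minimum positive area. Significance per metabolite is an
unpaired t-test (Welch by default — with n = 3 per side the pooled variant
is also exposed) with the star convention `*`: p < 0.05, `**`: p < 0.001,
boundary-exact. Fold change vs an empty-plasmid control (not per-metabolite
z-scores) is the default matrix; a z-score view can be computed from it.
The growth–metabolite association is a plain Pearson correlation across
strains with a two-sided t-based p.

## Synthetic data

Generators cover every consumed input, each returning its `GroundTruth`
(parameters + seed); the same seed reproduces tables exactly. Noise models:
multiplicative Gaussian for continuous signals, Poisson for spectral
counts, log-normal for peak areas. Defaults are the study-scale conditions:
SPR analyte grids 1.5–48 µM and 1–64 µM; substrate grids 20 µM–1 mM and
0.1–16 µM; OD sampled every 15 min for 12 h; three sample vs five control
co-IP runs over 300 background + 30 enriched (8×) proteins with per-protein
gamma(shape 2) baseline rates (mean 5 spectra), giving an expected
between-replicate intra-class correlation of 12.5/17.5 ≈ 0.71; three
replicates and ~10% CV for metabolites; 3% SD on fitness points, with the
overexpression branch spanning ~5- to ~850-fold abundance and a fitted
floor of 0.27 (a 73% maximal growth-rate reduction).

What these generators deliberately do **not** emulate: baseline drift and
mass-transport artefacts in SPR, substrate depletion during initial-rate
windows, diauxie or death phases in growth curves, run-to-run ionization
drift in LC-MS, and compositional/batch structure in co-IP counts. Passing
recovery and calibration tests therefore demonstrates correctness of the
estimators under their stated models, not robustness to every real-data
pathology.

## Problem sizes and determinism

The test and acceptance workloads use 100–200 fit replicates per recovery
study, 1000 random systems per solver-equivalence check, and 2000 trials
per type-I calibration — sizes at which the binomial uncertainty of a 5%
rejection rate (±1%) sits comfortably inside the ±2-point acceptance band.
All randomness flows through explicit `numpy.random.Generator` seeds; the
equilibrium quantities in `scripts/acceptance.py` are fully deterministic.
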