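# Methods

## The binding network and its solution

The equilibrium module models the competition at the heart of the eIF3
titration assay. Three components — R (40S·eIF1·eIF1A), T (ternary complex,
the radiolabeled tracer) and E (eIF3) — form three complexes RT, RE and RTE
through four dissociation reactions with constants K1–K4 (all nM; time, where
it appears, is in minutes). Because the four reactions form a closed
thermodynamic cycle, K1·K2 = K3·K4 exactly; the package treats K4 as derived
always, since eIF3 binding to the free 40S subunit is not measurable in a
tracer assay that only sees tRNA-containing bands. `EquilibriumConstants`
enforces closure to 1e-9 relative at construction, so no unclosed cycle can
enter any downstream computation.

Given totals (R_t, T_t, E_t), mass action reduces to two unknowns: free T and
free E. Free R is eliminated through its conservation law,

    R_free = R_t / (1 + T/K1 + E/K4 + T·E/(K1·K2)),

leaving two conservation residuals f_T(T, E) and f_E(T, E), each strictly
increasing in its own variable — which guarantees that [0, T_t] × [0, E_t]
brackets the root. The solver first runs a trust-region Newton iteration
(scipy `root`, `hybr`) on log-transformed free concentrations (log-space
keeps iterates positive and equalizes scales across the ~10 orders of
magnitude the constants can span); if that fails the per-component residual
test, it falls back to nested one-dimensional bracketing (outer on free E,
inner on free T, scipy `brentq` at effectively relative-only tolerance —
an absolute `xtol` would cap precision when a free concentration is orders
of magnitude below its total, e.g. a tight binder in excess receptor).
Acceptance requires each conservation law to close to 1e-9 relative *on its
own component's scale*, not the largest total: with very unequal totals a
residual negligible against the largest species can be large against the
smallest. Non-convergence raises with the residuals attached rather than
returning silently. Mixtures with any zero total collapse to at most one
reaction and are solved by the exact quadratic instead of the iteration.

Two scoping notes on monotonicity, established numerically. The
doubly-bound species RTE is non-decreasing in total eIF3 at fixed R and T
throughout. It is non-decreasing in total 40S only over the assay regime
(here ≤ 320 nM 40S with saturating eIF3): at extreme 40S excess, free
subunits sequester T and E into separate RT/RE complexes and RTE falls
again. The corresponding property test is deliberately restricted to the
assay range.

## The free-eIF3 correction and the choice of response

At the 30 nM 40S concentrations needed to measure eIF3:PIC affinity, free
40S subunits hold a substantial share of the added eIF3, so total eIF3 is a
poor stand-in for free eIF3. The gel resolves every tracer-containing
species, which pins the invisible 40S·eIF3 pool through K3:
RE = K3·RTE/T_free, hence E_free = E_total − RTE − RE. K3 is a per-condition
input (it is itself condition/variant dependent), never a hard-coded
constant. Lanes whose measured free-tracer band is zero cannot be corrected
(division by zero) and raise with instructions to exclude the lane; lanes
whose corrected free eIF3 comes out negative — possible with noisy
fractions — are floored at zero and flagged, never dropped, so noisy
replicates stay analyzable while the flag surfaces in the run log.

The default response for eIF3-binding isotherms is the fraction of PICs
that carry eIF3, RTE/(RT+RTE). At equilibrium RTE/RT = E_free/K2 exactly,
so this response is a pure Langmuir in free eIF3 with half-saturation at K2
— fitting it recovers K2 without bias (verified exactly on noiseless
model-generated data). The raw label fraction RTE/T_total is also exposed
(`response="frac_43s_eif3"`) but deliberately not the default: because
eIF3 tightens TC binding (K3 < K1), the tracer redistributes from the free
pool into PICs as eIF3 is titrated, and the label-fraction curve
half-saturates well above K2 (about 3-fold, at the wild-type-like
constants). Both ligand axes are likewise exposed, corrected free eIF3
(default) and loaded totals, the latter mainly for stoichiometric-regime
diagnostics.

40S titrations that measure TC affinity are handled in total-40S
coordinates with no free-ligand correction: the tracer sits at 1–2 nM, at
least ~5-fold below the smallest fitted K_D, so free and total 40S differ
by at most the tracer concentration. This is an approximation; it
contributes a bias of order T_t/2 (~0.5 nM at 1 nM tracer), far below the
fit uncertainty at these designs.

## Isotherm fitting, model choice, censoring, aggregation

Both isotherms are fit by bounded multi-start nonlinear least squares
(lmfit/TRF; 5 K-starts log-spaced over the sampled range, 3 Hill-coefficient
starts, tolerances 1e-13). Parameterization: amplitude A free in [0, 1.05]
(endpoints are condition-dependent and themselves reported; the 5% headroom
covers quantification slack), K as the half-saturation concentration in nM
(reported directly, never Kⁿ), Hill n in [0.5, 6]. K is searched within
[x_min/10, x_max·10]; a fit whose K lands on a search bound is reported as
a *failure*, not an estimate — this is what happens to the hyperbolic model
on severely cooperative curves that half-saturate beyond the titrated
range, and it prevents silent runaway estimates. Flat (saturated or empty)
responses fail for the same reason: K is unidentifiable. Failures are
values of the result type, not exceptions, so batch runs can log and
continue.

Model choice between Langmuir (2 parameters) and Hill (3) uses AICc
computed from the residual sum of squares; an automated criterion is needed
where by-eye comparison would otherwise decide. The Hill model nests the
Langmuir model at n = 1 (the suite asserts rss identity with n frozen), so
AICc is a like-for-like comparison; the rss is floored at 1e-12 to keep
exact fits from producing unbounded log-likelihoods, which conservatively
hands ties to the simpler model. A failed Langmuir fit auto-selects Hill
and vice versa.

Apparent affinities at or below the limiting 40S concentration (30 nM in
the eIF3 titration design) cannot be distinguished from stoichiometric
binding; `censor_apparent_kd` flags them (boundary inclusive) with the
limit recorded, retaining the value as an upper limit. In the
stoichiometric limit the fitted half-saturation on the total-ligand axis
concentrates near half the limiting 40S concentration regardless of the
true constant — the quantitative form of why such values are only bounds —
and the suite asserts exactly that.

Replicates are always fit individually and summarized as mean ± SEM
(sample SD/√n) of the per-replicate parameters — never a single pooled
fit, which would hide between-replicate variation. A single replicate
reports SEM as NaN rather than a misleading zero.

## Recruitment kinetics

Time courses of the fraction of labeled mRNA in the 48S band are fit with
y(t) = A·(1 − e^(−kt)), unweighted least squares, intercept fixed at zero
(reactions start on simultaneous mRNA/ATP addition; no burst term). At
least 5 time points are required for a rate. If the fitted curve already
reaches 90% of its amplitude at the earliest positive sample, the reaction
outran the sampling: the endpoint is kept but the rate is reported
unresolved, and `rate_ratio` refuses unresolved inputs, directing the
caller to report a bound instead. The 90% threshold is this package's
operationalization of "faster than the assay's time resolution". Terminal
extent-of-recruitment measurements bypass the kinetic model entirely
(`extent_at_completion` is plain replicate aggregation). Temperature
(26 °C vs 37 °C series) is metadata only; no temperature model is
attempted.

## Synthetic data: what it emulates and what it does not

The generator reproduces the statistical structure the analysis assumes:
band fractions computed either from the coupled-equilibrium model
(mechanistic eIF3/40S titrations) or directly from an isotherm or
exponential law (tracer-regime recovery studies), replicate structure with
independent noise substreams spawned from one master seed
(`SeedSequence.spawn`; bit-reproducible per seed), and the standard
concentration designs: eIF3 titrated 30–500 nM at 30 nM 40S and 2 nM
tracer TC, 40S titrated 10–320 nM (2-fold steps) at 1 nM tracer, time
courses within 0–120 min, ≥ 2 replicates by default.

Noise is additive Gaussian per band (default SD 0.02 on a fraction — a
realistic phosphorimager scale; the true quantification noise of any given
experiment is unknown, so σ is configurable), applied only to bands that
carry signal, then clipped to [0, 1] and renormalized to the pre-noise lane
total. Structurally dark bands stay at zero: an empty gel region is not
quantified, and folding clipped noise into it would add a half-normal
offset (~0.4σ) to every lane — enough to bias recovered Langmuir constants
several percent low.

Not emulated: gel-cage dissociation during electrophoresis (which makes
real endpoints conflate solution binding with in-gel stability),
band-calling/densitometry errors that correlate across lanes, pipetting
drift across a titration, and day effects between replicates. Passing
recovery tests therefore demonstrate that the analysis is correct and
well-calibrated for data that satisfy its own assumptions, not that those
assumptions hold for any particular gel.

## Problem sizes and numerical defaults

Recovery studies use 8 replicates for affinity/rate targets and 4 for
endpoint targets, on 6–8-lane curves — sizes chosen so each study is a few
hundred cheap fits and the SEM of the recovered mean sits well inside the
acceptance tolerances. Solver: residual tolerance 1e-9 relative
per component, iteration cap 200. Fits: tolerances 1e-13, bounds and
multi-starts as above. All stochastic tests fix master seeds (0 or 1) and
derive substreams; solver outputs are deterministic given inputs.

## Known limitations

- K3 uncertainty is not propagated into the corrected K2 (a wrong K3
  biases the correction most at low eIF3 totals and fades as totals grow;
  the suite quantifies the decay but the pipeline reports no combined
  error bar).
- No global/multi-curve or Bayesian fitting; every replicate is fit alone
  by design, mirroring the mean-of-individual-fits reporting convention.
- The binding network is fixed at three components/four reactions; larger
  networks and time-dependent approach to equilibrium are out of scope.
- Hill coefficients are reported as apparent cooperativity measures
  without mechanistic interpretation.
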