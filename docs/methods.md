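# Methods note

What ctrpharm models, what it assumes, and why the numerical choices were
made. The package is a simulated-recovery framework: the generators below
are also the fixtures for validating every fitting routine.

## Generative models and scope

All simulations share a default plate layout: a 13-point, 3-fold dilution
series descending from 1 µM, duplicate wells, 2.5×10⁴ cells/well. Seeds are
plain integers; derived child seeds come from `numpy.random.SeedSequence`
and are masked below 2³¹ so they remain valid everywhere.

**Functional curves.** Responses are generated from the operational model
(below) in percent of the system maximum, with additive Gaussian noise of
standard deviation `sd_frac × E_m` (default 5%). Noise is homoscedastic on
the percent scale — a simplification of real plate readers, which show
mild mean–variance coupling.

**Binding plates.** Expected specific binding follows the one-site
competition equations; expected counts come from the sites→cpm chain
(below). Counting noise is Gaussian with standard deviation
`max(sqrt(cpm), 2% of total binding)` — the Poisson-like square-root law
with a floor for pipetting error; a pure Poisson mode and a noise-free mode
(`count_noise="none"`, used for exact-recovery tests) are available.
Non-specific binding is fixed at 10% of maximal specific counts, an
assumed instrument/assay property rather than a fitted one.

**FACS expression.** Mean fluorescence intensities for parental
(untransfected), wild-type anchor, and sample populations, with 8%
log-normal-ish multiplicative spread; percent of wild type is
`100·(MFI_sample − MFI_parental)/(MFI_WT − MFI_parental)`.

The generators make no attempt to model plate-position effects, day
effects, or receptor reserve heterogeneity; they exist to give the fitting
stack a truth to recover, not to emulate a specific instrument.

## Unit conversions

Counts per minute → sites per cell:

    dpm  = cpm / efficiency                      (default efficiency 0.80)
    fmol = dpm / (specific_activity × 2.22)      (2.22 dpm per fmol per Ci/mmol;
                                                  default 2000 Ci/mmol → 4440 dpm/fmol)
    sites/cell = fmol × 6.022×10⁸ / cells_per_well

The factor 6.022×10⁸ is Avogadro's number scaled to femtomoles.

## Dose–response (3PL)

`R(C) = bottom + (top − bottom) / (1 + 10^(s·(logEC50 − logC)))` with Hill
slope fixed at 1 (`s = ±1` for ascending/descending curves). Fitting is
least squares with multi-start over logEC50 at the quartiles of the tested
range. Standard errors come from the analytic Jacobian
(`σ²(JᵀJ)⁻¹`), not from the optimizer's finite-difference covariance,
which degenerates to infinity on near-exact fits.

A fit is reported **N.D.** (not determined) when any of: the optimizer did
not converge; the fitted span is below 3 residual SDs (no signal); the
midpoint lies more than 1 log unit outside the tested range; or
SE(logEC50) exceeds 1 log unit. N.D. is a flag, never an exception, so
batch analyses keep running.

## Binding analysis

**Homologous** (`fit_homologous`): joint least squares over both hot-ligand
concentrations with shared pKd and log10 Bmax plus one non-specific-binding
level per series; total-binding and NSB control wells enter the residual
alongside the dilution series. The per-series IC50 identity `IC50 = L + Kd`
is exposed for checking. A single-hot-concentration fit is allowed but
flagged with a warning, since Kd and Bmax are then weakly separated.

**Heterologous** (`fit_heterologous`): specific binding is normalized per
series against its total and NSB controls, fitted with a descending 3PL,
and corrected with Cheng–Prusoff `Ki = IC50/(1 + L/Kd)` using the
radioligand Kd from the homologous fit. N.D. propagates from the 3PL stage.

## Operational model

    E(A) = basal + (E_m − basal) · τⁿAⁿ / ((A + K_A)ⁿ + τⁿAⁿ)
    EC50 = K_A / ((2 + τⁿ)^{1/n} − 1)

Parameters are fitted on the log scale (pK_A, log τ). With n = 1 — the
default throughout — the model curve is *exactly* a logistic in log
concentration, so (E_m, τ, K_A) are not jointly identifiable from a single
curve family: any change in E_m can be absorbed by τ and K_A. The default
policy therefore fixes E_m (at 100, the normalized system maximum). An
`em_policy="shared"` mode estimates one E_m jointly across ≥ 2 curves and
sets an `identifiability_warning` when the parameter correlation exceeds
0.99; it exists for n ≠ 1 or strongly partial-agonist panels, and its
estimates should be treated with care at n = 1.

**Expression correction.** `log τ_c = log τ − log10(expression%/100)`
removes the (assumed linear) dependence of operational efficacy on receptor
number. Undetectable expression (≤ 0% or missing) yields NaN, rendered as
N.D. Changes are reported as `Δ = wild type − mutant`, so positive Δ means
loss in the mutant.

## Dunnett's many-to-one test

Group comparisons use one-way ANOVA pooled variance and Dunnett's exact
adjustment. With control size n₀ and group sizes nᵢ, the comparison
t-statistics have correlation ρᵢⱼ = λᵢλⱼ with λᵢ = √(nᵢ/(nᵢ+n₀)), so the
joint CDF of max|Tᵢ| factorizes given the control deviate and the pooled
scale. We evaluate it by deterministic quadrature — Gauss–Hermite (64
nodes) over the control deviate times generalized Gauss–Laguerre (64
nodes, α = df/2 − 1) over the chi distributed scale — rather than
quasi-Monte Carlo, so p-values are exactly reproducible. Accuracy at the
default node counts is ≲ 10⁻⁵ (taking more nodes verifies convergence;
tests pin it at 10⁻⁶ with 160 Laguerre nodes and cross-check against an
independent QMC implementation at 10⁻³). For k = 1 the adjusted p reduces
to the pooled two-sided t-test within 10⁻⁴, and the familywise error rate
on 10⁴ balanced null simulations (5 groups, n = 6) falls in [0.04, 0.06].

Expression percentages, which are not exchangeable with the fitted
pharmacological parameters, are compared by Welch's t-test instead.

## Contact analysis

Frames are read from multi-model PDB files (Biopython parser); all models
must share one atom composition. Per frame:

- **contact**: ≥ 2 inter-residue atom pairs at distance **strictly
  < 3.5 Å**;
- **hydrogen bond**: donor–acceptor distance **≤ 3.0 Å** (inclusive) and
  deviation from donor–H–acceptor linearity ≤ 20°; donors are N/O/S heavy
  atoms with an attached hydrogen (D–H ≤ 1.25 Å), acceptors are N/O/S.

Fractions are percentages of frames; reporting thresholds default to
> 20% (contact) and > 2% (H-bond). Pairs are classified
sidechain/backbone (`ss`, `sb`, `bs`, `bb`) by the most frequent
atom-role combination, with backbone = {N, CA, C, O, H, HA}. Neighbor
search uses a k-d tree per frame; tests pin it against a brute-force
all-pairs oracle on random 200-atom frames.

## Determinism and reporting

`run_pipeline` derives every per-experiment seed from the config seed, so
reruns are byte-identical. Rendered tables show `mean ± SEM (n)` with `*`
for significant Dunnett (or Welch, for expression) comparisons against the
control variant, and `N.D.` where nothing was determined. A JSON run log
records the config, seed, and software versions.

## Known limitations

- Hill slopes other than 1 are supported by the model functions but the
  pipeline and most validation fix n = 1.
- The shared-E_m operational mode is weakly identified at n = 1 (see
  above); it is deliberately not the default.
- Binding noise ignores well-to-well volume variation beyond the 2% floor;
  NSB is simulated as a constant fraction, not fitted from its own
  saturation behavior.
- Asymptotic (Wald) standard errors are reported for all fits; no
  bootstrap or profile-likelihood intervals.
- Expression correction assumes efficacy scales linearly with receptor
  number, which fails for systems with large receptor reserve.
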