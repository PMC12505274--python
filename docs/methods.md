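# Methods

This note documents the models, numerical choices and limitations behind
`glasskinx`. Notation: α is crystallization conversion, β a heating rate
(K/min), R = 8.314 J/(mol K), temperatures in °C unless marked K.

## Kinetic model

Cold crystallization is modeled as a single Avrami–Erofeev process with an
Arrhenius rate constant:

    dα/dt = A e^(−Ea/RT) · n (1−α) [−ln(1−α)]^((n−1)/n),   A = e^{lnA} in 1/min.

The substitution u = [−ln(1−α)]^(1/n) reduces this to du/dt = k(T(t)), a
smooth one-dimensional ODE with no singularity at α = 0, which we integrate
with an adaptive stepper (`scipy.integrate.solve_ivp`, LSODA, rtol 1e−9)
along the piecewise-linear temperature program. This removes the need for
an artificial conversion floor at α = 0: a glass with no preformed nuclei
(`alpha0 = 0`) simply starts at u = 0. At constant temperature the solution
is closed-form, α(t) = 1 − exp(−(u₀ + kt)^n), which the tests use as an
independent oracle and which gives the closed-form `isothermal_t10`.

`alpha0` is the simulator's handle for preformed crystal nuclei created by
sub-Tg annealing: it sets the initial conversion equivalent
u₀ = [−ln(1−α₀)]^(1/n). No mapping from annealing time/temperature to
`alpha0` is claimed; that relation is experimental and left to user
configuration.

## Synthetic thermograms

Heat flow (mW/mg, endothermic up) is the sum of a sensible-heat baseline
Cp(T)·β with a logistic Cp step of height ΔCp (default 271.4 J/(mol K) ÷
471.67 g/mol) centered at Tg = 58.4 °C (width 1.5 °C), the exotherm
−ΔHc·dα/dt (total area exactly ΔHc·Δα), and two melting endotherms at
145.9 °C (form II) and 149.9 °C (form I). The endotherms are asymmetric
split-profile peaks in the Gaussian limit (left/right FWHM 1.0/1.6 °C):
asymmetry is retained through the two widths, while the Gaussian tails keep
melting energy from leaking into the exotherm window, preserving the 0.1%
energy bookkeeping that the tests enforce. Their areas follow from the
per-gram fusion enthalpies weighted by the form II / form I ratio and
scaled by the crystallized fraction; if conversion has not reached 0.999 by
5 °C below the form II melting point the trace is flagged
`incomplete_crystallization`.

The default kinetics (Ea = 134 kJ/mol, n = 4.7, α₀ = 1e−4) represent the
well-nucleated glass; the frequency factor lnA = 39.4102 was calibrated
once, by root-finding on the noise-free curve, so that the extrapolated
onset at 1 °C/min falls at 107.4 °C, and is frozen. The demo's second
condition (Ea = 115 kJ/mol, n = 4.1, α₀ = 1e−5, lnA = 32.6858) was
calibrated the same way to a 113.7 °C onset. The apparent ln A printed for
laboratory data (~55–63) is not comparable to these generator values: the
absolute magnitude of reported KAS intercepts depends on unstated unit and
rescaling conventions, so synthetic-data validation targets self-consistency
(round-trip recovery of the generating Ea and lnA) and the algebraic
ln A = intercept + ln(Ea·g(α)/R) identity on printed inputs, not absolute
intercept matching.

## Feature extraction

* **Tg**: apparent Cp (heat flow ÷ β) in the search window is fitted with a
  linear baseline plus logistic step; the logistic midpoint is Tg (the
  half-ΔCp convention) and |height| is ΔCp. A step below 3× the local noise
  (robust first-difference estimate) returns a not-found result rather than
  raising. Fitting baselines on both sides of the step keeps an enthalpy
  recovery overshoot from biasing the midpoint, provided the window edges
  sit outside the overshoot.
* **Onset**: standard extrapolated-onset construction — intersection of the
  pre-peak linear baseline with the tangent at the leading-edge inflection
  (maximum gradient before the peak). Noisy traces are Savitzky–Golay
  smoothed before differentiation.
* **Enthalpies**: linear baseline anchored at the integration limits;
  sigmoidal baselines are out of scope. Conversion curves are cumulative
  partial areas, exactly 0/1 at the window edges; the window therefore
  normalizes away any conversion outside it, which is why analysis windows
  should generously bracket the exotherm.
* **Melting doublet**: separated by model fitting (two split pseudo-Voigt
  peaks + linear baseline, bounded least squares, peak-finding
  initialization), not by a perpendicular drop; areas are reported ordered
  by center so the lower-melting form II is always first, and a vanishing
  form I peak yields an infinite-ratio flag rather than a division error.

## Modified Avrami fitting

f(t) = 100·0.9^((t/t10)^n) passes through 90% at t10 by construction, which
makes t10 directly interpretable and decouples it from n. Plateau heat
capacities are the means of the first and last `edge_count` (default 100)
samples; those samples are excluded from the fitted window so the data
defining the endpoints are not also fitted. f is not clipped to [0, 100] —
clipping noise would bias the fit. The optimizer is bounded nonlinear least
squares with a multistart over n ∈ {1…6} and t10 initialized at the
observed 90% crossing. The simulator samples every 0.01 min (0.6 s, close
to a 10 points/s instrument), so the 100-point plateau windows span only
1 min and stay flat even for fast-crystallizing conditions.

## KAS analysis

Units are fixed: β in K/min, T in K, Ea in J/mol, A in 1/min. Temperatures
at conversion are obtained by monotone piecewise-linear inversion of each
α(T) curve. The regression is ordinary least squares (statsmodels), whose
standard errors and R² are reported as-is. The α grid defaults to
0.01–0.50, but inference follows the low-conversion range α ≤ 0.10 where
single-step KAS is least biased; with Ea/RT ≈ 40 here, the KAS
approximation itself costs well under 1% in Ea (the round-trip tests bound
the whole pipeline at 2%). The Avrami exponent entering g(α) comes from the
isothermal fit of the matching condition (the 40-day values in the demo
config). ANCOVA is the standard nested-F construction: slope homogeneity
from dropping the x×group interaction, intercept effect from dropping the
group term under a common slope; identical zero-residual groups are flagged
degenerate with p = 1. A mixture of two kinetic processes with different
activation energies reproduces the falling-Ea(α) signature of multistep
kinetics, used as a qualitative property test.

## Split pseudo-Voigt convention

Each side of a peak is mix·Lorentzian + (1−mix)·Gaussian sharing that
side's FWHM and the common amplitude (Toraya-style, four asymmetry
parameters); the profile is continuous at the center with value =
amplitude. Areas are analytic — per side, half a Gaussian area
(amp·w·√(π/(4 ln 2))/2) plus half a Lorentzian area (amp·π·w/4) — and agree
with quadrature to better than 0.1%. Vendor packages differ in how they
parameterize the split profile; this convention is fixed and documented
here. The background is a polynomial (default degree 3) fitted jointly with
the peaks on a centered/scaled 2θ axis for conditioning.

## Dissolution and CNT

The dissolution trace is a phenomenological supersaturation shape: sin²
rise from the nominal predissolved concentration (default 40 μg/mL) to the
maximum at the peak time, then a Gaussian-in-time decay to the final
plateau, joined with zero slope so the trace is unimodal and C¹. The
first-point bias is a multiplicative probe-scale error, so the standard
correction corrected(t) = nominal/first × measured(t) removes it exactly
and preserves all timepoint ratios. The critical radius
r* = 2σTm/(ΔH_v(Tm − T)) demands a volumetric fusion enthalpy; a
molar-to-volumetric converter (needing the molar volume) is provided
because no interfacial energy σ or density is tabulated for TFD — r*
outputs are illustrative, never matched to a published number.

## Pipeline and determinism

Every random draw derives from the config seed via a named SHA-256
substream, so stages are independently reproducible and reruns are
bit-identical (the manifest's content hash covers all output files; stage
timings are recorded outside it). The demo run (two conditions × three
rates, full analysis) completes in seconds on one CPU; thermogram grids
resolve 0.05 °C in the pipeline and 0.02 °C in single-trace simulation,
sizes chosen to keep partial-area inversion accurate to ~0.02 K.

## What the synthetic data do not show

The generators reproduce the kinetic and noise *structure* of the
experiments, not every instrumental artifact: no baseline curvature or
drift, no enthalpy-relaxation overshoot at Tg, no crack-formation spikes,
no instrument time constant, no Kα2 doublets or preferred orientation in
PXRD, and iid Gaussian noise rather than 1/f drift. Passing round-trip
tests therefore demonstrates correctness of the estimators under the
stated model, not robustness to every artifact of real traces. Known
limitations: single-event windows must be supplied by the user (no
automatic segmentation); only linear integration baselines; no Friedman or
Vyazovkin isoconversional variants; no nucleation-rate or molecular-mobility
modeling.
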