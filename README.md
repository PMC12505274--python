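# glasskinx

Crystallization kinetics of amorphous pharmaceuticals: simulation and
analysis of the DSC/PXRD workflow used to study the physical stability of a
drug glass — here parameterized for amorphous terfenadine (TFD), a compound
whose nucleation is enhanced by annealing far below its glass transition.

Amorphous solid forms dissolve faster than crystals but are
thermodynamically unstable; whether and how fast they crystallize during
storage decides whether they are usable as dosage forms. This package
implements, end to end, the quantitative toolchain of such a stability
study, for formulation scientists and solid-state kineticists:

* **Thermogram features** — glass transition Tg and ΔCp (half-height
  midpoint of the heat-capacity step), extrapolated cold-crystallization
  onset T_onset, event enthalpies by linear-baseline integration, and
  deconvolution of the overlapping form II / form I melting doublet into the
  polymorph-proportion proxy ΔHf_II/ΔHf_I.
* **Modified Avrami kinetics** — from quasi-isothermal modulated-DSC
  reversing heat capacity, the residual amorphous fraction
  f(t) = (Cp(t) − Cp^crystal)/(Cp^amorphous − Cp^crystal)·100 is fitted with
  f(t) = 100·0.9^((t/t10)^n), giving the 10%-crystallization time t10 and
  the Avrami exponent n.
* **Isoconversional KAS analysis** — for each conversion α, ordinary least
  squares of ln(β/T_α²) on 1/T_α gives the apparent activation energy
  (E_a = −slope·R) and intercept ln(AR/(E_a·g(α))); with the Avrami–Erofeev
  model g(α) = [−ln(1−α)]^(1/n) the apparent frequency factor follows as
  ln A = intercept + ln(E_a·g(α)/R). ANCOVA (nested F-tests) compares slopes
  and intercepts between annealing conditions.
* **PXRD profile fitting** — split pseudo-Voigt peaks (independent left and
  right FWHM and Gaussian–Lorentzian mixing) plus a polynomial background,
  with analytic peak areas normalized to the 16.1° reflection scaled to 1000.
* **Closed-form helpers** — entropy of fusion ΔSf = ΔHf/Tm, the classical
  nucleation theory critical radius r* = 2σTm/(ΔH_v(Tm − T)), first-point
  correction of in-situ UV dissolution traces, solubility summaries.
* **Simulators** for every input (DSC, modulated DSC, PXRD, dissolution),
  with seeded Gaussian noise, so the whole pipeline is testable without
  instrument data. The cold-crystallization exotherm is generated by
  integrating the Avrami–Erofeev rate law
  dα/dt = A·e^(−Ea/RT)·n(1−α)[−ln(1−α)]^((n−1)/n) along an arbitrary
  temperature program.

The curve-fitting components (`AvramiModel`, `KASRegression`,
`SplitVoigtProfileModel`, `MeltingDoubletModel`) follow the scikit-learn
estimator convention (`fit`, `predict`, fitted attributes with a trailing
underscore) and compose with sklearn tooling; module-level functions wrap
them for one-call use.

## Worked example

```python
from glasskinx import (NoiseSpec, simulate_isothermal_trace,
                       frequency_factor, entropy_of_fusion)
from glasskinx.avrami import fit_trace

# quasi-isothermal crystallization at 100 degC, fitted back
trace = simulate_isothermal_trace(t10=17.5, n=4.9,
                                  noise=NoiseSpec(sd=0.02, seed=42))
fit = fit_trace(trace)
print(f"t10 = {fit.t10_min:.2f} min, Avrami exponent n = {fit.n:.2f}")

# apparent frequency factor from a KAS line (Ea in J/mol, alpha = 5%)
lnA = frequency_factor(Ea_J_mol=134.0e3, intercept=54.2, alpha=0.05, n=4.7)
print(f"ln A = {lnA:.1f}  (A in 1/min)")

print(f"dSf(form I) = {entropy_of_fusion(54.4, 149.9):.1f} J/(mol K)")
```

prints

```
t10 = 17.48 min, Avrami exponent n = 4.87
ln A = 63.3  (A in 1/min)
dSf(form I) = 128.6 J/(mol K)
```

The fitted t10 of 17.48 min recovers the generating 17.5 min within the
noise; n = 4.87 vs 4.9 likewise. An exponent near 5 points at a
time-dependent nucleation rate on top of three-dimensional growth — the
signature of a glass containing preformed nuclei. ln A = 63.3 is the
apparent frequency factor of the well-nucleated (−20 °C-annealed) glass;
a larger ln A at equal E_a means more pre-existing nuclei.

A full simulate → analyze → report run (two annealing conditions, three
heating rates, all four report tables plus a reproducibility manifest):

```bash
glasskinx run --config examples/demo.yaml --out results/demo
```

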