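# myokinetics

A five-stage kinetic model of adipose-derived stem cell (ASC)
myogenesis under cyclic mechanical strain, for researchers studying
stem-cell differentiation kinetics and mechanotransduction in vitro.

ASCs exposed to myogenic medium progress through marker-defined stages
— naive → PAX7⁺ → Desmin⁺ → MyoD⁺ → MHC⁺ (terminally differentiated) —
and cyclic uniaxial strain dramatically improves the yield of late
stages.  `myokinetics` models this as a switched, nonlinear system of
flux-balance ODEs:

    dnᵢ/dt = [ (2rᵢ−1)pᵢnᵢ − dᵢnᵢ + 2(1−rᵢ₋₁)pᵢ₋₁nᵢ₋₁ ] · f(n_tot)

with per-stage proliferation (pᵢ), death (dᵢ) and self-renewal ratios
(rᵢ), a division-free direct differentiation rate D from the MyoD⁺ to
the MHC⁺ stage, and a logistic crowding factor
f = 1/(1+exp(s(n_tot−n‡))) encoding the culture's density ceiling.
Rate coefficients switch between five epochs delimited by
state-threshold events (PAX7 peak, MyoD release, MHC release), each
smoothed by hysteretic piecewise-linear ramps, and every coefficient is
linear in the strain amplitude ε between the fitted static (0%) and
dynamic (10%) conditions.  The package provides:

* `simulate` — event-driven integration with dense output and an event log;
* `strain_sweep`, `critical_strain`, `summarize` — strain-dependence
  predictions and pattern classification (static-like vs dynamic-like);
* `markers_to_stages` / `stages_to_markers` — conversion between
  marker-panel counts (PAX7/Desmin/MyoD/MHC + total) and stage counts;
* `generate_synthetic`, `fit`, `calibrate_thresholds` — synthetic
  marker time series and calibration of the unreported thresholds and
  initial conditions;
* a thin `myokinetics` CLI (`simulate`, `sweep`, `critical`, `fit`,
  `synth`, `convert-markers`) over the same library.

## A worked example

```python
import myokinetics as mk

cfg = mk.default_config()                      # shipped calibration
for label, eps in (("static", 0.0), ("10% strain", 0.10)):
    res = mk.simulate(cfg.with_epsilon(eps).with_horizon(21.0))
    y21 = res.interp(21.0)
    print(label, {k: round(v, 2) for k, v in res.event_times.items()})
    print(f"  day-21: stem {100*y21[0]/y21.sum():.1f}%  "
          f"terminal {100*y21[4]/y21.sum():.1f}%")
```

prints

    static {'strain_applied': 3.0, 'n1_upper_met': 3.0, 'n1_peak': 3.51, 'n1_lower_met': 7.09}
      day-21: stem 60.7%  terminal 0.0%
    10% strain {'strain_applied': 3.0, 'n1_upper_met': 3.0, 'n1_peak': 3.16, 'n1_lower_met': 5.4, 'n3_upper_met': 9.23, 'n3_peak': 10.17}
      day-21: stem 3.6%  terminal 65.0%

Without strain the PAX7⁺ population peaks shortly after day 3 and MyoD
is released near day 7, but the MHC-release threshold is never met: the
culture stays dominated by naive stem cells and produces no terminally
differentiated cells.  Under 10% strain the same switching conditions
fire earlier and in full: MHC releases near day 9 and by day 21 about
two thirds of the population is terminally differentiated.  Sweeping ε
(`examples/strain_sweep.py`) shows the transition between these two
patterns at a critical strain of ≈1.2% (stem-cell maximum moves from
day 21 to day 3) with terminal cells first appearing at day 21 for
ε ≈ 4%.

The `examples/` directory contains runnable versions of this and the
other capabilities (`static_vs_dynamic.py`, `strain_sweep.py`,
`parameter_recovery.py`).

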