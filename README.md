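# icpkit

Simulation and analysis toolkit for membrane-based microfluidic
preconcentrators and the enzymatic assays they accelerate.

The device class it models: a shallow microchannel (1 cm x 17 um) with a
cation-permselective conductive-polymer membrane printed on the top wall
(400 um x 6 um), filled with dilute electrolyte (10 mM NaCl) and driven
by a DC field (3.6 V/mm).  Because the membrane transports cations
preferentially, an ion-depleted zone forms on its anodic side and an
enriched zone on the cathodic side (ion concentration polarization).
Charged biomolecules carried in by electroosmosis are stopped at the
depletion boundary and stack into a concentrated plug.  Concentrating an
enzyme locally accelerates its reaction: with Michaelis–Menten kinetics

    v = v_max c_s / (K_m + c_s),   v_max = k_cat c_E,

at saturating substrate the observed rate is proportional to the local
enzyme concentration, so minutes of electrokinetic preconcentration can
replace hours of static incubation.

The package has three layers:

* **Electrokinetics** — a steady 2D Poisson–Nernst–Planck–Stokes finite
  volume solver (Scharfetter–Gummel fluxes, damped Newton with analytic
  Jacobian, voltage continuation, staggered-grid Stokes with
  electroosmotic slip and electric body force), with post-processing for
  concentration profiles, depletion/enrichment metrics, ionic currents
  and recirculation vortices, plus frozen-field transport of a dilute
  tracer and its preconcentration factor.
* **Assay kinetics** — quadratic progress-curve fitting (rate = 2at + b),
  fold changes of net fluorescence against the negative control,
  acceleration factors, intra/inter-assay CVs, concentration bracketing
  against reference standards, reference-curve PCF estimation and the
  Kruskal–Wallis test.
* **Synthetic data** — a calibrated generator of multiwell fluorescence
  time courses (saturating negative-control background, quadratic
  concentration-dependent growth, multiplicative device- and well-level
  noise) so the whole assay pipeline is testable without instrument
  data.

See `docs/methods.md` for the model, its assumptions and numerical
choices.

## Worked example

```python
from icpkit import (QuadraticFit, reaction_rate_at, convert_rate,
                    acceleration_factor, fold_change, bracket_concentration)
from icpkit.synth import PlateDesign, default_calibration, generate_plate
from icpkit.kinetics import assay_cv

# rates from the two progress-curve fits (slow assay in hours, fast in minutes)
static = QuadraticFit.from_derivative(46.88, 29.33, time_unit="h")
fast = QuadraticFit.from_derivative(1017.94, 160.63, time_unit="min")
r_static = reaction_rate_at(static, 8.0)     # RFU/h after 8 h
r_fast = reaction_rate_at(fast, 8.0)         # RFU/min after 8 min

# one synthetic 12-device plate with realistic noise
plate = generate_plate(PlateDesign(), default_calibration(), seed=42, noise=True)
net = plate.net_signals(8.0)
nc = net[net["group"] == 0.0]["net"].mean()
intra, inter = assay_cv(plate, at_time=8.0)
```

prints (via the accompanying statements):

```
static incubation rate at 8 h : 404.37 RFU/h (= 6.7395 RFU/min)
accelerated rate at 8 min     : 8304.15 RFU/min
acceleration factor           : 1232.2x
fold change at     3 ng/mL    : 1.48
fold change at    30 ng/mL    : 3.89
fold change at   300 ng/mL    : 7.42
intra / inter assay CV        : 6.79% / 8.43%
unknown sample bracketed in   : (3, 30) ng/mL (log-linear estimate 7.5 ng/mL)
```

The accelerated reaction rate exceeds the static-incubation rate by more
than three orders of magnitude; a single noisy plate scatters around the
noise-free calibration (fold changes 1.5 / 3.8 / 7.3, CVs 9.80% / 9.45%
in ensemble expectation); an unknown sample with a net signal between
the 3 and 30 ng/mL standards is reported as that concentration range.

## Command line

```bash
icpkit simulate-icp --config case.toml --out out/   # steady PNP-Stokes solve -> VTK + report
icpkit analyze --state out/fields.vtk --out out/    # profiles, depletion, current, vortices
icpkit tracer  --state out/fields.vtk --t-end 60    # analyte accumulation, pcf(t)
icpkit synth   --seed 42 --out plate.csv            # synthetic plate
icpkit assay-fit --plate plate.csv --at 8           # fits, folds, CVs
```

All configuration is TOML with unit-suffixed keys (`channel_length_um`,
`c0_mM`, `zeta_bottom_mV`, `field_V_per_mm`, ...); an empty config
reproduces the reference device.

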