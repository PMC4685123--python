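# Methods

## Inverse size-exclusion chromatography

A packed column of adsorbent beads is probed with toluene (a fully
permeating tracer) and polystyrene standards of increasing molecular
mass. The tracer's retention volume anchors the total mobile-phase
volume `vt`; the largest, fully excluded standard anchors the
interparticle void volume `v0`. The distribution coefficient of any
probe, `Kd = (vr - v0)/(vt - v0)`, is the fraction of intraparticle
pore volume it can reach; by construction Kd is exactly 1 at the tracer
anchor and exactly 0 at the exclusion anchor.

**Stokes calibration.** Probe sizes come from the power law
`R_S = a * M^b` fitted by least squares in log-log space. Only polymer
standards enter the fit: the toluene tracer is a rigid small molecule,
not a polystyrene coil, and including it visibly bends the fit (its own
leave-one-out residual is ~3 %, versus <1 % for every polystyrene row).
On the bundled ladder the fit gives `a = 0.0122 nm`, `b = 0.588`,
log-log R² > 0.999.

**Accessibility threshold.** A probe counts as able to reach the inner
adsorbent surface while `Kd >= 0.1` (a tie at exactly 0.1 is
accessible). The accessible pore radius is reported as a bracket — the
Stokes radii of the largest accessible and smallest inaccessible
standards — never as an interpolated point, because only design masses
were measured. Measured Stokes radii are used for the bracket when the
standards table carries them; otherwise the calibration's prediction is
used (on the bundled ladder both routes agree at the reported
precision).

**Monotonicity.** Physically Kd cannot increase with probe size. Noisy
ladders are projected onto the non-increasing cone by isotonic
regression before bracketing (raw values are preserved and the
projection is flagged in reports), so a local noise bump cannot create
a second threshold crossing. A side effect of pool-adjacent-violators:
a violating pair that averages exactly onto the threshold counts as
accessible, consistent with the tie rule.

**Kd validation.** Raw Kd within 0.05 of [0, 1] is clipped with a
warning (measurement noise on the anchors); larger excursions raise an
error, since they indicate wrong anchor volumes rather than noise. The
tolerance is a parameter: the simulation pipeline widens it to 5 sigma
of the simulated Kd noise, because at 2 % retention noise benign
excursions beyond 0.05 are expected for fully excluded probes.

**Porosity and pore volume.** `porosity = 100*(vt - v0)/(vb - v0)` and
`pore volume = vt - v0`. The bed volume `vb` defaults to the geometric
volume of the standard 0.46 x 15 cm HPLC column, 2.493 mL; a
user-supplied bed volume is accepted but must satisfy `vt <= vb`
(violations raise, naming the offending values — a bed volume below the
mobile-phase volume is physically impossible and indicates a data
error). Reported radii/diameters and porosity are rounded to one
decimal and volumes to two, at serialization only.

**Secondary pore-size route.** The empirical polystyrene relation
`M = 2.25 * d^1.7` (d in Angstrom) maps the bracketing masses to
excluding-pore diameters. It is available behind `route="eq2"` and
labelled in reports; the default route doubles the Stokes radii, which
is what the bracket's radii already measure. The relation and its
inverse compose to the identity to better than 10 significant digits
across 10^2–10^7 Da.

## Scaled-down recirculating removal

The model circuit scales a clinical hemoperfusion device by bed volume:
300 mL clinical bed / 5 mL model bed = 60x, with the 60 mL reservoir
standing in for the 4–6 L blood volume and 1 mL/min for the
100–300 mL/min clinical flow. `linear_velocity` converts flow to
superficial velocity (cm/h) through a given bore; 1 mL/min through a
~1.18 cm bore gives the circuit's nominal 55 cm/h.

**Removal convention.** Removal is computed against the **control
circuit at the same endpoint**, not against the treated series' own
t = 0, because reservoir concentrations drift in the control too
(carryover, adsorption to tubing, degradation); the paired control
isolates the adsorbent's contribution. A `reference="t0"` switch is
provided for single-circuit data.

**Censoring.** Values below the limit of detection enter as `<LOD`.
The default substitution is LOD/2 (the conventional midpoint of the
censored interval), with LOD and zero as alternatives; censored
summaries are always flagged. A censored *control* endpoint makes
removal undefined and raises.

**Uncertainty.** When per-endpoint SDs are available, the removal SD is
propagated to first order, `sd^2 = (100/C)^2 sd_T^2 + (100 T/C^2)^2
sd_C^2`, assuming independent endpoints. This is labelled approximate:
replicate-level removal SDs (computed per circuit pair before
averaging) are generally smaller and cannot be reconstructed from
summary tables.

**Depletion model.** For synthetic-data recovery a single-compartment
model is used: well-mixed reservoir, constant single-pass extraction
efficiency E, no saturation — `C(t) = C0 exp(-kt)` with
`k = 60*flow*E/V` per hour. The fit is log-linear least squares on
uncensored positive points (>= 3 required); E is derived from the rate
and clipped into [0, 1] with a warning. The model is a deliberate
simplification for testing; breakthrough, competition (Vroman effect)
and saturation are out of scope for the *fitter*, though the
*simulator* offers a finite binding capacity.

## Dose–response activation thresholds

Plasma spiked at 0/50/100/500/1000/5000/10000 pg/mL and added to
culture at 10 % v/v exposes cells to a tenfold-diluted effective dose
(0–1000 pg/mL); thresholds are reported on the effective-dose scale. A
dose is called **active** when its mean response both exceeds
`baseline + 3 * baseline SD` and is at least `2 x baseline` — an
explicit, configurable stand-in for the by-eye reading such curves
usually get; both sub-rules are reported per dose. The threshold is the
bracket (last inactive design dose, first active design dose). A flat
series is an `open_high` flagged result; a series already active at its
lowest nonzero dose brackets against the baseline dose and is flagged
`open_low` (the true threshold may lie below the tested range). The
rule is invariant under positive rescaling of the response units. An
optional log-linear interpolation of the crossing dose exists but is
never the default output.

`relative_expression` is the plain ratio sample/positive-control in
percent. No background or isotype subtraction is applied; if the assay
requires one, it must happen upstream, and the reported number is
labelled accordingly.

## Synthetic-data generators

All generators are seeded (`numpy.random.default_rng`); equal seeds
give identical outputs.

* **iSEC**: partitioning of a spherical probe of radius r in a
  cylindrical pore of radius rp, `Kd = (1 - r/rp)^2` for r < rp else 0
  (classical SEC theory), mixture-weighted over a pore-size set;
  `vr = v0 + Kd*(vt - v0)` plus **additive** Gaussian noise on vr (UV
  retention volumes have roughly constant absolute error). The analysis
  modules never assume this partition law.
* **Depletion**: the closed-form exponential, or — with a finite
  capacity — fixed-step Euler integration (step <= 0.01 h; chosen for
  transparency over sophistication at these problem sizes) in which E
  drops to zero once the captured mass reaches capacity. Mass is
  conserved by construction to better than 1e-6 relative. Noise is
  **multiplicative** log-normal (immunoassays have roughly constant
  CV). The control circuit is E = 0.
* **Dose–response**: a Hill curve
  `baseline + emax*d^h/(ec50^h + d^h)`; each dose's reported mean is
  the average of n replicate draws of `N(true, noise_sd)` and the
  reported SD is the generating `noise_sd` itself — the assay's known
  dispersion — because an n = 3 sample SD is far too unstable to anchor
  a `+3*SD` activation rule. Noise is **additive** (fluorescence-like).

### Recovery-suite geometry

With the cylindrical partition law, Kd crosses the 0.1 threshold at
`(1 - sqrt(0.1)) * rp ≈ 0.68 rp`, not at rp. A standards ladder can
therefore bracket the *true* pore radius only if it steps from below
0.68 rp directly to above rp — a log-spacing ratio of at least ~1.5.
The recovery suites use 10 log-spaced probe radii over 0.22–44 nm
(ratio ≈ 1.8) against a 7.5 nm pore: the ladder has points at 4.18 nm
(true Kd ≈ 0.20, comfortably accessible under noise) and 7.54 nm
(excluded), so the returned bracket (4.18, 7.54) nm contains the truth
and is robust to the 2 % retention noise used. Real ladders with finer
spacing bracket the *threshold-crossing* radius instead; that is the
quantity the accessibility analysis is defined on.

### What the generators do not emulate

Inter-donor variability, protein competition and displacement on the
adsorbent, column breakthrough dynamics, assay calibration drift, and
non-Gaussian outliers. Passing recovery suites therefore show the
estimators are correct *under the stated error models*, not that real
assays meet those models.

## Problem sizes and runtime

The recovery suites use 100 seeded replicates each (pore-radius
bracket containment, extraction-efficiency error, dose–response bracket
identity), 10-point ladders, 7-point time series and the 7-dose grid —
sizes at which the full test suite runs in a few seconds on one CPU.

## Known limitations

* The bracket reports design-standard radii; resolution is limited by
  ladder spacing, and an open bracket (no crossing) is a flagged
  result the caller must handle.
* Endpoint removal percentages say nothing about kinetics; the
  exponential fit is exploratory and assumes constant extraction
  efficiency.
* First-order removal-SD propagation underestimates skew for treated
  values near zero and is labelled approximate wherever it appears.
* The source measurement tables carry rounded inputs; recomputed
  derived values can differ from their originally printed companions in
  the last digit (e.g. a pore volume of 1.24 vs 1.23 mL, porosity 86.5
  vs 86.2 %, a bracket bound of 20.9 vs 20.6 nm). Reports carry the
  recomputed values; the fixture keeps the printed ones in `*_printed`
  columns for comparison.
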