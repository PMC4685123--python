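# adsorbkit

Quantitative characterization of porous adsorbents for extracorporeal
blood purification (hemoadsorption). The package covers the three
analysis stages of a typical adsorbent-screening study:

1. **Inverse size-exclusion chromatography (iSEC)** — probe a packed
   column of adsorbent beads with a ladder of polystyrene size standards
   and a small-molecule tracer, and derive the accessible pore size,
   intraparticle porosity and pore volume.
2. **Removal analysis in a scaled-down recirculating circuit** — a small
   cartridge (~5 mL bed, ~60 mL reservoir, ~1 mL/min) mimicking a
   clinical hemoperfusion device at ~1/60 scale; endpoint cytokine
   concentrations versus a no-adsorbent control circuit yield removal
   percentages, with left-censored "<LOD" values handled explicitly.
3. **Dose–response activation thresholds** — bracket the lowest cytokine
   dose that activates endothelial-cell readouts (adhesion molecules,
   secreted interleukins) between adjacent design doses.

A seeded synthetic-data generator emulates all three assays so every
stage is testable end-to-end without laboratory data.

## The quantities computed

For a probe with retention volume $V_R$ on a column with interparticle
void volume $V_0$ (fully excluded probe) and total mobile-phase volume
$V_T$ (fully permeating tracer), the SEC distribution coefficient is

$$K_d = \frac{V_R - V_0}{V_T - V_0} \in [0, 1].$$

A probe is *accessible* (can reach the inner adsorbent surface) while
$K_d \ge 0.1$; the accessible pore radius is bracketed by the Stokes
radii of the last accessible and first inaccessible standards. Stokes
radii follow a power law $R_S = a\,M^b$ fitted in log-log space to the
polystyrene ladder (for the bundled ladder, $a \approx 0.0122$ nm,
$b \approx 0.588$, $R^2 > 0.999$). Porosity and pore volume are

$$\varepsilon_P = \frac{V_T - V_0}{V_B - V_0}, \qquad V_P = V_T - V_0,$$

with $V_B$ the (geometric) column bed volume. Removal at the endpoint
$t$ is $100\,(1 - C_\text{treated}(t)/C_\text{control}(t))$ %, and the
depletion of a well-mixed recirculating reservoir with single-pass
extraction efficiency $E$ follows
$C(t) = C_0 e^{-kt}$, $k = 60\,Q\,E/V_\text{res}$ (per hour, flow $Q$ in
mL/min).

## Worked example

Characterize the clinically approved hemoperfusion adsorbent (HAC) from
the bundled measurement tables:

```python
from adsorbkit import fixtures, characterize_adsorbent

cal = fixtures.stokes_calibration()
result = characterize_adsorbent(
    fixtures.isec_profile("HAC"),
    calibration=cal,
    radii=fixtures.measured_radii("HAC"),
)
print(result.to_report())
```

prints (abridged):

```
pore_diameter_lower_nm: 7.6    pore_diameter_upper_nm: 10.0
porosity_percent: 86.6         pore_volume_ml: 1.18
```

i.e. the Kd ladder crosses the 0.1 accessibility threshold between the
17.3 kDa standard (Stokes radius 3.82 nm) and the 27.5 kDa standard
(5.01 nm): pores admit solutes up to roughly 7.6–10 nm in diameter. The
column holds 1.18 mL of intraparticle pore volume and is 86.6 % porous.

Endpoint removal of TNF-α after 6 h of recirculation, against the
control circuit:

```python
from adsorbkit import removal_table
for row in removal_table(fixtures.endpoint_series()):
    if row.analyte == "TNF-alpha":
        print(row.to_report())
```

```
CG161c: 94.3 %   CG300m: 63.5 %   HAC: 53.4 %
```

— the large-pore CG161c adsorbent removes the bulky TNF-α trimer far
more effectively than the two smaller-pore materials, consistent with
its wider accessible-pore bracket (10.0–16.2 nm).

The same analyses are available from the shell:

```sh
adsorbkit fixtures export --dir data/
adsorbkit removal --series data/table3_endpoints.csv --out removal.json
adsorbkit simulate doseresponse --params params.yaml --seed 7 --out dr.csv
adsorbkit threshold --series dr.csv --out thresholds.json
```

## Documentation

`docs/methods.md` describes the models, the tunable parameters, the
synthetic generators and the numerical choices in detail.
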