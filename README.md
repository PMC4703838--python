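# uncagekit

Quantitative analysis of **photo-uncaging experiments in living cells** and
of the **calcium responses** they trigger, together with synthetic-data
generators that make every analysis stage testable against known ground
truth.

## The scientific problem

Caged signalling lipids carry a photocleavable coumarin group that masks
their activity until a light pulse releases them.  A membrane-impermeant
(sulfonated) coumarin cage localises the compound at the outer leaflet of
the plasma membrane (PM); after prolonged incubation a second pool is
endocytosed into vesicles.  This mixed localisation turns the cell itself
into an internal control for the photoreaction:

* at the **PM**, the released fluorescent coumarin alcohol disperses into
  the medium, so the fluorescence decrease ΔF_PM reflects *uncaging plus
  photobleaching*;
* inside a **vesicle**, the alcohol cannot escape and keeps fluorescing, so
  ΔF_ves reflects *photobleaching only*.

Two readouts follow.  **Completeness**: the residual normalized PM
intensity after photoactivation (≈ 0 when every caged molecule was
consumed).  **Efficiency**: the ratio ΔF_PM / ΔF_ves, which is large when
uncaging dominates over bleaching and falls toward 1 as increasing light
dose merely bleaches what is already uncaged.  Titrating the laser
intensity locates the window that is complete yet still efficient.

The kinetics are first order in light dose `D` with competing fates —
uncaging (`k_u`), bleaching of the caged ester (`k_b`) and bleaching of the
released alcohol (`k_a`):

```
caged(D)   = exp(-(k_u+k_b)·D)
alcohol(D) = k_u/(k_u+k_b-k_a) · (exp(-k_a·D) - exp(-(k_u+k_b)·D))   (vesicle)
           = 0                                                        (PM)
```

The analytic ΔF ratio tends to `(k_u+k_b)/k_b` at small dose and to 1 at
large dose, which is why the lowest dose that still uncages completely is
the efficient choice.

The second chain analyses single-cell calcium indicator traces around a
photoactivation event: robust baseline/noise estimation, transient
detection, **internal normalization** (each event's height relative to the
largest event of its own trace, high-intensity ⩾ 60 % — boundary
inclusive), 60-s binned high-intensity event counts before/after uncaging,
a Welch two-sample t-test on the pre/post distributions, and a rule-based
classification of each cell's response pattern (*initiated*, *potentiated*,
*transient suppression*, *terminated*, *no change*).

## Worked example

```bash
uncagekit run-demo --seed 1 --out demo/
cat demo/report.txt
```

```
uncagekit demo report
seed: 1

[uncaging titration]
level  dF_pm   dF_ves  ratio   remaining_pm  complete
  1.0  0.1240  0.0149   8.322  0.8760        False
  2.5  0.2803  0.0292   9.604  0.7197        False
  5.0  0.4835  0.0486   9.942  0.5165        False
 10.0  0.7321  0.0913   8.016  0.2679        False
 25.0  0.9628  0.1784   5.396  0.0372        True
 50.0  0.9987  0.2951   3.385  0.0013        True
complete_levels: [25.0, 50.0]
optimal_level: 5.0

[calcium population]
n_cells: 100
initiated                15  (0.150)
potentiated              22  (0.220)
transient_suppression    21  (0.210)
terminated               21  (0.210)
no_change                21  (0.210)
welch pre-vs-post high counts: t=-0.1385 df=196.68 p=0.89
```

Reading the titration table: ΔF_PM rises with laser level until the
photoreaction is complete (remaining PM fluorescence ≤ 5 % at 25–50 %
laser), while the efficiency ratio ΔF_PM/ΔF_ves peaks at low laser levels —
higher doses only add photobleaching (ΔF_ves grows from 0.015 to 0.295).
The calcium half simulates a 100-cell population with a known mix of
response classes, detects and labels every transient, and recovers the
class fractions; the Welch line compares each cell's high-intensity event
count before vs after uncaging (here the mix is balanced by design, so no
population-level shift is expected).

The same stages are available as individual subcommands
(`simulate-images`, `simulate-titration`, `quantify-uncaging`, `titrate`,
`simulate-traces`, `detect-events`, `classify-responses`, `qy`) and as
library functions:

```python
from uncagekit import (PhotoreactionParams, SceneParams, render_stack,
                       quantify_stack)

reaction = PhotoreactionParams(k_u=1.0, k_b=0.1, k_a=0.05, dose=1.0)
scene = SceneParams(shot_noise=False, read_noise_sigma=0.0, seed=42)
stack, masks, truth = render_stack(scene, reaction, n_pre=4, n_post=4)
result = quantify_stack(stack, masks)
print(result.dF_pm.value, result.dF_ves.value, result.efficiency_ratio)
# 0.6671289163019207 0.07820822941062178 8.5301626354338
```

## Layout

```
src/uncagekit/
  photochemistry.py    closed-form competing-fates kinetics
  synth_imaging.py     synthetic uncaging stack renderer
  uncaging_quant.py    segmentation, ΔF, efficiency ratio, titration
  synth_calcium.py     calcium trace / population generator
  calcium_events.py    transient detection, 60% labelling, binning, Welch
  response_analysis.py per-cell response features + classification
  photophysics.py      relative fluorescence quantum yield
  io.py, config.py     TIFF/CSV/YAML readers-writers, run configuration
  pipeline.py, cli.py  orchestration and the `uncagekit` CLI
docs/methods.md        model assumptions, parameter choices, limitations
```
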