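# Methods

This note documents the models behind `uncagekit`, the parameters that
matter, what the synthetic-data generators do and do not emulate, and the
numerical choices made where the design was genuinely open.

## 1. Competing-fates photochemistry

A caged coumarin compound under illumination partitions among three fates,
first order in the accumulated light dose `D` (dimensionless; proportional
to laser-intensity percent × number of photoactivation scans, the simplest
faithful mapping when only "% laser intensity" is controlled):

* uncaging with rate constant `k_u` (dose⁻¹), releasing the fluorescent
  coumarin alcohol and the cargo;
* direct photobleaching of the caged ester, `k_b`;
* photobleaching of the released alcohol, `k_a`.

With `c(D)` the caged fraction and `a(D)` the released-but-retained
alcohol fraction:

```
dc/dD = -(k_u + k_b) c,    c(0) = 1
da/dD =  k_u c - k_a a,    a(0) = 0
```

solved in closed form (degenerate limit `a = k_u D e^{-k_a D}` when
`k_u + k_b = k_a`, switched at relative tolerance 1e-12).  The compartment
enters only through alcohol retention: zero at the plasma membrane
(diffusive escape), full inside vesicles.  The closed form is validated
against adaptive Runge–Kutta integration to ≤ 1e-6 over random parameter
grids.

Measured quantities: `ΔF = (F_pre - F_post)/F_pre` per compartment, the
efficiency ratio `ΔF_PM/ΔF_ves` (→ `(k_u+k_b)/k_b` as D→0, → 1 as D→∞ for
`k_a > 0`, monotone non-increasing in dose), and completeness = residual
normalized PM fluorescence ≤ 0.05 (configurable; alternatively within
2·noise-sd of a supplied background trace).

The caged ester and the released alcohol are treated as equally bright
(their photophysics are near-identical); the ratio is exposed as
`SceneParams.alcohol_brightness_ratio` (default 1).

## 2. Synthetic image stacks

The renderer draws one cell as an elliptical PM ring (default width 3 px)
plus non-overlapping vesicle discs (radius 2–4 px) strictly interior to the
ring, over a uniform background.  Pre-frames carry full brightness; all
post-frames are scaled per compartment by its still-fluorescent fraction —
uncaging is treated as instantaneous between the last pre- and first
post-frame, matching single-scan photoactivation.  Optics and camera:
Gaussian PSF blur (σ default 1 px), Poisson shot noise on expected photons,
Gaussian read noise, additive camera offset; every noise source can be
switched off for exact tests.  One top-level seed drives placement and
noise; titrations derive per-level sub-streams deterministically, so a
series is reproducible from a single integer.

Not emulated: endocytosis dynamics (the vesicle set is static), cell
motion/drift, flat-field inhomogeneity, multi-channel optics, depth
effects.  Passing tests therefore demonstrate correctness of the
quantification chain, not robustness to motion or optical artefacts of
real microscopes.

## 3. Uncaging quantification

Segmentation (used when no label mask is supplied): Otsu threshold →
largest connected component with holes filled → PM band = component minus
its erosion by the ring width; vesicles = white top-hat spots (radius 5 px)
above a robust interior threshold (median + 5·1.4826·MAD), each blob
trimmed to its half-maximum contour (the half-max contour of a PSF-blurred
disc approximates the disc) and discarded below 4 px; spots within 2 px of
the PM band are excluded as mixed-mechanism pixels.  Background =
sub-threshold pixels beyond a safety margin around the cell.  A
user-supplied label mask bypasses all of this unchanged.

Traces are background-subtracted per frame (mean of the background mask,
removing camera offset) and normalized to the mean of the pre-activation
baseline window, so every baseline is exactly 1.  ΔF uses the mean of the
first 3 post-frames by default — late frames are increasingly confounded
by slow vesicle motion.  The s.e.m. of ΔF is computed across replicate
experiments (stacks), not across pixels; the ratio error follows standard
propagation, `err = ratio·sqrt((sem_pm/ΔF_pm)² + (sem_ves/ΔF_ves)²)`.
ΔF_ves below 1e-3 is reported as "bleach-free regime; ratio undefined"
rather than a number.  The titration optimum is the argmax of the
efficiency ratio with ties broken toward the lowest laser level (least
photodamage).

## 4. Synthetic calcium traces

Single-cell records default to 30 min at 2-s sampling with photoactivation
at 10 min (a typical confocal time-lapse scale; these are explicit
configuration, not claims about any particular dataset).  Events follow a
Poisson renewal process (rate λ_pre before, λ_post after uncaging);
transients are difference-of-exponentials kernels (rise 2 s, decay 15 s)
with log-normal amplitudes; Gaussian noise is added last.  Response-class
semantics:

| class | generative change at t₀ |
|---|---|
| initiated | λ_pre = 0, λ_post > 0 |
| potentiated | λ_post = 3·λ_pre and/or amplitude ×2 and/or baseline step |
| transient_suppression | λ = 0 for τ ~ U(4, 10) min, then restored |
| terminated | λ_post = 0 |
| no_change | identical statistics |

Populations draw per-cell rate (0.5–2.5 events/min), amplitude (5–20) and
noise (0.3–0.8) uniformly — the rate ceiling keeps transients resolvable
at the default kernel decay and sampling; the amplitude spread makes the
internal normalization step non-trivial.  A master seed spawns one
independent stream per cell.

Not emulated: spatial calcium dynamics, sensor photophysics
(e.g. indicator bleaching), bursting/regular (gamma-renewal) oscillations,
and correlated activity between cells.

## 5. Transient detection and event statistics

Baseline: running 10th percentile (91-sample window) of the 3-sample
smoothed trace.  A low quantile of pure noise sits `Φ⁻¹(q)·σ/√w` below the
true level; that known offset is added back using a difference-based noise
estimate, so the baseline is unbiased on event-free stretches instead of
hugging the noise floor (without the correction the null false-positive
rate is ~0.1 events/trace; with it ~0.002).

Noise scale: the smaller of two Gaussian-consistent robust estimates,
`1.4826·MAD(residual)` and `1.4826·MAD(Δvalues)/√2`.  Each alone fails in
a different regime — the residual MAD inflates severalfold when transients
occupy most of the record (dense oscillators), the difference MAD inflates
on steep rises — while the minimum tracks the true noise within tens of
percent in both.

Detection: local maxima of the smoothed, baseline-subtracted trace with
height ≥ k·σ (k = 3) **and** prominence ≥ k·σ; the prominence requirement
rejects noise bumps riding on a transient's decay shoulder, which clear
the absolute threshold with negligible local relief.  Peaks closer than
the minimum separation (10 s) keep the higher one, earlier on ties.  Event
height is read off the baseline-subtracted *raw* trace at the peak sample;
FWHM is interpolated at half that height.

Labelling: relative height = height / largest event height in the same
trace (whole record, pre + post); high-intensity iff ≥ 0.60, boundary
inclusive.  Heights are baseline-subtracted rather than raw so the 60 %
criterion is robust to per-cell offsets (raw mode available).  Note that
with heavily overlapping events, merged peaks carry summed amplitudes and
can become the per-trace maximum, demoting isolated events to "low" — an
intrinsic property of internal normalization, relevant when comparing
windows with very different event rates.

Binning: half-open 60-s bins `[t₀+k·60, t₀+(k+1)·60)` anchored at the
uncaging time; an event exactly on an edge belongs to the later bin;
events outside the configured window are ignored; traces with no events
contribute zero counts.  Population statistics are per-bin mean ± s.e.m.
across cells; pre/post distributions are compared with a two-sided Welch
two-sample t-test (Welch–Satterthwaite degrees of freedom; two
zero-variance samples with equal means report p = 1 by convention).

## 6. Response classification

Features per cell: pre/post event rates (all and high-only), pre/post mean
baseline-subtracted intensity (the proxy for average calcium level — no
calibration to molar units), mean event amplitude and FWHM, the longest
post-uncaging event-free gap, whether events occur after it, and the event
rate after it.  Decision list, first match wins:

1. **initiated** — pre rate ≤ 0.1/min and post rate above it;
2. **terminated** — post rate ≤ 0.2·pre rate with no recovery;
3. **transient_suppression** — an event-free gap of 4–10 min followed by
   recovery to ≥ 0.5·pre rate;
4. **potentiated** — post/pre rate ≥ 2, or post/pre amplitude ≥ 1.5, or a
   configured baseline step;
5. **no_change** otherwise.

Ordering initiation before suppression before potentiation prevents a cell
with zero pre-activity from being called potentiated.  All default
criteria are ratios, so classification is invariant to rescaling
intensities.  The rule set is a declared, configuration-driven construction
validated against synthetic ground truth only; it is not claimed to
reproduce any expert's per-cell assignments.  Known limitation: when the
drawn suppression interval τ is near its 10-min upper bound, the *observed*
gap (τ plus the waiting time to the next Poisson event) can exceed the
rule's bounds and the cell falls through to no_change; with default
parameters overall accuracy on 400-cell populations is 0.90–0.94, with
terminated and initiated recovered perfectly when detection is exact.
Event duration (FWHM) is computed but not used by the default rules.

## 7. Relative quantum yield

`QY = QY_ref · (I/I_ref) · (A_ref/A) · (η/η_ref)^p` with p = 2 by default
(the standard relative method; the exponent is exposed for auditability).
The bundled reference is coumarin 1 in ethanol, QY_ref = 0.73.  Absorbances
above 0.1 trigger an inner-filter warning, and an unphysical result > 1
warns rather than raises.  Spectrum parsing and peak integration are out of
scope; integrated intensities are inputs.

## 8. Determinism and problem sizes

Every stochastic component takes a seed; population and titration
generators derive per-item sub-streams via seed sequences, so outputs are
bit-identical across runs of the same seed (the demo pipeline's report
bundle is verified byte-for-byte).  Default validation sizes — 100-point
parameter grids for the kinetics oracle, 200 traces for detection scoring,
1000 null traces for the false-positive rate, 400 cells for classification
accuracy, 10 000 replicates for Welch type-I calibration — run in seconds
on one CPU and were chosen to make sampling error small relative to the
margins being tested.
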