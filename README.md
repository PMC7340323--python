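# rlm — radioluminescence microscopy simulation and analysis

Radioluminescence microscopy (RLM) images the decay of single radioactive
molecules in live cells: cells radiolabeled with a positron emitter such as
[¹⁸F]FDG are placed on (or sandwiched between) CdWO₄ scintillator crystals,
and every beta decay appears as a brief optical flash captured by an EMCCD
camera.  Counting flashes frame by frame quantifies the radiotracer content
of individual cells.  Sandwiching the cells between *two* scintillators
captures both emission hemispheres and doubles the detection sensitivity —
halving acquisition time, which matters for a tracer with a ~110-minute
half-life.

This package is a desk-scale, fully synthetic implementation of that
workflow for people who want to experiment with the dual-scintillator geometry,
the event-reconstruction pipeline, or the quantification statistics without
a Geant4 installation or a microscope:

* **`rlm.simulator`** — Monte Carlo of ¹⁸F decay: Fermi beta spectrum
  (endpoint 633.5 keV), isotropic emission, straight-ray positron transport
  into one or two slabs with an exponential range law calibrated to a 25 μm
  mean penetration depth, and an in-focus-energy detectability criterion.
* **`rlm.optics`** — microscope + EMCCD model: defocus-broadened Gaussian
  PSF, depth-of-field criterion, Poisson photoelectrons through a Gamma
  EM-gain register with read noise.
* **`rlm.reconstruction`** — ORBIT-style event reconstruction: dark-frame
  background model, per-frame thresholding, connected-component flash
  isolation, intensity-weighted centroids, aggregation into an event image.
* **`rlm.quantification`** — the statistical surface: expected-count model,
  decay correction, ROI counting with background subtraction, dual-vs-single
  regression, 2-D Gaussian FWHM, line profiles, efflux difference images.
* **`rlm.synthetic`** — ground-truth generator: heterogeneous cell fields
  (3–4× uptake spread), first-order tracer efflux into perinuclear annuli,
  and orchestration of single-then-double acquisition pairs 21 minutes apart.

## The model in brief

The decays detected from a cell holding N₀ tracer molecules follow

    D = S · Y · N₀ · (1 − exp(−ln2 · t / τ½))

with detection sensitivity S, particulate yield Y (0.97 for ¹⁸F) and
half-life τ½ ≈ 110 min.  Comparing a dual-scintillator acquisition taken Δt
after a single-scintillator one,

    S_double / S_single = D_double · exp(ln2 · Δt / τ½) / D_single,

where the exponential decay correction equals 1.14 for Δt = 21 min.  The
depth of field of the low-light microscope,

    d = n·λ/NA² + n·b·e/(M·NA)  ≈ 24.5 μm

(λ = 475 nm emission, NA 0.75, effective magnification 3.6×, 16 μm pixels at
4×4 binning), is what makes the sandwich geometry feasible: both crystal
surfaces sit within one depth of field.

## Worked example

Run the reduced-size synthetic experiment (20 cells, 1,000 frames per
configuration, 21-minute delay, no efflux) and print the headline numbers:

```python
from rlm.config import preset_config
from rlm.pipeline import run_pipeline

report = run_pipeline(preset_config("paper_scaled", seed=7))
s, r = report["sensitivity"], report["regression"]
print(f"dual/single sensitivity ratio: {s['ratio']:.2f}  "
      f"(95% CI {s['ci_low']:.2f}-{s['ci_high']:.2f})")
print(f"decay-correction factor (21 min): {s['correction_factor']:.3f}")
print(f"per-cell regression: slope {r['slope']:.2f} +/- {r['slope_stderr']:.2f}, "
      f"r^2 {r['r_squared']:.2f}")
```

prints

```
dual/single sensitivity ratio: 1.89  (95% CI 1.76-2.03)
decay-correction factor (21 min): 1.141
per-cell regression: slope 1.56 +/- 0.19, r^2 0.78
```

The sensitivity ratio is the decay-corrected total dual/single event count
over all cell ROIs — the doubling delivered by the second scintillator,
with a CI from Poisson counting statistics.  At this reduced problem size
(~60 counts per cell) the per-cell regression slope sits well below the
ratio: ordinary least squares is attenuated by counting noise in the
x-variable, a bias that shrinks at the full scenario's ~200 counts per cell
(see `docs/methods.md`).

The same pipeline is scriptable from the shell:

```bash
rlm dof                                    # depth-of-field calculator: 24.55 um
rlm simulate --scenario paper_scaled --seed 7 --outdir run1/
rlm reconstruct --frames run1/frames_single.tif --dark run1/dark.tif \
    --out events.csv --image events_single.tif
rlm quantify --events events_single.tif --cells run1/cells.csv --out rois.csv
rlm compare --single events_single.tif --double events_double.tif \
    --delta-t-min 21 --out compare.json
rlm run --scenario paper_default --seed 11 --out report.json
```

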