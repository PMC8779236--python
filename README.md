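# titinafm

Quantitative analysis of AFM nanosurgery experiments on single titin
molecules and their M-complexes.

## The problem

Titin is the giant elastic filament of the muscle sarcomere; its
C-terminal end carries a globular head — the **M-complex** — that
corresponds to the transverse unit of the sarcomeric M-band organized
around one myosin thick filament. In nanosurgical manipulation, an AFM
tip is pressed onto a surface-adsorbed molecule and dragged sideways to
displace, stretch, or unfold parts of it; a tapping-mode scan before and
after the drag records the structural consequences. Quantifying those
scan pairs requires a chain of image and model analyses:

* **tip convolution** — a recorded AFM image is the grayscale
  morphological dilation of the true surface by the probe shape (here a
  sphere of radius ~7 nm);
* **flattening** — per-scan-line polynomial background removal, with
  foreground excluded from the line fits;
* **masked volume analysis** — feature volume as the integral of the
  surface height over a thresholded mask, with volumes of the second scan
  rescaled by the volume ratio of an unmanipulated reference object
  imaged in both scans (inter-scan bias correction):
  `ΔV = (V_ref,before / V_ref,after) · V_target,after − V_target,before`;
* **filament metrics** — contour lengths, peak-to-peak spacings along
  section profiles (inter-M-complex bumps ~30 nm, titin filaments
  ~20 nm apart), loop strain `(L₁ + L₂)/L₀`, axial height decay of
  pulled-out strands, and necking (height/width of a strand from a
  least-squares rectangular fit to each perpendicular cross-section);
* **parametric models** — the thin-plate loop displacement
  `u(r) = k·ln(r₀/|r|)` and its tip-shifted variant
  `u(r) = k·ln(r₀/(|r| − d))` (the finite tip carves a gap of half-width
  `d` at the loop vertex; the two models are nested), the sigmoidal
  height decay `h(x) = B + (T − B)/(1 + (x/x₁/₂)^S)`, exponential and
  Gaussian histogram fits, a linear volume-vs-molecule-count fit with an
  intercept confidence interval, and the hydrated/dry fold-volume
  geometry (sphere for the M-complex: cube of the height ratio; fixed-
  length cylinder for the filament: square of the height ratio).

Because raw AFM scans of this kind are rarely deposited, the package
ships a first-class **synthetic topograph simulator**: ground-truth
molecule layouts (spherical-cap M-complexes, circular-segment filament
ridges, manipulation events imposed geometrically) rendered with tip
dilation and seeded scan artifacts (per-line tilt, Gaussian roughness,
multiplicative inter-scan gain). Every analysis stage is therefore
testable as a parameter-recovery problem with exact ground truth.

It is written for single-molecule AFM practitioners and for anyone who
needs a reproducible, tested reference implementation of these
measurements.

## Worked example

Fit the thin-plate loop model to a noisy synthetic loop generated with a
7 nm tip gap, both with and without the tip-radius shift:

```python
import numpy as np
from titinafm import ThinPlateModel, ThinPlateParams, eval_thin_plate

rng = np.random.default_rng(0)
true = ThinPlateParams(k=20.0, r0=60.0, d=7.0)
r_half = np.linspace(8.0, 66.5, 30)
r = np.concatenate([-r_half[::-1], r_half])          # symmetric loop
u = eval_thin_plate(true, r) + rng.normal(0, 0.5, len(r))

shifted = ThinPlateModel(r, u, with_tip_shift=True).fit()
original = ThinPlateModel(r, u, with_tip_shift=False).fit()
print(shifted.summary())
print(f"original-model SSR: {original.ssr:.2f}  (tip-shifted: {shifted.ssr:.2f})")
```

```
thin-plate loop (tip-shifted) fit results
==============================================
parameter           estimate       std err
----------------------------------------------
k                    20.0221       0.11157
r0                   60.1634       0.28039
d                    6.97884      0.029606
----------------------------------------------
n = 60, SSR = 11.8679, r^2 = 0.9994
tip_shift = True

original-model SSR: 1022.84  (tip-shifted: 11.87)
```

The tip-shifted fit recovers the generating parameters (k = 20 nm,
r₀ = 60 nm, d = 7 nm) and cuts the residual sum ~90-fold relative to the
original `d = 0` model, which cannot reproduce the gap at the loop
vertex — the signature of the finite tip radius.

An end-to-end volume experiment (simulate a manipulated + reference
M-complex pair with a 20% inter-scan gain mismatch, flatten, threshold,
mask, and bias-correct):

```python
from titinafm import run_experiment, volume_demo_config
report = run_experiment(volume_demo_config(seed=0))
print(report.summary_frame().to_string(index=False))
```

```
                     quantity        value
                   bias_ratio     0.833332
             dv_corrected_nm3  3294.948908
                ref_after_nm3 20233.680465
               ref_before_nm3 16861.377006
sphere_equivalent_diameter_nm    18.462196
                  true_dv_nm3  3300.000000
                  v_after_nm3 24190.655410
                 v_before_nm3 16863.902646
```

The recovered bias ratio matches the simulated gain pair (1.0, 1.2 →
1/1.2 ≈ 0.8333), and the corrected volume increment lands within 0.2% of
the 3300 nm³ ground truth — a volume increment equivalent to a sphere of
~18.5 nm diameter.

The same workflow is available from the shell:

```sh
titinafm simulate --seed 0 --out demo/        # before/after pair + ground truth
titinafm reproduce --seed 0                   # headline-number table
titinafm metrics strain --l0 65 --l1 130 --l2 130
titinafm fit thinplate --in loop.csv
```

## Layout

```
src/titinafm/
  synthetic.py    layout generation, manipulation, rendering, tip dilation,
                  scan artifacts
  heightmap.py    HeightMap/Mask/CrossSection containers + matrix/xyz/tiff I/O
  topography.py   flattening, thresholding, masked volumes, bias correction,
                  section profiles
  filament.py     contour length, peak spacings, strain, height decay, necking
  models.py       Model/Results fits: thin-plate, sigmoid, exponential,
                  Gaussian, linear, fold-volume geometry
  pipeline.py     configured simulate → analyze → report runs, demo configs
  cli.py          titinafm {simulate,flatten,volume,metrics,fit,run,reproduce}
```

See `docs/methods.md` for the models, their assumptions, and the
numerical choices.
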