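# fshapems

Functional-shape (F-shape) analysis of macular GCIPL thickness maps for
detecting multiple sclerosis from OCT, with an ETDRS sectoral baseline and
a synthetic-cohort generator.

## The problem

MS thins the ganglion cell–inner plexiform layer (GCIPL) of the retina,
concentrated in a horseshoe-shaped band around the fovea.  Classical
sectoral methods average thickness over a handful of ETDRS sectors and
throw away the spatial detail of the thinning pattern; they also depend on
an anatomical reference point.  The F-shape approach instead treats each
eye as a *functional shape* — the ILM surface geometry X carrying the
GCIPL thickness as a signal f — and compares eyes pointwise after
registering all of them to a common template.

The pipeline:

1. **F-shape construction** — orient every eye to right-eye convention,
   restrict to an annular region of interest around the fovea, decimate the
   pixel lattice onto a triangular mesh (≈4% of lattice points; squares of
   snapped side ≈5 split by their diagonals), and attach GCIPL thickness to
   ILM geometry at the mesh vertices.
2. **Atlas registration** — jointly estimate a mean template (X_m, f_m)
   and per-eye transformations by minimizing

       J = γ_f‖f_m‖² + Σ_i [ pᵢᵀK(X_m)pᵢ + γ_ζ‖ζᵢ‖² + γ_w A(registeredᵢ, eyeᵢ) ]

   where pᵢ are vertex momenta of an LDDMM-style kernel deformation
   (geodesic shooting), ζᵢ are per-vertex signal increments, and A is a
   functional-varifold kernel norm (Gaussian in face centroids and mean
   face signal, squared-cosine in normals, area-weighted) that needs no
   point correspondence.  Optimization is adaptive gradient descent with
   backtracking and exact hand-derived adjoint gradients.
3. **Classification** — the residual thickness f_m − f̃ᵢ on the template
   mesh is the feature vector; PCA (scree-rule dimension) then an SVM
   selected by leave-one-out grid search separate MS from healthy eyes.
   Test eyes are registered to the frozen template and classified.

Because the clinical dataset this kind of analysis is run on is not
public, the package ships a first-class synthetic generator that
reproduces the published group statistics (healthy GCIPL 75.9 ± 6.2 µm vs
MS 62.9 ± 5.4 µm across eyes), the horseshoe thinning geometry, smooth
per-eye anatomical warps and measurement noise, with ground truth for
recovery experiments.  See `docs/methods.md` for the full model and all
defaults.

## Worked example

```python
from fshapems.pipeline import RunConfig, run_experiment
from fshapems.synthetic import CohortConfig

cfg = RunConfig(cohort=CohortConfig(seed=1), split_seed=1)
res = run_experiment(cfg)
m = res["test_metrics"]
print(f"F-shape  ACC={m.ACC:.2f}  AUC={m.AUC:.2f}  (CV score {res['cv_score']:.2f}, k={res['pca_k']})")
sm = res["sectoral"]["metrics"]
print(f"sectoral ACC={sm.ACC:.2f}  AUC={sm.AUC:.2f}")
print(f"significant vertices: residual {res['significant_fraction_residual']:.0%}"
      f" vs raw {res['significant_fraction_raw']:.0%}")
```

prints (single core, a few minutes):

```
F-shape  ACC=1.00  AUC=1.00  (CV score 0.98, k=3)
sectoral ACC=1.00  AUC=1.00
significant vertices: residual 87% vs raw 67%
```

That is: on a 72-eye synthetic cohort (28+26 training, 9+9 test) at the
published effect size, the residual-feature SVM classifies the held-out
eyes perfectly, and the residual features flag substantially more
significantly different mesh vertices than raw pointwise thickness does —
the misalignment the atlas absorbs would otherwise blur the group
comparison.  (At this strong effect size the nine-sector baseline also
separates the test eyes; the residual-vs-raw fractions are where the
pointwise approach shows its advantage.)

The same steps are available as a CLI for file-based workflows:

```bash
fshapems simulate --out data/
fshapems train    --manifest data/manifest.csv --out model/
fshapems classify --manifest data/manifest.csv --model model/ --out pred.json
fshapems sectoral --manifest data/manifest.csv --out sect.json
fshapems report   --out summary.json
```

## Layout

| path | contents |
| --- | --- |
| `src/fshapems/grids.py` | thickness-map container, I/O, orientation, ROI |
| `src/fshapems/meshing.py` | mesh decimation, F-shape assembly, PLY/VTK export |
| `src/fshapems/registration.py` | kernel deformation, varifold metric, atlas estimation |
| `src/fshapems/features.py` | residuals, PCA, SVM kernels, LOO grid search, metrics |
| `src/fshapems/etdrs.py` | ETDRS nine-sector grid and sector means |
| `src/fshapems/synthetic.py` | synthetic cohort generator with ground truth |
| `src/fshapems/pipeline.py`, `cli.py` | orchestration and the `fshapems` CLI |
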