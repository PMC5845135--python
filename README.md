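# footshape

Geometric morphometrics of healthy adult 3D foot shape.

Foot morphology is usually quantified from 2D footprints, which discard
the vertical dimension entirely — arch height, instep girth, Achilles
tendon shape, toe height.  `footshape` implements the full 3D alternative
for researchers in biomechanics, orthotics and footwear design: dense
anatomical correspondence across triangulated foot scans, Procrustes
superimposition, a statistical shape model, and regression of shape on
subject characteristics.

The pipeline:

1. **Shape correspondence** — a reference mesh is deformed onto every
   scan, `X_target ≈ Ψ(T(X_ref), β)`, alternating an affine solve `T`
   with an elastic solve `Ψ` under an increasing elasticity schedule β,
   so all feet share one vertex ordering with vertices on the same
   anatomical positions.
2. **Generalized Procrustes Analysis** — shapes are normalized for
   position, size (centroid size) and orientation, with the population
   mean re-estimated as reference (three passes by default).
3. **Point-distribution model** — PCA of the aligned coordinates,
   `X = M + Σ Pᵢ wᵢ`: mean foot `M`, orthonormal shape modes `Pᵢ`,
   per-scan scores `wᵢ`; shapes are synthesized at ±3σ along each mode.
4. **Factor regression** — `F = W B + E`: subject factors (sex, age, shoe
   size, sport hours, BMI, loading, side) regressed on the most relevant
   PC scores, chosen by sequential forward selection under BIC, with
   per-factor R², p-values and post-hoc power (noncentral-F,
   `f² = R²/(1−R²)`, `λ = f²n`); per-vertex bilateral-asymmetry and
   loading measures; and model-predicted shape-difference maps for any
   factor.

Because no public 3D foot-scan cohort exists, the package ships a
first-class synthetic cohort generator: foot-like closed surfaces whose
variation is driven by six anatomical deformation modes (arch height,
ball width + toe spread, global width, hallux angle, toe-length type,
midfoot width), mode weights linearly coupled to factors, 0.3 mm scanner
noise, random pose, and optional remeshing — with exact ground truth
retained, so every stage is testable end to end.

## Worked example

```python
import dataclasses
from footshape.cli_report import PipelineConfig, run_pipeline

cfg = PipelineConfig(seed=7)
cfg.generator = dataclasses.replace(cfg.generator, n_subjects=12, resolution=1200)
res = run_pipeline(cfg, "study_out")

rep = res["explained"]
print("cumulative variance of first 6 PCs:", rep["cumulative"].round(3))
print(res["tables"]["significance"].round(4))
```

prints (seed 7, 12 subjects × 4 scans):

```
cumulative variance of first 6 PCs: [0.42  0.674 0.824 0.894 0.938 0.958]
             r_squared       p   power  significant
sex             0.5582  0.0000  1.0000         True
age             0.4213  0.0000  0.9990         True
shoe_size       0.3862  0.0001  0.9967         True
sport_hours     0.0303  0.7124  0.1435        False
bmi             0.7052  0.0000  1.0000         True
loading         0.0049  0.9748  0.0629        False
side            0.0000  1.0000  0.0500        False
```

The six planted deformation modes dominate the variance (95.8% in six
PCs at this small cohort size).  The factors planted with strong effects
on the modes (sex, age, shoe size, BMI) come out significant with high
power; loading and bilateral asymmetry are planted weak, and — exactly as
one expects at this sample size — their tests are non-significant with
power well below 0.8.  `study_out/` also receives the mean and ±3σ mode
shapes as PLY, PC scores, PC–factor correlation tables, asymmetry/loading
regressions, per-factor shape-difference maps (PLY with a per-vertex
`distance` scalar for colour mapping), and a manifest with content hashes;
re-running the same configuration reproduces every CSV bitwise.

The same stages are available as a CLI:

```bash
footshape simulate --n-subjects 10 --seed 1 --out scans/
footshape register --template scans/template.ply --targets scans/ --out corr/
footshape align --corresponded corr/ --out aligned.npz
footshape model --aligned aligned.npz --out model/
footshape run --seed 7 --out study_out/       # full pipeline
```

## Layout

| module | role |
| --- | --- |
| `footshape.synthetic_cohort` | template foot, deformation modes, cohort simulation with ground truth |
| `footshape.mesh_io` | OBJ/PLY/STL read/write (PLY per-vertex scalars), mirroring, ankle crop, plantar-PCA foot measurements |
| `footshape.correspondence` | affine ICP + elastic registration, correspondence-error oracle |
| `footshape.alignment` | GPA, centroid size, similarity tangent-space projection |
| `footshape.shape_model` | PCA model: fit, synthesize, project, explained variance, serialization |
| `footshape.factor_stats` | BIC forward selection, factor regression, power, correlations, asymmetry/loading analysis, shape prediction |
| `footshape.cli_report` | pipeline orchestration, manifest, `footshape` CLI |

See `docs/methods.md` for the statistical model, parameter defaults and
known limitations.
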