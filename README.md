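# densitycloud

Relative density clouds: visualization and decomposition of multivariate
differences between two groups.

Comparing two groups (e.g. treatment vs control, men vs women) on several
variables at once usually gets reduced to per-variable effect sizes,
which hide where in the joint distribution the groups actually diverge.
`densitycloud` estimates the local density ratio f_A(x)/f_B(x) of a
comparison group A over a reference group B at thousands of probe points
in d-dimensional space with a k-nearest-neighbor estimator,

    f̂(x) = (1 / (N·V_d)) · Σ_{j=1..k} j^(2/d) / [Σ_{j=1..k} ||x_j(x) − x||²]^(d/2),

and renders the probes in a d×d scatterplot matrix, colored by the
ratio's direction and made opaque in proportion to |log f̂_A/f̂_B|. The
overall difference can be factored into **location**, **scale**,
**covariation** (via ZCA-cor whitening/recoloring, W = R^(−1/2) V^(−1/2))
and **residual shape** components that multiply back to the overall ratio
exactly, and a random-split diagnostic shows whether the observed ratios
exceed estimation noise. Intended users: researchers in psychology,
epidemiology and adjacent fields exploring group differences in 2–10
commensurate scores. See `docs/methods.md` for the full model.

## Worked example

```python
import numpy as np
import densitycloud as dc

# two groups of 2,000 in d=3: centroid shift plus extra spread in V1
spec = dc.ScenarioSpec(
    n_per_group=2000, d=3,
    centroid_shift=[0.5, 0.2, 0.0],   # units of pooled SD
    sd_ratio=[1.3, 1.0, 1.0],         # group A is 30% wider on V1
    seed=42,
)
ds = dc.gaussian_groups(spec)

probes = dc.generate_probes(ds, seed=42)        # 9,333 probes at d=3
result = dc.decompose(ds, sequence="LSS", probes=probes, seed=42)
print(f"probes={probes.n_probes}, k={result.k}, equalized n={result.n_equalized}")
for comp in result.components:
    print(f"{comp.component:>14}: mean |log ratio| = "
          f"{np.mean(np.abs(comp.log_ratio)):.3f}, "
          f"displayed ratio range [{comp.ratio.min():.2f}, {comp.ratio.max():.2f}]")

dc.plot_cloud(result, dc.RenderConfig(), "clouds/", var_names=ds.var_names)
```

Output:

```
probes=9333, k=45, equalized n=2000
      location: mean |log ratio| = 0.473, displayed ratio range [0.28, 3.79]
         scale: mean |log ratio| = 0.251, displayed ratio range [0.59, 3.20]
residual_shape: mean |log ratio| = 0.203, displayed ratio range [0.45, 2.77]
```

The location component dominates (the injected centroid shift), the scale
component carries the V1 variance difference, and the residual shape term
is the estimation noise left over — their per-probe product equals the
overall ratio exactly. `plot_cloud` writes one scatterplot-matrix figure
per component; opacity is referenced to the sequence-wide maximum |log
ratio| so component strengths are visually comparable.

The same pipeline is available from the shell:

```bash
densitycloud simulate --spec scenario.yaml --out data.csv
densitycloud decompose --input data.csv --group-col group \
    --sequence LSCS+ --seed 42 --out results/
densitycloud diagnose --input data.csv --group-col group --out results/
```

Each run writes the figures, a per-probe CSV (coordinates, component,
ratio, log ratio, alpha) and the resolved configuration as YAML.

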