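# blastopower

Power and PCA simulations for single-cell expression studies in which the
treatment is applied per **blastocyst** while many cells are sampled from
each one. In that setting the blastocyst — not the cell — is the unit of
biological replication, and analyses that treat cells as independent
replicates (or that stop at a PCA score plot) can badly misjudge whether
treatments differ. This package is for statisticians and genomicists who
want to quantify, by simulation, what such a design can and cannot detect.

## The model

Expression of one gene for cell *i* is simulated as

    Y_i = mu + a[T_i] + c[C_i] + b[B_i] + e_i

with a 4-level treatment `T` (control, autologous, homologous,
heterologous; constant within blastocyst), a 4-level cell type `C`
(primitive endoderm, epiblast, trophectoderm, ambiguous), a blastocyst
random intercept `b ~ N(0, sigma_B^2)` and error `e ~ N(0, sigma_e^2)`,
with sigma_B = sigma_e = 10 by default. A treatment "effect size" delta
places the four level means at 0, delta, 2·delta, 3·delta; Cohen's
d = delta / sigma_e, so delta = 1 is d = 0.1 and delta = 10 is d = 1.

Each gene is tested with the mixed model
`Y ~ treatment + cell_type + (1 | blastocyst)`: a likelihood-ratio
comparison (ML fits, chi-square with 3 df) against the model without
treatment. Power is the fraction of significant genes per 100-gene batch,
averaged over batches with a 95% CI.

## Worked example

```python
import blastopower as bp

set1 = bp.run_set1(effect_sizes=[1, 4, 7, 10], n_batches=5, batch_size=20, seed=1)
print(set1.summary_frame().round(3).to_string(index=False))
```

```
 setting  mean_power  ci_low  ci_high  n_batches
     1.0        0.25   0.162    0.338          5
     4.0        0.38   0.300    0.460          5
     7.0        0.49   0.357    0.623          5
    10.0        0.72   0.590    0.850          5
```

Reading this: on the real study's scale (8 blastocysts, 32 cells), even a
very large per-gene effect (delta = 10, i.e. d = 1) is detected only ~72%
of the time, and small effects essentially never stand out above the
test's baseline rejection rate. The blastocyst-count sweep
(`bp.run_set2`) shows the complement: at a realistic d = 0.2, power stays
low until hundreds of blastocysts are sequenced.

The PCA demonstration simulates a 12,000-gene panel with genuine
differential expression whose direction varies gene to gene, and scores
treatment clustering on PC1/PC2 with a silhouette coefficient:

```python
res = bp.run_scenario(bp.build_balanced_design(8), bp.FIG3_PRESET,
                      bp.SimulationParams(), seed=0, out_dir="results/fig3")
print(res.separation.silhouette_mean)   # 0.129 — no treatment clustering
```

1,200 of those 12,000 genes are genuinely differentially expressed, yet
the score plot shows nothing attributable to treatment (the modest
positive silhouette comes from blastocyst clumping, not treatment
separation — see `docs/methods.md`). With every gene shifted in the same
direction instead (`permute_treatment_order=False`, 100% DE at d = 1) the
silhouette jumps to ~0.65: PCA hides inconsistent effects, not all
effects.

The `examples/` scripts walk through designs, single-gene tests, both
power sweeps and the PCA scenarios; each prints its numbers with a line on
how to read them.

## Command line

```bash
simulate-power set1 --n-batches 100 --batch-size 100 --seed 1 --out results/set1
simulate-power set2 --counts 8,48,96,144,192,240 --spacing 2 --out results/set2
simulate-power pca --preset fig3 --seed 1 --out results/fig3
simulate-power report results/set1 results/fig3 --out report.md
```

Every run writes CSV summaries, raw batch powers, plots, the resolved
config and a manifest with SHA-256 hashes; identical config + seed gives
bit-identical tabular outputs.

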