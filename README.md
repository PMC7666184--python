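# rarepart

Rare-species sensitivity of environment/space variation partitioning for
community matrices.

## The problem

Community ecologists routinely ask how much of the variation in a site ×
species abundance matrix **Y** is explained by local environmental
conditions versus pure spatial structure (dispersal, history). The standard
tool is two-block variation partitioning by partial redundancy analysis
(pRDA): with an environmental predictor block **X** and a spatial predictor
block **W** (PCNM eigenvectors of the inter-site distance matrix), the
adjusted canonical R² of the three nested models decomposes into

    [a] = adjR²(Y ~ X ∪ W) − adjR²(Y ~ W)      pure environment
    [b] = adjR²(Y ~ X) + adjR²(Y ~ W) − adjR²(Y ~ X ∪ W)   shared
    [c] = adjR²(Y ~ X ∪ W) − adjR²(Y ~ X)      pure space
    [d] = 1 − adjR²(Y ~ X ∪ W)                 residual

where adjR² = 1 − (1 − R²)(n − 1)/(n − m − 1) (Ezekiel) and m is the
effective rank of the block. In field data the residual [d] often exceeds
50 %, and a recurring suspicion is that rare species — noisy, zero-inflated,
idiosyncratic — inflate it.

`rarepart` tests that suspicion directly. It ranks species by commonness,
removes them one at a time (rarest first, or commonest first) down to half
of the original richness, re-runs the partition at every step, and compares
the resulting shift

    ΔR² = explained(before) − explained(after)

against a null distribution generated by *stratified random removal*:
species are deleted at random, but proportionally across abundance strata,
so each null replicate preserves the community's relative-abundance
structure. The permutation p-value uses the add-one convention, so 999
repetitions bound p below by 0.001.

The package also ships the full predictor-construction chain (coefficient-
of-variation screening of the environmental battery, permutation-tested
forward selection, correlation-matrix PCA retaining ≥ 90 % variance, PCNM
spatial filters) and a synthetic metacommunity generator with known ground
truth, so every stage is testable without field data.

## Worked example

```python
from rarepart import (RunConfig, simulate_metacommunity, run_varpart_pipeline,
                      run_cascade, delta_r2, null_distribution)

# 120 sites, 80 species with lognormal abundances; the common species carry
# the environmental signal, gradients are partly spatially structured
community, env, coords, truth, _ = simulate_metacommunity("mixed", seed=1)
cfg = RunConfig(seed=1)

pipe = run_varpart_pipeline(community, env, coords, cfg)
vp = pipe.varpart
print(f"pure environment [a] = {vp.frac_a:.3f}")
print(f"shared            [b] = {vp.frac_b:.3f}")
print(f"pure space        [c] = {vp.frac_c:.3f}")
print(f"residual          [d] = {vp.frac_d:.3f}")

for direction in ("remove_rare_first", "remove_common_first"):
    trace = run_cascade(community, pipe.env_block, pipe.space_block,
                        direction=direction, config=cfg)
    obs = delta_r2(trace, "explained_total")
    null = null_distribution(community, pipe.env_block, pipe.space_block,
                             config=cfg, observed=obs)
    print(f"{direction}: dR2 = {obs:+.3f}  p = {null.p_value:.3f}")
```

prints

```
pure environment [a] = 0.222
shared            [b] = 0.171
pure space        [c] = 0.103
residual          [d] = 0.503
remove_rare_first: dR2 = -0.027  p = 0.496
remove_common_first: dR2 = +0.189  p = 0.001
```

Half the variance stays unexplained even in this simulated community, and
the asymmetry is the point: deleting the rarest 40 species barely moves the
explained fraction (the slightly negative ΔR² means the adjusted fit even
improved, indistinguishable from random removal at p ≈ 0.5), while deleting
the commonest 40 — the carriers of the environmental signal — collapses it
by 0.19, far outside the null (p = 0.001, the smallest value 999
repetitions can resolve).

The same analyses run from the shell:

```bash
rarepart simulate --scenario mixed --seed 1 --outdir data/
rarepart varpart  --community data/community.csv --env data/env.csv \
                  --coords data/coords.csv --outdir out/
rarepart cascade  --community data/community.csv --env data/env.csv \
                  --coords data/coords.csv --direction remove_common_first \
                  --outdir out/
rarepart null     --community data/community.csv --env data/env.csv \
                  --coords data/coords.csv --outdir out/
```

## Estimator API

The stages are scikit-learn estimators and compose with sklearn pipelines:
`CVScreen`, `ForwardSelector`, `RetainedVariancePCA` and
`HellingerTransformer` are transformers/selectors; `PCNM` builds the
spatial filter basis; `VariationPartitioning`, `RemovalCascade` and
`StratifiedNullModel` are analysis estimators whose `fit(Y, env, space)`
exposes fitted attributes (`fractions_`, `trace_`, `delta_r2_`,
`p_value_`). The module-level functions used above are thin wrappers over
them.

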