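# pcqm — point-centred quarter method density estimation, evaluated by Monte Carlo

The point-centred quarter method (PCQM) is a plotless technique for
estimating plant density: at each of *N* random sample points the area
is split into four quadrants (*k* = 4) and the distance *R* to a
designated nearest plant in each quadrant is recorded. It is the method
of choice where plot-based sampling is impractical — mangroves, steep
or remote terrain — because it needs nothing but a compass and a tape.
The *order* *g* selects which nearest plant is measured per quadrant
(PCQM1 the 1st, PCQM2 the 2nd, PCQM3 the 3rd; nearer plants are
skipped, not measured).

Two estimator families circulate in the literature for converting the
distances to a density ρ̂ (per m², reported here per hectare):

    published:  ρ̂ = N·k·(g·k − 1) / (π Σᵢ Σⱼ R²ᵢⱼ)     → 12N, 28N, 44N
    corrected:  ρ̂ = k·(g·N·k − 1) / (π Σᵢ Σⱼ R²ᵢⱼ)     → 4(4N−1), 4(8N−1), 4(12N−1)

The corrected family is the consistent extension of Pollard's
order-1 estimator: over the whole survey g·N·k plants are measured, and
the unbiased reciprocal-gamma moment requires the multiplier
(g·N·k − 1). The published family applies the per-point count g·k
instead and therefore underestimates density by the factor
(gk − 1)/(gk) — about 25%, 12.5% and 8.3% for g = 1, 2, 3 — no matter
how many points are measured. (Field note: the denominator is π times
the *sum of squared distances*, never the sum of inverse squared
distances.)

This package provides

* the estimators (both families, any order, with g ∈ {1, 2, 3} as the
  named presets),
* synthetic stand generators — random (binomial), aggregated (cluster)
  and regular (hard-core sequential inhibition) — characterised by the
  Clark–Evans aggregation index *R*,
* a virtual-survey sampler (edge-buffered sample points, half-open
  axis-aligned quadrants, g-th-nearest search),
* a Monte Carlo evaluation framework producing RRMSE/RBIAS tables and
  rank-based comparisons (Wilcoxon rank-sum between families,
  Kruskal–Wallis with Dunn/Holm post hoc across orders),
* a `pcqm` command-line tool tying it together.

It is aimed at vegetation scientists choosing a survey protocol and at
methodologists studying plotless density estimators.

## Worked example: field data

Ten sample points, first-nearest distances (meters) in each quadrant,
in `field.csv` with columns `q1,q2,q3,q4`:

```sh
$ pcqm estimate --sample field.csv --order 1 --estimator corrected
estimator: corrected (PCQM1)
N = 10 sample points, k = 4 quadrants
numerator = 156
sum R^2 = 65.1071 m^2
density = 7626.9 stems/ha
```

With `--estimator published` the same distances give numerator 120 and
5866.8 stems/ha — the ~25% shortfall described above, obtained from the
identical field measurements.

## Worked example: Monte Carlo accuracy

```python
from pcqm import PatternSpec, ScenarioConfig, Window, run_scenario

config = ScenarioConfig(
    scenario_id="demo",
    pattern=PatternSpec("random", 5000, Window.from_size(100, 100)),
    sample_sizes=(30, 100), orders=(1,), replicates=200, seed=42,
)
result = run_scenario(config)
print(result.metrics[["samples", "pcqm_eqn", "rrmse", "rbias"]]
      .round(3).to_string(index=False))
```

```
 samples  pcqm_eqn  rrmse  rbias
      30 published  0.252 -0.241
      30 corrected  0.097  0.004
     100 published  0.250 -0.246
     100 corrected  0.052  0.002
```

Each replicate builds a fresh 5,000 stems/ha random stand in 1 ha,
drops sample points in the central 80% × 80% (10% boundary strip),
measures the quadrant distances and applies both estimators. The
corrected estimator is unbiased (RBIAS ≈ 0) and its relative RMSE
shrinks from ~10% at N = 30 to ~5% at N = 100; the published estimator
is stuck near −25% bias regardless of N.

The bundled `examples/random-5000.yaml` runs the full
7 sample sizes × 3 orders × 2 families grid:

```sh
pcqm simulate --config examples/random-5000.yaml --out-dir results
pcqm compare --raw results/raw.csv
```

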