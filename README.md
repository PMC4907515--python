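# metgain

Analysis of multi-environment trials (METs) from recurrent-selection
breeding programs, built around the rainfed / restricted-irrigation design
used to evaluate drought tolerance in wheat.  The package is aimed at
quantitative geneticists and breeders who need, from plot-level phenotype
records:

- **variance components and broad-sense heritability** from a balanced
  genotype × treatment × year model with replicates nested in
  treatment-year,
- **genetic advance and genetic gain** statistics (the breeder's equation),
- the six classical **yield-based drought-tolerance indices**
  (TOL, MPI, GMP, MRP, REI, STI) with per-index entry rankings,
- **population comparisons**: Welch t-tests, Dunnett many-to-one tests with
  familywise error control, trait correlations on adjusted means, and
- **progeny BLUPs** from a six-term random-effects yield model fitted by
  EM-REML,

plus a **synthetic MET generator** (known variance components, truncation
selection, stress-specific yield ratios) so the whole pipeline is testable
without field data.

## The model

A plot observation decomposes as

```
y_ijkl = μ + G_i + T_j + Y_k + GT_ij + GY_ik + GTY_ijk + R_l(jk) + ε_ijkl
```

Method-of-moments estimates of σ²G, σ²GT, σ²GY, σ²GTY, σ²e from the
balanced ANOVA give broad-sense heritability on an entry-mean basis

```
H_BS = σ²G / (σ²G + σ²GT/t + σ²GY/y + σ²GTY/(t·y) + σ²e/(r·t·y)) × 100
```

and the expected response to truncation selection

```
GA = K · σP · H_BS/100 ,      genetic gain % = GA / mean × 100
```

with K = 2.06 the standardized selection intensity for the top 5% of a
normal distribution and σP the phenotypic SD of entry means.

The drought indices contrast an entry's mean yield under stress (rainfed,
`Yi_s`) and non-stress (restricted irrigation, `Yi_ns`), the normalized
ones relative to population reference means `Y_s`, `Y_ns`:
TOL = Yi_ns − Yi_s, MPI = (Yi_ns + Yi_s)/2, GMP = √(Yi_s·Yi_ns),
MRP = Yi_s/Y_s + Yi_ns/Y_ns, REI = (Yi_s/Y_s)(Yi_ns/Y_ns),
STI = Yi_ns·Yi_s / Y_ns².

## Worked example

The bundled example table holds per-entry mean yields (g/plot) under RF
and RI for ten half-sib families, their pooled population (`hsib`), the
base population, two checks, and the two parents of the original cross:

```python
import metgain as mg
from metgain.datasets import example_yield_means

tbl = mg.compute_index_table(example_yield_means(), "hsib")
print(tbl[["entry", "y_rf", "y_ri", "TOL", "MPI", "STI", "rank_STI"]]
      .round(2).head(8).to_string(index=False))
```

```
entry  y_rf  y_ri   TOL    MPI  STI  rank_STI
hs116 595.7 564.9 -30.8 580.30 0.94      11.0
 hs26 621.0 551.5 -69.5 586.25 0.96      10.0
 hs35 593.9 584.3  -9.6 589.10 0.97       9.0
 hs39 626.0 602.3 -23.7 614.15 1.06       8.0
 hs48 616.5 648.8  32.3 632.65 1.12       4.0
 hs65 710.8 638.8 -72.0 674.80 1.27       1.0
 hs68 623.0 628.3   5.3 625.65 1.10       5.0
 hs79 652.8 596.7 -56.1 624.75 1.09       6.0
```

A negative TOL means the entry yields more under stress than non-stress;
`hs65` combines the highest mean productivity (MPI 674.8 g/plot) with the
top stress-tolerance index (STI 1.27, rank 1).  Heritability and gain from
known variance components:

```python
vc = mg.VarComps(4.0, 2.0, 2.0, 2.0, 8.0, mg.DesignDims(g=100, t=2, y=2, r=2))
H = mg.broad_sense_heritability(vc)   # 53.33 (%)
GA = mg.genetic_advance(sigmaP=2.74, H_pct=H)           # 3.01 (g/plot)
gain = mg.genetic_gain_percent(GA, 550.0)               # 0.55 (%)
```

The full pipeline (load or simulate → gain tables → indices → t/Dunnett
tests → correlations → BLUPs) runs from a YAML config:

```
metgain analyze --config config.yaml
metgain indices --input means.csv --reference hsib
metgain simulate --entries 50 --out trial.csv --seed 1
```

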