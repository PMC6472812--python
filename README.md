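# refstab

Reference-gene stability analysis for RT-qPCR experiments.

Before a qPCR study can report that a target gene is up- or
down-regulated, it must normalize against reference genes (RGs) that
are themselves stable across the experimental conditions. `refstab`
implements the complete candidate-selection and validation workflow
used in plant stress-response studies and similar designs:

* **screening** of candidate RGs and target genes from RNA-Seq
  differential-expression statistics (flat in all contrasts:
  |log₂FC| ≤ 1 and P > 0.05; induced in ≥ 1 contrast: log₂FC > 2 and
  P < 0.05);
* **efficiency calibration** from serial-dilution standard curves,
  `E = 10^(−1/slope)`, with the conventional acceptable slope window
  [−3.58, −3.10] (≈ 90–110% efficiency);
* three **stability algorithms** on relative quantities
  `Q = E^(minCq − Cq)` or raw Cq:
  * *geNorm*: `M_j = mean_k SD_s(log₂ Q_j/Q_k)`, stepwise exclusion,
    normalization factors, pairwise variation `V_{n/n+1}` and the
    `V ≤ 0.15` rule for the optimal number of RGs;
  * *NormFinder*: model-based decomposition into intra-group variance
    and inter-group bias, `ρ = mean_g(|d̂_g| + √(γ̂²_g/n_g))`;
  * *BestKeeper*: Cq descriptives, SD > 1 exclusion, per-sample
    geometric-mean index, Pearson-r ranking;
* **consensus**: top-k congruence between algorithms and across all
  2^T − 1 factorial subsets of collection times;
* **target-gene expression** with the REST-style ratio
  `E_t^(ΔCq_t)/geomean_r(E_r^(ΔCq_r))` and a pairwise
  fixed-reallocation randomization test plus bootstrap intervals;
* a **synthetic-data generator** with known ground truth (injected
  shifts, known efficiencies) so every stage is testable without any
  instrument data.

See `docs/methods.md` for the models, assumptions, and design choices.

## Worked example

Simulate the built-in ten-gene benchmark (three stable genes G01–G03
among seven genes with graded injected shifts), then rank candidates
with all three algorithms:

```sh
$ refstab simulate cq --seed 42 --out sim
wrote 24 samples x 10 genes

$ refstab stability --cq sim/cq_long.csv \
    --efficiencies sim/efficiencies.csv --algorithm all --out stab
genorm: G03 > G02 > G01 > G04
normfinder: G07 > G01 > G03 > G02
bestkeeper: G01 > G02 > G03 > G04
```

The three zero-shift genes head the geNorm and BestKeeper rankings and
appear in every algorithm's top-4. `stab/` now contains one ranking
TSV per algorithm, the cross-algorithm congruence matrix, the geNorm
pairwise-variation series, and a JSON run manifest. The V series for
this run starts

```
n    v
2    0.0538
3    0.0705
```

so V₂/₃ ≤ 0.15 and two reference genes suffice for this dataset.
The congruence matrix shows 100% top-4 overlap between geNorm and
BestKeeper and 75% for the NormFinder pairs.

Quantify a target gene against the two best references at one
collection time:

```sh
$ refstab expression --cq sim/cq_long.csv \
    --efficiencies sim/efficiencies.csv \
    --targets G10 --refs G01,G02 --time 2h --iterations 2000 --seed 7
G10: ratio 17.54 (p = 0.0955, ns)
```

G10 carries an injected 4-cycle response at 2 h, hence the ~17-fold
ratio — yet the call is `ns`: with 3-vs-3 replicates a two-sided
randomization test has only C(6,3) = 20 reallocations and its smallest
attainable p is 0.1, whatever the effect size. Designs that need
p < 0.05 from this test require at least 4-vs-4 replicates (see
`docs/methods.md`).

The same functionality is available as a library:

```python
from refstab import (benchmark_spec, generate_cq_dataset,
                     relative_quantities, m_values)

ds, truth = generate_cq_dataset(benchmark_spec(), seed=42)
m = m_values(relative_quantities(ds))
print(m.nsmallest(3))   # the three stable genes, M ~ 1.1
```

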