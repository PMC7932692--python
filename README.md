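# sistermem

**Lineage-pair memory analysis for sisters-machine single-cell data.**

How long does a bacterium remember the state it inherited from its mother?
Along a single microfluidic lineage this question is confounded: a slowly
fluctuating trap micro-environment produces persistent correlations that
look exactly like inheritance.  A "sisters machine" — a mother-machine
variant whose trapping channels are joined pairwise by a v-shaped tip —
holds the *two daughters of one mother* side by side in an identical
environment, so the confound can be subtracted by comparing three kinds of
cell pairs:

* **SC** — sister cells, tracked from the division that created them
  (shared inheritance *and* environment);
* **NC** — neighbour cells: co-trapped, unrelated cells aligned at a frame
  where both start a cycle with nearly identical lengths (shared
  environment only);
* **RP** — random pairs from different traps, aligned artificially at a
  cycle start (shared nothing).

`sistermem` implements the statistics of this comparison and a calibrated
mechanistic generator of synthetic sisters-machine datasets to drive and
validate them.

## The statistics

For a property y (cycle time T, instantaneous length, elongation rate
α(t) = d ln L/dt, protein concentration f) measured on an ensemble of n
aligned pairs, the **pair Pearson correlation function**

> PCF⁽ʸ⁾(g) = (1/n) Σᵢ (yᵢ⁽¹⁾ − ⟨y⁽¹⁾⟩)(yᵢ⁽²⁾ − ⟨y⁽²⁾⟩) / (σ_y⁽¹⁾ σ_y⁽²⁾)

is evaluated per generation g (or per frame, for size), symmetrised over
the two orderings of each pair, with PCF = 1 at the alignment origin by
convention.  Memory is summarised by the half-life ln2/λ of an unweighted
least-squares fit of A·e^(−λg) over g ∈ [0, 10].  Complementary
difference statistics δy(t) = y⁽¹⁾(t) − y⁽²⁾(t) (growth rate over 6-min
windows, fluorescence per frame) are summarised by their across-pair
variance dynamics: sisters start with δf ≈ 0 and an *elevated* δα
variance (the smaller sister transiently grows faster, in inverse
proportion to the size fraction it received), and both relax to the
unrelated-pair plateau on characteristic timescales.

The generator couples exponential single-cell growth, adder division
control, AR(1)-heritable growth and size factors, static and dynamic
trap-shared environments, a transient post-division growth-rate
compensation, symmetric protein partitioning with finite-memory
expression noise, and multiplicative measurement noise, observed every
3 min.  See `docs/methods.md` for the model, its parameters and its
limitations.

## Worked example

```bash
sistermem simulate --preset LB-default --seed 1 --out run/
sistermem analyze --data run/lineages.tsv --seed 1 --out run/results/
```

or equivalently in Python:

```python
import sistermem as sm
from sistermem.pipeline import AnalysisParams, analyze_dataset

cfg = sm.get_preset("LB-default", seed=5)        # 700 v-traps, 30 generations
df = sm.simulate_experiment(cfg)                 # one row per cell per frame
bundle = analyze_dataset(df, AnalysisParams(n_sc_max=122, n_boot=300, seed=5))
print(bundle["counts"])
print(round(bundle["cycle_stats"]["mean_T_min"], 2))
print({k: (round(v, 2) if isinstance(v, float) else v)
       for k, v in bundle["half_lives"].items()})
```

which prints (numbers from this exact seed):

```
{'SC': 122, 'NC': 95, 'RP': 150, 'cycles': 42000, 'lineages': 1400}
34.39
{'sc_t_gen': 4.76, 'nc_t_gen': 1.24, 'rp_t_gen': 0.27, 'sc_over_nc': 3.83,
 'sc_size_gen': 2.48}
```

Reading: from ~120 sister pairs the cycle-time correlation decays with a
half-life of ~4.8 generations, while neighbour pairs — which share only
the trap environment — lose correlation within ~1.2 generations; the
inherited component of cycle-time memory therefore outlives the
environmental one roughly 4-fold here.  Random pairs carry no real
correlation, so their "half-life" is an artifact of fitting noise and
should be ignored.  Fitted half-lives from ~100-pair ensembles scatter
considerably between replicate experiments (the neighbour-pair value
especially — see `docs/methods.md`), which is why the headline numbers
below are medians over five replicates.  The bundle also carries the
time-resolved size PCF, the δα and δf variance series with their
saturation metrics, per-generation variance curves, the
average-rate-difference summary and full provenance (config echo, seed,
package version).

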