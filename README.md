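# synterate

Genome-rearrangement rates in prokaryotic clades, measured as the loss
of gene order conservation with evolutionary time.

Radiation-resistant bacteria repair DNA double-strand breaks with
unusual efficiency, yet their chromosomes turn out to be *less* stable
over evolutionary time than those of related, nonresistant species.
Testing that kind of claim needs a chain of comparative-genomics
machinery: one-to-one ortholog maps between genomes, order-based
rearrangement distances that are robust to how many orthologs two
genomes happen to share, a molecular-clock axis, a saturating decay
model with honest confidence intervals, and permutation inference that
respects the pairwise (non-independent) structure of the data.
`synterate` implements that chain for anyone comparing gene-order
evolution between groups of bacterial or archaeal genomes, together
with a clade simulator so the whole pipeline is testable without
downloading a single genome.

## The measures and the model

For a genome pair with `n` shared orthologs (best bidirectional hits
at ≥ 40% identity and ≤ 20% length difference):

- **GOC** (gene order conservation) — the fraction of orthologs whose
  neighbour is the same in both genomes: 1 for identical order,
  falling toward 0 as breakpoints accumulate.
- **Inversion distance** — the exact minimum number of segment
  reversals transforming one signed gene order into the other,
  computed from the breakpoint graph (cycles, hurdles, fortress):
  `d = (n+1) − c + h + f`.
- **GOC₂₅₀ / GRIMM₂₅₀ / GOC₁₀₀** — means of the two measures over 100
  random subsamples of 250 (or 100) orthologs, with identical
  subsamples feeding both measures. Fixing the subsample size makes
  pairs with very different shared-ortholog counts comparable.

Plotting GOC₂₅₀ against the pairwise 16S rRNA distance `x` (maximum
likelihood under HKY85) and fitting

```
GOC(x) = f_i + (1 − f_i) · pˣ
```

gives two interpretable parameters: `f_i`, the saturation floor (the
portion of ortholog neighbours that essentially never separate), and
`p ∈ (0, 1]`, the per-unit-time retention of gene order — the smaller
`p`, the steeper the decline, the faster the clade rearranges. Fits
use least squares with multi-start Nelder–Mead; confidence intervals
are BCa bootstrap (10,000 resamples by default). Per-species
**genome-stability indices** (mean residual against a reference fit)
and Fisher–Pitman permutation tests compare resistant (R) against
nonresistant (N) species; Tukey–Kramer HSD compares groups of
stability indices. Supporting analyses cover the five genomic
indicators of selection on genome organization (leading-strand gene
fraction, rRNA counts and origin distances, ΔGC skew, single-gene
ratio), exact-repeat scanning with a chance-significance length
threshold, and MUM detection for dot plots.

## Worked example

Simulate a 10-species clade in which 4 radiation-resistant species
invert their genomes three times faster, then fit and compare:

```python
import numpy as np, pandas as pd
import synterate as st

cfg = st.SimulationConfig(n_species=10, n_resistant=4, n_genes=500,
                          tree_model="yule", depth=0.08, rate_N=250.0,
                          rate_R=750.0, gene_loss_rate=0.3, seed=7)
clade = st.evolve_gene_orders(cfg)

rng = np.random.default_rng(1)
rows = []
for a, b in clade.pairs():
    est = st.resampled_estimate(clade.ortholog_map(a, b), 250, 100, rng=rng)
    rows.append({"species_a": a, "species_b": b, "x": clade.x(a, b),
                 "goc": est.goc_mean, "category": clade.pair_category(a, b)})

model = st.GeneOrderDecay(pd.DataFrame(rows))
res = model.fit().bootstrap_ci(n_boot=2000, rng=rng)
print(res.summary())
```

```
Gene-order decay model: GOC(x) = f_i + (1 - f_i) * p**x
  points:   45
  fit mode: free
  f_i  = 0.705042   95% CI [0.578689, 0.750628]
  p    = 2.03654e-05   95% CI [1.84209e-08, 0.00285843]
  SSE  = 0.0647846
```

The 45 genome pairs decay from GOC = 1 toward a floor of ≈ 0.71 (the
clade is shallow, so most neighbour pairs are still intact) at
retention rate `p ≈ 2e-05` per substitution/site. Category fits with
the saturation pinned to the pooled estimate order the rates exactly
as simulated — pairs containing resistant species lose gene order
faster (smaller `p` = steeper decline):

```
p(RR) = 1.000e-09
p(RN) = 7.081e-06
p(NN) = 3.532e-04

residual-category test p = 3e-05
stability R-vs-N test p  = 0.0333
mean stability index:  N +0.0143   R -0.0219
```

The residual-category permutation test (R-containing pairs vs N-N
pairs) and the per-species stability comparison both detect the
contrast; resistant species sit below the clade's typical decay curve
(negative indices = more rearranged than expected at their
divergence).

The same workflow is scriptable from the shell (`synterate simulate`,
`distances`, `divergence`, `fit`, `stability`, `features`, `repeats`,
`mums`, `run-all`); `synterate run-all --seed 2 --out run/` writes the
full report bundle (points table, fits, stability indices, tests) with
a config hash so reruns are bit-identical.

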