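# devconnectome

Analysis toolkit for asking how the developmental history of neurons shapes
the wiring of the *Caenorhabditis elegans* somatic nervous system — the 279
interconnected neurons whose lineage, positions and synaptic contacts are
essentially invariant across individuals. It is written for systems
biologists and network neuroscientists who want to quantify, on a connectome
plus per-neuron developmental metadata, how much of the wiring is explained
by four attributes: neurite (process) length class, birth cohort, cell
lineage, and bilateral symmetry.

## What it computes

**Attribute homophily.** For a partition of neurons by an attribute
(process-length class S/M/L, or the early/late birth cohort) the modularity

&nbsp;&nbsp;&nbsp;&nbsp;*Q* = (1/*L*) Σᵢⱼ [*A*ᵢⱼ − *k*ᵢⁱⁿ *k*ⱼᵒᵘᵗ / *L*] δ(*c*ᵢ, *c*ⱼ)

measures the excess of same-class connections over the degree-matched
expectation, with the class-pair decomposition *Q*₍XY₎ (Σ_X *Q*₍XX₎ = *Q*
exactly). Significance comes from two bespoke nulls: a label shuffle that
preserves class sizes, and a degree-preserving edge rewiring constrained by
physical reach (a connection is feasible only when the cell-body separation
does not exceed the sum of the two neurons' process lengths). Deviations are
reported as z-scores against the ensemble (population-SD convention).

**Lineage structure.** Sulston lineage-name strings (e.g. `ABprpapaap`) are
parsed into tree positions; the rung *R* is the division count from the
zygote, and the lineage distance *l* between two cells counts the dividing
progenitors on the tree path between them, so *l*max(*R*₁, *R*₂) =
(*R*₁−1) + (*R*₂−1) − 1 and distinct same-rung cells always have odd *l*.
Ganglion-level statistics of *l* are calibrated against a leaf-permutation
null that preserves the pairwise-distance multiset exactly. A stochastic
asymmetric branching model (independent branch probabilities P1 ≥ P2 per
rung, sharply reduced after a cutoff) simulates lineage trees and its
per-rung probabilities can be re-estimated from any observed tree.

**Dyadic regression.** The probability that a neuron pair is connected is
modelled as logit P(*Y*=1) = β₀ + β_p·X_p + β_b·X_b + β_s·X_s + β_l·X_l,
with indicators for same process class, same cohort and bilateral
partnership, and the integer lineage distance; plain maximum likelihood,
with Belsley condition indices as the collinearity screen.

**Cartography and circuits.** Within-module degree z-scores and
participation coefficients on a supplied module partition classify neurons
into roles R1–R7; functional-circuit completion curves and two-sample KS
tests compare circuit neurons' degree distributions with the rest.

**Synthetic worms.** `devconnectome.synthetic.generate_worm` produces a
complete dataset — branching-model lineage tree, bilateral pairs, bimodal
birth times and positions, and a connectome drawn from the logistic model at
planted coefficients under the reach constraint — so every stage runs and
can be calibrated (type-I error, coefficient recovery) without any external
download. All planted parameters are returned in a truth record.

## Worked example

```python
from devconnectome import generate_worm, SyntheticConfig
from devconnectome.homophily import homophily_report
from devconnectome.regression import build_design, fit_logistic
from devconnectome.symmetry import pair_connection_stats

table, conn, tree, truth = generate_worm(SyntheticConfig(seed=3))

res = homophily_report(conn, table.column("cohort"), graph="syn", n_real=100, seed=0)
print(f"Q = {res.Q:.3f}, null = {res.surrogate_mean:.3f} ± {res.surrogate_sd:.3f}, z = {res.z:.1f}")

fit = fit_logistic(build_design(conn, table, graph="syn"))
print(fit.coefficients.round(3))

s = pair_connection_stats(conn, table)
print(f"bilateral pairs: syn {s.p_syn_pair:.2f}, reciprocal {s.p_syn_recip:.2f}, "
      f"gap {s.p_gap_pair:.3f} (all-pair baselines {s.p_syn_all:.4f}, "
      f"{s.p_syn_recip_all:.4f}, {s.p_gap_all:.4f})")
```

prints (370 generated neurons):

```
Q = 0.095, null = -0.001 ± 0.006, z = 14.8
       estimate  std_err  p_value
const    -2.991    0.073      0.0
x_p       0.127    0.031      0.0
x_b       0.656    0.034      0.0
x_s       3.119    0.131      0.0
x_l      -0.054    0.004      0.0
bilateral pairs: syn 0.79, reciprocal 0.27, gap 0.500 (all-pair baselines 0.0646, 0.0027, 0.0102)
```

Birth-cohort homophily stands far above its shuffle null (z ≈ 15); the
fitted coefficients sit near the planted values (β_b = 0.71, β_l = −0.06),
with β_s inflated by the planted module overlay and β_p attenuated by the
reach constraint — both compositions the generator documents; and bilateral
partners are connected by gap junctions half the time against a ~1%
baseline. On empirical data the same calls run on tables loaded with
`devconnectome.io.load_neuron_table` / `load_connectome` (CSV edge lists of
`(pre, post)` rows).

The whole pipeline runs from the shell:

```bash
devconnectome run --synthetic --seed 7 --out report/
devconnectome regress --config config.yaml --graph syn
```

`report/` then holds tidy CSVs per stage plus `manifest.yaml` with the
config snapshot, per-stage seeds and output hashes; the same seed
reproduces every file byte for byte.

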