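# Methods

This note records the models, conventions and numerical choices behind
`devconnectome`, and what the synthetic-worm generator does and does not
emulate.

## Data model and conventions

A dataset is a neuron table (one row per neuron: 2D cell-body position in
mm on the anterior-posterior / dorsal-ventral plane, process-length class
S/M/L, birth time in minutes and stage Embryo/L1/L2/L3, Sulston lineage
name, ganglion G1–G10, functional type, bilateral partner, circuit
memberships F1–F9, topological module label) plus two binary edge sets:
directed chemical synapses and symmetric gap junctions.

* **Adjacency orientation.** `syn[i, j] = 1` means neuron *i* receives a
  connection from neuron *j*; edge-list files are `(pre, post)` rows and
  are transposed on load. This keeps the modularity formula literal with
  k_in(i) = Σⱼ A[i, j].
* **Binarization.** Connections are existence-only; synapse multiplicity
  and weights are ignored throughout.
* **Gap junctions.** The symmetric matrix is used directly, so the link
  count L counts each undirected junction twice and k_in = k_out = k.
  This makes gap-junction Q values directly comparable with directed ones.
* **Process classes.** S: ℓ ≤ L_body/3 (closed boundary), M: up to
  2·L_body/3, L: beyond. The body length defaults to the anterior-posterior
  span of the loaded positions, overridable, since the raw tables do not
  state one.
* **Cohorts.** early = embryonic stage; the numeric hatching time
  (default 800 min post-fertilization) is only a fallback when the stage
  label is absent.
* **Positions are 2D projections.** All distances are Euclidean in the
  AP–DV plane; this is a stated limitation of the position source, not a
  modelling choice.
* **Missing attributes.** Process class may be unknown for a subset of
  neurons (the empirical tables cover 225 of 279). Analyses that need an
  attribute either exclude the unlabeled neurons pairwise (modularity,
  dyad designs — the effective n is logged) or refuse with an explicit
  message when the whole column is empty.

## Homophily statistics

Modularity Q and the class-pair decomposition Q_XY follow the formula in
the README; both are evaluated as vectorized matrix sums and are tested
against a literal O(N²) double loop on all small random graphs. Two null
ensembles calibrate them:

* **Attribute shuffle.** Uniform random permutations of the label vector;
  class sizes are preserved exactly. Note that E[Q] under this null is not
  exactly zero but carries the familiar small negative finite-size bias
  (diagonal null-model terms always count as same-label); the test suite
  checks convergence to the analytic expectation rather than to zero.
* **Reach-constrained rewiring.** Degree-preserving double-edge swaps
  (directed for synapses, undirected for gap junctions). A proposed swap is
  rejected if it would create a self-loop or multi-edge, or if either new
  pair violates the reach constraint d(i, j) ≤ ℓᵢ + ℓⱼ. Because only the
  class of each neurite length is known, one numeric length per neuron is
  drawn uniformly within its class band ([0, L/3], [L/3, 2L/3],
  [2L/3, L]) once per realization (not per swap). The swap count
  (default 5×10⁵ per realization, 100 realizations) counts *attempts*;
  the acceptance rate is logged. z-scores divide by the population
  standard deviation of the ensemble samples.

The birth-cohort analysis stratifies connected pairs by cell-body distance
(thirds of the body length) and compares the counts of early–early /
early–late / late–late connected pairs with the rewiring null per stratum;
a stratum is flagged when a same-cohort count exceeds the null mean by more
than two null SDs.

## Lineage metrics

The rung of a cell is the length of its division path from the zygote,
read directly off the lineage-name string (AB counts as one letter;
non-AB founders carry built-in depth offsets from standard embryology:
P1 = 1, EMS/P2 = 2, MS/E/C/P3 = 3, D/P4 = 4, overridable).

The lineage distance between two distinct cells counts the **dividing
progenitors on the tree path** between them: with the last common
progenitor at rung k, l = (R_a − k) + (R_b − k) − 1. The division of the
common progenitor is shared by both lineages and counted once. This
convention — rather than the plain sum of divisions on both sides — is the
one consistent with three facts about the system: the maximum distance
between cells at rungs R₁, R₂ is (R₁−1) + (R₂−1) − 1; two distinct cells
on the same rung always have an odd distance; and the deepest observed
distance in the somatic nervous system is 25 (rung-14 cells). On leaf
names l is a metric (property-tested).

Ganglion-level means and coefficients of variation of l are compared with
an ensemble of trees whose neuron-to-leaf assignment is randomized by
repeated pairwise swaps (default 10⁴ swaps per realization, 10³
realizations), which decouples ganglion membership from tree position
while preserving the global multiset of pairwise distances exactly.
Internal-node division times, when not supplied, are linearly interpolated
between the zygote and the earliest descendant leaf and flagged imputed;
imputed times feed only the chrono-dendrogram export, never a statistic.

## Branching model

The lineage tree is modelled as an asymmetric branching process: each node
at rung r spawns branch 1 with probability P1(r) and, independently,
branch 2 with probability P2(r); a node with no branches is a terminal
leaf. The profile is piecewise constant around a cutoff rung, default
P1 = 1, P2 = 0.85 before and P1 = 0.25, P2 = 0.2 after. The source
descriptions place the change point at rung 9 in one place and rung 10 in
another, so the cutoff is an explicit parameter (library default 10; the
generator uses 9, see below); both values are exercised in tests. A hard
`max_rung` guard (default 16, above the empirical maximum of 14) prevents
non-termination under pathological profiles.

**Estimation.** The per-rung observables are f_any (fraction of nodes with
≥ 1 child, estimating P1 + P2 − P1·P2) and f_both (fraction with two
children, estimating P1·P2). The reported estimates invert these moments —
P1̂, P2̂ are the roots of x² − (f_any + f_both)x + f_both, with the
discriminant clamped at zero against sampling noise. Reading f_any as P1
directly is only consistent in the near-binary regime (P1 = 1); the
moment inversion coincides with it there and remains consistent elsewhere.
Both raw fractions are reported alongside the estimates.

## Dyadic logistic regression

Synapse designs use ordered dyads (each unordered pair contributes both
directions; the outcome matrix is directed while all four predictors are
symmetric), gap-junction designs unordered dyads; the convention is a flag
and coefficient magnitudes agree between the two, though standard errors
differ. The fit is plain MLE via `statsmodels` with no regularization and
no multiple-testing adjustment; the score identities (residuals orthogonal
to every predictor) are asserted in tests. Belsley condition indices are
computed on the unit-length-scaled predictor columns without the intercept
by default: an uncentered count predictor such as the lineage distance is
structurally near-collinear with a constant column, and including the
intercept would flag that alignment (top index ≈ 12 on any such design)
rather than dependence among the predictors, which is the question of
interest (all indices < 5 on realistic designs).

## Cartography

Within-module degree z uses the population SD over module members; the
hub threshold z ≥ 0.7 is inclusive. The participation coefficient is
P = 1 − Σ_c (κ_c / k)², zero for purely intra-modular nodes and at most
1 − 1/m. Role classes: non-hubs R1 (P ≤ 0.05), R2 (≤ 0.62), R3 (≤ 0.8),
R4 (> 0.8); hubs R5 (P ≤ 0.3), R6 (≤ 0.75), R7 (> 0.75) — upper-inclusive
throughout, so the thresholds partition the (z, P) plane without gaps or
overlaps (property-tested on a grid). Degrees default to the undirected
combined network (synapses in either direction plus gap junctions,
binarized union), the convention under which the supplied six-module
partition was derived; `syn`/`gap` are selectable. The KS significance
level is a configuration value (default 0.05) and every reported rejection
indicator records the alpha it used.

## Synthetic worm generator

The generator's defaults are the study conditions: ≈ 280 neurons, 66% of
them in bilateral pairs, 72% born before hatching, planted connection
coefficients at the magnitudes estimated for the real system
(β_syn = (−3.0, 0.35, 0.71, 1.78, −0.06) for
(intercept, process, cohort, symmetry, lineage); β_gap =
(−3.5, 0.22, 0.16, 3.22, −0.08)), with intercepts chosen to give a few
percent connection density. Construction:

1. **Tree.** One branching-model realization with cutoff 9 — under the
   default early/late probabilities this centers the leaf count on ≈ 270
   (mean over seeds), matching the somatic neuron count; cutoff 10 roughly
   doubles it. Leaf counts inherit the large variance of a branching
   process (SD ≈ 80), which is left as is.
2. **Cohorts and times.** Internal nodes at rungs 6–9 are greedily marked
   as "stalled" until the leaves below them make up the late fraction;
   early leaves get times linear in rung plus noise (all before hatching
   at 800 min), late leaves are dispersed uniformly over the larval
   stages, reproducing the bimodal birth-time distribution.
3. **Pairs.** Leaves are matched into partners within the same rung and
   cohort; same-rung distinct leaves have odd lineage distance by the
   parity theorem, so no extra constraint is needed. A configurable number
   of cross-rung (even-distance) exceptions is planted deliberately and
   recorded in the truth record. Pairs whose common progenitor is at rung
   ≤ 3 are labelled symmetric-blastomere origin, the rest non-symmetric.
4. **Attributes.** Process classes i.i.d. by the stated proportions but
   shared within a pair; positions from a bimodal head/tail AP mixture for
   S and L classes and uniform for M, with small DV jitter and partners
   mirrored across the midline; motor-heavy functional types in the late
   cohort; ganglia assigned by mapping rung-4 clades round-robin onto ten
   labels (so each ganglion is a union of lineage "families"); module
   labels uniform over six blocks, shared within pairs.
5. **Connectome.** Each dyad's connection is Bernoulli at the logistic
   model with the planted coefficients; the module overlay multiplies the
   odds within blocks (default ×3) and an optional early-hub bias
   multiplies the odds of dyads touching a marked subset of early neurons.
   The reach constraint is applied as post-hoc rejection (dyads whose
   cell-body separation exceeds the summed drawn lengths are zeroed),
   mirroring how the rewiring null treats feasibility rather than
   renormalizing the model.

**What passing tests on synthetic data do and do not show.** The generator
reproduces the marginal structures the analyses assume (bimodality, pair
parity, cohort bursts, planted homophily) but not the real system's joint
geometry: lineage does not drive position, ganglia are only weakly
spatially coherent, and there is no neurite anatomy beyond the reach
lengths. Parameter-recovery tests therefore disable the two deliberate
confounders — the module overlay (omitted-variable inflation of β_s by
log 3) and the reach filter (attenuation of β_p) — or use the pure dyad
simulator; pipeline-level tests keep them on and treat the shifts as the
documented compositions they are. Agreement on synthetic data does not
certify digit-level agreement on the empirical tables, which must be
supplied by the user.

## Numerical choices

* Bimodality coefficient: population-moment skewness and excess kurtosis
  with the explicit finite-sample term; n ≥ 4 and nonzero variance
  required; BC > 5/9 (the uniform benchmark) flags bimodality. Affine
  invariance is property-tested.
* Distance-profile binning: 10 equal-width bins by default (configurable);
  correlations on binned profiles are sign/magnitude comparisons, not
  digit-exact, because bin widths are a free choice. Lineage profiles bin
  on the observed integer distances. Bins left empty are dropped and
  logged; a degenerate (constant) profile reports an undefined
  correlation rather than a spurious one.
* Surrogate z-scores everywhere use the population-SD convention; a
  zero-variance ensemble yields an undefined z unless the empirical value
  equals the ensemble value exactly (then 0). SDs at machine epsilon
  (full-population resampling) are treated as zero.
* The pipeline derives one independent seed per stage from the global seed
  (stage-name-keyed), so adding a stage never perturbs the randomness of
  existing ones; with a fixed seed every report file is byte-identical
  across runs.
* Default problem sizes in the shipped test-suite and pipeline runs are
  scaled-down versions of the full analyses (surrogate ensembles of
  tens-to-hundreds of realizations, swap counts in the thousands, compact
  branching profiles); the full-scale defaults (10³ realizations,
  5×10⁵ swaps) remain the module-level defaults for real analyses.

## Known limitations

* Lineage distances are derived purely from name strings; an external
  distance table, if supplied, is cross-validated rather than trusted, and
  discrepancies are reported, not silently resolved.
* The rewiring null can stall on very sparse or tightly constrained
  graphs; the achieved swap count is logged and a low acceptance rate
  warns rather than fails.
* The dyadic model treats dyads as independent (no reciprocity or
  triadic dependence terms); it ranks attribute contributions, it does not
  claim to be a generative network model.
* Empirical reproduction of published point values requires the public
  connectome and developmental tables as inputs; the package ships only
  their schemas and the synthetic stand-in.
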