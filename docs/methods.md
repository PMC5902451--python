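# Methods

## Scoring model

Each candidate SAP receives up to three component scores in [0, 1].

**Interface score (I).** Binary membership of the mutated position in
any annotated interface residue range of its protein. Ranges are
1-based inclusive and combine by OR; membership is purely positional
(the residue identities play no role). A protein with no interface
annotation scores 0 — structural coverage is incomplete in real
interactome data, and absence of coverage is deliberately
indistinguishable from absence of interface involvement. This caps the
component's sensitivity but keeps its specificity high.

**Topology score (T).** Over the background PPI graph with unit edge
weights, `T_i = mean(d(i, neutral nodes)) / mean(d(i, cancer nodes))`.
Conventions, chosen to keep the ratio well-defined and unbiased:

* the source node is excluded from both target sets, so a
  cancer-annotated protein is scored by its distance to the *other*
  cancer nodes and cannot inflate its own score through a zero distance;
* unreachable targets are dropped from both averages (PPI networks have
  a giant component, so this is rare and affects both sets
  symmetrically);
* a protein absent from the network, or one from which an entire target
  class is unreachable, scores exactly 1 — indistinguishable from a
  random node.

Raw scores are min–max normalized over all network nodes; the constants
are persisted in the calibration model and later proteins clip into
[0, 1]. The fallback value 1 enters the extremes only if some node
attains it. Distances come from an all-sources breadth-first pass
(scipy's sparse-graph machinery) cached on the network object, making
whole-table scoring linear in SAPs after one O(V·E) pass.

**Conservation score (S).** `1 − SIFT`. SIFT tolerance probabilities
are inputs (table column or sidecar file; the sidecar wins on conflict,
logged). SAPs with no SIFT output keep S absent rather than S = 0:
the weighting rule below then removes the component, which is the
behaviour the weighted average is written for.

## Condel fusion

`WAS = Σ Sᵢ Wᵢ / Σ Wᵢ`. The weight of a present component is one minus
the empirical probability that a training mutation of the *opposite*
class exceeds the observed score: opposite = neutral when the component
alone calls the SAP deleterious (score ≥ θ_c), deleterious otherwise.
Exceedance is a strict-count empirical tail — no binning or smoothing —
so ties resolve toward the larger weight; this matters for the I-score,
whose deleterious mass sits entirely at 1.0. Absent components weigh 0.
When every weight is 0 the SAP is flagged *unscorable* (score 0) so
ranking can distinguish "no evidence" from "evidence of neutrality".
When exactly one component has positive weight the WAS returns that
component's score exactly (special-cased to avoid `s·w/w` floating-point
drift).

Component cutoffs default to θ_S = 0.95 (the customary SIFT 0.05
tolerance cutoff mapped through S = 1 − SIFT), θ_T = 0.9 on the
*normalized* T-score, θ_I = 0.5 (an interface hit is a deleterious
call); the meta cutoff defaults to 0.9. All are configuration. θ_T can
optionally be re-derived from training data by maximizing Youden's J
(ties toward the higher threshold, favouring specificity).

## Evaluation

Stratified k-fold cross-validation (default k = 10, seeded shuffle).
The Condel weight samples and cutoffs are refit inside every fold from
the k−1 training folds only; the T normalization is network-derived and
unsupervised, so it is fit once globally. Both the pooled held-out
report and per-fold means are returned — the literature is split on
which aggregation to quote, and they answer slightly different
questions. AUC is the rank-based Mann–Whitney estimator (ties count
1/2); MCC uses the determinant formula with the zero-marginal
convention MCC = 0.

## Synthetic benchmark

The generator emits a complete instance: scale-free background network
(Barabási–Albert, m = 2, matching the ~1.7 edges-per-node density of
curated human interactome snapshots; Erdős–Rényi retained for null
tests), a cancer-node subset (14% of nodes, drawn uniformly by default
with a hub-biased option, since known cancer genes skew high-degree),
interface ranges on half the edges (widths 10–50 on proteins of length
200–800), 400 deleterious + 1,200 neutral SAPs across 95 samples, and a
survival table.

Planted signal per label:

* deleterious SAPs hit an interface with probability 0.41 vs 0.01 for
  neutral ones — the sensitivity/specificity regime reported for
  interface evidence on real cancer training data, implying a binary
  AUC near 0.70;
* SIFT tolerances draw from Beta(1.6, 2.8) (deleterious) vs
  Beta(2.8, 1.6) (neutral), whose analytic P(X < Y) is 0.818, matching
  the discrimination SIFT shows on cancer benchmarks;
* with probability 0.85 a deleterious SAP's protein comes from the
  cancer-proximal pool — the 15% of nodes with the smallest relative
  mean hop distance to the cancer set. The pool formulation plants
  exactly the property the T-score measures, the same way interface
  membership is planted for the I-score. A fixed 1–2-hop neighbourhood
  was rejected at design time: on a small-world scale-free graph it
  covers ≈95% of nodes around a 14% cancer subset and carries no
  signal.

Survival times are exponential with log-hazard linear (coefficient 0.25
per SAP) in the sample's planted deleterious-SAP count around its mean,
baseline hazard 1/1000 days⁻¹; censoring is an independent exponential
time calibrated to a 20% censoring fraction. A separate helper plants a
clean two-group draw with a specified hazard ratio for
parameter-recovery checks.

Each sub-generator draws from its own named stream of the master seed,
so extending the generator never perturbs existing draws; identical
configurations emit byte-identical files (scores serialized at 6
decimal places).

What the generator does *not* emulate: identifier semantics (accessions
are opaque), realistic protein sequences or structures, degree-correlated
mutation rates, correlated component evidence (the three signals are
planted independently given the label), and inter-patient heterogeneity
beyond uniform SAP-to-sample assignment. Passing tests therefore
demonstrate correct recovery of independently planted signals, not
performance on real interactome data.

A consequence of the synthetic score distributions: at the default meta
cutoff 0.9 the benchmark yields high specificity (~0.99) but low
sensitivity (~0.05), because synthetic component scores are less extreme
than real training data; discrimination (AUC ≈ 0.94) is unaffected.
Under defaults the component pattern is S ≈ 0.82, T ≈ 0.87, I ≈ 0.70,
meta ≈ 0.94, with the topology component the strongest single signal.

## Survival stage

Per-sample burden = sum of the top-30 meta-scores (all scores when a
sample has fewer). The split statistic is the mean by default, with the
median provided as an alternative — descriptions of this analysis in the
literature disagree between the two, so both are implemented and neither
is asserted as canonical. Ties at exactly the split value go to the low
group (strict ">"). Group comparison delegates to lifelines: two-group
log-rank test plus a single-covariate Cox proportional-hazards fit on
the group indicator; the hazard ratio is exp of the fitted coefficient
(high vs low).

## Numerical and degenerate-input choices

* Strict-mode input validation by default (any invalid row rejects the
  file with row-level messages); lenient mode drops rows with a logged
  count.
* Ranked score tables break meta-score ties by (protein, position) so
  output is deterministic.
* An all-identical raw T distribution makes min–max normalization
  degenerate and is an error, as are an empty cancer subset, a
  single-class training set, and an all-equal burden distribution.
* Calibration sorts its per-class samples, so it is invariant to
  training-row order.

## Problem sizes

The default benchmark (1,000 nodes, 1,600 SAPs, 95 samples) is the
package's reference condition; effect sweeps run at 300 nodes and 480
SAPs over 10 seeds per level, and survival recovery uses n = 200 samples
over 10 seeds (200 replicates for null calibration). These sizes give
stable estimates while keeping the full suite fast on one CPU.
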