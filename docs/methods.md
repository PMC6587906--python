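# Methods

This note documents the model, the numerical choices, the synthetic
benchmark and the open design decisions of `tfnetprop`, in enough detail to
reproduce or re-derive any behavior of the package.

## Data model

- **Template network** `G = (V, E)`: directed TF → target edges. Edge
  sources must be TFs; TF → TF edges are allowed and essential (regulatory
  cascades reach DEGs through intermediate TFs). Self-loops are rejected;
  duplicate edges collapse keeping the last weight.
- **Expression** `e_{i,j,k}`: gene *i*, time *j* = 0..T (0 is the
  unstressed baseline), replicate *k* = 1..K.
- **Differential expression** `d_{i,j}`: a statistic from an external DEG
  caller comparing time *j* to baseline (limma z-score or DESeq2 log2 fold
  change) with a p-value. A gene is a DEG at *j* iff `p < α_deg`
  (strict; default 0.05). When a d-only file is supplied, a two-sided
  p-value is derived treating d as a standard-normal z-score.
- **Edge weights**: Pearson correlation of the two endpoint genes over all
  post-baseline samples (j ≥ 1, all replicates). The baseline is excluded
  because correlation under perturbation, not at rest, carries the
  regulatory signal. Edges with a missing endpoint or a zero-variance
  series get weight 0 rather than being dropped, so the template topology
  is independent of the weighting (the count is reported). Signed weights
  are retained in the containers; the sign policy is applied downstream.

## Stage 1 — time-specific networks

`V_j = (TGset ∩ DEGset_j) ∪ TFset`, intersected with the template's nodes;
`E_j` is the induced edge set. TFs are always included, DEG or not: a
regulator's transcript change is a poor proxy for its regulatory role.
DEGs absent from the template are dropped (counted in a coverage report) —
the template defines the analyzable universe. Non-DEG, non-TF intermediary
genes are not retained. Isolated TFs stay in `V_j` and simply earn zero
influence, which keeps the ranking universe constant across time points.

## Stage 2 — influence ranking

Independent-cascade Monte Carlo: each round retains edge `e` with
probability `p_e = clamp(w_e, 0, 1)` (alternative `|w_e|` behind
`prob_map="abs"`). Negative-PCC edges therefore never transmit under the
default — the method deliberately does not model inhibition, because the
downstream random walk does not converge with negative weights. One
subgraph is sampled per round and shared by all TFs. A TF's contribution is
`Σ_{s ∈ R\TFset} DE(s) / |R|` with `R` the set of nodes reachable from the
TF, excluding the TF itself (self-influence is meaningless and would
distort the denominator); `|R| = 0` contributes 0. Note the asymmetry, kept
deliberately: TFs are excluded from the numerator but counted in the
denominator, so `IL` is the expected DE mass per reachable node — a purity-
rather than volume-flavored score. `IL` is the mean over rounds (default
1000). Ranking ties break by node DE (descending), then gene id, making
the ranking deterministic.

Implementation: reachability uses `scipy.sparse.csgraph` BFS per TF per
round. For networks with ≤ 14 edges the per-subset contribution of every
TF is enumerated once (2^|E| subsets) and each round's per-edge uniform
draws index that table; this is draw-for-draw identical to the explicit
loop (a test asserts equality) and makes high-round oracle comparisons
cheap. `exact_influence` computes the exact expectation by full subset
enumeration (cap 16 edges) and is the package's internal oracle;
`exact_influence_moments` additionally returns the per-round contribution
variance, giving exact sampling error bars for Monte-Carlo checks.

Properties that hold exactly and are tested: `IL` is linear in the DE
vector; zero-weight edges and isolated nodes are inert; fixed seed implies
bit-identical scores.

## Stage 3 — propagation and greedy selection

Transition matrix: `W[v,u] = w⁺(u→v) / Σ_x w⁺(u→x)` with `w⁺ = max(w, 0)`
— column-stochastic out-degree normalization, so mass flows along the
TF → target direction. Dangling columns are zero: their walk mass leaks and
only restart replenishes it (`Σ p_k ≤ 1`, equality without dangling
nodes). An `in_degree` normalization is available behind a flag.

RWR: `p_k = α p_0 + (1−α) W p_{k−1}`, iterated until the L1 change falls
below `tol` (default 1e-9, cap 1000 iterations, warning + last iterate on
non-convergence). The fixed point equals `α (I − (1−α)W)^{-1} p_0`; tests
require agreement within `10·tol`. The restart rate α defaults to 0.1,
favoring network smoothing over the prior — consistent with the method's
emphasis on multi-step regulation — and is a surfaced parameter since
results depend on it.

Seed vector for a candidate set `S`: `p_0(t) = DE(t)` for `t ∈ S`,
normalized to sum 1; uniform over `S` if all seed DE vanish. DE-weighted
seeding mirrors the use of DE as node information in the influence stage.

Objective: Spearman rank correlation between `IP(v)` and `DE(v)` over all
of `V_j` (average ranks on ties; defined as 0 for constant vectors). The
greedy pass seeds with the top-ranked TF unconditionally, then accepts each
next TF iff the trial SCC is *strictly* greater than the current best
(ties reject). It stops as soon as the accepted TFs directly cover more
than half of `deg_set`; the check runs after each acceptance, not after
rejections.

Two open readings were resolved as follows:

- **Coverage** is the count of `deg_set` genes that are *direct*
  out-neighbors of the selected TFs (simplest verifiable reading); a
  propagation-flavored alternative counting path-reachable DEGs is
  available via `coverage_mode="reachable"`.
- **Candidate pool**: only TFs with `IL > 0` are tried. A TF with zero
  estimated influence has no sampled path to any DEG; admitting it lets a
  high-DE but network-irrelevant TF be accepted purely because restart
  mass on a high-DE seed flatters the rank correlation. The first-ranked
  TF still seeds the set unconditionally.

The result network `MTFnet_j` contains the selected TFs plus every
`deg_set` gene reachable from them along paths whose intermediate nodes
are themselves selected TFs (unselected TFs do not relay explanations),
with all induced edges; every non-TF node in it is a DEG.

Control variant: seed DEG sets become `DEGset_j^stress − DEGset_j^control`
per time point (time grids must match); everything downstream is
unchanged. With an empty control profile the variant is exactly the plain
run (tested).

Per-time-point RNG seeds derive from `SeedSequence([master_seed, j])`, so
time points are independent, individually reproducible and order-free; the
manifest records every derived seed. Serialized outputs use fixed float
formatting and sorted orders, making identically seeded runs byte-identical.

## Synthetic benchmark

The generator emulates the statistical structure the method assumes: DE
signal concentrated on the regulons of a few per-stage master regulators,
propagating a limited distance through the TF layer, over Gaussian noise.

- **Template**: each of `n_tf` TFs regulates `1 + ⌊Pareto(2) · n_tg/30⌋`
  distinct targets, truncated at `n_tg/15` — heavy-tailed ("power-law-
  like") regulon sizes with a bounded maximum. TF → TF edges appear with
  probability 0.02, matching the density of a real plant regulation
  template (~280 targets per TF out of ~25k genes). The truncation and the
  planting floor below are identifiability requirements: an unbounded tail
  lets one regulon span more than half of all DEGs, at which point the
  method's own stopping rule truncates recovery no matter how well it
  ranks, and regulons of a handful of genes are indistinguishable from the
  α-level false DEGs.
- **Planting**: per stage, `n_active` master TFs (default 3 over 3
  stages), disjoint across stages, drawn from TFs with ≥ `n_tg/30` targets
  (master regulators have large regulons; falls back to the largest
  regulons if the draw under-fills).
- **Signal**: when a regulator is active, its direct targets — and the
  regulator's own transcript — shift by `effect_size` (default 3) on the z
  scale of the induced test; targets of a regulated TF shift at half
  strength (2 hops maximum, damping 0.5). The regulator's own shift is
  what gives the correlation-based edge weighting signal to work with.
  Signs are random per gene and fixed across replicates and stages.
- **Noise and nuisance**: expression is `Normal(8, noise_sd)` per
  replicate (default sd 1, K = 2 replicates); `d` is the exact two-sample
  z-statistic (known variance), so the DEG threshold has analytic
  operating characteristics — e.g. power 0.851 at effect 3, which the
  consistency tests use with binomial slack. Spurious DEGs are injected at
  `background_rate` (default 1%) with their own magnitude (3 z-units),
  independent of `effect_size`.
- **Background program**: optionally one additional regulator, active in
  *both* the stress and the control series, with square-wave activity
  (sign alternates across time points, giving its targets both detectable
  shifts at every time point and strong correlation with the regulator)
  and amplitude 5 z-units — a strong, circadian-like confound whose
  targets the control DEG caller detects with power ≈ 0.999, so control
  subtraction tests the subtraction logic rather than DEG-calling power.

What the generator does **not** emulate: microarray intensity
distributions, replicate-specific batch effects, continuous waveforms,
inhibitory (negative) regulation, or feedback loops. Passing recovery
tests therefore demonstrates correctness of the machinery under the
method's own assumptions, not performance on real transcriptomes.

## Evaluation utilities

Precision/recall/F1 against a truth set (zero-denominator cases return 0),
at TF level (selected sets) or gene level (non-TF network nodes), and the
Jaccard overlap of node sets of adjacent time-point networks (0 when both
empty).

## Problem sizes used by `scripts/acceptance.py`

- Influence oracle: 20 random networks (2–4 TFs, 3–7 targets, ≤ 12 signed
  edges), 20,000 rounds, 4-sigma bars from exact variances.
- Fixed point: 24 random graphs (≤ 50 nodes), α ∈ {0.1, 0.5, 0.9}.
- Monotonicity: 50 runs of a 10-TF/60-gene benchmark at 200 rounds.
- Recovery: 20 seeds of the default 30-TF/300-gene/3-stage benchmark at
  1000 rounds; the same runs yield the adjacent-overlap summary.
- Control subtraction: 20 seeds with the background regulator, plain vs.
  subtracted, 1000 rounds.
- Determinism: one 10-TF benchmark fitted twice and saved; files compared
  byte-wise.

## Known limitations

- Inhibitory regulation is invisible by design (negative weights are
  clamped); anti-correlated TF → target pairs contribute nothing.
- The greedy pass is order-dependent by construction: a TF rejected early
  is never revisited, and acceptance uses strict improvement, so plateaus
  end the growth of the seed set's explanatory power.
- The template is trusted as given; false edges propagate influence.
- Unobserved time points are not interpolated; each time point is analyzed
  independently.
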