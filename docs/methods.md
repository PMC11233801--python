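# Methods

## The analysis

`mdbn` studies how the functional organization of a multi-channel EEG
recording evolves over the final seconds before a behaviorally relevant
event (here: an anticipated vehicle collision in a driving-simulator task
with three conditions — a non-alert baseline NAS, alert trials ending in a
collision AS-CE, and alert trials without one AS-NC).  The pipeline is:

1. **Preprocessing** — resample to 256 Hz (polyphase, anti-aliased),
   zero-phase FIR band-pass into theta (4–8 Hz), alpha (8–13 Hz) or beta
   (13–30 Hz), cut 3-s epochs ending at each event (half-open `[t−3, t)`),
   common-average reference, Hilbert analytic phase.  The phase is computed
   on the whole epoch *before* windowing, so the sliding windows carry no
   per-window Hilbert edge artifacts.
2. **Connectivity** — phase-lag index (PLI) between channel pairs,
   `PLI = |⟨sign(Δφ(t))⟩|`, over five 1-s windows stepped by 0.5 s (W1–W5;
   W5 ends at the event).  PLI discards zero-lag synchronization and with
   it most volume-conduction artifact.  Intra-window PLI gives the layer
   adjacency A_l; PLI between the phases of two different windows (samples
   aligned by within-window offset, all channel pairs including a channel
   with itself) gives the inter-layer blocks H_lm.
3. **Multi-layer network** — the blocks are stacked into one
   (C·L)×(C·L) supra-adjacency matrix (all-ones inter-layer pattern).  A
   per-band threshold is the 95th percentile of the pooled upper-triangle
   PLI values of the three condition-average supra matrices — diagonal and
   off-diagonal blocks pooled together so within- and between-window
   connections are weighed equally.  Thresholding zeroes sub-threshold
   entries but keeps surviving weights.
4. **Metrics** — multilayer modularity Q (Mucha null model, generalized
   Louvain), multiplex participation coefficient (MPC, binary degrees),
   layer–layer Pearson correlation (LLC), and seven weighted single-layer
   metrics per thresholded window block: node strength, path length, local
   efficiency, betweenness, eigenvector centrality, clustering coefficient
   (global mean), assortativity.
5. **Statistics** — Shapiro–Wilk and Levene assumption checks (logged, not
   fatal), one-way ANOVA across the three conditions per metric cell,
   Benjamini–Hochberg FDR within each (band, metric) family, star
   convention `*`/`**`/`***` at 0.05/0.01/0.001.
6. **Classification** — 22 biomarker features (alpha: Q, W4 node strength
   at Pz/P4/T6/FT7/CP4, W4 local efficiency at Fp1/P3/P4/T6/CP4/CPz, W4
   global CC; beta: W5 node strength at F3/Fz/C4/CP3/CP4, W5 local
   efficiency at F3/P3/FC4, W5 global CC), stratified 5-fold CV with
   SVM (linear/RBF), random forest (500 trees) and 3-NN; standardization is
   fit inside each training fold.  Sensitivity/precision treat AS-CE
   (collision) as the positive class.  A single-layer-only ablation drops
   the multilayer (Q) column under the identical protocol.

## Multilayer modularity

Quality of a node-layer partition under the Mucha et al. multilayer null
model:

    Q = (1/2μ) Σ_{ijlm} [ (A_l[ij] − γ_l k_il k_jl / 2m_l) δ_lm
                           + δ_ij ω (1−δ_lm) ] δ(g_il, g_jm)

with per-layer resolution γ_l = 1, uniform inter-layer coupling ω = 1
(neither is reported by typical studies; both are exposed in config), and
2μ = Σ_l 2m_l + ω·C·L·(L−1).  The measured inter-window PLI blocks are
*data* (they enter thresholding and LLC); the modularity coupling between a
node's copies is the parameter ω, per the standard formulation.  The
optimizer is a dense-matrix generalized Louvain (greedy local moves +
community aggregation) with seeded random restarts (100 by default at the
function level; the pipeline uses 20, which on these 160-node-layer
networks always reproduced the 100-restart optimum in our checks).  Q is
reported unclamped; the textbook "0 to 1" range is descriptive, not an
invariant.

Correctness anchors: Q of the one-community partition of a single layer is
exactly 0 at γ = 1; on an 8-node two-clique toy graph the optimizer matches
exhaustive search over all 4,140 partitions; at ω = 0 on identical layers
the multilayer Q equals the single-layer value; at ω = 1 identical layers
yield layer-consistent labels.

## Single-layer metric conventions

* Weight→length map is reciprocal, `d = 1/w`, the dominant convention for
  PLI graphs.
* Path length averages *finite* distances only; unreachable pairs are
  excluded rather than assigned an arbitrary ceiling (isolated nodes are
  NaN).
* Local efficiency of node i is the efficiency (mean of 1/d over ordered
  pairs) of the subgraph induced by i's neighbors; < 2 neighbors ⇒ 0.
* Clustering is the Onnela geometric-mean-of-triangle-weights form,
  normalized by the maximum weight in the graph (scale-invariant); the
  binary verbal definition is ambiguous for weighted graphs.
* Betweenness is normalized by (C−1)(C−2)/2.
* Assortativity is the Pearson correlation of endpoint strengths over
  edges, each undirected edge contributing both orientations; zero-variance
  graphs (e.g. regular) are NaN.

Every metric is tested for equality against a brute-force oracle
(Floyd–Warshall, exhaustive simple-path enumeration, triple-loop triangle
counting, direct eigendecomposition, direct Pearson) on 100 seeded random
graphs of ≤ 6 nodes.

## The synthetic generator

`mdbn.synthetic` plants a known coupling graph per (condition, window):
channel pairs with coupling c share a common sinusoidal oscillator with
weight √c at a fixed phase lag (π/2 in the default scenario), each channel
keeps a private oscillator with weight √(1−c) whose frequency is jittered
by 10% (relative sd) so uncoupled channels drift rather than lock, and 1/f
noise (power exponent 1) is added at `noise_sd` relative amplitude (0.5 by
default).  Window-resolved coupling is realized on the six half-second
sub-segments of a 3-s trial, each taking the mean coupling of the windows
that cover it.  PLI on the generated data is a monotone function of the
planted c — exactly 1 at c = 1 with no noise, null-level at c = 0 —
verified as a Spearman-ρ > 0.9 parameter-recovery test.

The `paper-like` scenario plants a ring of coupling over 13
frontal/central/parietal electrodes (the biomarker channels): NAS flat at
0.15; AS-CE ramping 0.2→0.85 through W3–W5; AS-NC ramping then collapsing
to 0.25 in W5.  Ten trials per condition by default (the alert task of the
emulated dataset has ten collision and ten no-collision trials per
participant).  A ring rather than a clique keeps the per-edge shared
variance — and hence the planted pairwise PLI — high.

What the generator does *not* emulate: volume conduction and reference
leakage, non-sinusoidal waveforms, inter-participant variability, ocular or
muscular artifacts, and realistic scalp topography.  Passing tests
therefore demonstrate that the estimators recover planted structure of
this idealized kind, not that the biological claims of any particular
dataset reproduce.

## Numerical choices

* FIR band-pass: windowed-sinc (Hamming), transition bandwidth 25% of the
  low cutoff, odd tap count, applied forward-backward (`filtfilt`) for an
  identically zero passband phase.
* Phases are wrapped to (−π, π]; `sign(0)` contributes 0 to PLI (exact-zero
  differences are kept).
* The pooled threshold uses the empirical quantile (`numpy.quantile`,
  linear interpolation) of upper-triangle values; on a symmetric matrix the
  one- vs two-triangle choice does not change the quantile.
* Louvain ties in Q are broken first-found; move tolerance 1e−12.
* Degenerate inputs: empty (all-zero) networks make Q a ValueError and are
  recorded as missing; LLC of a zero-variance block is NaN; MPC of an
  everywhere-isolated node is 0.
* All random operations take explicit integer seeds; the pipeline derives
  per-band child seeds from the global seed via `numpy.random.SeedSequence`.

## Problem sizes used in the bundled checks

The end-to-end checks run the alpha band with 8 trials per condition, 5
Louvain restarts and 4-fold CV over 20 seeds; the parameter-recovery check
uses 50 replicate trials per coupling level.  These sizes are the package's
own choice of a desk-scale experiment; larger runs only sharpen the same
comparisons.

## Known limitations

* Inter-layer PLI of strongly stationary narrowband signals saturates near
  1, so the pooled threshold is dominated by inter-layer values when
  coupling is stationary; real EEG is far less stationary.
* The generalized Louvain is a heuristic; restarts mitigate but do not
  abolish local optima on large networks.
* The t-SNE embedding is for visualization only; no cluster-quality claims
  attach to it.
* With trials pooled as the statistical unit, within-participant dependence
  is ignored; participant-level averaging is available as a config
  alternative.
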