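# Methods

This note documents the models, parameter choices and numerical decisions
behind `gridscreen`, and what the synthetic-data experiments do and do not
demonstrate about real screens.

## Dynamic mass-aware gridding similarity

Each sample is reduced to a sparse occupancy map: after denoising, every
marker axis is divided into `n` equal-width intervals between the sample's
own per-channel minimum and maximum, and each event is assigned the integer
index vector of its hypercube.  The top interval is closed on the right so
maxima land in bin `n − 1`; ties at interior boundaries resolve by the
floor rule, deterministically.  Channels with zero range carry no
positional information and are dropped with a warning; a single-event table
occupies one hypercube with mass 1.  Only occupied cubes are stored and
visited ("dynamic" = data-adaptive sparse enumeration; no recursive
multi-resolution refinement is attempted).

Because the grid is built from each sample's own range, the index vectors
— and therefore the similarity — are exactly invariant under any strictly
increasing per-channel affine map of one sample's intensities.  This is
the mechanism behind the method's robustness to signal shift (drift, batch
effects) without explicit correction.  Note the limit of this guarantee:
the LOF denoising step is invariant under rigid translations and uniform
scalings but not under anisotropic per-channel rescaling, so exact
invariance of the full pipeline holds for per-channel *shifts*; with
denoising disabled it holds for all positive affine maps.

Two occupancy maps are compared per cube by `min(p, q) / max(p, q)` —
equivalently `1 − |p − q| / max(p, q)` — averaged over the union of
occupied cubes and scaled to 0–100.  Cubes exclusive to one sample score
0; identical maps score exactly 100.  The unweighted average makes the
score sensitive to low-mass boundary cubes: two finite i.i.d. draws from
the same distribution plateau well below 100 (≈75–85 at 10⁴ events for a
two-population mixture), converging to 100 monotonically as sample size
grows.  Rankings — which sample is most similar to which — are what the
score is used for downstream, and those are stable at desk scales.

**Parameters.**  `n` (intervals per axis, default 5) is assay-specific;
published analyses of comparable assays used 3–5 depending on channel
count.  LOF denoising uses `k = 30` neighbours and threshold 1.5 on the
standard LOF score, capped at 10% of events (worst offenders first).  On
wells above 50,000 events the LOF model is fitted on a seeded uniform
subsample and out-of-sample events inherit their nearest fitted
neighbour's score, keeping the step deterministic and near-linear.
Denoising is computed once per sample and cached, not per pair.

## Graph clustering

The pruning cutoff is the minimum edge weight of the maximum spanning tree
over negative-control wells (after outlier-control removal): the weakest
link that still keeps all controls mutually connected.  Edges exactly at
the cutoff are retained, so the controls themselves always remain
connected.  Inactive = path-connected to any control (not merely
adjacent); everything else is active.  Maximal cliques over active wells
use pivoting Bron–Kerbosch (`networkx`), with singleton cliques reported
and output sorted lexicographically; the enumeration refuses graphs above
5,000 active nodes.  Communities come from walktrap (`igraph`) with walk
length 4 on the weighted pruned graph, renumbered in first-member order.

A structural property of this cutoff worth knowing: it is the
connectivity bottleneck of the control graph, roughly the
`1 − ln(m)/m` quantile of the control-pair similarity distribution for
`m` controls.  A fresh well exchangeable with the controls therefore
fails to connect with probability on the order of `1/m`.  In real screens
this is mitigated because untreated wells vary biologically (lowering the
bottleneck) while replicate responses are reproducible; the synthetic
end-to-end experiment models exactly that (below).

## Bias correction

Intra-plate: per plate and channel, OLS of well medians on read order;
every event in a well read at order *t* is shifted by `b·(t̄ − t)` — the
line rotates to slope zero about the mean read order, each well moves
rigidly, and the plate's mean level is preserved.  Viability: the same
regression on live counts, applied multiplicatively (`count · f(t̄)/f(t)`)
since counts cannot go negative; a fitted line non-positive at any well is
an error.  Inter-plate: per channel, each plate is translated so its
median (over negative-control wells when every plate has ≥ 3, else all
wells) meets the median of plate medians.  Order: intra-plate signal →
viability → inter-plate.  On noise-free inputs the full correction is
idempotent to 1e−9.

## Quality control

Plate heatmap statistics (channel medians, live counts) are
rank-normalized to the empirical CDF (mid-ranks for ties), making the
palette invariant under monotone transforms.  Drift is flagged by the
two-sided OLS slope test at p < 0.01; edge effects by a two-sided
Wilcoxon rank-sum of border vs interior wells at p < 0.01 (the artifact
is named in the screening literature without a canonical test; rank-sum
is distribution-free and behaves at 384-well counts).  Outlier negative
controls are removed once (no iteration) when their median similarity to
the other controls falls below the lower Tukey fence (Q1 − 1.5·IQR) of
those per-control medians, capped at half the controls.  The fence is
computed over per-control medians rather than all pairwise values because
an aberrant control contaminates a large fraction of the pairwise pool
(2/m of all pairs), which would drag Q1 to the outlier's own level and
blind the rule.

## Synthetic screens

`simulate_screen` lays wells on 384-well plates (controls first, then
drug × dose × replicates, read order following layout), draws each well's
events from a Gaussian mixture, and injects artifacts as functions of read
order, plate and position: linear per-channel signal drift, per-plate
batch offsets, additive border-well edge effects and a linear viability
trend.  Event counts are Poisson around the nominal per-well count so
wells genuinely differ in size.  Dose response is a Hill curve in dose
(logistic in log-dose).  Effects: `mean_shift` (translate a population),
`abundance_shift` (additive weight change, renormalized; a per-population
vector expresses subtype-specific kill or expansion), `viability_loss`
(expected-count reduction — note that pure count loss is invisible to a
mass-fraction similarity, by design).

Two pieces of biological realism matter for the end-to-end experiments:

- **Well-to-well variability** (`well_jitter_sd`): each well's population
  means get independent offsets drawn uniformly (bounded support —
  plate-level biology varies within limits) with the given sd.  Untreated
  and inert wells scatter accordingly.
- **Canalization**: the jitter is scaled by `1 − response fraction`, so a
  saturating dose drives every well with that response toward the same
  state.  This is the standard dose-response saturation argument, and it
  is what makes replicate strong responses more mutually similar than
  replicate controls — the premise of clique recovery.

What the simulations do not model: spectral spillover, doublets,
acquisition-time cell death within a well, autofluorescence, non-Gaussian
population shapes.  Passing tests demonstrate the pipeline's statistical
machinery under known ground truth, not instrument physics.

## Experiment scales and conditions

Chosen once as desk-scale study conditions and used by both the test suite
and `scripts/acceptance.py`:

- Comparison count / axioms: 21 samples × 5,000 events (210 pairs);
  50 random instances for axiom checks; 100 instances for the
  sparse-vs-dense oracle (agreement to 1e−12).
- Batch-effect recovery: 10 base mixtures (4 markers, 2,000 events),
  Gaussian noise of 0.75 × the within-population sd — strong enough to
  depress self-similarity from 100 to ≈35 ("undermines similarity") while
  leaving the population configuration intact, which is the stated premise
  of the experiment; nearest-original recovery is ≥ 95% over 20 seeds.
- Subpopulation removal: a 25%-weight target population removed at
  0/25/50/75/100% with nested seeded draws; similarity to the intact
  sample is non-increasing with a strict final drop.
- Drift correction: 24-well plates, slope 0.5 units/read-order; after
  correction the drift test is non-significant (p ≥ 0.01) in ≥ 95/100
  plates; exact-line inputs flatten to 1e−9.
- End-to-end: 20 controls, 3 effect groups (2 drugs each, subtype-specific
  complete kills with a different surviving population per group), 3 inert
  drugs, 3-point dose range, 5,000 events/well, `well_jitter_sd = 0.65`.
  Effect groups are recovered in common cliques in 20/20 seeds; all inert
  wells are inactive in 18/20 — the residual failures are single inert
  wells at the exchangeability floor of the bottleneck cutoff discussed
  above, a property of the cutoff rule, not of the implementation.

## Other numerical decisions

- Similarity matrices are computed once per sample pair; results are
  independent of worker count and pair order (pure functions, fixed
  reduction order).
- The band transform rescales each row by its own off-diagonal min/max and
  applies `f(x) = (e^{kx} − 1)/(e^k − 1)` with `k = 5` by default —
  strictly increasing, so within-row rankings are preserved; constant rows
  map to 0.5 by convention.
- The dispersion map z-scores centroid statistics, drops constant columns,
  and embeds with seeded UMAP (neighbourhood scaled down below 15
  cliques); below 4 cliques the neighbourhood embedding degenerates and
  principal-component coordinates are returned instead, keeping the
  two-clique case and determinism.
- The maximum spanning tree breaks ties lexicographically by edge ids, so
  dispersion graphs are reproducible.
- All pipeline randomness (LOF subsampling, simulator, embedding,
  community tie-breaks) flows from the single root seed in `RunConfig`.

## Known limitations

- The per-cube min/max score's absolute level depends on sample size and
  grid resolution; scores are comparable within an analysis, not across
  different `n` or very different event counts.
- Exact affine invariance holds per channel for the gridding; LOF
  denoising weakens it to shift invariance (see above).
- The cutoff's exchangeability floor means occasional false actives among
  wells statistically identical to controls; more controls lower the
  floor.
- Drift correction is linear in read order; nonlinear (loess-like) drifts
  and 2-D row/column surface effects are out of scope.
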