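# gridscreen

Analysis toolkit for small- to large-scale multiparameter screening data —
high-throughput flow cytometry, mass cytometry and similar per-well
single-cell assays.  Given one event table per well (cells × marker
channels) and a plate map, `gridscreen` performs quality control, two-step
plate bias correction, pairwise sample similarity by **dynamic mass-aware
gridding**, and graph-based clustering of wells into drug-response cliques
and communities.

## The method

**Similarity.**  For each sample individually, every marker axis is split
into *n* equal-width intervals between that sample's own minimum and
maximum (after local-outlier-factor denoising), so a *d*-marker sample
occupies at most *n*<sup>*d*</sup> hypercubes; only occupied cubes are
stored.  A hypercube is identified by its integer index vector — its
*relative* spatial position — which makes the representation exactly
invariant under per-channel shifts and rescalings of the raw intensities:
batch effects and signal drift cancel without any explicit correction.
Two samples *A*, *B* with per-cube mass fractions *p<sub>h</sub>*,
*q<sub>h</sub>* are scored

&nbsp;&nbsp;&nbsp;&nbsp;S(A, B) = 100 · (1 / |H<sub>A</sub> ∪ H<sub>B</sub>|) ·
Σ<sub>h ∈ H<sub>A</sub> ∪ H<sub>B</sub></sub> min(p<sub>h</sub>, q<sub>h</sub>) / max(p<sub>h</sub>, q<sub>h</sub>),

so cubes occupied by only one sample contribute 0 and identical samples
score exactly 100.  Mass fractions make the score independent of absolute
event counts.

**Clustering.**  Samples form a complete weighted graph.  The pruning
cutoff is the minimum edge weight of the maximum spanning tree over the
negative-control wells — the weakest link that still keeps all controls
mutually connected.  After pruning, wells still connected by a path to a
control are *inactive*; disconnected wells are *active* agents, grouped by
maximal-clique enumeration (Bron–Kerbosch) and, more loosely, by
random-walk (walktrap) communities.

**Bias correction.**  Per plate and channel, well medians are regressed on
acquisition read order and every event is translated so the fitted drift
line rotates to slope zero about the mean read order; live-cell counts are
detrended multiplicatively; plates are then translated so their medians
meet at a common baseline.

## Worked example

```python
from gridscreen import GridSimilarity, CliqueClusterer
from gridscreen.simulate import PopulationSpec, DrugEffectSpec, simulate_screen
from gridscreen.qc import remove_control_outliers

pops = [PopulationSpec((0, 0, 0), (1, 1, 1), 0.6),     # progenitor-like
        PopulationSpec((5, 5, 0), (1, 1, 1), 0.4)]     # differentiated
drugs = [DrugEffectSpec("cytarabine_like", 0, "abundance_shift",
                        (-0.6, 0.0), hill_midpoint=0.1),
         DrugEffectSpec("vehicle_like", 0, "mean_shift", (0, 0, 0))]
screen = simulate_screen(pops, drugs, doses=[10.0],
                         wells_per_condition=2, events_per_well=3000,
                         n_controls=12, well_jitter_sd=0.65, seed=11,
                         channels=["CD11b", "Gr-1", "CD16_32"])

est = GridSimilarity(n=5, lof_k=30).fit(screen)
sim = est.similarity_
print(f"{est.n_comparisons_} pairwise comparisons, "
      f"similarity range {sim.values.min():.1f}-{sim.values.max():.1f}")

controls = remove_control_outliers(sim, screen.control_ids)
cl = CliqueClusterer().fit(sim, controls=controls)
print(f"cutoff inferred from controls: {cl.cutoff_:.1f}")
active = [s for s, l in cl.labels_.items() if l == "active"]
print(f"active wells: {sorted(active)}")
for i, c in enumerate(cl.cliques_, 1):
    drugs_in = {screen.well(s).drug or "control" for s in c}
    print(f"clique C{i}: {list(c)} <- {sorted(drugs_in)}")
```

prints

```
120 pairwise comparisons, similarity range 17.8-100.0
cutoff inferred from controls: 39.1
active wells: ['P1/A13', 'P1/A14']
clique C1: ['P1/A13', 'P1/A14'] <- ['cytarabine_like']
```

The 16 wells yield 16·15/2 = 120 comparisons.  The cutoff (39.1) is the
bottleneck similarity among the 12 untreated control wells.  Both wells of
the progenitor-depleting drug fall below it against every control, are
called active, and — having the same response phenotype — form one clique;
the vehicle-like wells remain connected to the controls (inactive).

`GridSimilarity`, `DriftCorrector` and `CliqueClusterer` follow
scikit-learn estimator conventions (`fit`, `transform`/`predict`,
`get_params`, fitted `*_` attributes); the per-operation functions in
`gridscreen.similarity`, `gridscreen.correct` and `gridscreen.cluster` are
thin wrappers over them.

## Command line

```sh
gridscreen simulate --config spec.json --out screen/ --seed 3
gridscreen run --config run.json          # qc -> correct -> similarity -> cluster -> viz
gridscreen qc|correct|similarity|cluster|viz ...   # single stages
```

`run` emits a QC report, the serialized correction model, the similarity
matrix, the inferred cutoff, clique and community tables, GraphML graphs,
the band-transformed similarity matrix, dispersion-tree and dispersion-map
coordinates, and a provenance log.

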