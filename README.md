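# engramkit

Quantification of neuronal-ensemble ("engram") reactivation from
dual-channel fluorescence microscopy of the hippocampal dentate gyrus —
particle detection and counting, the four ensemble-overlap statistics, and
exact small-sample statistical inference, together with a synthetic-data
generator that provides ground truth for every stage.

## The problem

Memory-trace experiments tag the sparse population of granule cells active
during learning (e.g. an activity-dependent GFP reporter, ~5% of cells) and
stain the population active at recall (the immediate-early gene Fos). The
question is whether the two populations overlap more than chance. With
per-slice counts of Hoechst⁺ (all nuclei), GFP⁺, Fos⁺ and double-labeled
GFP⁺Fos⁺ cells, the standard statistics are

```
observed overlap  = (GFP⁺Fos⁺) / Hoechst⁺ × 100
chance overlap    = GFP⁺/Hoechst⁺ × Fos⁺/Hoechst⁺ × 100
reactivation rate = (GFP⁺Fos⁺) / GFP⁺ × 100
similarity index  = (GFP⁺Fos⁺) / (GFP⁺ + Fos⁺ − GFP⁺Fos⁺) × 100   (Jaccard)
```

Slices are quantified individually, averaged per animal, optionally
normalized to the control-group mean within an experimental batch, and
compared with a Shapiro–Wilk-gated choice between Student's *t* and exact
rank tests. Because such cohorts have 5–7 animals per group, the package
enumerates the Wilcoxon signed-rank and Mann–Whitney null distributions
exactly (dynamic programming over rank subsets) instead of relying on
asymptotics; `W` is the sum of signed ranks, `U` the min-convention
statistic, and all p-values two-tailed.

## Worked example

Exact signed-rank inference from a published-style summary statistic —
7 animals whose observed overlap exceeded chance with signed-rank sum 26:

```python
>>> import engramkit as ek
>>> res = ek.wilcoxon_exact(n=7, w=26)
>>> print(f"W = {res.statistic:+.0f}, n = {res.n[0]}, "
...       f"exact two-tailed p = {res.p_two_tailed:.4f}")
W = +26, n = 7, exact two-tailed p = 0.0312
```

A full simulated two-group experiment (6 animals/group, 3 slices/animal,
2000 cells/region; control reactivation probability 0.30 vs treated 0.45):

```python
>>> from engramkit.pipeline import GroupSpec, PipelineConfig, simulate_experiment
>>> cfg = PipelineConfig(
...     groups={
...         "control": GroupSpec(truth=ek.EnsembleGroundTruth(n_cells=2000, rho=0.30), n_animals=6),
...         "treated": GroupSpec(truth=ek.EnsembleGroundTruth(n_cells=2000, rho=0.45), n_animals=6),
...     },
...     seed=7,
... )
>>> b = simulate_experiment(cfg)
>>> tot = b.animal_rates[b.animal_rates.region == "total"]
>>> tot.groupby("group")[["observed_overlap", "chance_overlap", "reactivation_rate"]].mean().round(3)
         observed_overlap  chance_overlap  reactivation_rate
group
control             1.642           0.266             31.748
treated             2.156           0.237             44.275
```

Both groups overlap far above the ~0.25% chance level, and the treated
group's reactivation rate recovers its generating parameter (44.3 vs the
true 45). The bundle's `tests` list holds the gated comparisons, e.g.
`control vs treated: reactivation rate ... unpaired_t p = 0.0001279`.

The image path does the same starting from rendered multi-channel z-stacks:
`render_slice` produces per-channel TIFF-ready stacks plus a per-cell truth
table, and `quantify_slice` runs background subtraction, maximum projection,
ROI clearing, Otsu (or fixed) thresholding, the >50-pixel particle filter,
Hoechst confirmation and footprint colocalization to recover the same count
table. There is also a CLI: `engramkit simulate|detect|census|engram-stats|
intensity|test|run`.

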