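# replitrack

Automated analysis of replisome positioning in time-lapse and snapshot
fluorescence microscopy of bacteria — plus a ground-truthed simulator of
"replication factory" dynamics to validate every stage of the analysis.

## The problem

Two models have been proposed for where the DNA-replication machinery
(replisome) sits in a bacterial cell. In the **Factory Model** the two
sister replication forks stay spatially co-localized while the chromosome
is pulled through them; in the **Track Model** the forks translocate
independently along the DNA and separate for much of the cycle. A
high-copy replisome marker such as the DnaN beta-clamp forms
diffraction-limited fluorescent foci, so the question becomes statistical:
across thousands of cell-frames, what fraction of sister fork pairs appear
as a single focus (co-localized) versus a narrowly separated focus pair
(resolved sisters)? The analysis is confounded by re-initiation of
replication before division, which adds focus *pairs* at the quarter-cell
positions that are easily mistaken for separated sisters.

`replitrack` implements the full quantification chain for people doing
single-cell bacterial microscopy:

* **cell tracking** from integer label masks: long-axis geometry,
  exponential growth fits `L(t) = L0·exp(t/t0)` with doubling time
  `tD = t0·ln 2`, and automated cell-selection filters;
* **focus detection**: watershed candidates on the blurred image,
  sub-pixel 2-D Gaussian localization, and the significance score
  `σ = Ia / (δI·√A)` (disk intensity over the expected noise of A pixels,
  with δI the intensity standard deviation over the cell mask); foci with
  `σ ≥ 4` are retained;
* **pair statistics**: all unique within-cell relative focus separations,
  a two-Gaussian mixture fitted by EM separating resolved sisters
  (mean ≈ 0.2 cell lengths) from quarter-cell factory pairs (≈ 0.45),
  posterior-based disjoint pair classification, and factory counting
  `n_coloc = n_foci − 2·n_resolved`;
* **a synthetic-data generator** that simulates growing, dividing cells
  with factory-model fork dynamics (confined motion, transient fission,
  pre-division re-initiation in ~45 % of cycles) and renders TIFF
  fluorescence + label-mask stacks with exported ground truth;
* **reporting**: kymographs, cell towers, conditional position densities,
  localization-pattern tables and co-localization pie fractions, each with
  a machine-readable CSV twin.

See `docs/methods.md` for the model, parameter defaults and numerical
choices, and `examples/` for short narrative scripts.

## Worked example

Simulate 30 E. coli-like lineages for five hours at five-minute intervals,
run the whole pipeline, and read off the headline statistics:

```python
import replitrack as rt

cfg = rt.PipelineConfig(preset="ecoli_dnaN", n_cells=30,
                        duration_min=300.0, seed=3, out_dir="out")
results = rt.run_pipeline(cfg)
s = results["summary"]
print(f"selected cells:        {s['n_selected']}")
print(f"retained foci:         {s['n_retained_foci']}")
print(f"mean doubling time:    {s['mean_doubling_time_h']:.2f} h")
print(f"mixture means:         {s['mixture']['mu_low']:.3f} / "
      f"{s['mixture']['mu_high']:.3f} cell lengths")
print(f"co-localized fraction: {s['colocalized_fraction']:.3f} "
      f"(ground truth {s['truth_colocalized_fraction']:.3f})")
```

prints

```
selected cells:        74
retained foci:         2274
mean doubling time:    3.03 h
mixture means:         0.204 / 0.463 cell lengths
co-localized fraction: 0.808 (ground truth 0.802)
```

The mixture means say that resolved sister forks sit ~0.20 cell lengths
apart while quarter-cell factory pairs sit ~0.45 apart; the co-localized
fraction says that a sister fork pair appears as a single
diffraction-limited focus in ~80 % of observations — factory-like
behaviour — and agrees with the generator's ground truth to well under a
percentage point here. `out/` additionally contains the foci/pairs/counts
CSV tables, the mixture JSON, density matrix, pattern table, kymograph and
pie-chart figures, and a manifest recording the config and seed.

The same chain is available from the shell:

```sh
replitrack simulate --preset ecoli_dnaN --cells 30 --seed 3 -o sim/
replitrack run --preset ecoli_dnaN --cells 30 --seed 3 -o out/
```

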