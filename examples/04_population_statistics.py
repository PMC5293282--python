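"""From foci to the factory-vs-track verdict.

Pools all within-cell focus separations, fits the two-Gaussian mixture,
classifies resolved-sister pairs by posterior, and counts co-localized
fork pairs.
"""
import pandas as pd
import replitrack as rt

cfg = rt.PipelineConfig(preset="ecoli_dnaN", n_cells=30, duration_min=300.0,
                        seed=3, out_dir="out_stats", make_figures=True)
results = rt.run_pipeline(cfg)

mix = results["mixture"]
print(f"separation mixture: low {mix.mu_low:.3f} +/- {mix.sd_low:.3f} "
      f"(weight {mix.w_low:.2f}), high {mix.mu_high:.3f} +/- {mix.sd_high:.3f}")
print(f"co-localized fraction: {results['coloc_fraction']:.3f} "
      f"(truth {results['summary']['truth_colocalized_fraction']:.3f})")
print("\nlocalization patterns (overall):")
print(results["patterns"]["overall"].round(3).to_string())
# The low mixture component (~0.2 cell lengths) is transiently resolved
# sister forks; the high one (~0.45) is pairs of re-initiated factories at
# the quarter-cell positions. A co-localized fraction near 0.8 is the
# factory-model signature.
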