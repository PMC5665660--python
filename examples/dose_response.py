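"""Dose-response recovery: double the droplet rate, measure the fold change.

Emulates an LDL-loading experiment: two arms of synthetic FOVs whose only
difference is the mean droplet count per cell (8 vs 16). The pipeline's
"LDs per positive cell" should double.
"""

from lipidquant.pipeline import quantify_fov
from lipidquant.quantification import SampleSummary, fold_change
from lipidquant.synthetic_data import SynthConfig, generate_dose_series

base = SynthConfig(rng_seed=7)
batches = generate_dose_series(base, [1.0, 2.0], fovs_per_arm=6)

summaries = []
for mult, arm in zip((1.0, 2.0), batches):
    sample = SampleSummary(fovs=[quantify_fov(f, s).summary for f, s, _ in arm])
    summaries.append(sample)
    print(f"rate x{mult:g}: {sample.mean_lds_per_positive_cell:.2f} LDs per positive cell "
          f"(mean over {len(arm)} FOVs)")

fc = fold_change(summaries[1], summaries[0], "lds_per_positive_cell")
print(f"\nmeasured fold change: {fc:.3f}  (generator truth: 2.0)")
print("A fold change near 2 shows the pipeline tracks graded changes in")
print("lipid load, the property used to follow LDL uptake over time/dose.")
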