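"""Cohort-level contrast: deviant long-range coupling, awake vs anesthesia.

Twelve simulated subjects carry prefrontal-temporal couplings active only
during deviant tones. For each subject, condition and state, the pipeline
computes the wPLI network over the MMN window, sweeps edge densities
6-90%, and sums long- (inter-area) and short- (intra-area) distance
connection weights; Ratio = L_all / S_all. Paired t-tests then compare
conditions within state. The planted effect is detected awake and is
abolished when anesthesia attenuates coupling strengths to 25%.

Runs in about 10 s (48 ROIs grouped into the 14 cortical areas).
"""

from mmnconn.pipeline import demo_config, run_pipeline

config = demo_config(n_subjects=12, n_rois=48, tones_per_block=300, seed=11)
result = run_pipeline(config)

cols = ["comparison", "mean_x", "std_x", "mean_y", "std_y", "t", "p",
        "significant"]
print(result.tables["ratio_by_condition"][cols].round(4).to_string(index=False))
print()
t3 = result.tables["global_by_condition"]
print(t3[t3.comparison.str.startswith("awake")][cols].round(4)
      .to_string(index=False))
print()
print("-> awake: Ratio(deviant) > Ratio(standard), driven by L_all;"
      " under anesthesia the difference disappears - the signature of"
      " long-range integration behind mismatch detection.")
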