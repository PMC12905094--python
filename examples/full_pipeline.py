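"""Run the whole analysis on the bundled 16-lesion synthetic cohort.

simulate -> segment -> quantify -> pvc -> respond, writing the report
bundle to ./pipeline_demo and printing the cohort summary blocks plus the
per-target truth comparison.
"""

from petresponse.pipeline import AnalysisConfig, run_pipeline

result = run_pipeline(AnalysisConfig(seed=1), "pipeline_demo")

print("cohort summaries (rates in %, rounded half-to-even):")
print(result["summary"].to_string(index=False))

cmp = result["truth_comparison"]
correct = (cmp["true_category"] == cmp["measured_category"]).sum()
print(f"\ntruth check: {correct}/{len(cmp)} targets classified to their true category")
print(
    "\nThe raw all-evaluable SUV_mean block reads the true cohort composition"
    "\n(10 responders, 5 indeterminate, 1 progression -> 62.5/31.2/6.2%)."
    "\nEvery number above can be recomputed from the CSV/JSON files in"
    "\n./pipeline_demo."
)
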