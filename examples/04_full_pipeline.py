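"""The full two-species analysis in one call.

Runs the default desk-scale study — an ectotherm-analogue predator and an
endotherm-analogue prey on a shared synthetic landscape, with warming-family
futures and two paleo periods — and prints the run summary: cross-validated
AUC per species, niche overlap, and the vulnerability table (percent change
in summed suitability; rows are the two species plus their co-occurrence
area, columns the scenarios).
"""

from pathlib import Path

from nicheshift import RunConfig, render_report, run_pipeline

out = Path("scratch/example_run")
result = run_pipeline(RunConfig(master_seed=7), out_dir=out)
print(render_report(out))
print(f"maps, models and tables written under {out}/")
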