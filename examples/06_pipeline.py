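"""Run the end-to-end pipeline at reduced scale and print its report.

Stages: generate -> fit_rheology -> train -> evaluate -> optimize, all
artifacts persisted under the output directory.  The default config runs
the full validation protocol; this example trims iterations for speed.
"""

from bioinkflow.pipeline import PipelineConfig, render_report, run_pipeline

config = PipelineConfig.default(seed=0)
config.raw["validation"]["iterations"] = 10
config.raw["surrogates"][-1]["n_trees"] = 50

report = run_pipeline(config, "pipeline_out")
print(render_report(report))
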