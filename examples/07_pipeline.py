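"""Run every analysis stage end-to-end from a single config.

Executes descriptors -> screen -> COMPARE -> consensus -> genomics ->
network over synthetic inputs, writes one CSV per stage plus run metadata,
and prints the consolidated text report. Two runs with the same config and
seed produce byte-identical outputs.
"""

from screenkit.pipeline import PipelineConfig, render_report, run

config = PipelineConfig(out_dir="scratch/pipeline_demo", seed=1)
bundle = run(config)

print("outputs written:")
for name, path in sorted(bundle["outputs"].items()):
    print(f"  {name:22s} {path}")

print()
print(render_report(bundle))
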