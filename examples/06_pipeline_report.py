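"""The multi-stage pipeline: one config, one reproducible report.

Runs the residency, pore and variant stages on generated inputs and
prints the numeric report; a manifest with content hashes of every
output lands next to it.  Re-running with the same config and seed
produces a byte-identical report.
"""

import json

from slc26kit.pipeline import ResidencyConfig, RunConfig, run_pipeline

config = RunConfig(outdir="scratch/pipeline_demo", seed=1,
                   residency=ResidencyConfig(preset="preset_cl", n_frames=20_000))
report = run_pipeline(config)

print(json.dumps(report["stages"], indent=2))
print("\nresidency:", report["stages"]["residency"]["percent_report"],
      "| pore:", report["stages"]["pore"]["classification"],
      "| variants:", report["stages"]["variants"]["category_counts"])
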