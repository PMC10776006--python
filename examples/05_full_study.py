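"""One-command study: simulate -> aggregate -> correlate -> PCA.

Runs the orchestrated pipeline on a default-sized synthetic study
(20 ROIs x 25 vertices, 40 participants, parameter-level estimates) and
prints the report.  All outputs (TSV tables, manifest with config hash and
seeds) land in ./scratch/example_study.
"""

import json

from dnprf.pipeline import PipelineConfig, run_pipeline
from dnprf.synth import StudyConfig

config = PipelineConfig(
    study=StudyConfig(participant_model="estimates", seed=7),
    out_dir="scratch/example_study",
    n_perm=10_000,
)
report = run_pipeline(config)

print(json.dumps(report, indent=2, default=float))
print("\nThe four planted correlations keep their (+, -, +, -) sign pattern;"
      "\nthe two-receptor GLMs out-predict both one-receptor models out of"
      "\nsample; re-running this script reproduces identical numbers.")
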