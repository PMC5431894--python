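"""Run every stage end to end and write the report bundle.

Equivalent to ``nerkasweep report --seed 1 --out nerkasweep_out`` from
the shell; stage sizes are reduced here so the example finishes in
seconds.
"""

import json

from nerkasweep import ChainConfig, PipelineConfig, SimScenario, run_pipeline

config = PipelineConfig(
    seed=1,
    out_dir="nerkasweep_out",
    scenario=SimScenario(seq_length=5000, seed=1),
    chain=ChainConfig(n_iterations=30_000, n_chains=2, thin=10),
)
report = run_pipeline(config)

print(json.dumps(report, indent=2, default=float))
print("\nstage outputs (FASTA, VCF, WIG, CSV, JSON) are under", config.out_dir)
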