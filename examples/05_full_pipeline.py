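"""The whole analysis in one call: simulate -> peaks -> differential ->
classify -> categories -> annotate -> metaprofiles -> conflicts.

Writes all stage tables (BED/TSV/JSON) plus a markdown report into
./pipeline_out and prints the report.
"""

import rloopmap as rl

config = rl.RunConfig(truth=rl.TruthConfig(seed=1))
result = rl.run_pipeline(config, out_dir="pipeline_out")
print(rl.report(result))
# Expected shape of the result: hpr1 gains in G1 and S, sen1 gains in S
# only, ~40/30/25 specific/specific/common labels, a positive sen1
# damage asymmetry, and a strongly significant head-on bias for the
# sen1-specific class only.
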