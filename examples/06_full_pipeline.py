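"""One-call pipeline: simulate, analyse every stage, write artifacts.

Equivalent to `mpcommunity run-all --out pipeline_out --seed 42` from the
shell.  All stage outputs land in the output directory as TSV/JSON; the
printed summary only restates numbers stored in those files.
"""

import mpcommunity as mpc

config = mpc.PipelineConfig(outdir="pipeline_out", seed=42, n_permutations=999)
bundle = mpc.run_pipeline(config)
print(mpc.render_report(bundle))
print("stage artifacts:")
for name, path in sorted(bundle.paths.items()):
    print(f"  {name}: {path}")
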