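"""One-call orchestration of the whole workflow.

Runs every stage (chemistry, bioassay, ToxPi, grouping, association) on a
synthetic panel and lists the run directory.  The same workflow is
available from the shell::

    uvcblink all --outdir run --seed 7
    uvcblink chem --config my_run.yaml
"""

import json
from pathlib import Path

from uvcblink.pipeline import RunConfig, run_pipeline

config = RunConfig(outdir="run_example", seed=7, n_perm=200)
outdir = run_pipeline(config)

manifest = json.loads((outdir / "manifest.json").read_text())
print("stages run:", ", ".join(manifest["stages_run"]))
print("selected lambda:", round(manifest["assoc"]["lambda_selected"], 3))
print("overall-score q-value:", round(manifest["assoc"]["q_overall"], 4))
print("\noutputs:")
for f in sorted(Path(outdir).iterdir()):
    print(" ", f.name)
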