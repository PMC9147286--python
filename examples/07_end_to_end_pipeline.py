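"""Full pipeline: synthesize plants, tile, count, aggregate, report.

Uses the ground-truth oracle as the counting model, so plant totals are
conserved exactly — the pipeline-plumbing baseline against which trained
models are compared. Swap `model="scount"` plus a checkpoint to run a
trained counter instead (see examples/03).
"""

import json
import tempfile

from weakcount.pipeline import RunConfig, run_end2end

out = tempfile.mkdtemp(prefix="weakcount_e2e_")
report = run_end2end(RunConfig(seed=4, n_plants=3, out_dir=out))

for pid, info in sorted(report["plants"].items()):
    print(f"{pid}: true total {info['true_total']}, "
          f"predicted {info['predicted_total']:.0f}, tiles {info['tile_counts']}")
print(f"\nartifacts: {out}/manifest.json, {out}/report.json")
manifest = json.load(open(f"{out}/manifest.json"))
print(f"reproducibility: seed {manifest['seed']}, config hash {manifest['config_hash']}")
# Identical config + seed rewrites these reports byte-for-byte.
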