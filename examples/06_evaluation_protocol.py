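"""The run-ensemble evaluation protocol on a toy set of predictions.

Five independently trained runs predict each tile; the per-tile error
uses the median of the five, RMSE is reported per count bin as
mean +/- std over runs, and a least-squares line of predicted on true
counts summarizes calibration (slope 1, R^2 1 would be perfect).
"""

import numpy as np

from weakcount.evaluation import RunEnsemble, evaluate_runs

rng = np.random.default_rng(0)
truth = {f"tile_{i:03d}": int(c) for i, c in enumerate(rng.integers(0, 13, size=60))}
# five noisy "runs": unbiased noise of ~1 boll around the truth
preds = {
    tid: [max(0, c + int(rng.integers(-1, 2))) for _ in range(5)]
    for tid, c in truth.items()
}
report = evaluate_runs(truth, RunEnsemble(preds))

print("RMSE by count bin (mean ± std over the 5 runs):")
for name, (mean, std) in report.rmse_by_bin.items():
    print(f"  {name:7s} {mean:.3f} ± {std:.3f}")
m, s = report.overall_rmse
print(f"overall: {m:.3f} ± {s:.3f}")
print(f"fraction of median errors within ±3: {report.fraction_within_3:.2f}")
slope, intercept, r2 = report.fit
print(f"least-squares fit: slope {slope:.3f}, intercept {intercept:.3f}, R² {r2:.3f}")
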