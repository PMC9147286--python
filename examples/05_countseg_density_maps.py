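"""Train CountSeg: density-map counting with image-level lower counts.

A shared 1x1-conv feature block feeds a classification branch (presence
score) and a density branch whose rectified map sums to the predicted
count. Counts beyond the subitizing range only contribute a lower-bound
hinge. Peaks of the density map localize individual bolls.
Runtime: ~40 s on one CPU core.
"""

from weakcount.benchmark import heldout_rmse, make_benchmark, train_benchmark_countseg
from weakcount.models.countseg import countseg_forward, peak_instances

data = make_benchmark(seed=0)
model = train_benchmark_countseg(data, seed=0)
print(f"held-out RMSE: {heldout_rmse(model, data):.3f} bolls")

ex = next(e for e in data.test if e.count_ >= 3)
score, conf, density = countseg_forward(model, ex.image_)
peaks = peak_instances(density, threshold=0.1, neighborhood_px=1)
print(f"example tile: true count {ex.count_}, density sum {density.global_count:.2f}")
print(f"presence score (max of confidence map): {score:.2f}")
print(f"density peaks at image coords: {[(round(x), round(y)) for x, y in peaks]}")
print(f"true boll centers:             {[(round(x), round(y)) for x, y in ex.points_]}")
# The density sum is the count; its peaks should land near the true boll
# centers even though training never saw a boll location.
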