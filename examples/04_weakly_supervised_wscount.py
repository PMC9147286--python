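"""Train WS-Count: counting supervised only by presence/absence labels.

Stage 1 fits the presence-absence classifier (PAC) on binary class
labels; stage 2 trains the counter over 21 multi-scale patches per tile
to satisfy classifier consistency (an occupied patch must count >= 1,
an empty one 0) and spatial consistency (the totals at the three scales
must agree). No ground-truth count is ever consumed.
Runtime: ~3 min on one CPU core.
"""

from weakcount.benchmark import heldout_rmse, make_benchmark, train_benchmark_wscount
from weakcount.models.wscount import pac_accuracy

data = make_benchmark(seed=0)
model = train_benchmark_wscount(data, seed=0)

print(f"PAC held-out accuracy: {pac_accuracy(model, data.test):.2f}")
print(f"held-out counting RMSE: {heldout_rmse(model, data):.3f} bolls")

ex = next(e for e in data.test if e.count_ >= 3)
out = model.forward_branches(ex.image_)
c1 = out.counts[0]
c4 = out.counts[1:5].sum()
c16 = out.counts[5:21].sum()
print(f"example tile (true {ex.count_}): scale totals C1={c1:.2f} C4={c4:.2f} C16={c16:.2f}")
# The three totals agreeing is what spatial consistency trains for; the
# RMSE is higher than the supervised model's — the price of never seeing
# a count during training.
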