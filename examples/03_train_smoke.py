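"""Train the toy backbone with the full dual-guided objective.

Desk-scale smoke run: 60 synthetic clips, 15 epochs on one CPU
(~1 minute).  Prints the per-epoch total loss and the held-out metrics.
"""

import numpy as np

from dualdistill import SynthParams, default_model_factory, evaluate, generate_dataset, smoke_config, stratified_split, train

clips, _ = generate_dataset((20, 20, 20), SynthParams(), seed=100)
labels = [c.label for c in clips]
tr, te = stratified_split(labels, 0.8, seed=0)

cfg = smoke_config(seed=0)
model = default_model_factory()(seed=0)
_, history = train([clips[i] for i in tr], model, cfg)

for epoch, (loss, lr) in enumerate(zip(history.losses, history.lrs)):
    print(f"epoch {epoch:2d}  lr {lr:.5f}  total {loss['total']:.4f}  "
          f"ce {loss['ce_sum']:.4f}  rgsd {loss['rgsd']:.4f}  agsd {loss['agsd']:.4f}")

report, scores, preds = evaluate(model, [clips[i] for i in te], cfg)
print(f"\nheld-out accuracy {report.accuracy:.3f}  "
      f"macro AUC {np.nanmean(report.auc_per_class):.3f}")
# The total loss falls as the warmup ends; accuracy above 1/3 shows the
# model picks up the echogenicity signal even at this tiny scale.
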