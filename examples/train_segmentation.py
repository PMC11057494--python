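"""Overfit the atrous segmentation network on ten synthetic frames.

A capacity check, not a clinical model: the scaled-down encoder + ASPP
network is trained on ten speckled frames of a pulsating ellipse until
it reproduces their masks.  Dice against the ground-truth masks shows
the architecture and training loop work end to end on a CPU.
"""

import numpy as np

from echolvef import LVShapeSpec, RhythmSpec, simulate
from echolvef.segmentation import SegConfig, build_acnn, dice, predict_mask, train

echo = simulate(RhythmSpec(n_cycles=1, mean_period=20, seed=2),
                LVShapeSpec(per_cycle_ef=(55.0,)), snr=5.0, seed=2)
frames, masks = echo.video.frames[:10], echo.masks[:10]

config = SegConfig(epochs=200, width_scale=0.125, seed=0)
model = build_acnn(config)
print(f"parameters: {sum(p.size for p in model.state_arrays())}")

model = train(model, frames, masks)
print(f"training loss: {model.training_history[0]:.3f} -> {model.training_history[-1]:.4f}")

scores = [dice(predict_mask(model, f), m) for f, m in zip(frames, masks)]
print(f"mean Dice vs truth masks: {np.mean(scores):.3f}")
# Dice near 1 means the network can represent and learn the LV shape;
# generalisation to real echo requires real training data.
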