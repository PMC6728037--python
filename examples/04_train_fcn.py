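"""Train the quarter-VGG16 + FCN-8s segmenter on phantoms (small demo).

A deliberately tiny run — 60 frame/mask pairs at 96x64 for 4 epochs —
just to show the training API; expect a validation Dice around 0.85
after a minute or two on one CPU (the full scaled exercise in the test
suite uses 200 pairs and 10 epochs and reaches ~0.95).  The learning-rate schedule is
the step form initial_lr / 10^floor(epoch / 50): at full scale
(200 epochs, initial 1e-4) it decays at epochs 50, 100 and 150.
"""

from bladdervol import dice, generate_dataset, predict_mask
from bladdervol.segmentation import AugmentationConfig, TrainingConfig
from bladdervol.segmentation.train import train

pairs, _ = generate_dataset(40, seed=1)
data = []
for p in pairs:
    data.append((p.transverse_frame, p.transverse_mask))
    data.append((p.longitudinal_frame, p.longitudinal_mask))
train_set, val_set = data[:60], data[60:80]

config = TrainingConfig(
    epochs=4,
    initial_lr=0.1,          # raised for the short schedule; full-scale default is 1e-4
    class_weights=(1.0, 3.0),
    seed=0,
    augmentation=AugmentationConfig(resize_to=(96, 64)),
)
model, history = train(train_set, config, validation=val_set)

print("per-epoch training Dice:", [round(v, 3) for v in history["dice"]])
print("per-epoch val Dice:     ", [round(v, 3) for v in history["val_dice"]])
print("learning rates:         ", history["lr"])

holdout = pairs[-1]
mask = predict_mask(model, holdout.transverse_frame)
print(f"held-out phantom Dice:   {dice(mask, holdout.transverse_mask):.3f}")
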