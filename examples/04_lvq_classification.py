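"""Train the LVQ1 classifier on flattened activation-map vectors.

Class prototypes start at the class means in the 81-dimensional
activation space and are sharpened by the LVQ1 rule (toward same-class
examples, away from other-class examples).  The loss curve is the
training-set misclassification ratio per epoch.
"""

import numpy as np

import sarcomap as sm
from sarcomap.activation import ActivationMap

rng = np.random.default_rng(4)

# synthetic activation maps: each class concentrates on its own neuron
# block with per-tumor variation
maps, labels = {}, {}
for i in range(8):
    hits = np.zeros(81, dtype=int)
    hot = rng.integers(0, 20, 3) if i < 4 else rng.integers(60, 81, 3)
    hits[hot] = rng.integers(30, 120, 3)
    sid = f"tumor_{i}"
    maps[sid] = ActivationMap.from_hits(sid, hits)
    labels[sid] = "sRCC" if i < 4 else "nsRCC"

x = np.asarray([sm.flatten_map(m) for m in maps.values()])
y = [labels[sid] for sid in maps]
model = sm.train_lvq(x, y, sm.LvqConfig(learning_rate=0.001, epochs=1000,
                                        seed=4))

print(f"prototypes: {len(model.prototypes)} "
      f"({', '.join(model.labels)}), dimension {model.prototypes.shape[1]}")
print(f"training loss: epoch 1 = {model.loss_curve[0]:.2f}, "
      f"epoch {len(model.loss_curve)} = {model.loss_curve[-1]:.2f}")

for sid in list(maps)[:4]:
    pred = sm.predict(model, sm.flatten_map(maps[sid]))
    print(f"  {sid}: true {labels[sid]:6s} predicted {pred}")
# loss 0 means every training map falls in its own class's Voronoi cell.
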