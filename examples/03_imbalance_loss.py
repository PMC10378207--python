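"""The logit-adjusted loss: priors, correction factors, and loss values.

Shows how class frequencies turn into additive logit corrections and how
LASCE relates to plain cross-entropy at tau = 0.
"""

import numpy as np

from mexflow import ce_loss, lasce_loss, prior_adjustment

labels = np.array([0] * 60 + [1] * 25 + [2] * 102)  # skewed 3-class sample
adj = prior_adjustment(labels, n_classes=3, tau=0.5)
print("class priors p:", np.round(adj.p, 4))
print("corrections a = log(p^0.5 + 1e-12):", np.round(adj.a, 4))
# Rare classes get the most negative correction; during training the model
# must overcome that handicap, which pushes its decision boundary toward
# the minority classes at test time.

rng = np.random.default_rng(0)
logits = rng.standard_normal((8, 3)).astype(np.float32)
batch = rng.integers(0, 3, 8)
print(f"cross-entropy: {float(ce_loss(logits, batch)):.4f}")
print(f"LASCE tau=0.5: {float(lasce_loss(logits, batch, adj)):.4f}")

adj0 = prior_adjustment(labels, n_classes=3, tau=0.0)
print(f"LASCE tau=0:   {float(lasce_loss(logits, batch, adj0)):.4f} "
      "(equals cross-entropy)")
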