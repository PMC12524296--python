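"""Spectral pre-processing chains: SNV, derivatives, OSC.

Shows what each chain does to the same spectra and how response-
dependent steps (OSC) are fit on training rows only.
"""

import numpy as np

import glycospec as gs
from glycospec.preprocess import apply_chain

dataset, _ = gs.generate_dataset(gs.SyntheticConfig(n_per_day=20, seed=2))
X, y = dataset.X, dataset.y

for chain in ("none", "snv + 1st derivative", "1st derivative",
              "osc + 1st derivative", "|1st der| + snv"):
    Xp, _ = apply_chain(chain, X, y)
    print(f"{chain:>22}: row mean {Xp[0].mean():9.4f}  row sd {Xp[0].std():8.4f}")

# OSC is fit on the training block and applied frozen to held-out rows
train, test = gs.split_70_30(X.shape[0], seed=0)
Xtr, Xte = apply_chain("osc + 1st derivative", X[train], y[train], X[test])
print(f"\nOSC chain: train {Xtr.shape}, test {Xte.shape} "
      "(test rows transformed without seeing their reference values)")

# SNV standardizes each spectrum (scatter removal); derivatives suppress
# baseline offsets, which is why their row means sit near zero.
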