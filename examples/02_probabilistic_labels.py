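"""From a binary expert tracing to probabilistic training labels.

A traced edge pixel keeps probability 1; probability decays as a
Gaussian (sigma = 1 px) into the cell bodies, and vanishes beyond the
7x7 support.  Thresholding at p > 0.5 accepts exactly a 1-px error in
edge localisation.
"""

import numpy as np

from ceseg import binarize_labels, make_probabilistic_labels

gold = np.zeros((7, 7), dtype=np.uint8)
gold[3, 3] = 1  # one isolated traced edge pixel

p = make_probabilistic_labels(gold)
print("label around an isolated edge pixel:")
print(np.round(p[1:6, 1:6], 4))
print(f"\ncentre p = {p[3, 3]:.4f}  (traced edge keeps probability 1)")
print(f"4-neighbour p = {p[3, 4]:.4f}  (= exp(-1/2), above the 0.5 threshold)")
print(f"diagonal p = {p[4, 4]:.4f}  (= exp(-1), below the threshold)")
print(f"\nedge class after p > 0.5: {int(binarize_labels(p).sum())} pixels "
      "(the pixel and its 4-neighbours - a 1-px tolerance band)")
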