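"""Turn a processed bout into labelled classifier windows.

A 10 s action gives a 7 s centre slice (transitions to/from rest are
discarded), which sections into six 30-sample windows at a 20-sample
(1 s) stride. Each window's label is the median of its per-sample labels.
"""

import numpy as np

import scratchkit as sk

cfg = sk.SynthConfig(seed=3)
rec, labels = sk.generate_action(sk.ActionSpec("scratch_arm"), cfg)
pc = sk.process_recording(rec)

pc_center, lab_center = sk.extract_center(pc, labels, duration_s=7.0)
print(f"centre slice: {pc_center.n_samples} samples "
      f"(from {rec.n_samples})")

ws = sk.make_windows(pc_center, lab_center)
print(f"windows: {len(ws)} of shape (30, 13), starts {ws.starts.tolist()}")
print(f"window labels: {ws.labels.tolist()}  (all 1: scratch bout)")

# the median rule on a mixed transition window
mixed = np.array([0] * 14 + [1] * 16)
print(f"median label of a 14/16 transition window: "
      f"{sk.label_window(mixed)} (majority scratching)")
tie = np.array([0] * 15 + [1] * 15)
print(f"median label of an exact 15/15 tie: {sk.label_window(tie)} "
      f"(ties favour detection)")
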