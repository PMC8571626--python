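"""Resistance and resilience from a hand-built distance-to-control contrast.

The indices need four numbers per treatment: the mean within-control
Bray–Curtis dissimilarity (C) and the mean treatment-to-control dissimilarity
(D), each directly after the stress (1) and after the recovery period (2).
"""

from microstab import stability_indices

C1, D1 = 0.30, 0.55   # treatment displaced well beyond the control baseline
C2, D2 = 0.30, 0.35   # most of the displacement closed after recovery

idx = stability_indices(C1, D1, C2, D2)
print(f"C1={C1}  D1={D1}  ->  resistance RS = {idx.RS:.3f}")
print(f"C2={C2}  D2={D2}  ->  resilience RL = {idx.RL:.3f}")
print("\nRS = 1 - 2|C1-D1| / (C1 + |C1-D1|): 1 means no displacement, 0 means"
      "\nthe displacement equals the baseline itself.  RL compares the two"
      "\ndisplacements: +1 full return, 0 unchanged, negative still diverging.")
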