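"""Shared label codes.

Class order is fixed everywhere, including file outputs:
index 0 = tumor, 1 = non-malignant tissue, 2 = white (empty background).
"""

TUMOR = 0
NON_MALIGNANT = 1
WHITE = 2

CLASS_NAMES = ("tumor", "non_malignant", "white")
N_CLASSES = 3
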