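"""Plain-text artifact IO.

All numeric grids are stored as whitespace-delimited text matrices with a
JSON sidecar (``<name>.json``) describing what they are — language-portable
and diffable, at the cost of size (irrelevant at heatmap scale).
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
from PIL import Image


def write_matrix(path, array, sidecar: dict | None = None, fmt="%.10g"):
    path = Path(path)
    np.savetxt(path, np.asarray(array), fmt=fmt)
    if sidecar is not None:
        path.with_suffix(path.suffix + ".json").write_text(
            json.dumps(sidecar, indent=2, sort_keys=True) + "\n"
        )


def read_matrix(path, dtype=float):
    arr = np.loadtxt(path, dtype=dtype, ndmin=2)
    return arr


def write_image(path, array):
    """Write an RGB uint8 array as PNG or TIFF by extension."""
    Image.fromarray(np.asarray(array, dtype=np.uint8)).save(path)


def read_image(path):
    return np.asarray(Image.open(path).convert("RGB"))


def write_json(path, obj):
    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n")


def read_json(path):
    return json.loads(Path(path).read_text())
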