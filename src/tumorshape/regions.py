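"""Region morphology on heatmap label grids.

A label grid assigns each heatmap cell (one cell = one classified patch of
the source image) to tumor, non-malignant tissue, or white background.  This
module segments the grid into physical tissue samples, extracts the
8-connected tumor regions inside each sample, identifies the main (largest)
tumor region, and finds enclosed holes.

Connectivity is 8 for both foreground regions and holes.  Using the same
connectivity on both sides departs from the usual dual-connectivity
convention of digital topology, so a diagonal "checkerboard" chain of
background cells can leak out of an apparently closed ring; this is a
deliberate, documented property of the method, not a bug.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from skimage.morphology import closing as _closing, disk

from ._constants import TUMOR, WHITE

__all__ = [
    "TissueRegion",
    "TumorRegion",
    "HoleSet",
    "connected_components",
    "segment_tissue_regions",
    "extract_tumor_regions",
    "find_holes",
]

_STRUCT8 = np.ones((3, 3), dtype=bool)
_STRUCT4 = np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]], dtype=bool)


def connected_components(grid: np.ndarray, connectivity: int = 8):
    """Label connected components of a binary grid.

    Components are numbered 1..n in row-major order of their first cell,
    so labeling is deterministic and independent of library internals.

    Parameters
    ----------
    grid : 2-D boolean array
    connectivity : 4 or 8

    Returns
    -------
    labels : int array, 0 = background
    n : number of components
    """
    grid = np.asarray(grid, dtype=bool)
    if grid.ndim != 2:
        raise ValueError("grid must be 2-D")
    if connectivity not in (4, 8):
        raise ValueError("connectivity must be 4 or 8")
    structure = _STRUCT8 if connectivity == 8 else _STRUCT4
    labels, n = ndimage.label(grid, structure=structure)
    if n > 1:
        # relabel in row-major discovery order
        flat = labels.ravel()
        first = np.full(n + 1, flat.size, dtype=np.intp)
        nz = np.flatnonzero(flat)
        # reversed so earlier indices win
        first[flat[nz[::-1]]] = nz[::-1]
        order = np.argsort(first[1:], kind="stable")
        remap = np.zeros(n + 1, dtype=labels.dtype)
        remap[1 + order] = np.arange(1, n + 1)
        labels = remap[labels]
    return labels, n


@dataclass
class TissueRegion:
    """One physical tissue sample: an 8-connected set of non-white cells."""

    id: int
    mask: np.ndarray  # full-grid boolean mask
    area: int

    @property
    def cells(self) -> np.ndarray:
        return np.argwhere(self.mask)


@dataclass
class TumorRegion:
    """An 8-connected tumor component within one tissue sample."""

    id: int
    tissue_id: int
    mask: np.ndarray  # full-grid boolean mask
    area: int
    is_main: bool = False

    @property
    def cells(self) -> np.ndarray:
        return np.argwhere(self.mask)

    @property
    def bbox(self):
        """(rmin, cmin, rmax, cmax), inclusive."""
        rows, cols = np.nonzero(self.mask)
        return rows.min(), cols.min(), rows.max(), cols.max()


@dataclass
class HoleSet:
    """Enclosed holes of a region: count, per-hole areas, cell masks."""

    n_holes: int
    areas: list[int] = field(default_factory=list)
    mask: np.ndarray | None = None  # full-grid mask of all hole cells

    @property
    def total_area(self) -> int:
        return int(sum(self.areas))


def segment_tissue_regions(label_map: np.ndarray, closing_radius: int = 1):
    """Segment a label grid into tissue samples.

    Tissue cells are those labeled tumor or non-malignant.  A binary closing
    (disk of ``closing_radius``) bridges one-cell classification gaps before
    components are found with 8-connectivity.  Samples smaller than half of
    the largest sample in the same grid (strict ``<``, areas measured after
    closing) are discarded as fragments.

    Returns a list of :class:`TissueRegion`, largest need not be first; ids
    follow row-major discovery order of the retained components.
    """
    label_map = np.asarray(label_map)
    tissue = label_map != WHITE
    if not tissue.any():
        warnings.warn("label map contains no tissue cells", stacklevel=2)
        return []
    if closing_radius > 0:
        tissue = _closing(tissue, disk(closing_radius)).astype(bool)
    labels, n = connected_components(tissue, connectivity=8)
    areas = ndimage.sum_labels(np.ones_like(labels), labels, np.arange(1, n + 1))
    cutoff = 0.5 * areas.max()
    regions: list[TissueRegion] = []
    next_id = 0
    for k in range(1, n + 1):
        if areas[k - 1] < cutoff:
            continue
        mask = labels == k
        regions.append(TissueRegion(id=next_id, mask=mask, area=int(areas[k - 1])))
        next_id += 1
    return regions


def extract_tumor_regions(tissue: TissueRegion, label_map: np.ndarray):
    """8-connected tumor components within one tissue sample.

    The largest component is flagged as the main tumor region; ties are
    broken toward the component whose first cell comes earliest in
    row-major order (which is also discovery order).
    """
    label_map = np.asarray(label_map)
    tumor = (label_map == TUMOR) & tissue.mask
    labels, n = connected_components(tumor, connectivity=8)
    if n == 0:
        return []
    regions = []
    areas = ndimage.sum_labels(np.ones_like(labels), labels, np.arange(1, n + 1))
    for k in range(1, n + 1):
        regions.append(
            TumorRegion(
                id=k - 1,
                tissue_id=tissue.id,
                mask=labels == k,
                area=int(areas[k - 1]),
            )
        )
    # main = max area; discovery order breaks ties toward earlier first cell
    main = max(regions, key=lambda r: (r.area, -r.id))
    main.is_main = True
    return regions


def find_holes(region_mask: np.ndarray) -> HoleSet:
    """Find enclosed holes of a region.

    Holes are 8-connected components of background cells inside the region's
    bounding box (padded by one cell) that do not reach the pad frame.

    Parameters
    ----------
    region_mask : full-grid or bbox-cropped boolean mask of one region
    """
    region_mask = np.asarray(region_mask, dtype=bool)
    if not region_mask.any():
        raise ValueError("region is empty")
    rows, cols = np.nonzero(region_mask)
    r0, r1 = rows.min(), rows.max() + 1
    c0, c1 = cols.min(), cols.max() + 1
    box = np.zeros((r1 - r0 + 2, c1 - c0 + 2), dtype=bool)
    box[1:-1, 1:-1] = region_mask[r0:r1, c0:c1]
    comp, n = connected_components(~box, connectivity=8)
    frame_labels = np.unique(
        np.concatenate([comp[0, :], comp[-1, :], comp[:, 0], comp[:, -1]])
    )
    areas: list[int] = []
    hole_full = np.zeros_like(region_mask)
    for k in range(1, n + 1):
        if k in frame_labels:
            continue
        cells = comp == k
        areas.append(int(cells.sum()))
        hole_full[r0:r1, c0:c1] |= cells[1:-1, 1:-1]
    return HoleSet(n_holes=len(areas), areas=areas, mask=hole_full)
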