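"""Nuclear / cellular segmentation and cytokeratin-mask construction.

The pipeline is deliberately classical and deterministic: Gaussian
smoothing, a global threshold (Otsu by default), hole filling, removal of
small objects, then a distance-transform watershed to split touching
nuclei.  Whole-cell regions are obtained by bounded nearest-nucleus
expansion, and the epithelial ("cytokeratin") mask is the union of the
pixels of cells whose mean cytokeratin intensity clears a spot-level
threshold.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage as ndi
from skimage.feature import peak_local_max
from skimage.filters import gaussian, threshold_li, threshold_mean, threshold_otsu
from skimage.measure import label as cc_label
from skimage.morphology import remove_small_objects
from skimage.segmentation import expand_labels, relabel_sequential, watershed

__all__ = [
    "segment_nuclei",
    "segment_cells",
    "make_cytokeratin_mask",
    "nuclei_from_centers",
]

_THRESHOLDS = {"otsu": threshold_otsu, "li": threshold_li, "mean": threshold_mean}


def segment_nuclei(
    dapi: np.ndarray,
    min_area_px: int = 15,
    threshold_method: str | float = "otsu",
    smoothing_sigma: float = 0.5,
    min_peak_distance: int = 2,
) -> np.ndarray:
    """Segment DAPI-positive nuclei into a label image.

    Parameters
    ----------
    dapi
        2-D nonnegative nuclear-stain image.
    min_area_px
        Connected regions smaller than this (in pixels) are discarded.
    threshold_method
        ``"otsu"`` (default), ``"li"``, ``"mean"``, or a fixed numeric
        threshold on the smoothed image.
    smoothing_sigma
        Gaussian pre-smoothing sigma in pixels (0 disables smoothing).
    min_peak_distance
        Minimum separation of watershed seed peaks in the distance
        transform; set near the expected nucleus radius.

    Returns
    -------
    ndarray of int
        Label image, 0 background, object ids contiguous from 1.  An
        all-zero (or constant) input yields an empty label map.
    """
    dapi = np.asarray(dapi, dtype=float)
    if dapi.ndim != 2:
        raise ValueError("dapi must be a 2-D image")
    if dapi.size and dapi.min() < 0:
        raise ValueError("dapi must be nonnegative")

    img = gaussian(dapi, sigma=smoothing_sigma, preserve_range=True) if smoothing_sigma > 0 else dapi
    if np.isclose(img.max(), img.min()):
        return np.zeros(dapi.shape, dtype=np.int32)
    if isinstance(threshold_method, str):
        try:
            thr = _THRESHOLDS[threshold_method](img)
        except KeyError:
            raise ValueError(f"unknown threshold method {threshold_method!r}") from None
    else:
        thr = float(threshold_method)

    binary = img > thr
    binary = ndi.binary_fill_holes(binary)
    binary = remove_small_objects(binary, max_size=int(min_area_px) - 1)
    if not binary.any():
        return np.zeros(dapi.shape, dtype=np.int32)

    distance = ndi.distance_transform_edt(binary)
    blobs = cc_label(binary)
    coords = peak_local_max(
        distance, min_distance=int(min_peak_distance), labels=blobs,
        exclude_border=False,
    )
    markers = np.zeros(dapi.shape, dtype=np.int32)
    for i, (r, c) in enumerate(coords, start=1):
        markers[r, c] = i
    if markers.max() == 0:  # degenerate: fall back to connected components
        labels = blobs
    else:
        labels = watershed(-distance, markers, mask=binary)
    labels, _, _ = relabel_sequential(labels)
    return labels.astype(np.int32)


def segment_cells(nuclei: np.ndarray, expansion_radius_px: float = 6.0) -> np.ndarray:
    """Grow each nucleus outward into a whole-cell region.

    Every nucleus label is dilated up to ``expansion_radius_px`` (Euclidean);
    growth stops where two cells meet, with pixels assigned to the nearest
    nucleus.  The cell label set equals the nucleus label set, and radius 0
    returns the input unchanged.
    """
    if expansion_radius_px < 0:
        raise ValueError("expansion_radius_px must be nonnegative")
    nuclei = np.asarray(nuclei)
    if expansion_radius_px == 0:
        return nuclei.copy()
    return expand_labels(nuclei, distance=expansion_radius_px)


def make_cytokeratin_mask(
    ck: np.ndarray,
    cells: np.ndarray,
    cell_positive_rule: str | float = "otsu",
) -> np.ndarray:
    """Build the epithelial mask from cytokeratin-positive segmented cells.

    A cell is cytokeratin-positive iff its *mean* CK intensity exceeds a
    spot-level threshold; the mask is the union of the pixels of positive
    cells.  ``cell_positive_rule`` is ``"otsu"`` (Otsu over the per-cell
    means; if all means are equal, cells are positive iff that mean is > 0)
    or a fixed numeric threshold.  No cells yields an empty mask.  The
    output is invariant to any relabeling of ``cells``.
    """
    ck = np.asarray(ck, dtype=float)
    cells = np.asarray(cells)
    if ck.shape != cells.shape:
        raise ValueError("ck and cells must share one shape")
    ids = np.unique(cells)
    ids = ids[ids > 0]
    if ids.size == 0:
        return np.zeros(ck.shape, dtype=bool)
    means = np.asarray(ndi.mean(ck, labels=cells, index=ids))
    if isinstance(cell_positive_rule, str):
        if cell_positive_rule != "otsu":
            raise ValueError(f"unknown cell_positive_rule {cell_positive_rule!r}")
        if np.allclose(means, means[0]):
            positive = means > 0
        else:
            positive = means > threshold_otsu(means)
    else:
        positive = means > float(cell_positive_rule)
    return np.isin(cells, ids[positive])


def nuclei_from_centers(centers: np.ndarray, shape: tuple[int, int],
                        radius: int) -> np.ndarray:
    """Rasterize ground-truth nucleus centers into a label image (one disk
    per center, labels 1..n in center order).  Used to bypass segmentation
    when validating quantification against generator ground truth."""
    labels = np.zeros(shape, dtype=np.int32)
    rr, cc = np.mgrid[0 : shape[0], 0 : shape[1]]
    for i, (cy, cx) in enumerate(np.asarray(centers, dtype=int), start=1):
        lo_r, hi_r = max(cy - radius, 0), min(cy + radius + 1, shape[0])
        lo_c, hi_c = max(cx - radius, 0), min(cx + radius + 1, shape[1])
        sub = (rr[lo_r:hi_r, lo_c:hi_c] - cy) ** 2 + (cc[lo_r:hi_r, lo_c:hi_c] - cx) ** 2
        region = labels[lo_r:hi_r, lo_c:hi_c]
        region[sub <= radius**2] = i
    return labels
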