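"""Deterministic single-cell segmentation and feature extraction.

Nuclei are detected by thresholding the nuclear channel (DNA intercalator,
DAPI or HOECHST), labelling 4-connected components and filtering by equivalent
diameter 2*sqrt(area/pi).  Whole cells are then obtained by expanding each
nucleus with one of three strategies:

* ``radial`` — grow up to a maximum Euclidean distance, but only into
  membrane-mask-positive pixels (the most restrictive reading of growth
  "over a membrane mask");
* ``watershed`` — watershed of the distance-to-nearest-nucleus surface seeded
  by the nuclei, restricted to nucleus-or-membrane pixels;
* ``isotropic`` — plain nearest-nucleus growth by a fixed number of pixels
  with no mask constraint.

In every mode cells are disjoint, each nucleus pixel keeps its label, and a
pixel contested by several nuclei goes to the nearest one (exact ties to the
lower label, so output is independent of traversal order).  Touching nuclei
are not split: declumping is out of scope and documented as a limitation.

A label image produced by an external segmenter (e.g. a deep-learning model)
can be fed straight into :func:`extract_features`; nothing downstream depends
on how the labels were produced.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy.spatial import cKDTree
from skimage.segmentation import watershed as _watershed

from .errors import IntegrityError, MetadataMismatchError, ParameterError, ShapeError
from .io import ChannelStack
from .preprocess import BinaryMask, threshold_otsu

logger = logging.getLogger(__name__)

#: connectivity structure used everywhere (4-connectivity)
STRUCTURE_4 = np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]], dtype=bool)

#: fixed CellTable columns (marker mean-intensity columns follow, one per channel)
CELL_TABLE_COLUMNS = [
    "cell_id",
    "sample_id",
    "centroid_x_px",
    "centroid_y_px",
    "centroid_x_um",
    "centroid_y_um",
    "area_px",
    "compartment",
    "cell_type",
    "cluster_id",
]


@dataclass
class LabelImage:
    """H x W integer image; 0 is background, labels run 1..n_cells."""

    pixels: np.ndarray
    n_cells: int = -1

    def __post_init__(self):
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim != 2:
            raise ShapeError("label image must be 2-D")
        if not np.issubdtype(self.pixels.dtype, np.integer):
            raise ShapeError("label image must hold integers")
        present = np.unique(self.pixels)
        present = present[present > 0]
        if self.n_cells < 0:
            self.n_cells = int(present[-1]) if present.size else 0
        if present.size and (
            present[0] < 1 or present[-1] != self.n_cells or present.size != self.n_cells
        ):
            raise IntegrityError(
                f"labels must be exactly 1..{self.n_cells}; found {present.size} "
                f"labels spanning [{present[0] if present.size else 0}, "
                f"{present[-1] if present.size else 0}]"
            )
        if present.size == 0 and self.n_cells != 0:
            raise IntegrityError("empty label image with n_cells > 0")


@dataclass
class SegmentationParams:
    """Nucleus detection and cell-expansion settings.

    ``nucleus_threshold`` is either the string "otsu" or a fixed intensity.
    ``expansion`` is one of "radial", "watershed", "isotropic";
    ``expansion_px`` is the growth limit for radial/isotropic modes.
    ``membrane_mask`` is required for radial and watershed expansion.
    """

    nucleus_channel: str
    nucleus_threshold: str | float = "otsu"
    min_diameter_px: float = 4.0
    max_diameter_px: float = 60.0
    expansion: str = "isotropic"
    expansion_px: float = 5.0
    membrane_mask: BinaryMask | None = None

    def __post_init__(self):
        if self.min_diameter_px >= self.max_diameter_px:
            raise ParameterError("min_diameter_px must be < max_diameter_px")
        if self.expansion not in ("radial", "watershed", "isotropic"):
            raise ParameterError(f"unknown expansion mode {self.expansion!r}")
        if self.expansion in ("radial", "isotropic") and self.expansion_px <= 0:
            raise ParameterError("expansion_px must be positive")


def detect_nuclei(stack: ChannelStack, params: SegmentationParams) -> LabelImage:
    """Threshold the nucleus channel and keep size-filtered 4-connected blobs.

    Survivors are relabelled 1..N in raster order of their topmost-leftmost
    pixel.  Zero surviving nuclei yields an empty label image with a warning.
    """
    channel = stack.channel(params.nucleus_channel)
    if params.nucleus_threshold == "otsu":
        mask, _ = threshold_otsu(channel)
        binary = mask.pixels
    else:
        binary = channel > float(params.nucleus_threshold)
    labels, n = ndimage.label(binary, structure=STRUCTURE_4)
    if n == 0:
        logger.warning("no nuclei detected in %s", stack.sample_id)
        return LabelImage(np.zeros_like(labels), 0)
    areas = np.bincount(labels.ravel(), minlength=n + 1)[1:]
    diameters = 2.0 * np.sqrt(areas / np.pi)
    keep = (diameters >= params.min_diameter_px) & (diameters <= params.max_diameter_px)
    if not keep.any():
        logger.warning("all %d nuclei filtered out by size in %s", n, stack.sample_id)
        return LabelImage(np.zeros_like(labels), 0)
    # raster order of first (topmost-leftmost) pixel per surviving label
    flat = labels.ravel()
    first_idx = np.full(n + 1, flat.size, dtype=np.int64)
    np.minimum.at(first_idx, flat, np.arange(flat.size))
    survivors = np.nonzero(keep)[0] + 1
    order = survivors[np.argsort(first_idx[survivors], kind="stable")]
    remap = np.zeros(n + 1, dtype=np.int32)
    remap[order] = np.arange(1, len(order) + 1)
    return LabelImage(remap[labels], len(order))


def _nearest_seed_assignment(
    nuclei: LabelImage, allowed: np.ndarray, max_dist_px: float
) -> np.ndarray:
    """Assign allowed pixels within range to the nearest nucleus.

    Distances are between pixel centres, so squared distances are integers;
    exact ties are broken towards the lower label by inspecting all seeds at
    the minimal distance.
    """
    lab = nuclei.pixels
    out = lab.astype(np.int32).copy()
    seed_rc = np.argwhere(lab > 0)
    if seed_rc.size == 0:
        return out
    seed_labels = lab[seed_rc[:, 0], seed_rc[:, 1]].astype(np.int32)
    candidates = np.argwhere(allowed & (lab == 0))
    if candidates.size == 0:
        return out
    tree = cKDTree(seed_rc)
    max_d2 = max_dist_px * max_dist_px
    k = min(8, len(seed_rc))
    dist, idx = tree.query(candidates, k=k)
    if k == 1:
        dist = dist[:, None]
        idx = idx[:, None]
    d2 = np.rint(dist * dist).astype(np.int64)
    best = d2[:, 0]
    in_range = best <= max_d2 + 1e-9
    # minimum label among all seeds at the minimal (integer) squared distance
    tied = d2 == best[:, None]
    labels_at = np.where(tied, seed_labels[idx], np.iinfo(np.int32).max)
    winner = labels_at.min(axis=1)
    # if every returned neighbour is tied, there may be more beyond k: re-query
    exhausted = tied.all(axis=1) & in_range
    if exhausted.any() and k < len(seed_rc):
        for i in np.nonzero(exhausted)[0]:
            d_all, i_all = tree.query(candidates[i], k=min(64, len(seed_rc)))
            d2_all = np.rint(np.asarray(d_all) * np.asarray(d_all)).astype(np.int64)
            sel = d2_all == d2_all[0]
            winner[i] = seed_labels[np.asarray(i_all)[sel]].min()
    rows = candidates[in_range, 0]
    cols = candidates[in_range, 1]
    out[rows, cols] = winner[in_range]
    return out


def _keep_connected_to_nucleus(labels: np.ndarray, nuclei: np.ndarray) -> np.ndarray:
    """Trim expansion pixels not 4-connected to their own nucleus."""
    out = labels.copy()
    slices = ndimage.find_objects(labels)
    for lab, sl in enumerate(slices, start=1):
        if sl is None:
            continue
        cell = labels[sl] == lab
        comp, n = ndimage.label(cell, structure=STRUCTURE_4)
        if n <= 1:
            continue
        nucleus_comps = np.unique(comp[(nuclei[sl] == lab) & cell])
        keep = np.isin(comp, nucleus_comps[nucleus_comps > 0])
        out_sl = out[sl]
        out_sl[cell & ~keep] = 0
        out[sl] = out_sl
    return out


def expand_cells(
    nuclei: LabelImage, stack: ChannelStack, params: SegmentationParams
) -> LabelImage:
    """Grow nuclei into whole cells; see module docstring for the three modes."""
    if nuclei.pixels.shape != stack.shape[:2]:
        raise ShapeError("nuclei and stack dimensions differ")
    if nuclei.n_cells == 0:
        return LabelImage(nuclei.pixels.copy(), 0)
    mode = params.expansion
    if mode in ("radial", "watershed"):
        if params.membrane_mask is None:
            raise ParameterError(f"{mode} expansion requires a membrane mask")
        if params.membrane_mask.pixels.shape != nuclei.pixels.shape:
            raise ShapeError("membrane mask dimensions differ from label image")
        membrane = params.membrane_mask.pixels
    if mode == "isotropic":
        out = _nearest_seed_assignment(
            nuclei, np.ones_like(nuclei.pixels, dtype=bool), params.expansion_px
        )
    elif mode == "radial":
        allowed = membrane | (nuclei.pixels > 0)
        out = _nearest_seed_assignment(nuclei, allowed, params.expansion_px)
    else:  # watershed
        allowed = membrane | (nuclei.pixels > 0)
        surface = ndimage.distance_transform_edt(nuclei.pixels == 0)
        out = _watershed(
            surface, markers=nuclei.pixels, mask=allowed, connectivity=1
        ).astype(np.int32)
    out = _keep_connected_to_nucleus(out, nuclei.pixels)
    return LabelImage(out, nuclei.n_cells)


def extract_features(cells: LabelImage, stack: ChannelStack) -> pd.DataFrame:
    """Per-cell centroid, area and mean marker intensities (the CellTable).

    Mean intensity is the arithmetic mean of the channel over the cell's
    pixels; the centroid is the unweighted mean of pixel centres.  Marker
    columns are named by channel name and follow the fixed columns.
    """
    if cells.pixels.shape != stack.shape[:2]:
        raise ShapeError("label image and stack dimensions differ")
    lab = cells.pixels
    present = np.unique(lab)
    present = present[present > 0]
    if present.size != cells.n_cells or (
        present.size and present[-1] != cells.n_cells
    ):
        raise IntegrityError(
            f"label image claims {cells.n_cells} cells but labels are {present.tolist()[:10]}..."
        )
    n = cells.n_cells
    flat = lab.ravel()
    counts = np.bincount(flat, minlength=n + 1)[1:]
    rows, cols = np.indices(lab.shape)
    sum_y = np.bincount(flat, weights=rows.ravel(), minlength=n + 1)[1:]
    sum_x = np.bincount(flat, weights=cols.ravel(), minlength=n + 1)[1:]
    cy = sum_y / counts
    cx = sum_x / counts
    data = {
        "cell_id": np.arange(1, n + 1),
        "sample_id": stack.sample_id,
        "centroid_x_px": cx,
        "centroid_y_px": cy,
        "centroid_x_um": cx * stack.pixel_size_um,
        "centroid_y_um": cy * stack.pixel_size_um,
        "area_px": counts.astype(np.int64),
        "compartment": pd.Series([None] * n, dtype=object),
        "cell_type": pd.Series([None] * n, dtype=object),
        "cluster_id": pd.Series([pd.NA] * n, dtype="Int64"),
    }
    table = pd.DataFrame(data)
    for c in stack.channels:
        values = stack.pixels[:, :, c.index].ravel()
        sums = np.bincount(flat, weights=values, minlength=n + 1)[1:]
        table[c.channel_name] = sums / counts
    return table


def marker_columns(cells: pd.DataFrame) -> list[str]:
    """Channel-intensity columns of a CellTable (everything non-structural)."""
    return [c for c in cells.columns if c not in CELL_TABLE_COLUMNS]
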