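"""Channel normalisation, background thresholding and mask recipes.

A raw multiplexed image is made comparable across samples by rescaling each
channel to its 99th intensity percentile (values above the percentile clip to
1).  Thresholding then separates signal from background, and small
morphological programs ("recipes") turn thresholded channels into tissue
compartment or marker masks: e.g. a lamina-propria mask from the vimentin
channel with hole filling, or an epithelium mask built from pan-keratin and
E-cadherin with dilation, hole filling, a large opening and subtraction of the
lamina propria.

Thresholded "positive" always means strictly greater than the threshold, so a
zero background stays negative at threshold 0.  Disk structuring elements
contain the pixels whose centre distance from the origin is <= radius; for
speed they are applied through Euclidean distance transforms, which is exactly
equivalent.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy import ndimage
from skimage import filters

from .errors import (
    DegenerateInputError,
    ParameterError,
    RecipeError,
    ShapeError,
    StateError,
)
from .io import ChannelStack

logger = logging.getLogger(__name__)


@dataclass
class BinaryMask:
    """A named boolean image with a record of the recipe that produced it."""

    pixels: np.ndarray
    name: str
    provenance: str = ""

    def __post_init__(self):
        self.pixels = np.asarray(self.pixels, dtype=bool)
        if self.pixels.ndim != 2:
            raise ShapeError(f"mask {self.name!r}: expected 2-D pixels")

    @property
    def area_px(self) -> int:
        return int(self.pixels.sum())


@dataclass(frozen=True)
class NormalisationParams:
    """Percentile rescaling parameters.

    ``percentile`` defaults to 99 (the distribution's 99th percentile maps to
    1); ``scope`` selects whether the percentile is taken per image or pooled
    over all samples of a run.
    """

    percentile: float = 99.0
    scope: str = "per_image"  # or "pooled_across_samples"

    def __post_init__(self):
        if not 0 < self.percentile <= 100:
            raise ParameterError("percentile must be in (0, 100]")
        if self.scope not in ("per_image", "pooled_across_samples"):
            raise ParameterError(f"unknown normalisation scope {self.scope!r}")


def channel_percentiles(
    stacks: Sequence[ChannelStack], params: NormalisationParams
) -> np.ndarray:
    """Per-channel percentile pooled over the pixels of several stacks."""
    n_channels = len(stacks[0].channels)
    out = np.empty(n_channels)
    for i in range(n_channels):
        pooled = np.concatenate([s.pixels[:, :, i].ravel() for s in stacks])
        out[i] = np.percentile(pooled, params.percentile)
    return out


def normalise_percentile(
    stack: ChannelStack,
    params: NormalisationParams = NormalisationParams(),
    percentiles: np.ndarray | None = None,
) -> ChannelStack:
    """Rescale each channel so its ``percentile`` maps to 1, clipping above.

    Percentiles use linear interpolation between order statistics.  For
    pooled-across-samples scope, precompute the per-channel percentiles with
    :func:`channel_percentiles` and pass them here.  A channel whose
    percentile is 0 becomes all zeros (warning logged).
    """
    if stack.normalised:
        raise StateError(f"stack {stack.sample_id!r} is already normalised")
    if percentiles is None:
        percentiles = np.array(
            [
                np.percentile(stack.pixels[:, :, i], params.percentile)
                for i in range(stack.shape[2])
            ]
        )
    percentiles = np.asarray(percentiles, dtype=np.float64)
    if percentiles.shape != (stack.shape[2],):
        raise ParameterError("one percentile per channel required")
    out = np.empty_like(stack.pixels, dtype=np.float32)
    for i, p in enumerate(percentiles):
        if p <= 0:
            logger.warning(
                "channel %s: percentile is 0, channel set to all zeros",
                stack.channels[i].channel_name,
            )
            out[:, :, i] = 0.0
        else:
            out[:, :, i] = np.minimum(stack.pixels[:, :, i] / p, 1.0)
    return stack.copy_with(out, normalised=True)


OTSU_BINS = 256  # histogram bins for (multi-)Otsu thresholds


def threshold_otsu(channel: np.ndarray, name: str = "otsu") -> tuple[BinaryMask, float]:
    """Otsu threshold over a 256-bin histogram of the channel's range.

    Returns the mask of pixels strictly greater than the threshold and the
    threshold itself (the between-class-variance maximiser).
    """
    channel = np.asarray(channel)
    if channel.min() == channel.max():
        raise DegenerateInputError("constant channel: Otsu threshold undefined")
    t = float(filters.threshold_otsu(channel, nbins=OTSU_BINS))
    return BinaryMask(channel > t, name, provenance=f"threshold_otsu(t={t:g})"), t


def threshold_multiotsu(
    channel: np.ndarray,
    classes: int,
    background_classes: int,
    name: str = "multiotsu",
) -> tuple[BinaryMask, list[float]]:
    """Multi-class Otsu; mask keeps the top (classes - background_classes) classes."""
    if classes < 2:
        raise ParameterError("classes must be >= 2")
    if not 1 <= background_classes < classes:
        raise ParameterError("background_classes must satisfy 1 <= b < classes")
    channel = np.asarray(channel)
    try:
        thresholds = filters.threshold_multiotsu(
            channel, classes=classes, nbins=OTSU_BINS
        )
    except ValueError as exc:
        raise DegenerateInputError(
            f"too few distinct values for {classes}-class Otsu: {exc}"
        ) from exc
    thresholds = [float(t) for t in thresholds]
    cut = thresholds[background_classes - 1]
    mask = BinaryMask(
        channel > cut,
        name,
        provenance=f"threshold_multiotsu(classes={classes}, background={background_classes})",
    )
    return mask, thresholds


def smooth_gaussian(channel: np.ndarray, radius_px: float) -> np.ndarray:
    """Isotropic Gaussian smoothing (sigma = radius_px, reflective boundary)."""
    if radius_px <= 0:
        raise ParameterError("radius_px must be positive")
    return ndimage.gaussian_filter(
        np.asarray(channel, dtype=np.float64), sigma=radius_px, mode="reflect"
    )


# ---------------------------------------------------------------------------
# Morphology on binary masks (disk structuring elements via EDT)

def dilate_disk(mask: np.ndarray, radius_px: float) -> np.ndarray:
    """Binary dilation by a disk of the given radius (centre distance <= r)."""
    if radius_px <= 0:
        raise ParameterError("dilation radius must be positive")
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        return mask.copy()
    dist = ndimage.distance_transform_edt(~mask)
    return dist <= radius_px


def erode_disk(mask: np.ndarray, radius_px: float) -> np.ndarray:
    """Binary erosion by a disk; a pixel survives iff the disk around it fits.

    Pixels outside the image count as background, so foreground touching the
    border erodes like an interior boundary.
    """
    if radius_px <= 0:
        raise ParameterError("erosion radius must be positive")
    mask = np.asarray(mask, dtype=bool)
    pad = int(np.ceil(radius_px)) + 1
    padded = np.pad(mask, pad, mode="constant", constant_values=False)
    dist = ndimage.distance_transform_edt(padded)
    return dist[pad:-pad, pad:-pad] > radius_px


def opening_disk(mask: np.ndarray, radius_px: float) -> np.ndarray:
    """Morphological opening (erosion then dilation) with a disk element."""
    eroded = erode_disk(mask, radius_px)
    if not eroded.any():
        return eroded
    return dilate_disk(eroded, radius_px)


def fill_holes(mask: np.ndarray, max_area_px: float) -> np.ndarray:
    """Fill background holes of area strictly less than ``max_area_px``.

    Holes are 4-connected background components that do not touch the image
    border; border-touching background is outside tissue, not a hole.
    """
    if max_area_px <= 0:
        raise ParameterError("max_area_px must be positive")
    mask = np.asarray(mask, dtype=bool)
    background = ~mask
    labels, n = ndimage.label(background, structure=[[0, 1, 0], [1, 1, 1], [0, 1, 0]])
    if n == 0:
        return mask.copy()
    border_labels = np.unique(
        np.concatenate(
            [labels[0, :], labels[-1, :], labels[:, 0], labels[:, -1]]
        )
    )
    areas = np.bincount(labels.ravel(), minlength=n + 1)
    fill = np.zeros(n + 1, dtype=bool)
    fill[1:] = areas[1:] < max_area_px
    fill[border_labels] = False
    return mask | fill[labels]


# ---------------------------------------------------------------------------
# Mask recipes

@dataclass(frozen=True)
class RecipeStep:
    op: str
    args: tuple = ()

    _VALID = {
        "threshold_otsu": 0,
        "threshold_multiotsu": 2,  # (classes, background_classes)
        "threshold_fixed": 1,
        "smooth_gaussian": 1,
        "dilate": 1,
        "fill_holes": 1,
        "opening": 1,
        "union": 0,
        "subtract": 1,  # mask name
        "intersect": 1,  # mask name
    }

    def __post_init__(self):
        if self.op not in self._VALID:
            raise RecipeError(f"unknown recipe op {self.op!r}")
        if len(self.args) != self._VALID[self.op]:
            raise RecipeError(
                f"{self.op} expects {self._VALID[self.op]} argument(s), got {len(self.args)}"
            )


@dataclass(frozen=True)
class MaskRecipe:
    """An ordered morphological program producing one named binary mask.

    ``sources`` are channel names and/or previously built mask names.  Channel
    sources must pass through a thresholding step before any binary operation
    (Gaussian smoothing is permitted first, to suppress hot-pixel artefacts
    before the threshold is taken).  ``union`` merges all working images into
    one; if the program ends with several working images they are unioned
    implicitly.
    """

    name: str
    sources: tuple[str, ...]
    steps: tuple[RecipeStep, ...]

    def __post_init__(self):
        if not self.sources:
            raise RecipeError(f"recipe {self.name!r}: no sources")
        if not self.steps:
            raise RecipeError(f"recipe {self.name!r}: no steps")


def run_mask_recipe(
    stack: ChannelStack,
    recipe: MaskRecipe,
    existing: Mapping[str, BinaryMask] | None = None,
) -> BinaryMask:
    """Execute a mask recipe against a stack and previously built masks."""
    existing = existing or {}
    channel_names = set(stack.channel_names)

    # working: list of (array, is_binary)
    working: list[tuple[np.ndarray, bool]] = []
    for src in recipe.sources:
        if src in existing:
            working.append((existing[src].pixels.copy(), True))
        elif src in channel_names:
            working.append((stack.channel(src).astype(np.float64), False))
        else:
            raise RecipeError(
                f"recipe {recipe.name!r}: unknown source {src!r}"
            )

    def require_binary(idx: int, step: RecipeStep):
        for arr, is_bin in working:
            if not is_bin:
                raise RecipeError(
                    f"recipe {recipe.name!r} step {idx} ({step.op}): "
                    "channel source not thresholded yet"
                )

    for idx, step in enumerate(recipe.steps):
        if step.op == "smooth_gaussian":
            working = [
                (smooth_gaussian(arr, step.args[0]) if not is_bin else arr, is_bin)
                for arr, is_bin in working
            ]
        elif step.op == "threshold_otsu":
            working = [
                (threshold_otsu(arr)[0].pixels if not is_bin else arr, True)
                for arr, is_bin in working
            ]
        elif step.op == "threshold_multiotsu":
            classes, background = step.args
            working = [
                (
                    threshold_multiotsu(arr, int(classes), int(background))[0].pixels
                    if not is_bin
                    else arr,
                    True,
                )
                for arr, is_bin in working
            ]
        elif step.op == "threshold_fixed":
            (t,) = step.args
            working = [
                (arr > float(t) if not is_bin else arr, True)
                for arr, is_bin in working
            ]
        elif step.op == "union":
            require_binary(idx, step)
            merged = working[0][0]
            for arr, _ in working[1:]:
                merged = merged | arr
            working = [(merged, True)]
        elif step.op in ("dilate", "fill_holes", "opening"):
            require_binary(idx, step)
            fn = {"dilate": dilate_disk, "fill_holes": fill_holes, "opening": opening_disk}[step.op]
            working = [(fn(arr, step.args[0]), True) for arr, _ in working]
        elif step.op in ("subtract", "intersect"):
            require_binary(idx, step)
            (other_name,) = step.args
            if other_name not in existing:
                raise RecipeError(
                    f"recipe {recipe.name!r} step {idx} ({step.op}): "
                    f"unknown mask {other_name!r}"
                )
            other = existing[other_name].pixels
            if step.op == "subtract":
                working = [(arr & ~other, True) for arr, _ in working]
            else:
                working = [(arr & other, True) for arr, _ in working]

    for arr, is_bin in working:
        if not is_bin:
            raise RecipeError(
                f"recipe {recipe.name!r}: a channel source was never thresholded"
            )
    result = working[0][0]
    for arr, _ in working[1:]:
        result = result | arr
    provenance = f"{'+'.join(recipe.sources)} | " + " -> ".join(
        s.op + (str(list(s.args)) if s.args else "") for s in recipe.steps
    )
    return BinaryMask(result, recipe.name, provenance=provenance)
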