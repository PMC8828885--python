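"""Cell-agnostic quantification of marker-positive area.

Secreted or extracellular signal (e.g. IgA in transit through the epithelium)
is invisible to cell segmentation; this module measures it directly at the
pixel level.  The numerator is a boolean combination of marker masks; the
denominator is a compartment mask or the whole image.  Numerator pixels
outside the denominator are excluded before counting, so the fraction is the
share of the *denominator* region that is positive.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np

from .errors import ShapeError, UndefinedFractionError
from .expressions import parse_mask_expression, referenced_names
from .preprocess import BinaryMask


@dataclass(frozen=True)
class PixelAreaResult:
    sample_id: str
    numerator_expression: str
    denominator_name: str
    positive_px: int
    denominator_px: int
    fraction: float

    @property
    def area_um2(self) -> float | None:
        return None  # convert with pixel_size_um**2 at the call site


def positive_area(
    masks: Mapping[str, BinaryMask],
    numerator: str,
    denominator: str = "image",
    sample_id: str = "",
) -> PixelAreaResult:
    """Fraction of the denominator region positive for the numerator expression.

    ``numerator`` is a boolean expression over mask names (AND/OR/NOT and
    parentheses); ``denominator`` is a mask name or the literal "image".
    """
    tree = parse_mask_expression(numerator)
    shapes = {m.pixels.shape for m in masks.values()}
    if len(shapes) > 1:
        raise ShapeError(f"masks differ in shape: {sorted(shapes)}")
    env = {}
    for name in referenced_names(tree):
        if name not in masks:
            raise UndefinedFractionError(f"unknown mask {name!r} in numerator")
        env[name] = masks[name].pixels
    num = tree.evaluate(env)
    if denominator == "image":
        denom = np.ones_like(num, dtype=bool)
    else:
        if denominator not in masks:
            raise UndefinedFractionError(f"unknown denominator mask {denominator!r}")
        denom = masks[denominator].pixels
    denominator_px = int(denom.sum())
    if denominator_px == 0:
        raise UndefinedFractionError(
            f"denominator mask {denominator!r} is empty; fraction undefined"
        )
    positive_px = int((num & denom).sum())
    return PixelAreaResult(
        sample_id=sample_id,
        numerator_expression=numerator,
        denominator_name=denominator,
        positive_px=positive_px,
        denominator_px=denominator_px,
        fraction=positive_px / denominator_px,
    )
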