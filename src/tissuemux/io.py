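"""Image and metadata I/O.

Multiplexed imaging platforms deliver either TIFF images (one per marker, or a
multi-page stack) or — for mass-cytometry ablations — tab-delimited text files
with one row per pixel and one intensity column per channel.  This module
reads both into a :class:`ChannelStack`, the pipeline's in-memory container,
and writes stacks back out as single-channel 32-bit float TIFFs plus a channel
metadata CSV.

Conventions used throughout the package: coordinates are 0-based with origin
at the top-left, pixel (row=y, col=x); distances are measured between pixel
centres; intensities are non-negative floats, and a normalised stack has all
values in [0, 1].
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import tifffile

from .errors import FormatError, MetadataMismatchError, ShapeError

logger = logging.getLogger(__name__)

ROLES = ("nucleus", "membrane", "marker", "ignore")


@dataclass(frozen=True)
class ChannelMetadata:
    """One channel of a multiplexed panel.

    ``channel_name`` is the marker (e.g. ``CD3``); ``label`` the metal or
    fluorophore tag (e.g. ``Er170``); ``role`` marks how the channel is used
    downstream (nucleus / membrane / marker / ignore).
    """

    channel_name: str
    label: str
    index: int
    role: str = "marker"

    def __post_init__(self):
        if self.index < 0:
            raise MetadataMismatchError(f"negative channel index {self.index}")
        if self.role not in ROLES:
            raise MetadataMismatchError(
                f"channel {self.channel_name!r}: unknown role {self.role!r}"
            )


def validate_channel_table(channels: Sequence[ChannelMetadata]) -> None:
    names = [c.channel_name for c in channels]
    if len(set(names)) != len(names):
        raise MetadataMismatchError("duplicate channel_name in channel table")
    indices = sorted(c.index for c in channels)
    if indices != list(range(len(channels))):
        raise MetadataMismatchError(
            "channel indices must be unique and contiguous from 0"
        )


@dataclass
class ChannelStack:
    """H x W x C grid of non-negative intensities with per-channel metadata."""

    pixels: np.ndarray
    channels: list[ChannelMetadata]
    pixel_size_um: float = 1.0
    sample_id: str = ""
    normalised: bool = False

    def __post_init__(self):
        self.pixels = np.asarray(self.pixels, dtype=np.float32)
        if self.pixels.ndim != 3:
            raise ShapeError(f"expected H x W x C pixels, got shape {self.pixels.shape}")
        if self.pixels.shape[2] != len(self.channels):
            raise MetadataMismatchError(
                f"{self.pixels.shape[2]} image channels but "
                f"{len(self.channels)} metadata rows"
            )
        if not np.isfinite(self.pixels).all():
            raise ShapeError("non-finite pixel values")
        if (self.pixels < 0).any():
            raise ShapeError("negative pixel values")
        if self.pixel_size_um <= 0:
            raise ShapeError("pixel_size_um must be positive")
        validate_channel_table(self.channels)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.pixels.shape

    @property
    def channel_names(self) -> list[str]:
        return [c.channel_name for c in self.channels]

    def channel(self, name: str) -> np.ndarray:
        """2-D view of one channel by marker name."""
        for c in self.channels:
            if c.channel_name == name:
                return self.pixels[:, :, c.index]
        raise MetadataMismatchError(f"no channel named {name!r}")

    def copy_with(self, pixels: np.ndarray, normalised: bool | None = None) -> "ChannelStack":
        return ChannelStack(
            pixels=pixels,
            channels=list(self.channels),
            pixel_size_um=self.pixel_size_um,
            sample_id=self.sample_id,
            normalised=self.normalised if normalised is None else normalised,
        )


def read_channel_table(path: str | Path) -> list[ChannelMetadata]:
    """Read a channel-metadata CSV (header channel_name,label,index,role)."""
    df = pd.read_csv(path, dtype={"channel_name": str, "label": str})
    required = {"channel_name", "label", "index", "role"}
    missing = required - set(df.columns)
    if missing:
        raise FormatError(f"channel table {path}: missing columns {sorted(missing)}")
    channels = [
        ChannelMetadata(str(r.channel_name), str(r.label), int(r.index), str(r.role))
        for r in df.itertuples()
    ]
    channels.sort(key=lambda c: c.index)
    validate_channel_table(channels)
    return channels


def write_channel_table(channels: Sequence[ChannelMetadata], path: str | Path) -> None:
    pd.DataFrame(
        {
            "channel_name": [c.channel_name for c in channels],
            "label": [c.label for c in channels],
            "index": [c.index for c in channels],
            "role": [c.role for c in channels],
        }
    ).to_csv(path, index=False)


def _match_channel_column(channel: ChannelMetadata, header: Sequence[str]) -> str:
    """Find the header token carrying this channel.

    Ablation text headers look like ``CD3(Er170Di)``: the marker name or the
    tag appears as a substring of the token.  Exactly one column must match.
    """
    matches = [
        tok
        for tok in header
        if tok not in ("X", "Y")
        and (channel.channel_name in tok or (channel.label and channel.label in tok))
    ]
    if not matches:
        raise MetadataMismatchError(
            f"channel {channel.channel_name!r} ({channel.label}) not found in header"
        )
    if len(matches) > 1:
        raise MetadataMismatchError(
            f"channel {channel.channel_name!r} matches several header columns: {matches}"
        )
    return matches[0]


def parse_imc_text(
    path: str | Path,
    channel_table: Sequence[ChannelMetadata],
    pixel_size_um: float = 1.0,
    sample_id: str | None = None,
) -> ChannelStack:
    """Reconstruct a multi-channel image from a mass-cytometry ablation text file.

    The file is tab-delimited with integer X and Y pixel coordinates and one
    intensity column per channel.  The output image spans (max Y + 1) rows by
    (max X + 1) columns; pixels absent from the file are filled with 0 (a
    truncated ablation still yields a rectangular grid) and counted in a
    logged warning.
    """
    validate_channel_table(channel_table)
    df = pd.read_csv(path, sep="\t")
    for coord in ("X", "Y"):
        if coord not in df.columns:
            raise FormatError(f"{path}: missing required column {coord!r}")
    xs = df["X"].to_numpy()
    ys = df["Y"].to_numpy()
    if len(df) == 0:
        raise FormatError(f"{path}: no pixel rows")
    if (xs < 0).any() or (ys < 0).any():
        raise FormatError(f"{path}: negative pixel coordinates")
    width = int(xs.max()) + 1
    height = int(ys.max()) + 1
    flat = ys.astype(np.int64) * width + xs.astype(np.int64)
    if len(np.unique(flat)) != len(flat):
        order = np.argsort(flat, kind="stable")
        dup_pos = order[np.nonzero(np.diff(flat[order]) == 0)[0][0] + 1]
        raise FormatError(
            f"{path}: duplicate pixel row at (X={xs[dup_pos]}, Y={ys[dup_pos]})"
        )
    n_missing = height * width - len(flat)
    if n_missing:
        logger.warning(
            "%s: %d of %d pixels absent; filled with 0", path, n_missing, height * width
        )
    pixels = np.zeros((height, width, len(channel_table)), dtype=np.float32)
    for c in channel_table:
        column = _match_channel_column(c, list(df.columns))
        plane = np.zeros(height * width, dtype=np.float32)
        plane[flat] = df[column].to_numpy(dtype=np.float32)
        pixels[:, :, c.index] = plane.reshape(height, width)
    return ChannelStack(
        pixels=pixels,
        channels=list(channel_table),
        pixel_size_um=pixel_size_um,
        sample_id=sample_id or Path(path).stem,
    )


def read_stack(
    image_paths: Sequence[str | Path],
    channel_table: Sequence[ChannelMetadata],
    pixel_size_um: float = 1.0,
    sample_id: str = "",
    normalised: bool = False,
) -> ChannelStack:
    """Load a stack from one multi-page TIFF or one single-channel TIFF per channel.

    Integer storage types are promoted to float without rescaling: a 16-bit
    image with maximum 65535 keeps that value.
    """
    validate_channel_table(channel_table)
    planes: list[np.ndarray] = []
    if len(image_paths) == 1:
        data = tifffile.imread(image_paths[0])
        if data.ndim == 2:
            data = data[None]
        if data.ndim != 3:
            raise ShapeError(f"{image_paths[0]}: expected 2-D or 3-D TIFF data")
        planes = [np.asarray(p) for p in data]
    else:
        for p in image_paths:
            plane = tifffile.imread(p)
            if plane.ndim != 2:
                raise ShapeError(f"{p}: expected a single-channel 2-D TIFF")
            planes.append(np.asarray(plane))
    if len(planes) != len(channel_table):
        raise MetadataMismatchError(
            f"{len(planes)} image pages/files but {len(channel_table)} channel rows"
        )
    shapes = {p.shape for p in planes}
    if len(shapes) != 1:
        raise ShapeError(f"channel images differ in size: {sorted(shapes)}")
    pixels = np.stack([p.astype(np.float32) for p in planes], axis=-1)
    return ChannelStack(
        pixels=pixels,
        channels=list(channel_table),
        pixel_size_um=pixel_size_um,
        sample_id=sample_id,
        normalised=normalised,
    )


def _sanitise(name: str, index: int) -> str:
    cleaned = re.sub(r"[^A-Za-z0-9_\-]+", "_", name).strip("_")
    if not cleaned:
        cleaned = f"channel{index}"
        logger.warning("empty channel name at index %d; using %r", index, cleaned)
    return cleaned


def write_channels(
    stack: ChannelStack, out_dir: str | Path, overwrite: bool = False
) -> list[Path]:
    """Write one 32-bit float single-channel TIFF per channel plus a metadata CSV.

    Files are named ``<sample_id>_<channel_name>.tiff``; returns the paths
    written (metadata CSV last).
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    prefix = _sanitise(stack.sample_id, 0) if stack.sample_id else "sample"
    paths: list[Path] = []
    targets = []
    for c in stack.channels:
        name = _sanitise(c.channel_name, c.index)
        targets.append((out_dir / f"{prefix}_{name}.tiff", c))
    csv_path = out_dir / f"{prefix}_channels.csv"
    if not overwrite:
        for p, _ in targets:
            if p.exists():
                raise FileExistsError(f"{p} exists; pass overwrite=True to replace")
        if csv_path.exists():
            raise FileExistsError(f"{csv_path} exists; pass overwrite=True to replace")
    for p, c in targets:
        tifffile.imwrite(p, stack.pixels[:, :, c.index].astype(np.float32))
        paths.append(p)
    write_channel_table(stack.channels, csv_path)
    paths.append(csv_path)
    return paths
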