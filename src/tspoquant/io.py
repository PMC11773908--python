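"""Image and table input/output.

Images are multi-page 16-bit grayscale TIFFs; channel identity is always
established through an explicit page-index -> channel-name map, never by page
order alone (staining panels vary between rounds).  All tabular artifacts
(nuclei, cells, lesions, ROIs, fit summaries) travel as plain CSV.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import tifffile

__all__ = [
    "MultiplexImage",
    "RoiSpec",
    "um_to_px",
    "read_multiplex_tiff",
    "write_multiplex_tiff",
    "read_table",
    "write_table",
    "ChannelCountError",
    "BitDepthError",
]

#: physical pixel pitch of the acquisition, micrometres per pixel
DEFAULT_PIXEL_SIZE_UM = 0.325


class ChannelCountError(ValueError):
    """TIFF page count disagrees with the channel map."""


class BitDepthError(ValueError):
    """Image data is not 16-bit and coercion was not requested."""


def um_to_px(um: float, pixel_size_um: float = DEFAULT_PIXEL_SIZE_UM) -> int:
    """Convert a physical length to whole pixels, rounding down.

    Rounding down guarantees the pixel extent never exceeds the stated
    physical extent (500 um -> 1538 px at 0.325 um/px).
    """
    if pixel_size_um <= 0:
        raise ValueError("pixel_size_um must be positive")
    return int(np.floor(um / pixel_size_um))


@dataclass
class MultiplexImage:
    """Named 16-bit channels on a shared pixel grid.

    Parameters
    ----------
    channels
        Mapping from channel name (e.g. ``"DAPI"``, ``"Iba1"``, ``"TSPO"``)
        to a 2-D ``uint16`` array.  All channels must share one shape.
    pixel_size_um
        Physical size of one pixel in micrometres.
    """

    channels: dict[str, np.ndarray]
    pixel_size_um: float = DEFAULT_PIXEL_SIZE_UM

    def __post_init__(self) -> None:
        if not self.channels:
            raise ValueError("MultiplexImage requires at least one channel")
        if self.pixel_size_um <= 0:
            raise ValueError("pixel_size_um must be positive")
        shapes = {arr.shape for arr in self.channels.values()}
        if len(shapes) != 1:
            raise ValueError(f"channels have inconsistent shapes: {shapes}")
        (shape,) = shapes
        if len(shape) != 2:
            raise ValueError("channels must be 2-D arrays")
        for name, arr in self.channels.items():
            if arr.dtype != np.uint16:
                raise BitDepthError(
                    f"channel {name!r} has dtype {arr.dtype}, expected uint16"
                )

    @property
    def height_px(self) -> int:
        return next(iter(self.channels.values())).shape[0]

    @property
    def width_px(self) -> int:
        return next(iter(self.channels.values())).shape[1]

    @property
    def shape(self) -> tuple[int, int]:
        return (self.height_px, self.width_px)

    def __getitem__(self, name: str) -> np.ndarray:
        try:
            return self.channels[name]
        except KeyError:
            raise KeyError(
                f"channel {name!r} not present; available: {sorted(self.channels)}"
            ) from None


@dataclass
class RoiSpec:
    """Axis-aligned region of interest, 0-based, half-open [y0, y0+h) x [x0, x0+w)."""

    roi_id: str
    x0_px: int
    y0_px: int
    width_px: int
    height_px: int
    side: str = "none"  # {"left", "right", "none"}

    def __post_init__(self) -> None:
        if self.width_px <= 0 or self.height_px <= 0:
            raise ValueError(f"ROI {self.roi_id}: width/height must be positive")
        if self.x0_px < 0 or self.y0_px < 0:
            raise ValueError(f"ROI {self.roi_id}: origin must be non-negative")
        if self.side not in {"left", "right", "none"}:
            raise ValueError(f"ROI {self.roi_id}: side must be left/right/none")

    def validate_within(self, image: MultiplexImage) -> None:
        if (
            self.y0_px + self.height_px > image.height_px
            or self.x0_px + self.width_px > image.width_px
        ):
            raise ValueError(
                f"ROI {self.roi_id} exceeds image bounds "
                f"{image.shape} at ({self.y0_px},{self.x0_px})"
                f"+({self.height_px},{self.width_px})"
            )

    @property
    def slices(self) -> tuple[slice, slice]:
        return (
            slice(self.y0_px, self.y0_px + self.height_px),
            slice(self.x0_px, self.x0_px + self.width_px),
        )


def read_multiplex_tiff(
    path: str | Path,
    channel_map: Mapping[int, str],
    pixel_size_um: float = DEFAULT_PIXEL_SIZE_UM,
    coerce_dtype: bool = False,
) -> MultiplexImage:
    """Read a multi-page TIFF into a :class:`MultiplexImage`.

    ``channel_map`` maps 0-based page index to channel name and must cover
    every page of the file exactly.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    data = tifffile.imread(path)
    if data.ndim == 2:
        data = data[None, :, :]
    if data.ndim != 3:
        raise ValueError(f"{path}: expected stack of 2-D pages, got shape {data.shape}")
    n_pages = data.shape[0]
    if n_pages != len(channel_map):
        raise ChannelCountError(
            f"{path}: {n_pages} pages but channel_map has {len(channel_map)} entries"
        )
    if sorted(channel_map) != list(range(n_pages)):
        raise ChannelCountError(
            f"{path}: channel_map keys must be 0..{n_pages - 1}, got {sorted(channel_map)}"
        )
    if data.dtype != np.uint16:
        if not coerce_dtype:
            raise BitDepthError(
                f"{path}: dtype {data.dtype} is not uint16 (pass coerce_dtype=True to convert)"
            )
        warnings.warn(f"{path}: coercing {data.dtype} data to uint16", stacklevel=2)
        data = np.clip(data, 0, 65535).astype(np.uint16)
    channels = {channel_map[i]: np.ascontiguousarray(data[i]) for i in range(n_pages)}
    return MultiplexImage(channels=channels, pixel_size_um=pixel_size_um)


def write_multiplex_tiff(
    image: MultiplexImage, path: str | Path, channel_order: list[str] | None = None
) -> dict[int, str]:
    """Write a multi-page 16-bit TIFF; returns the page->channel map used.

    Pages are written in ``channel_order`` (default: insertion order of
    ``image.channels``), so a round trip through
    :func:`read_multiplex_tiff` with the returned map is bit-identical.
    """
    order = channel_order if channel_order is not None else list(image.channels)
    missing = set(order) - set(image.channels)
    if missing:
        raise KeyError(f"channel_order names absent channels: {sorted(missing)}")
    stack = np.stack([image.channels[name] for name in order])
    tifffile.imwrite(Path(path), stack, photometric="minisblack")
    return {i: name for i, name in enumerate(order)}


def write_table(df: pd.DataFrame, path: str | Path, allow_empty: bool = True) -> None:
    """Write a record table as CSV with a header row, full float precision."""
    if df.empty and not allow_empty:
        raise ValueError(f"refusing to write empty table to {path}")
    df.to_csv(Path(path), index=False)


def read_table(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    return pd.read_csv(path)


def rois_to_frame(rois: list[RoiSpec]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "roi_id": r.roi_id,
                "x0_px": r.x0_px,
                "y0_px": r.y0_px,
                "width_px": r.width_px,
                "height_px": r.height_px,
                "side": r.side,
            }
            for r in rois
        ]
    )


def rois_from_frame(df: pd.DataFrame) -> list[RoiSpec]:
    return [
        RoiSpec(
            roi_id=str(row.roi_id),
            x0_px=int(row.x0_px),
            y0_px=int(row.y0_px),
            width_px=int(row.width_px),
            height_px=int(row.height_px),
            side=str(row.side),
        )
        for row in df.itertuples()
    ]
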