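"""Iba1+ cell-mask construction and per-cell marker calling.

A microglia/macrophage cell mask is the nucleus plus every above-threshold
Iba1 connected component reachable within a Euclidean radius ``r_px``
(default 15 px) of the nucleus edge.  Iba1 fragments without a nucleus never
produce a cell.  Masks contested between nuclei are partitioned by
nearest-nucleus distance; each resolved mask is then scanned for the marker
panel (TSPO, CD74, CD163, MRP14, Arg1, ...) with strict ``>`` thresholds and
a minimum above-threshold pixel count.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy.spatial import cKDTree

from .config import PipelineConfig
from .io import MultiplexImage
from .segmentation import NucleusLabel, segment_nuclei

__all__ = [
    "CellRecord",
    "build_cell_mask",
    "resolve_contested_pixels",
    "call_markers",
    "extract_cells",
    "cells_to_frame",
    "DEFAULT_MARKERS",
]

DEFAULT_MARKERS = ("TSPO", "CD74", "CD163", "MRP14", "Arg1")

_STRUCT8 = np.ones((3, 3), dtype=int)


@dataclass
class CellRecord:
    """One nucleus-anchored cell: mask pixels plus per-marker calls."""

    cell_id: int
    nucleus_id: int
    pixels: tuple[np.ndarray, np.ndarray]  # (ys, xs) of the full mask
    nucleus_pixels: tuple[np.ndarray, np.ndarray]
    iba1_positive: bool = False
    iba1_px: int = 0
    border_clipped: bool = False
    marker_positive: dict[str, bool] = field(default_factory=dict)
    marker_px: dict[str, int] = field(default_factory=dict)
    marker_mean: dict[str, float] = field(default_factory=dict)

    @property
    def area_px(self) -> int:
        return int(self.pixels[0].size)


def _ring_distance_mask(
    nucleus: NucleusLabel, shape: tuple[int, int], r_px: int
) -> tuple[np.ndarray, tuple[int, int]]:
    """Boolean patch of pixels with 0 < Euclidean distance <= r_px from the
    nucleus pixel set, together with the patch origin (clipped to the image)."""
    ys, xs = nucleus.pixels
    y0 = max(int(ys.min()) - r_px - 1, 0)
    x0 = max(int(xs.min()) - r_px - 1, 0)
    y1 = min(int(ys.max()) + r_px + 2, shape[0])
    x1 = min(int(xs.max()) + r_px + 2, shape[1])
    patch = np.zeros((y1 - y0, x1 - x0), dtype=bool)
    patch[ys - y0, xs - x0] = True
    dist = ndimage.distance_transform_edt(~patch)
    ring = (dist > 0) & (dist <= r_px)
    return ring, (y0, x0)


def build_cell_mask(
    nucleus: NucleusLabel,
    iba1: np.ndarray,
    config: PipelineConfig | None = None,
    iba1_labels: np.ndarray | None = None,
) -> CellRecord:
    """Build the cell mask for one nucleus.

    ``iba1_labels`` may carry a pre-computed 8-connected labelling of the
    above-threshold Iba1 mask (as produced once per image by
    :func:`extract_cells`); otherwise it is computed here.
    """
    config = config or PipelineConfig()
    theta = config.threshold_for("Iba1")
    if iba1_labels is None:
        iba1_labels, _ = ndimage.label(iba1 > theta, structure=_STRUCT8)

    ys, xs = nucleus.pixels
    shape = iba1.shape
    border_clipped = (
        ys.min() < config.r_px
        or xs.min() < config.r_px
        or ys.max() >= shape[0] - config.r_px
        or xs.max() >= shape[1] - config.r_px
    )

    if config.r_px > 0:
        ring, (y0, x0) = _ring_distance_mask(nucleus, shape, config.r_px)
        ring_labels = iba1_labels[y0 : y0 + ring.shape[0], x0 : x0 + ring.shape[1]]
        touched = np.unique(ring_labels[ring])
        touched = touched[touched != 0]
    else:
        touched = np.array([], dtype=iba1_labels.dtype)

    if touched.size:
        sel = np.isin(iba1_labels, touched)
        sel[ys, xs] = True  # mask = nucleus union selected Iba1 pixels
        mys, mxs = np.nonzero(sel)
    else:
        mys, mxs = ys.copy(), xs.copy()

    cell = CellRecord(
        cell_id=nucleus.nucleus_id,
        nucleus_id=nucleus.nucleus_id,
        pixels=(mys, mxs),
        nucleus_pixels=(ys, xs),
        border_clipped=bool(border_clipped),
    )
    iba1_px = int(np.count_nonzero(iba1[mys, mxs] > theta))
    cell.iba1_px = iba1_px
    cell.iba1_positive = iba1_px >= config.min_iba1_px
    return cell


def resolve_contested_pixels(cells: list[CellRecord], shape: tuple[int, int]) -> list[CellRecord]:
    """Assign every pixel claimed by several cells to exactly one.

    A contested pixel goes to the cell whose nucleus is nearest (Euclidean
    distance to the nucleus pixel set, i.e. to its boundary for exterior
    pixels); exact ties go to the lower ``nucleus_id``.  Nucleus pixels
    always stay with their own cell.  Output masks are disjoint.
    """
    if not cells:
        return cells
    claim_count = np.zeros(shape, dtype=np.int32)
    for cell in cells:
        claim_count[cell.pixels] += 1
    contested = claim_count > 1
    if not contested.any():
        return cells

    cys, cxs = np.nonzero(contested)
    pts = np.column_stack([cys, cxs]).astype(float)
    # nearest-nucleus distance per contested pixel, per claiming cell
    best_dist = np.full(len(pts), np.inf)
    best_owner = np.full(len(pts), -1, dtype=np.int64)
    order = sorted(cells, key=lambda c: c.nucleus_id)
    contested_index = {}
    for i, (y, x) in enumerate(zip(cys, cxs)):
        contested_index[(int(y), int(x))] = i
    for cell in order:
        mys, mxs = cell.pixels
        idx = [
            contested_index[(int(y), int(x))]
            for y, x in zip(mys, mxs)
            if (int(y), int(x)) in contested_index
        ]
        if not idx:
            continue
        tree = cKDTree(np.column_stack(cell.nucleus_pixels).astype(float))
        d, _ = tree.query(pts[idx])
        for j, dj in zip(idx, d):
            # strict <: ties resolved in nucleus_id order (lower id first)
            if dj < best_dist[j]:
                best_dist[j] = dj
                best_owner[j] = cell.nucleus_id

    resolved = []
    for cell in order:
        mys, mxs = cell.pixels
        keep = np.ones(mys.size, dtype=bool)
        for k, (y, x) in enumerate(zip(mys, mxs)):
            j = contested_index.get((int(y), int(x)))
            if j is not None and best_owner[j] != cell.nucleus_id:
                keep[k] = False
        cell.pixels = (mys[keep], mxs[keep])
        resolved.append(cell)
    return resolved


def call_markers(
    cell: CellRecord,
    image: MultiplexImage,
    markers: tuple[str, ...] = DEFAULT_MARKERS,
    config: PipelineConfig | None = None,
) -> CellRecord:
    """Fill per-marker positivity, above-threshold pixel counts and means.

    A marker is positive iff at least ``min_pos_px`` mask pixels exceed its
    configured threshold (strict ``>``).
    """
    config = config or PipelineConfig()
    mys, mxs = cell.pixels
    for marker in markers:
        channel = image[marker]
        theta = config.threshold_for(marker)
        values = channel[mys, mxs]
        n_pos = int(np.count_nonzero(values > theta))
        cell.marker_px[marker] = n_pos
        cell.marker_mean[marker] = float(values.mean()) if values.size else 0.0
        cell.marker_positive[marker] = n_pos >= config.min_pos_px
    return cell


def extract_cells(
    image: MultiplexImage,
    config: PipelineConfig | None = None,
    markers: tuple[str, ...] = DEFAULT_MARKERS,
    nuclei: list[NucleusLabel] | None = None,
    iba1_channel: str = "Iba1",
) -> tuple[list[CellRecord], list[NucleusLabel]]:
    """Full per-image phenotyping: segment nuclei, build masks, resolve
    contested pixels, call markers.  Returns (cells, nuclei)."""
    config = config or PipelineConfig()
    if nuclei is None:
        nuclei = segment_nuclei(image["DAPI"], config)
    iba1 = image[iba1_channel]
    theta = config.threshold_for(iba1_channel)
    iba1_labels, _ = ndimage.label(iba1 > theta, structure=_STRUCT8)
    cells = [build_cell_mask(nl, iba1, config, iba1_labels=iba1_labels) for nl in nuclei]
    cells = resolve_contested_pixels(cells, image.shape)
    for cell in cells:
        # recompute Iba1 positivity on the resolved (disjoint) mask
        mys, mxs = cell.pixels
        cell.iba1_px = int(np.count_nonzero(iba1[mys, mxs] > theta))
        cell.iba1_positive = cell.iba1_px >= config.min_iba1_px
        call_markers(cell, image, markers, config)
    return cells, nuclei


def cells_to_frame(
    cells: list[CellRecord], markers: tuple[str, ...] = DEFAULT_MARKERS
) -> pd.DataFrame:
    rows = []
    for cell in cells:
        row = {
            "cell_id": cell.cell_id,
            "nucleus_id": cell.nucleus_id,
            "area_px": cell.area_px,
            "iba1_pos": bool(cell.iba1_positive),
            "iba1_px": cell.iba1_px,
            "border_clipped": cell.border_clipped,
        }
        for marker in markers:
            key = marker.lower()
            row[f"{key}_pos"] = bool(cell.marker_positive.get(marker, False))
            row[f"{key}_px"] = cell.marker_px.get(marker, 0)
            row[f"{key}_mean"] = cell.marker_mean.get(marker, 0.0)
        rows.append(row)
    columns = [
        "cell_id",
        "nucleus_id",
        "area_px",
        "iba1_pos",
        "iba1_px",
        "border_clipped",
    ]
    for marker in markers:
        key = marker.lower()
        columns += [f"{key}_pos", f"{key}_px", f"{key}_mean"]
    return pd.DataFrame(rows, columns=columns)
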