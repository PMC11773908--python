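"""Nucleus segmentation and shape classification.

The DAPI channel is binarised (Otsu by default), 8-connected objects are
classified as spherical, elliptical, bilobed (two overlapping nuclei) or
irregular cluster, and bilobed/cluster objects are split into their member
nuclei — first by raising the local intensity threshold stepwise (overlap
necks are dimmer than nucleus centres), falling back to marker-controlled
watershed on the distance transform for homogeneous objects.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from skimage import measure
from skimage.filters import threshold_otsu
from skimage.morphology import h_maxima
from skimage.segmentation import watershed

from .config import PipelineConfig

__all__ = [
    "NucleusLabel",
    "segment_nuclei",
    "classify_shape",
    "split_object",
    "count_lobes",
    "SaturatedImageError",
]

SHAPE_SPHERICAL = "spherical"
SHAPE_ELLIPTICAL = "elliptical"
SHAPE_BILOBED = "bilobed"
SHAPE_CLUSTER = "cluster"
SHAPE_BILOBED_MEMBER = "bilobed_member"
SHAPE_CLUSTER_MEMBER = "cluster_member"


class SaturatedImageError(ValueError):
    """Every pixel is saturated; no threshold can be defined."""


@dataclass
class NucleusLabel:
    """One segmented nucleus: a disjoint pixel set with a shape class."""

    nucleus_id: int
    parent_object_id: int
    shape_class: str
    pixels: tuple[np.ndarray, np.ndarray]  # (ys, xs), absolute image coords
    centroid: tuple[float, float]
    area_px: int
    split_failed: bool = False

    @classmethod
    def from_pixels(
        cls,
        nucleus_id: int,
        parent_object_id: int,
        shape_class: str,
        ys: np.ndarray,
        xs: np.ndarray,
        split_failed: bool = False,
    ) -> "NucleusLabel":
        return cls(
            nucleus_id=nucleus_id,
            parent_object_id=parent_object_id,
            shape_class=shape_class,
            pixels=(ys, xs),
            centroid=(float(ys.mean()), float(xs.mean())),
            area_px=int(ys.size),
            split_failed=split_failed,
        )

    def mask_patch(self) -> tuple[np.ndarray, tuple[int, int]]:
        """Binary patch covering the nucleus plus its (y0, x0) offset."""
        ys, xs = self.pixels
        y0, x0 = int(ys.min()), int(xs.min())
        patch = np.zeros((int(ys.max()) - y0 + 1, int(xs.max()) - x0 + 1), dtype=bool)
        patch[ys - y0, xs - x0] = True
        return patch, (y0, x0)


def _object_patch(ys: np.ndarray, xs: np.ndarray, pad: int = 1):
    """Binary patch of an object with `pad` background pixels of margin."""
    y0, x0 = int(ys.min()) - pad, int(xs.min()) - pad
    patch = np.zeros(
        (int(ys.max()) - y0 + 1 + pad, int(xs.max()) - x0 + 1 + pad), dtype=bool
    )
    patch[ys - y0, xs - x0] = True
    return patch, y0, x0


def count_lobes(mask: np.ndarray, peak_h_frac: float = 0.20) -> tuple[int, np.ndarray]:
    """Count significant maxima of the Euclidean distance transform.

    A maximum counts as a separate lobe when it stands at least
    ``peak_h_frac * max(EDT)`` (but no less than 1 px) above the saddle
    connecting it to a higher maximum; this merges the spurious plateau
    maxima a discretised ridge produces.  Returns the lobe count and the
    labelled marker image (same shape as ``mask``).
    """
    edt = ndimage.distance_transform_edt(mask)
    peak = float(edt.max())
    if peak <= 0:
        return 0, np.zeros_like(mask, dtype=np.int32)
    # floor of 1.25 px suppresses the ~1 px quantisation bumps the integer
    # lattice produces along thin diagonal ridges
    h = max(1.25, peak_h_frac * peak)
    maxima = h_maxima(edt, h)
    markers, n = ndimage.label(maxima, structure=np.ones((3, 3), dtype=int))
    return int(n), markers.astype(np.int32)


def classify_shape(
    object_pixels: tuple[np.ndarray, np.ndarray], config: PipelineConfig | None = None
) -> str:
    """Classify an unsplit connected object by its silhouette.

    Rules, in order of precedence:

    1. one distance-transform lobe and circularity
       ``4*pi*A/P**2 >= c_spherical``              -> spherical
    2. ``solidity >= s_min`` and
       ``eccentricity >= e_min``                   -> elliptical
    3. exactly two lobes                           -> bilobed
    4. otherwise                                   -> cluster

    The lobe count gates the spherical class because a pair of strongly
    overlapping nuclei can exhibit high rasterised circularity; the
    eccentricity cutoff is set high enough (default 0.85) that an
    end-to-end overlapping pair (union eccentricity ~0.8) fails the
    ellipse test while genuinely elongated nuclei pass.
    """
    config = config or PipelineConfig()
    ys, xs = object_pixels
    if ys.size < config.min_area:
        raise ValueError(f"object of {ys.size} px is below min_area={config.min_area}")
    patch, _, _ = _object_patch(ys, xs)
    if min(patch.shape) <= 3:  # 1-px-wide ribbon after padding: degenerate
        warnings.warn("degenerate thin object classified as cluster", stacklevel=2)
        return SHAPE_CLUSTER
    props = measure.regionprops(patch.astype(np.uint8))[0]
    perimeter = props.perimeter
    if perimeter <= 0:
        warnings.warn("zero-perimeter object classified as cluster", stacklevel=2)
        return SHAPE_CLUSTER
    circularity = 4.0 * np.pi * props.area / perimeter**2
    n_lobes, _ = count_lobes(patch, config.peak_h_frac)
    if n_lobes <= 1 and circularity >= config.c_spherical:
        return SHAPE_SPHERICAL
    if props.solidity >= config.s_min and props.eccentricity >= config.e_min:
        return SHAPE_ELLIPTICAL
    if n_lobes == 2:
        return SHAPE_BILOBED
    return SHAPE_CLUSTER


def _assign_to_nearest(members: np.ndarray, parent: np.ndarray) -> np.ndarray:
    """Extend member labels to cover every parent pixel (nearest member wins)."""
    _, (iy, ix) = ndimage.distance_transform_edt(members == 0, return_indices=True)
    filled = members[iy, ix]
    filled[~parent] = 0
    return filled


def split_object(
    object_pixels: tuple[np.ndarray, np.ndarray],
    dapi: np.ndarray,
    config: PipelineConfig | None = None,
    expect: int | None = None,
    allow_watershed: bool = True,
) -> tuple[list[tuple[np.ndarray, np.ndarray]], bool]:
    """Split a bilobed/cluster object into member nuclei.

    The local threshold is raised in steps of ``split_step_frac`` times the
    object's intensity maximum, scanning the whole intensity range for the
    labelling that separates the object into the most component cores; if
    no threshold separates it, a watershed on the distance transform seeded
    at the lobe maxima is used.  Parent pixels not claimed by any core are
    assigned to the nearest member, so members partition the parent.

    Returns ``(members, split_failed)``; on total failure the parent comes
    back unsplit with ``split_failed=True``.  With ``expect=k`` the smallest
    surplus members are merged into their nearest neighbour until exactly
    ``k`` remain (used for bilobed objects, which must yield 2).
    """
    config = config or PipelineConfig()
    ys, xs = object_pixels
    patch, y0, x0 = _object_patch(ys, xs)
    # intensity patch aligned with `patch`
    inten = np.zeros(patch.shape, dtype=float)
    inten[ys - y0, xs - x0] = dapi[ys, xs].astype(float)

    local_max = float(inten.max())
    base = float(inten[patch].min())
    step = max(config.split_step_frac * local_max, 1.0)
    structure = np.ones((3, 3), dtype=int)
    # cores only need half the nucleus area: they are grown back to full
    # members afterwards, and cluster-member cores are small at high thresholds
    core_area = max(config.min_area // 2, 9)

    members_lab = None
    best_count = 1
    # cap the scan below the dome top: near the intensity maximum the
    # supra-threshold set is noise-dominated and can fragment spuriously
    t_cap = base + 0.8 * (local_max - base)
    t = base + step
    while t < t_cap:
        lab, n = ndimage.label(patch & (inten > t), structure=structure)
        if n >= 2:
            sizes = ndimage.sum_labels(np.ones_like(lab), lab, index=np.arange(1, n + 1))
            keep = np.flatnonzero(sizes >= core_area) + 1
            if keep.size > best_count:
                members_lab = np.where(np.isin(lab, keep), lab, 0)
                best_count = keep.size
        t += step

    if members_lab is None and not allow_watershed:
        return [(ys, xs)], True

    if members_lab is None:
        # homogeneous intensity: marker-controlled watershed on the EDT
        edt = ndimage.distance_transform_edt(patch)
        n_markers, markers = count_lobes(patch, config.peak_h_frac)
        if n_markers >= 2:
            ws = watershed(-edt, markers, mask=patch)
            sizes = ndimage.sum_labels(
                np.ones_like(ws), ws, index=np.arange(1, int(ws.max()) + 1)
            )
            keep = np.flatnonzero(sizes >= core_area) + 1
            if keep.size >= 2:
                members_lab = np.where(np.isin(ws, keep), ws, 0)

    if members_lab is None:
        return [(ys, xs)], True

    filled = _assign_to_nearest(members_lab, patch)
    labels = [int(v) for v in np.unique(filled) if v != 0]

    if expect is not None and len(labels) > expect:
        # merge smallest members into their nearest remaining neighbour
        while len(labels) > expect:
            sizes = {v: int((filled == v).sum()) for v in labels}
            smallest = min(labels, key=lambda v: (sizes[v], v))
            rest = np.where((filled > 0) & (filled != smallest), filled, 0)
            nearest = _assign_to_nearest(rest, patch)
            filled[filled == smallest] = nearest[filled == smallest]
            labels = [int(v) for v in np.unique(filled) if v != 0]

    members = []
    for v in labels:
        mys, mxs = np.nonzero(filled == v)
        members.append((mys + y0, mxs + x0))
    # deterministic member order: raster order of first pixel
    members.sort(key=lambda m: (int(m[0][0]), int(m[1][0])))
    return members, False


def segment_nuclei(
    dapi: np.ndarray, config: PipelineConfig | None = None
) -> list[NucleusLabel]:
    """Segment the DAPI channel into individual nuclei.

    Returns nuclei with disjoint pixel sets, classified and (for bilobed and
    cluster objects) split into members.  Objects below ``min_area`` are
    discarded as debris; ids are assigned in raster order of the centroid so
    repeated runs are identical.
    """
    config = config or PipelineConfig()
    dapi = np.asarray(dapi)
    if dapi.ndim != 2:
        raise ValueError(f"dapi must be 2-D, got shape {dapi.shape}")
    if dapi.size == 0:
        return []
    lo, hi = int(dapi.min()), int(dapi.max())
    if lo == hi:
        if hi >= 65535:
            raise SaturatedImageError("image is uniformly saturated; threshold undefined")
        return []  # constant background: nothing to segment
    thr = config.dapi_threshold if config.dapi_threshold is not None else float(
        threshold_otsu(dapi)
    )
    binary = dapi > thr
    lab, n_obj = ndimage.label(binary, structure=np.ones((3, 3), dtype=int))
    if n_obj == 0:
        return []

    nuclei: list[NucleusLabel] = []
    for region in measure.regionprops(lab):
        if region.area < config.min_area:
            continue
        ys, xs = np.nonzero(lab[region.slice] == region.label)
        ys = ys + region.slice[0].start
        xs = xs + region.slice[1].start
        parent_id = int(region.label)
        shape_class = classify_shape((ys, xs), config)
        if shape_class == SHAPE_SPHERICAL and region.area > config.max_area:
            shape_class = SHAPE_CLUSTER  # oversized blob: treat as unresolved cluster
        if shape_class in (SHAPE_SPHERICAL, SHAPE_ELLIPTICAL):
            # silhouette says single nucleus, but strongly overlapping pairs
            # can mimic an ellipse: trust the intensity cores when the
            # re-threshold scan finds more than one
            members, failed = split_object(
                (ys, xs), dapi, config, allow_watershed=False
            )
            if failed or len(members) == 1:
                nuclei.append(
                    NucleusLabel.from_pixels(-1, parent_id, shape_class, ys, xs)
                )
                continue
            member_class = (
                SHAPE_BILOBED_MEMBER if len(members) == 2 else SHAPE_CLUSTER_MEMBER
            )
            for mys, mxs in members:
                if mys.size < config.min_area:
                    continue
                nuclei.append(
                    NucleusLabel.from_pixels(-1, parent_id, member_class, mys, mxs)
                )
            continue
        expect = 2 if shape_class == SHAPE_BILOBED else None
        members, failed = split_object((ys, xs), dapi, config, expect=expect)
        if failed:
            nuclei.append(
                NucleusLabel.from_pixels(
                    -1, parent_id, shape_class, ys, xs, split_failed=True
                )
            )
            continue
        member_class = (
            SHAPE_BILOBED_MEMBER if shape_class == SHAPE_BILOBED else SHAPE_CLUSTER_MEMBER
        )
        for mys, mxs in members:
            if mys.size < config.min_area:
                continue
            nuclei.append(NucleusLabel.from_pixels(-1, parent_id, member_class, mys, mxs))

    nuclei.sort(key=lambda nl: (nl.centroid[0], nl.centroid[1]))
    for i, nl in enumerate(nuclei):
        nl.nucleus_id = i
    return nuclei


def nuclei_to_frame(nuclei: list[NucleusLabel]):
    import pandas as pd

    return pd.DataFrame(
        [
            {
                "nucleus_id": nl.nucleus_id,
                "parent_object_id": nl.parent_object_id,
                "shape_class": nl.shape_class,
                "centroid_y": nl.centroid[0],
                "centroid_x": nl.centroid[1],
                "area_px": nl.area_px,
                "split_failed": nl.split_failed,
            }
            for nl in nuclei
        ],
        columns=[
            "nucleus_id",
            "parent_object_id",
            "shape_class",
            "centroid_y",
            "centroid_x",
            "area_px",
            "split_failed",
        ],
    )
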