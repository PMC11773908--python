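"""Summary quantities: densities, TSPO+ fractions, phenotype combination
tables, and neuron-ROI fractions."""

from __future__ import annotations

import itertools
from typing import Callable

import numpy as np
import pandas as pd

from .config import PipelineConfig
from .io import MultiplexImage, RoiSpec
from .phenotyping import cells_to_frame, extract_cells
from .segmentation import segment_nuclei

__all__ = [
    "density_per_100k",
    "density_per_mm2",
    "tspo_fraction",
    "phenotype_table",
    "neuron_roi_fractions",
    "PHENOTYPE_MARKERS",
]

PHENOTYPE_MARKERS = ("CD74", "CD163", "MRP14", "Arg1")


def density_per_100k(count: int, area_px: int) -> float:
    """Cell density per 100,000 pixels: ``count / area_px * 1e5``."""
    if area_px <= 0:
        raise ValueError("area_px must be positive")
    if count < 0:
        raise ValueError("count must be non-negative")
    return count / area_px * 1e5


def density_per_mm2(count: int, area_px: int, pixel_size_um: float = 0.325) -> float:
    """Convenience conversion of the same density to cells per mm^2."""
    if pixel_size_um <= 0:
        raise ValueError("pixel_size_um must be positive")
    area_mm2 = area_px * (pixel_size_um / 1000.0) ** 2
    if area_mm2 <= 0:
        raise ValueError("area must be positive")
    return count / area_mm2


def tspo_fraction(
    cells: pd.DataFrame,
    subset: Callable[[pd.DataFrame], pd.Series] | pd.Series | None = None,
    tspo_col: str = "tspo_pos",
) -> float:
    """Fraction of cells (optionally a predicate-selected subset) that are TSPO+.

    Raises on an empty subset rather than returning 0: an empty denominator
    is a design problem, not a zero rate.
    """
    if subset is None:
        sel = cells
    else:
        mask = subset(cells) if callable(subset) else subset
        sel = cells[np.asarray(mask, dtype=bool)]
    if len(sel) == 0:
        raise ValueError("subset is empty; TSPO fraction undefined")
    return float(sel[tspo_col].sum() / len(sel))


def phenotype_table(
    cells: pd.DataFrame, markers: tuple[str, ...] = PHENOTYPE_MARKERS
) -> pd.DataFrame:
    """Counts and TSPO+ percentages for all marker combinations.

    Considers Iba1+ cells only and enumerates all ``2**len(markers)``
    status combinations (zero rows included).  Adds two aggregate rows
    (``subset`` = "any_marker" / "no_marker"): cells expressing at least
    one phenotype marker, and cells expressing none; combination rows have
    an empty ``subset``.  ``pct_tspo_pos`` is NaN where ``n_cells`` is 0.
    """
    cols = [f"{m.lower()}_pos" for m in markers]
    missing = [c for c in cols + ["iba1_pos", "tspo_pos"] if c not in cells.columns]
    if missing:
        raise KeyError(f"cell table lacks required columns: {missing}")
    iba1 = cells[cells["iba1_pos"].astype(bool)]
    rows = []
    for combo in itertools.product([True, False], repeat=len(markers)):
        sel = np.ones(len(iba1), dtype=bool)
        for c, state in zip(cols, combo):
            sel &= iba1[c].astype(bool).to_numpy() == state
        n = int(sel.sum())
        n_tspo = int(iba1.loc[sel, "tspo_pos"].astype(bool).sum())
        row = {m: combo[i] for i, m in enumerate(markers)}
        row.update(
            {
                "n_cells": n,
                "n_tspo_pos": n_tspo,
                "pct_tspo_pos": 100.0 * n_tspo / n if n else np.nan,
            }
        )
        rows.append(row)
    table = pd.DataFrame(rows)

    any_marker = iba1[cols].astype(bool).any(axis=1).to_numpy()
    for label, sel in (("any_marker", any_marker), ("no_marker", ~any_marker)):
        n = int(sel.sum())
        n_tspo = int(iba1.loc[sel, "tspo_pos"].astype(bool).sum())
        agg = {m: pd.NA for m in markers}
        agg.update(
            {
                "n_cells": n,
                "n_tspo_pos": n_tspo,
                "pct_tspo_pos": 100.0 * n_tspo / n if n else np.nan,
            }
        )
        table = pd.concat(
            [table, pd.DataFrame([{**agg, "subset": label}])], ignore_index=True
        )
    table["subset"] = table["subset"].fillna("")
    return table


def neuron_roi_fractions(
    image: MultiplexImage,
    rois: list[RoiSpec],
    config: PipelineConfig,
    markers: tuple[str, ...] = ("TSPO", "GLS2", "PVA"),
) -> pd.DataFrame:
    """Per-ROI fractions of NeuN+ neurons expressing TSPO (and GLS2/PVA).

    Neurons are nuclei whose cell mask (grown over contiguous NeuN signal,
    same rule as the Iba1 mask) is NeuN-positive.  ROIs without any neuron
    are flagged (``flagged=True``) so downstream weighting can exclude
    them.  This automates a count performed manually in the original
    workflow; a manually counted CSV with the same columns is accepted by
    the model fit as a drop-in.
    """
    for roi in rois:
        roi.validate_within(image)
    if "NeuN" not in image.channels:
        raise KeyError("image lacks a NeuN channel")
    records = []
    for roi in rois:
        sub_channels = {
            name: np.ascontiguousarray(arr[roi.slices])
            for name, arr in image.channels.items()
        }
        sub = MultiplexImage(channels=sub_channels, pixel_size_um=image.pixel_size_um)
        cells, _ = extract_cells(
            sub, config, markers=("NeuN",) + markers, iba1_channel="NeuN"
        )
        frame = cells_to_frame(cells, markers=("NeuN",) + markers)
        # the mask-growing channel was NeuN, so iba1_pos is NeuN positivity
        neurons = frame[frame["neun_pos"].astype(bool)]
        n_neurons = len(neurons)
        n_tspo = int(neurons["tspo_pos"].sum()) if n_neurons else 0
        records.append(
            {
                "roi_id": roi.roi_id,
                "side": roi.side,
                "n_neurons": n_neurons,
                "n_tspo_pos": n_tspo,
                "fraction": n_tspo / n_neurons if n_neurons else np.nan,
                "n_gls2_pos": int(neurons["gls2_pos"].sum()) if n_neurons else 0,
                "n_pva_pos": int(neurons["pva_pos"].sum()) if n_neurons else 0,
                "flagged": n_neurons == 0,
            }
        )
    return pd.DataFrame(records)
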