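"""Synthetic multiplex tissue: images and tables with known ground truth.

The image generator renders DAPI nuclei of four silhouette classes
(spherical, elliptical, bilobed pairs, irregular clusters of >= 3), gives a
configurable subset of nuclei an Iba1 cytoplasmic annulus contiguous with
the nucleus, renders each marker channel bright over a cell's mask iff that
cell's true state is positive, and degrades everything with blur, Poisson
shot noise and additive Gaussian read noise.  Detached Iba1 "debris" blobs
with no nucleus exercise the fragment-exclusion rule.

The tabular generators emulate the statistical structure of the lesion-age
and neuron-ROI analyses: Gaussian animal- and lesion-level random effects on
the fraction scale, a categorical month profile with a persistent drop at a
changepoint month (default -12.8 percentage points at month 5), a binary
treatment indicator, and binomial counting noise.

All outputs are pure functions of (params, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage

from .io import MultiplexImage

__all__ = [
    "ImageSimParams",
    "GroundTruth",
    "LesionSimParams",
    "generate_multiplex_image",
    "generate_lesion_dataset",
    "generate_neuron_rois",
    "PackingError",
]

# channels always present in a generated image
ALL_CHANNELS = (
    "DAPI",
    "Iba1",
    "TSPO",
    "CD74",
    "CD163",
    "MRP14",
    "Arg1",
    "NeuN",
    "GLS2",
    "PVA",
)

IBA1_MARKERS = ("TSPO", "CD74", "CD163", "MRP14", "Arg1")


class PackingError(ValueError):
    """Requested objects cannot be placed at the configured density."""


@dataclass
class ImageSimParams:
    """Parameters of the multiplex image generator.

    Marker frequencies default to the microglial co-expression profile
    measured in healthy primate cortex (TSPO in roughly three-quarters of
    Iba1+ cells, Arg1 the commonest phenotype marker, MRP14 nearly absent).
    Intensities are 16-bit camera counts.
    """

    shape: tuple[int, int] = (512, 512)
    n_spherical: int = 40
    n_elliptical: int = 12
    n_bilobed: int = 8  # pairs
    n_cluster: int = 4
    cluster_k: int = 3
    radius_range: tuple[float, float] = (5.0, 8.0)
    ellipse_ratio_range: tuple[float, float] = (2.2, 2.8)
    bilobed_sep_frac: float = 1.6  # centre separation as multiple of radius
    iba1_fraction: float = 0.6
    annulus_thickness: int = 4
    marker_freqs: dict[str, float] = field(
        default_factory=lambda: {
            "TSPO": 0.765,
            "CD74": 0.112,
            "CD163": 0.017,
            "MRP14": 0.0005,
            "Arg1": 0.221,
        }
    )
    n_neurons: int = 0
    neuron_gls2_freq: float = 0.6
    neuron_pva_freq: float = 0.2
    neuron_tspo_given_gls2: float = 0.407
    neuron_tspo_baseline: float = 0.05
    n_debris: int = 4
    debris_radius_range: tuple[float, float] = (3.0, 5.0)
    fg_mean: float = 20000.0
    bg_mean: float = 500.0
    blur_sigma: float = 1.0
    gaussian_noise_sd: float = 150.0
    poisson_noise: bool = True
    max_pack_frac: float = 0.35
    r_px: int = 15  # kept clear around debris so fragments stay detached

    def __post_init__(self) -> None:
        for name, f in {**self.marker_freqs,
                        "iba1_fraction": self.iba1_fraction,
                        "neuron_gls2_freq": self.neuron_gls2_freq,
                        "neuron_pva_freq": self.neuron_pva_freq,
                        "neuron_tspo_given_gls2": self.neuron_tspo_given_gls2,
                        "neuron_tspo_baseline": self.neuron_tspo_baseline}.items():
            if not 0.0 <= f <= 1.0:
                raise ValueError(f"frequency {name}={f} outside [0, 1]")
        for name in ("n_spherical", "n_elliptical", "n_bilobed", "n_cluster",
                     "n_neurons", "n_debris"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.cluster_k < 3:
            raise ValueError("cluster_k must be >= 3")
        if self.fg_mean <= self.bg_mean:
            raise ValueError("fg_mean must exceed bg_mean")

    @property
    def midpoint_threshold(self) -> float:
        """Default positivity threshold: midpoint of background and foreground."""
        return 0.5 * (self.fg_mean + self.bg_mean)

    def default_thresholds(self) -> dict[str, float]:
        return {name: self.midpoint_threshold for name in ALL_CHANNELS}


@dataclass
class GroundTruth:
    """Everything the generator knows about a rendered image."""

    nuclei: pd.DataFrame  # nucleus_id, group_id, shape_class, centroid_y/x, area_px
    nucleus_pixels: list[tuple[np.ndarray, np.ndarray]]
    cells: pd.DataFrame  # cell_id, nucleus_id, role, iba1 + marker/neuron states
    cell_pixels: list[tuple[np.ndarray, np.ndarray]]
    marker_counts: dict[str, int]  # positives among true Iba1+ cells

    @property
    def n_nuclei(self) -> int:
        return len(self.nuclei)


# ---------------------------------------------------------------- rendering

_PROFILE_K = np.log(4.0)  # dome profile: 25% of peak at the boundary


def _render_soft_ellipse(canvas, cy, cx, a, b, theta, peak, blend="add"):
    """Add a flat-topped dome blob (``exp(-k u^4)`` radial profile, so the
    thresholded silhouette tracks the true boundary); returns its true
    pixel set (``u <= 1``).

    ``blend="max"`` composes overlapping blobs by maximum rather than sum
    (overlapping nuclei do not double their chromatin signal), keeping the
    silhouette waist between overlapping nuclei visible.
    """
    ext = int(np.ceil(max(a, b) * 1.4)) + 1
    y0, y1 = max(int(cy) - ext, 0), min(int(cy) + ext + 1, canvas.shape[0])
    x0, x1 = max(int(cx) - ext, 0), min(int(cx) + ext + 1, canvas.shape[1])
    yy, xx = np.mgrid[y0:y1, x0:x1]
    dy, dx = yy - cy, xx - cx
    ct, st = np.cos(theta), np.sin(theta)
    u = np.sqrt(((dx * ct + dy * st) / a) ** 2 + ((-dx * st + dy * ct) / b) ** 2)
    inside = u <= 1.4
    contrib = peak * np.exp(-_PROFILE_K * u[inside] ** 4)
    view = canvas[y0:y1, x0:x1]
    if blend == "max":
        view[inside] = np.maximum(view[inside], contrib)
    else:
        view[inside] += contrib
    tys, txs = np.nonzero(u <= 1.0)
    return tys + y0, txs + x0


def _footprint(kind: str, radius: float, params: ImageSimParams) -> float:
    if kind == "elliptical":
        return radius * np.sqrt(params.ellipse_ratio_range[1])
    if kind == "bilobed":
        return radius * (1.0 + params.bilobed_sep_frac / 2.0)
    if kind == "cluster":
        return radius * 1.8
    return radius


def generate_multiplex_image(
    params: ImageSimParams, seed: int | None = None
) -> tuple[MultiplexImage, GroundTruth]:
    """Render a synthetic multiplex image and its ground truth.

    Raises :class:`PackingError` when the requested objects exceed the
    configured packing density or cannot be placed by rejection sampling.
    """
    rng = np.random.default_rng(seed)
    h, w = params.shape
    rmin, rmax = params.radius_range

    # ------------------------------------------------ plan objects
    kinds = (
        ["spherical"] * params.n_spherical
        + ["elliptical"] * params.n_elliptical
        + ["bilobed"] * params.n_bilobed
        + ["cluster"] * params.n_cluster
        + ["neuron"] * params.n_neurons
        + ["debris"] * params.n_debris
    )
    radii = []
    for kind in kinds:
        if kind == "debris":
            radii.append(rng.uniform(*params.debris_radius_range))
        else:
            radii.append(rng.uniform(rmin, rmax))
    margin = params.annulus_thickness + 3
    exts = [
        _footprint(k if k != "neuron" else "spherical", r, params) + margin
        for k, r in zip(kinds, radii)
    ]
    if sum((2 * e) ** 2 for e in exts) > params.max_pack_frac * h * w:
        raise PackingError(
            f"{len(kinds)} objects exceed max packing fraction {params.max_pack_frac}"
        )

    centres: list[tuple[float, float]] = []
    placed_ext: list[float] = []
    placed_kind: list[str] = []
    for kind, ext in zip(kinds, exts):
        ok = False
        for _ in range(5000):
            cy = rng.uniform(ext, h - ext)
            cx = rng.uniform(ext, w - ext)
            ok = True
            for (py, px), pe, pk in zip(centres, placed_ext, placed_kind):
                sep = ext + pe + 2
                if kind == "debris" or pk == "debris":
                    sep += params.r_px  # debris must stay unreachable from cells
                if (cy - py) ** 2 + (cx - px) ** 2 < sep**2:
                    ok = False
                    break
            if ok:
                break
        if not ok:
            raise PackingError("rejection sampling failed; lower object counts")
        centres.append((cy, cx))
        placed_ext.append(ext)
        placed_kind.append(kind)

    # ------------------------------------------------ render nuclei (DAPI)
    canvases = {name: np.zeros((h, w), dtype=float) for name in ALL_CHANNELS}
    dapi = canvases["DAPI"]

    nuc_rows = []
    nucleus_pixels: list[tuple[np.ndarray, np.ndarray]] = []
    nucleus_group: list[int] = []
    nucleus_role: list[str] = []  # "cell" (candidate Iba1) or "neuron"
    debris_specs: list[tuple[float, float, float]] = []

    def add_nucleus(group_id, shape_class, role, cy, cx, a, b, theta):
        tys, txs = _render_soft_ellipse(
            dapi, cy, cx, a, b, theta, params.fg_mean, blend="max"
        )
        nuc_rows.append(
            {
                "group_id": group_id,
                "shape_class": shape_class,
                "centroid_y": float(tys.mean()),
                "centroid_x": float(txs.mean()),
                "area_px": int(tys.size),
            }
        )
        nucleus_pixels.append((tys, txs))
        nucleus_group.append(group_id)
        nucleus_role.append(role)

    group_id = 0
    for kind, radius, (cy, cx) in zip(kinds, radii, centres):
        if kind == "debris":
            debris_specs.append((cy, cx, radius))
            continue
        theta = rng.uniform(0, np.pi)
        if kind in ("spherical", "neuron"):
            role = "neuron" if kind == "neuron" else "cell"
            add_nucleus(group_id, "spherical", role, cy, cx, radius, radius, theta)
        elif kind == "elliptical":
            q = rng.uniform(*params.ellipse_ratio_range)
            a, b = radius * np.sqrt(q), radius / np.sqrt(q)
            add_nucleus(group_id, "elliptical", "cell", cy, cx, a, b, theta)
        elif kind == "bilobed":
            d = params.bilobed_sep_frac * radius / 2.0
            for s in (-1.0, 1.0):
                add_nucleus(
                    group_id,
                    "bilobed_member",
                    "cell",
                    cy + s * d * np.sin(theta),
                    cx + s * d * np.cos(theta),
                    radius,
                    radius,
                    theta,
                )
        elif kind == "cluster":
            r_mem = radius * 0.9
            ring = 0.80 * radius
            phase = rng.uniform(0, 2 * np.pi)
            for j in range(params.cluster_k):
                ang = phase + 2 * np.pi * j / params.cluster_k
                add_nucleus(
                    group_id,
                    "cluster_member",
                    "cell",
                    cy + ring * np.sin(ang),
                    cx + ring * np.cos(ang),
                    r_mem,
                    r_mem,
                    theta,
                )
        group_id += 1

    n_nuc = len(nucleus_pixels)

    # de-overlap true nucleus pixel sets (members of a pair/cluster overlap):
    # each shared pixel goes to the nearest nucleus centre, lower id on ties
    owner = np.full((h, w), -1, dtype=np.int32)
    best = np.full((h, w), np.inf)
    for i, (tys, txs) in enumerate(nucleus_pixels):
        cy, cx = nuc_rows[i]["centroid_y"], nuc_rows[i]["centroid_x"]
        d2 = (tys - cy) ** 2 + (txs - cx) ** 2
        closer = d2 < best[tys, txs]
        owner[tys[closer], txs[closer]] = i
        best[tys[closer], txs[closer]] = d2[closer]
    for i in range(n_nuc):
        tys, txs = nucleus_pixels[i]
        keep = owner[tys, txs] == i
        nucleus_pixels[i] = (tys[keep], txs[keep])
        nuc_rows[i]["area_px"] = int(keep.sum())
        nuc_rows[i]["centroid_y"] = float(tys[keep].mean())
        nuc_rows[i]["centroid_x"] = float(txs[keep].mean())

    # ------------------------------------------------ true cell masks
    # mask = nucleus + annulus of configured thickness touching the boundary;
    # contested cytoplasm goes to the nearest nucleus (as in the pipeline)
    nuc_label = np.zeros((h, w), dtype=np.int32)
    for i, (tys, txs) in enumerate(nucleus_pixels):
        nuc_label[tys, txs] = i + 1
    dist, (iy, ix) = ndimage.distance_transform_edt(nuc_label == 0, return_indices=True)
    nearest = nuc_label[iy, ix]  # nearest nucleus id + 1, everywhere
    cytoplasm = (dist > 0) & (dist <= params.annulus_thickness)
    cell_pixels: list[tuple[np.ndarray, np.ndarray]] = []
    for i in range(n_nuc):
        ann = cytoplasm & (nearest == i + 1)
        ays, axs = np.nonzero(ann)
        tys, txs = nucleus_pixels[i]
        cell_pixels.append(
            (np.concatenate([tys, ays]), np.concatenate([txs, axs]))
        )

    # ------------------------------------------------ cell states
    is_neuron = np.array([r == "neuron" for r in nucleus_role])
    iba1_state = np.zeros(n_nuc, dtype=bool)
    iba1_state[~is_neuron] = rng.random((~is_neuron).sum()) < params.iba1_fraction

    marker_state = {m: np.zeros(n_nuc, dtype=bool) for m in IBA1_MARKERS}
    for m in IBA1_MARKERS:
        draws = rng.random(n_nuc)
        marker_state[m] = iba1_state & (draws < params.marker_freqs[m])

    gls2 = np.zeros(n_nuc, dtype=bool)
    pva = np.zeros(n_nuc, dtype=bool)
    neuron_tspo = np.zeros(n_nuc, dtype=bool)
    idx_neu = np.flatnonzero(is_neuron)
    if idx_neu.size:
        gls2[idx_neu] = rng.random(idx_neu.size) < params.neuron_gls2_freq
        pva[idx_neu] = rng.random(idx_neu.size) < params.neuron_pva_freq
        draws = rng.random(idx_neu.size)
        for k, i in enumerate(idx_neu):
            if gls2[i]:
                neuron_tspo[i] = draws[k] < params.neuron_tspo_given_gls2
            elif pva[i]:
                neuron_tspo[i] = False  # TSPO absent from PVA+ GLS2- interneurons
            else:
                neuron_tspo[i] = draws[k] < params.neuron_tspo_baseline

    # ------------------------------------------------ render cytoplasm/markers
    for i in range(n_nuc):
        if iba1_state[i]:
            ays, axs = cell_pixels[i]
            canvases["Iba1"][ays, axs] += params.fg_mean
            for m in IBA1_MARKERS:
                if marker_state[m][i]:
                    canvases[m][ays, axs] += params.fg_mean
        if is_neuron[i]:
            ays, axs = cell_pixels[i]
            canvases["NeuN"][ays, axs] += params.fg_mean
            if gls2[i]:
                canvases["GLS2"][ays, axs] += params.fg_mean
            if pva[i]:
                canvases["PVA"][ays, axs] += params.fg_mean
            if neuron_tspo[i]:
                canvases["TSPO"][ays, axs] += params.fg_mean

    for cy, cx, radius in debris_specs:
        _render_soft_ellipse(
            canvases["Iba1"], cy, cx, radius, radius, 0.0, params.fg_mean
        )

    # ------------------------------------------------ degrade and digitise
    channels = {}
    for name in ALL_CHANNELS:
        img = canvases[name] + params.bg_mean
        if params.blur_sigma > 0:
            img = ndimage.gaussian_filter(img, params.blur_sigma)
        if params.poisson_noise:
            img = rng.poisson(np.clip(img, 0, None)).astype(float)
        if params.gaussian_noise_sd > 0:
            img = img + rng.normal(0.0, params.gaussian_noise_sd, size=img.shape)
        channels[name] = np.clip(np.rint(img), 0, 65535).astype(np.uint16)

    image = MultiplexImage(channels=channels)

    # ------------------------------------------------ package truth
    nuclei_df = pd.DataFrame(nuc_rows)
    nuclei_df.insert(0, "nucleus_id", np.arange(n_nuc))
    cells_rows = []
    for i in range(n_nuc):
        row = {
            "cell_id": i,
            "nucleus_id": i,
            "role": nucleus_role[i],
            "iba1": bool(iba1_state[i]),
        }
        for m in IBA1_MARKERS:
            row[m.lower()] = bool(marker_state[m][i])
        row["neun"] = bool(is_neuron[i])
        row["gls2"] = bool(gls2[i])
        row["pva"] = bool(pva[i])
        row["neuron_tspo"] = bool(neuron_tspo[i])
        cells_rows.append(row)
    cells_df = pd.DataFrame(cells_rows)
    marker_counts = {m: int(marker_state[m].sum()) for m in IBA1_MARKERS}
    marker_counts["Iba1"] = int(iba1_state.sum())

    truth = GroundTruth(
        nuclei=nuclei_df,
        nucleus_pixels=nucleus_pixels,
        cells=cells_df,
        cell_pixels=cell_pixels,
        marker_counts=marker_counts,
    )
    return image, truth


# ---------------------------------------------------------------- tables


@dataclass
class LesionSimParams:
    """Design of the simulated lesion-age dataset.

    The month profile is flat at baseline ``mu`` until ``changepoint_month``,
    then drops by ``delta`` (default -12.8 percentage points) for all later
    months, so the successive-difference-from-cumulative-average contrast at
    the changepoint month equals ``delta`` exactly.  The treated-animal
    indicator is carried in the design (last two animals by default, as in a
    six-animal cohort with two steroid-treated members) with a zero default
    effect.
    """

    n_animals: int = 6
    lesions_per_animal: int = 8
    month_levels: tuple[int, ...] = (1, 2, 3, 4, 5, 6, 7, 8)
    mu: float = 0.88
    changepoint_month: int = 5
    delta: float = -0.128
    month_effects: dict[int, float] | None = None
    beta_treat: float = 0.0
    treated_animals: tuple[int, ...] | None = None
    sigma_animal: float = 0.03
    sigma_lesion: float = 0.02
    n_cells: int = 1000

    def __post_init__(self) -> None:
        if self.n_animals < 2:
            raise ValueError("need >= 2 animals")
        if len(self.month_levels) < 2:
            raise ValueError("need >= 2 month levels")
        if self.sigma_animal < 0 or self.sigma_lesion < 0:
            raise ValueError("random-effect SDs must be >= 0")
        if self.n_cells < 1:
            raise ValueError("n_cells must be >= 1")
        if self.lesions_per_animal < 1:
            raise ValueError("lesions_per_animal must be >= 1")

    def resolved_month_effects(self) -> dict[int, float]:
        if self.month_effects is not None:
            return dict(self.month_effects)
        return {
            m: (self.delta if m >= self.changepoint_month else 0.0)
            for m in self.month_levels
        }

    def resolved_treated(self) -> tuple[int, ...]:
        if self.treated_animals is not None:
            return tuple(self.treated_animals)
        if self.n_animals >= 3:
            return (self.n_animals - 1, self.n_animals)  # 1-based animal ids
        return ()


def generate_lesion_dataset(
    params: LesionSimParams, seed: int | None = None
) -> tuple[pd.DataFrame, dict]:
    """Simulate one lesion table.

    Per lesion the latent fraction is
    ``clamp(mu + beta_month + beta_T * treated + a_i + b_ij, 0, 1)`` with
    Gaussian animal and lesion effects, observed through
    ``Binomial(n_cells)/n_cells``.  Months cycle through the level set
    within each animal so the design is balanced.  Returns the table and a
    truth dict (true month means, effects, clamp count).
    """
    rng = np.random.default_rng(seed)
    effects = params.resolved_month_effects()
    treated = set(params.resolved_treated())
    rows = []
    n_clamped = 0
    levels = list(params.month_levels)
    for animal in range(1, params.n_animals + 1):
        a_i = rng.normal(0.0, params.sigma_animal) if params.sigma_animal > 0 else 0.0
        is_treated = animal in treated
        for j in range(params.lesions_per_animal):
            month = levels[j % len(levels)]
            b_ij = (
                rng.normal(0.0, params.sigma_lesion)
                if params.sigma_lesion > 0
                else 0.0
            )
            p = (
                params.mu
                + effects[month]
                + (params.beta_treat if is_treated else 0.0)
                + a_i
                + b_ij
            )
            p_clamped = min(max(p, 0.0), 1.0)
            if p_clamped != p:
                n_clamped += 1
            frac = rng.binomial(params.n_cells, p_clamped) / params.n_cells
            rows.append(
                {
                    "animal_id": animal,
                    "lesion_id": f"A{animal}L{j + 1}",
                    "month": month,
                    "treated": is_treated,
                    "fraction": frac,
                    "n_cells": params.n_cells,
                }
            )
    df = pd.DataFrame(rows)
    truth = {
        "mu": params.mu,
        "month_effects": effects,
        "month_means": {m: params.mu + effects[m] for m in levels},
        "beta_treat": params.beta_treat,
        "treated_animals": sorted(treated),
        "sigma_animal": params.sigma_animal,
        "sigma_lesion": params.sigma_lesion,
        "n_clamped": n_clamped,
    }
    return df, truth


def generate_neuron_rois(
    n_animals_control: int = 1,
    n_animals_eae: int = 5,
    rois_per_side: int = 2,
    p_control: float = 0.006,
    p_eae: float = 0.121,
    sigma_animal: float = 0.05,
    cells_per_roi: int = 150,
    seed: int | None = None,
) -> pd.DataFrame:
    """Simulate the neuron-ROI counting design.

    One control and five EAE animals by default, with left/right cortical
    ROIs, Gaussian animal effects on the fraction scale, and per-ROI TSPO+
    counts drawn ``Binomial(cells_per_roi, clamp(p_group + a_i, 0, 1))``.
    Group means default to the healthy/EAE cortical values (0.6% and 12.1%).
    """
    if not (0.0 <= p_control <= 1.0 and 0.0 <= p_eae <= 1.0):
        raise ValueError("group probabilities must lie in [0, 1]")
    if n_animals_control < 1 or n_animals_eae < 1:
        raise ValueError("need >= 1 animal per group")
    if sigma_animal < 0:
        raise ValueError("sigma_animal must be >= 0")
    rng = np.random.default_rng(seed)
    rows = []
    animal = 0
    for group, n_group, p_group in (
        ("control", n_animals_control, p_control),
        ("EAE", n_animals_eae, p_eae),
    ):
        for _ in range(n_group):
            animal += 1
            a_i = rng.normal(0.0, sigma_animal) if sigma_animal > 0 else 0.0
            p_i = min(max(p_group + a_i, 0.0), 1.0)
            for side in ("left", "right"):
                for k in range(rois_per_side):
                    n_pos = int(rng.binomial(cells_per_roi, p_i))
                    rows.append(
                        {
                            "animal_id": animal,
                            "group": group,
                            "side": side,
                            "roi_id": f"A{animal}{side[0].upper()}{k + 1}",
                            "n_neurons": cells_per_roi,
                            "n_tspo_pos": n_pos,
                            "fraction": n_pos / cells_per_roi,
                        }
                    )
    return pd.DataFrame(rows)
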