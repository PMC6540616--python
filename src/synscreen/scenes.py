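"""Synthetic multi-channel microscopy scenes with exact ground truth.

Three scene kinds mirror the three imaging assays quantified by
:mod:`synscreen.quant`:

* :func:`make_hek_scene` — a HEK-cell co-clustering field: cell-fill blobs,
  liprin puncta inside them, and V5 reporter channels whose true
  inside/outside-puncta mean-intensity ratio equals the requested
  recruitment ratio exactly (before noise).
* :func:`make_coculture_scene` — a neuron/COS coculture field: one COS cell
  blob (inducer), axon ribbons (Tau), dendrite ribbons (MAP2), and synapsin
  puncta placed by a Poisson process at one density on the axon–COS contact
  region (away from dendrites) and another elsewhere on axons.
* :func:`make_field_scene` — a low-magnification field: Tau and MAP2 masks
  with prescribed area fractions and a known number of disjoint nuclei.

Shapes are deliberately minimal — blobs, ribbons and disks — chosen so that
every ROI the measures need is nonempty and analytically known.  Puncta get
Gaussian-blurred edges (sigma = radius/3) so thresholding behaves as on real
images; channels that must carry exact ratios or masks stay piecewise
constant.  Noise is additive Gaussian truncated at zero; a linear background
gradient can be added to exercise rolling-ball subtraction.  Every scene
records the masks, ratios, densities and counts it was built from in
``ground_truth``, sufficient to compute each downstream measure analytically.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import yaml
from scipy import ndimage

from .errors import PlacementError
from .quant import Mask, dilate_mask

__all__ = [
    "Scene",
    "HekSceneSpec",
    "CocultureSceneSpec",
    "FieldSceneSpec",
    "make_hek_scene",
    "make_coculture_scene",
    "make_field_scene",
    "save_scene",
    "load_scene",
]


@dataclass
class Scene:
    """A multi-channel 2-D image with a channel-role map and optional
    generation ground truth."""

    channels: dict[str, np.ndarray]
    pixel_size_um: float = 0.2
    ground_truth: dict | None = None

    def __post_init__(self) -> None:
        shapes = {ch.shape for ch in self.channels.values()}
        if len(shapes) > 1:
            raise ValueError(f"channels must share a shape, got {shapes}")
        for name, ch in self.channels.items():
            if np.any(ch < 0):
                raise ValueError(f"channel {name!r} has negative intensities")

    @property
    def shape(self) -> tuple[int, int]:
        return next(iter(self.channels.values())).shape


# ---------------------------------------------------------------------------
# geometry helpers

def _disk(shape: tuple[int, int], cy: float, cx: float, r: float) -> np.ndarray:
    yy, xx = np.ogrid[: shape[0], : shape[1]]
    return (yy - cy) ** 2 + (xx - cx) ** 2 <= r**2


def _place_disks(
    shape: tuple[int, int],
    n: int,
    radius: float,
    rng: np.random.Generator,
    allowed: np.ndarray | None = None,
    max_tries: int = 2000,
    what: str = "disks",
) -> tuple[np.ndarray, list[tuple[float, float]]]:
    """Place ``n`` non-overlapping disks, fully inside the frame and, if
    given, with centers inside ``allowed``; raises PlacementError when the
    retry budget runs out."""
    mask = np.zeros(shape, dtype=bool)
    centers: list[tuple[float, float]] = []
    eligible = None
    if allowed is not None:
        # centers whose whole disk fits inside `allowed`
        eligible = np.flatnonzero(ndimage.distance_transform_edt(allowed) > radius)
        if n > 0 and eligible.size == 0:
            raise PlacementError(f"no room for {what} of radius {radius}")
    tries = 0
    while len(centers) < n:
        if tries >= max_tries:
            raise PlacementError(
                f"could not place {n} {what} (radius {radius}) after {max_tries} tries"
            )
        tries += 1
        if eligible is None:
            cy = rng.uniform(radius, shape[0] - 1 - radius)
            cx = rng.uniform(radius, shape[1] - 1 - radius)
        else:
            cy, cx = np.unravel_index(rng.choice(eligible), shape)
        d = _disk(shape, cy, cx, radius)
        if (mask & d).any():
            continue
        mask |= d
        centers.append((float(cy), float(cx)))
    return mask, centers


def _ribbons(
    shape: tuple[int, int],
    n: int,
    width: float,
    rng: np.random.Generator,
    step: float = 2.0,
    wiggle: float = 0.25,
) -> np.ndarray:
    """Random-walk ribbons crossing the frame: each starts on a border,
    heads inward, and meanders until it leaves the frame."""
    mask = np.zeros(shape, dtype=bool)
    h, w = shape
    max_steps = 4 * (h + w)
    for _ in range(n):
        side = rng.integers(4)
        if side == 0:
            y, x, heading = 0.0, rng.uniform(0, w - 1), np.pi / 2
        elif side == 1:
            y, x, heading = float(h - 1), rng.uniform(0, w - 1), -np.pi / 2
        elif side == 2:
            y, x, heading = rng.uniform(0, h - 1), 0.0, 0.0
        else:
            y, x, heading = rng.uniform(0, h - 1), float(w - 1), np.pi
        for _ in range(max_steps):
            mask |= _disk(shape, y, x, width / 2.0)
            heading += rng.normal(0.0, wiggle)
            x += step * np.cos(heading)
            y += step * np.sin(heading)
            if not (0 <= y < h and 0 <= x < w):
                break
    return mask


def _finish(img: np.ndarray, noise_sd: float, rng: np.random.Generator) -> np.ndarray:
    if noise_sd > 0:
        img = img + rng.normal(0.0, noise_sd, size=img.shape)
    return np.maximum(img, 0.0)


def _background(shape: tuple[int, int], level: float, gradient: float) -> np.ndarray:
    xx = np.linspace(0.0, 1.0, shape[1])
    return level + gradient * np.broadcast_to(xx, shape)


# ---------------------------------------------------------------------------
# HEK co-clustering scene

@dataclass(frozen=True)
class HekSceneSpec:
    """HEK co-clustering scene: cells containing liprin puncta, with the V5
    reporter recruited into the puncta at a known mean-intensity ratio.

    ``recruitment_ratio`` is the true V5 mean inside the puncta divided by
    the mean over the rest of the cell, before noise; ``noise_sd`` is in
    the same intensity units as ``v5_base`` (so 5% noise means
    ``noise_sd = 0.05 * v5_base``).  ``background_level`` and
    ``background_gradient`` apply to the fill and liprin channels (the
    channels that get thresholded/background-subtracted); the V5 channels
    carry only signal and noise so their ground-truth ratio stays exact.
    """

    image_shape: tuple[int, int] = (256, 256)
    n_cells: int = 3
    cell_radius_px: float = 38.0
    clusters_per_cell: int = 6
    cluster_radius_px: float = 4.0
    recruitment_ratio: float = 2.0
    v5_base: float = 50.0
    v5_surface_fraction: float = 0.6
    liprin_intensity: float = 150.0
    cell_fill_intensity: float = 120.0
    background_level: float = 10.0
    background_gradient: float = 0.0
    noise_sd: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.recruitment_ratio < 0:
            raise ValueError("recruitment_ratio must be >= 0")
        if self.cluster_radius_px < 1:
            raise ValueError("cluster_radius_px must be >= 1")
        if self.n_cells < 0 or self.clusters_per_cell < 0:
            raise ValueError("counts must be >= 0")


def make_hek_scene(spec: HekSceneSpec) -> Scene:
    """Build a HEK co-clustering scene; see :class:`HekSceneSpec`."""
    rng = np.random.default_rng(spec.seed)
    shape = spec.image_shape
    cell_mask, cell_centers = _place_disks(
        shape, spec.n_cells, spec.cell_radius_px, rng, what="cells"
    )
    # puncta centers must keep the whole punctum inside its cell
    inner = np.zeros(shape, dtype=bool)
    for cy, cx in cell_centers:
        inner |= _disk(shape, cy, cx, spec.cell_radius_px - spec.cluster_radius_px - 1)
    cluster_mask = np.zeros(shape, dtype=bool)
    if spec.n_cells > 0 and spec.clusters_per_cell > 0:
        cluster_mask, _ = _place_disks(
            shape,
            spec.n_cells * spec.clusters_per_cell,
            spec.cluster_radius_px,
            rng,
            allowed=inner,
            what="clusters",
        )

    bg = _background(shape, spec.background_level, spec.background_gradient)
    blur = spec.cluster_radius_px / 3.0
    cfp = spec.cell_fill_intensity * cell_mask + bg
    liprin = ndimage.gaussian_filter(spec.liprin_intensity * cluster_mask.astype(float), blur) + bg
    # piecewise-constant V5: base inside the cell, base*ratio inside puncta,
    # so the true inside/outside mean ratio equals recruitment_ratio exactly
    v5 = spec.v5_base * cell_mask.astype(float)
    v5[cluster_mask] = spec.v5_base * spec.recruitment_ratio
    v5_surface = spec.v5_surface_fraction * v5

    channels = {
        "cfp_fill": _finish(cfp, spec.noise_sd, rng),
        "liprin": _finish(liprin, spec.noise_sd, rng),
        "v5_total": _finish(v5, spec.noise_sd, rng),
        "v5_surface": _finish(v5_surface, spec.noise_sd, rng),
    }
    gt = {
        "cell_mask": cell_mask,
        "cluster_mask": cluster_mask,
        "recruitment_ratio": spec.recruitment_ratio,
        "n_cells": spec.n_cells,
        "cell_centers": cell_centers,
    }
    return Scene(channels=channels, ground_truth=gt)


# ---------------------------------------------------------------------------
# coculture scene

@dataclass(frozen=True)
class CocultureSceneSpec:
    """Neuron/COS coculture scene.

    Synapsin puncta are placed by Poisson sampling at
    ``synapsin_density_on_contact`` (puncta per pixel) on the contact
    region — COS ∧ axon ∧ ¬(MAP2 dilated by ``map2_exclusion_px``) — and at
    ``synapsin_density_off_contact`` elsewhere on axons.  Punctum centers
    are kept far enough from the region boundary that no punctum straddles
    it, so the on/off densities are exact by construction.
    """

    image_shape: tuple[int, int] = (256, 256)
    cos_radius_px: float = 70.0
    n_axons: int = 6
    axon_width_px: float = 3.0
    n_dendrites: int = 3
    dendrite_width_px: float = 7.0
    map2_exclusion_px: float = 5.0
    synapsin_density_on_contact: float = 0.02
    synapsin_density_off_contact: float = 0.002
    puncta_radius_px: float = 2.0
    puncta_intensity: float = 180.0
    diffuse_synapsin: float = 15.0
    tau_intensity: float = 90.0
    map2_intensity: float = 110.0
    inducer_intensity: float = 100.0
    v5_level: float = 80.0
    noise_sd: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.synapsin_density_on_contact < 0 or self.synapsin_density_off_contact < 0:
            raise ValueError("puncta densities must be >= 0")


def _sample_puncta_centers(
    region: np.ndarray,
    density: float,
    rng: np.random.Generator,
    exclude: np.ndarray | None = None,
    margin: float = 4.0,
) -> np.ndarray:
    """Poisson(density * area(region)) punctum centers inside ``region``.

    Centers are kept at least ``margin`` pixels away from ``exclude`` (the
    complementary puncta region) so a punctum never straddles the
    on-contact/off-contact boundary and the two densities stay exact by
    construction.  The count is drawn from the full region area; only the
    placement is restricted.
    """
    area = int(region.sum())
    if area == 0 or density == 0:
        return np.empty((0, 2), dtype=int)
    n = rng.poisson(density * area)
    if n == 0:
        return np.empty((0, 2), dtype=int)
    eligible = region
    if exclude is not None and exclude.any():
        eligible = region & (ndimage.distance_transform_edt(~exclude) > margin)
    idx = np.flatnonzero(eligible)
    if idx.size == 0:
        return np.empty((0, 2), dtype=int)
    chosen = rng.choice(idx, size=n, replace=True)
    return np.stack(np.unravel_index(chosen, region.shape), axis=1)


def make_coculture_scene(spec: CocultureSceneSpec) -> Scene:
    """Build a coculture scene; see :class:`CocultureSceneSpec`."""
    rng = np.random.default_rng(spec.seed)
    shape = spec.image_shape
    h, w = shape
    cos_mask = _disk(shape, h / 2.0, w / 2.0, spec.cos_radius_px)
    axon_mask = _ribbons(shape, spec.n_axons, spec.axon_width_px, rng)
    map2_mask = _ribbons(shape, spec.n_dendrites, spec.dendrite_width_px, rng)

    dendrite_free = ~dilate_mask(Mask(map2_mask), spec.map2_exclusion_px).pixels
    contact = cos_mask & axon_mask & dendrite_free
    off_contact = axon_mask & ~contact

    margin = spec.puncta_radius_px + 2.0
    centers_on = _sample_puncta_centers(
        contact, spec.synapsin_density_on_contact, rng,
        exclude=off_contact, margin=margin,
    )
    centers_off = _sample_puncta_centers(
        off_contact, spec.synapsin_density_off_contact, rng,
        exclude=contact, margin=margin,
    )
    puncta = np.zeros(shape, dtype=float)
    for cy, cx in np.concatenate([centers_on, centers_off]):
        puncta[_disk(shape, cy, cx, spec.puncta_radius_px)] = spec.puncta_intensity
    puncta = ndimage.gaussian_filter(puncta, spec.puncta_radius_px / 3.0)

    channels = {
        "synapsin": _finish(puncta + spec.diffuse_synapsin * axon_mask, spec.noise_sd, rng),
        "tau": _finish(spec.tau_intensity * axon_mask.astype(float), spec.noise_sd, rng),
        "map2": _finish(spec.map2_intensity * map2_mask.astype(float), spec.noise_sd, rng),
        "inducer": _finish(spec.inducer_intensity * cos_mask.astype(float), spec.noise_sd, rng),
        "v5_surface": _finish(spec.v5_level * cos_mask.astype(float), spec.noise_sd, rng),
    }
    gt = {
        "cos_mask": cos_mask,
        "axon_mask": axon_mask,
        "map2_mask": map2_mask,
        "contact_mask": contact,
        "off_contact_mask": off_contact,
        "density_on_contact": spec.synapsin_density_on_contact,
        "density_off_contact": spec.synapsin_density_off_contact,
        "n_puncta_on": len(centers_on),
        "n_puncta_off": len(centers_off),
        "puncta_radius_px": spec.puncta_radius_px,
    }
    return Scene(channels=channels, ground_truth=gt)


# ---------------------------------------------------------------------------
# low-magnification field scene

@dataclass(frozen=True)
class FieldSceneSpec:
    """Low-magnification field: Tau/MAP2 masks with prescribed area
    fractions (thresholded smooth random fields) and disjoint nuclei."""

    image_shape: tuple[int, int] = (256, 256)
    n_nuclei: int = 20
    nucleus_radius_px: float = 6.0
    tau_area_fraction: float = 0.2
    map2_area_fraction: float = 0.3
    tau_intensity: float = 100.0
    map2_intensity: float = 100.0
    dapi_intensity: float = 150.0
    correlation_px: float = 8.0
    noise_sd: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        for f in (self.tau_area_fraction, self.map2_area_fraction):
            if not 0.0 <= f <= 1.0:
                raise ValueError("area fractions must be in [0, 1]")
        if self.n_nuclei < 0:
            raise ValueError("n_nuclei must be >= 0")


def _fraction_mask(
    shape: tuple[int, int], fraction: float, corr: float, rng: np.random.Generator
) -> np.ndarray:
    """Smooth random field thresholded at a quantile so the foreground area
    fraction matches ``fraction`` to within pixel rounding."""
    if fraction == 0.0:
        return np.zeros(shape, dtype=bool)
    if fraction == 1.0:
        return np.ones(shape, dtype=bool)
    fld = ndimage.gaussian_filter(rng.standard_normal(shape), corr)
    return fld >= np.quantile(fld, 1.0 - fraction)


def make_field_scene(spec: FieldSceneSpec) -> Scene:
    """Build a field-morphology scene; see :class:`FieldSceneSpec`."""
    rng = np.random.default_rng(spec.seed)
    shape = spec.image_shape
    tau_mask = _fraction_mask(shape, spec.tau_area_fraction, spec.correlation_px, rng)
    map2_mask = _fraction_mask(shape, spec.map2_area_fraction, spec.correlation_px, rng)
    nuclei_mask, _ = _place_disks(
        shape, spec.n_nuclei, spec.nucleus_radius_px, rng, what="nuclei"
    )
    channels = {
        "tau": _finish(spec.tau_intensity * tau_mask.astype(float), spec.noise_sd, rng),
        "map2": _finish(spec.map2_intensity * map2_mask.astype(float), spec.noise_sd, rng),
        "dapi": _finish(spec.dapi_intensity * nuclei_mask.astype(float), spec.noise_sd, rng),
    }
    gt = {
        "tau_mask": tau_mask,
        "map2_mask": map2_mask,
        "nuclei_mask": nuclei_mask,
        "n_nuclei": spec.n_nuclei,
        "tau_area_fraction": spec.tau_area_fraction,
        "map2_area_fraction": spec.map2_area_fraction,
    }
    return Scene(channels=channels, ground_truth=gt)


# ---------------------------------------------------------------------------
# scene I/O: TIFF stack + channel-role map + ground-truth side files

def save_scene(scene: Scene, prefix: str) -> None:
    """Write ``{prefix}.tif`` (float32 channel stack), ``{prefix}.channels.yaml``
    (channel-role map + pixel size), and, when ground truth is present,
    ``{prefix}.ground_truth.json``-style YAML for scalars plus a
    ``{prefix}.masks.tif`` uint8 stack for mask arrays."""
    import tifffile

    names = sorted(scene.channels)
    stack = np.stack([scene.channels[n].astype(np.float32) for n in names])
    tifffile.imwrite(f"{prefix}.tif", stack)
    meta: dict = {"channels": names, "pixel_size_um": scene.pixel_size_um}
    if scene.ground_truth is not None:
        scalars, mask_names, masks = {}, [], []
        for key, val in scene.ground_truth.items():
            if isinstance(val, np.ndarray) and val.ndim == 2:
                mask_names.append(key)
                masks.append(val.astype(np.uint8))
            elif isinstance(val, (int, float, str, bool, np.integer, np.floating)):
                scalars[key] = val.item() if isinstance(val, np.generic) else val
        meta["ground_truth"] = scalars
        meta["ground_truth_masks"] = mask_names
        if masks:
            tifffile.imwrite(f"{prefix}.masks.tif", np.stack(masks))
    with open(f"{prefix}.channels.yaml", "w") as fh:
        yaml.safe_dump(meta, fh)


def load_scene(prefix: str) -> Scene:
    """Round-trip counterpart of :func:`save_scene`."""
    import tifffile

    with open(f"{prefix}.channels.yaml") as fh:
        meta = yaml.safe_load(fh)
    stack = tifffile.imread(f"{prefix}.tif")
    channels = {name: stack[i].astype(float) for i, name in enumerate(meta["channels"])}
    gt = None
    if "ground_truth" in meta:
        gt = dict(meta["ground_truth"])
        mask_names = meta.get("ground_truth_masks", [])
        if mask_names:
            masks = tifffile.imread(f"{prefix}.masks.tif")
            if masks.ndim == 2:
                masks = masks[None]
            for i, name in enumerate(mask_names):
                gt[name] = masks[i].astype(bool)
    return Scene(channels=channels, pixel_size_um=meta["pixel_size_um"], ground_truth=gt)
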