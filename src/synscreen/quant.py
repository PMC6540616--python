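"""Fluorescence-image quantification: ROI algebra and recruitment measures.

These are the image-analysis procedures behind three assays:

* **HEK co-clustering** — liprin-α2 forms puncta in transfected HEK cells;
  the extent to which V5-PTPσ is recruited into those puncta is measured as
  the mean V5 intensity inside (cell ∧ liprin-puncta) divided by the mean
  over the remaining cell area.  The liprin channel is first background-
  subtracted with a rolling ball (radius 14 px); the V5 channels are never
  thresholded.
* **Neuron/COS coculture** — presynaptic differentiation induced at sites
  where axons contact an inducer-expressing COS cell is measured as
  punctate synapsin per unit contact area.  The contact ROI is
  (COS ∧ axon) minus the MAP2 dendrite mask dilated by 5 px, which removes
  native, dendrite-associated synapses from the measure.
* **Low-magnification morphology** — Tau/MAP2 areas per field normalized
  to the DAPI nucleus count.

ROIs are plain boolean masks with set algebra, Euclidean-disk dilation and
inversion — the mask operations the measures are defined in terms of.
Thresholds are explicit inputs (they were chosen manually per image in the
original workflow); :func:`auto_threshold` offers an Otsu criterion as a
labelled convenience for synthetic data.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage.filters import threshold_otsu

from .errors import MaskShapeError, UndefinedRatioError

__all__ = [
    "Mask",
    "RecruitmentResult",
    "CocultureMeasures",
    "MorphologyMeasures",
    "threshold_mask",
    "auto_threshold",
    "dilate_mask",
    "invert_mask",
    "combine_masks",
    "rolling_ball_subtract",
    "coclustering_ratio",
    "coculture_contact_measures",
    "match_surface_expression",
    "normalize_to_control",
    "morphology_measures",
]


@dataclass(frozen=True)
class Mask:
    """A binary 2-D region of interest supporting set algebra."""

    pixels: np.ndarray

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels, dtype=bool)
        if px.ndim != 2:
            raise ValueError("Mask requires a 2-D boolean array")
        object.__setattr__(self, "pixels", px)

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape

    @property
    def area(self) -> int:
        return int(self.pixels.sum())

    def _check(self, other: "Mask") -> None:
        if self.shape != other.shape:
            raise MaskShapeError(f"mask shapes differ: {self.shape} vs {other.shape}")

    def __and__(self, other: "Mask") -> "Mask":
        self._check(other)
        return Mask(self.pixels & other.pixels)

    def __or__(self, other: "Mask") -> "Mask":
        self._check(other)
        return Mask(self.pixels | other.pixels)

    def __sub__(self, other: "Mask") -> "Mask":
        self._check(other)
        return Mask(self.pixels & ~other.pixels)

    def __invert__(self) -> "Mask":
        return Mask(~self.pixels)

    def __eq__(self, other) -> bool:
        return isinstance(other, Mask) and self.shape == other.shape and bool(
            np.array_equal(self.pixels, other.pixels)
        )


def threshold_mask(image: np.ndarray, threshold: float) -> Mask:
    """Lower-inclusive intensity threshold: pixel in ⇔ intensity >= threshold."""
    if threshold < 0:
        raise ValueError("threshold must be >= 0")
    return Mask(np.asarray(image) >= threshold)


def auto_threshold(image: np.ndarray) -> float:
    """Otsu between-class-variance threshold.

    Convenience for synthetic scenes; the measures themselves take explicit
    thresholds, mirroring the per-image manual choice of the original
    workflow.
    """
    return float(threshold_otsu(np.asarray(image, dtype=float)))


def _disk_offsets(radius: float) -> np.ndarray:
    r = int(np.floor(radius))
    dy, dx = np.mgrid[-r : r + 1, -r : r + 1]
    return (dy**2 + dx**2) <= radius**2


def dilate_mask(mask: Mask, radius_px: float = 5.0) -> Mask:
    """Euclidean-disk dilation: pixel in ⇔ distance to the mask <= radius.

    Radius 0 is the identity.  Computed from the exact Euclidean distance
    transform of the complement, so the result is the true disk dilation
    rather than an iterated-structuring-element approximation.
    """
    if radius_px < 0:
        raise ValueError("radius_px must be >= 0")
    if radius_px == 0 or not mask.pixels.any():
        return Mask(mask.pixels.copy())
    dist = ndimage.distance_transform_edt(~mask.pixels)
    return Mask(dist <= radius_px)


def invert_mask(mask: Mask) -> Mask:
    return ~mask


def combine_masks(a: Mask, b: Mask, op: str) -> Mask:
    """Pixelwise set algebra: op in {"and", "or", "minus"}."""
    if op == "and":
        return a & b
    if op == "or":
        return a | b
    if op == "minus":
        return a - b
    raise ValueError(f"unknown mask op {op!r}")


# ---------------------------------------------------------------------------
# rolling-ball background subtraction

def _ball_structure(radius_px: int) -> tuple[np.ndarray, np.ndarray]:
    """Footprint and height profile of a spherical-cap structuring element."""
    r = int(radius_px)
    dy, dx = np.mgrid[-r : r + 1, -r : r + 1]
    d2 = dy**2 + dx**2
    footprint = d2 <= r**2
    heights = np.zeros_like(d2, dtype=float)
    heights[footprint] = np.sqrt(float(r) ** 2 - d2[footprint])
    return footprint, heights


def rolling_ball_subtract(image: np.ndarray, radius_px: int = 14) -> np.ndarray:
    """Rolling-ball background subtraction.

    The background is the grayscale morphological opening of the image with
    a ball (spherical-cap) structuring element of the given radius — the
    surface traced by the apex of a ball rolled under the intensity
    landscape.  The opening cannot follow features narrower than the ball,
    so puncta-scale peaks survive subtraction while smooth background is
    removed.  Output = input − background, floored at 0; output <= input
    everywhere.  Borders are handled by edge replication.
    """
    image = np.asarray(image, dtype=float)
    if image.ndim != 2:
        raise ValueError("rolling_ball_subtract expects a 2-D image")
    if radius_px < 1:
        raise ValueError("radius_px must be >= 1")
    if 2 * radius_px + 1 > min(image.shape):
        raise ValueError(
            f"ball diameter {2 * radius_px + 1} exceeds image extent {min(image.shape)}"
        )
    footprint, heights = _ball_structure(radius_px)
    eroded = ndimage.grey_erosion(
        image, footprint=footprint, structure=heights, mode="nearest"
    )
    background = ndimage.grey_dilation(
        eroded, footprint=footprint, structure=heights, mode="nearest"
    )
    # anti-extensivity holds analytically; clip guards float round-off only
    background = np.minimum(background, image)
    return image - background


# ---------------------------------------------------------------------------
# recruitment / co-clustering

@dataclass
class RecruitmentResult:
    """An intensity-ratio measure with the ROI areas that produced it."""

    value: float
    roi_in_area: int
    roi_out_area: int
    normalized_value: float | None = None


def coclustering_ratio(v5: np.ndarray, liprin_mask: Mask, cell_mask: Mask) -> RecruitmentResult:
    """Mean V5 intensity inside (cell ∧ puncta) over mean inside (cell ∧ ¬puncta).

    The reporter channel is used raw (never thresholded); ratio 1 means no
    recruitment into the puncta, >1 co-clustering, <1 exclusion.
    """
    v5 = np.asarray(v5, dtype=float)
    if v5.shape != cell_mask.shape or v5.shape != liprin_mask.shape:
        raise MaskShapeError("v5 image and masks must share a shape")
    roi_in = cell_mask & liprin_mask
    roi_out = cell_mask - liprin_mask
    if roi_in.area == 0 or roi_out.area == 0:
        raise UndefinedRatioError(
            f"empty ROI (inside={roi_in.area}, outside={roi_out.area} px)"
        )
    mean_in = float(v5[roi_in.pixels].mean())
    mean_out = float(v5[roi_out.pixels].mean())
    if mean_out == 0:
        raise UndefinedRatioError("outside-puncta mean intensity is zero")
    return RecruitmentResult(
        value=mean_in / mean_out, roi_in_area=roi_in.area, roi_out_area=roi_out.area
    )


# ---------------------------------------------------------------------------
# coculture contact measures

@dataclass
class CocultureMeasures:
    """Per-cell coculture quantification.

    ``synapsin_per_contact_area`` is the default punctate-area measure
    (thresholded synapsin pixels in the contact ROI per contact-ROI pixel);
    the integrated-intensity variant is kept alongside.  Values are ``None``
    (absent, not zero) when the contact ROI is empty.
    """

    synapsin_per_contact_area: float | None
    synapsin_intensity_per_contact_area: float | None
    synapsin_per_cos_area: float | None
    contact_area: int
    cos_area: int
    inducer_surface_intensity: float | None


def _size_filter(mask: np.ndarray, min_px: int, max_px: int | None) -> np.ndarray:
    if min_px <= 1 and max_px is None:
        return mask
    labels, n = ndimage.label(mask)
    if n == 0:
        return mask
    sizes = ndimage.sum_labels(np.ones_like(labels), labels, index=np.arange(1, n + 1))
    keep = sizes >= min_px
    if max_px is not None:
        keep &= sizes <= max_px
    keep_ids = np.flatnonzero(keep) + 1
    return np.isin(labels, keep_ids)


def coculture_contact_measures(
    channels: Mapping[str, np.ndarray],
    thresholds: Mapping[str, float],
    map2_dilate_px: float = 5.0,
    min_punctum_px: int = 1,
    max_punctum_px: int | None = None,
) -> CocultureMeasures:
    """Quantify induced presynaptic differentiation for one COS cell.

    ROIs:
        contact = COS ∧ axon(Tau) ∧ ¬dilate(MAP2, 5 px)
        cos     = COS ∧ ¬dilate(MAP2, 5 px)

    The MAP2 dilation-and-inversion removes dendrites plus a 5-px margin
    where spine-associated native synapses could sit.  Synapsin is
    thresholded high enough to keep only punctate signal (threshold via
    ``thresholds["synapsin"]``, optional punctum size filter), then
    integrated over the ROI and divided by ROI area.
    """
    required = {"synapsin", "tau", "map2", "inducer"}
    missing = required - set(channels)
    if missing:
        raise ValueError(f"missing channels: {sorted(missing)}")
    cos_mask = threshold_mask(channels["inducer"], thresholds["inducer"])
    if cos_mask.area == 0:
        raise UndefinedRatioError("COS (inducer) mask is empty")
    tau_mask = threshold_mask(channels["tau"], thresholds["tau"])
    map2_mask = threshold_mask(channels["map2"], thresholds["map2"])
    dendrite_free = ~dilate_mask(map2_mask, map2_dilate_px)
    contact = cos_mask & tau_mask & dendrite_free
    cos_roi = cos_mask & dendrite_free

    puncta = threshold_mask(channels["synapsin"], thresholds["synapsin"]).pixels
    puncta = _size_filter(puncta, min_punctum_px, max_punctum_px)
    syn = np.asarray(channels["synapsin"], dtype=float)

    def _per_area(roi: Mask) -> tuple[float | None, float | None]:
        if roi.area == 0:
            return None, None
        punct_in = puncta & roi.pixels
        return (
            float(punct_in.sum()) / roi.area,
            float(syn[punct_in].sum()) / roi.area,
        )

    area_contact, intens_contact = _per_area(contact)
    area_cos, _ = _per_area(cos_roi)
    inducer_mean = (
        float(np.asarray(channels["inducer"], dtype=float)[cos_roi.pixels].mean())
        if cos_roi.area > 0
        else None
    )
    return CocultureMeasures(
        synapsin_per_contact_area=area_contact,
        synapsin_intensity_per_contact_area=intens_contact,
        synapsin_per_cos_area=area_cos,
        contact_area=contact.area,
        cos_area=cos_roi.area,
        inducer_surface_intensity=inducer_mean,
    )


# ---------------------------------------------------------------------------
# cohort-level helpers

def match_surface_expression(
    cells: pd.DataFrame,
    reference_group: str,
    band: tuple[float, float] = (10.0, 90.0),
    level_col: str = "v5_level",
    group_col: str = "group",
) -> pd.DataFrame:
    """Keep cells whose surface-reporter level falls inside the reference band.

    Matches surface expression across conditions before downstream
    measures: a cell is kept iff its level lies within the
    [p_lo, p_hi] percentile band (default 10th–90th) of the
    ``reference_group`` cells.  Returns a copy with ``kept`` and ``reason``
    columns; exclusions are reported, never dropped silently.
    """
    ref = cells.loc[cells[group_col] == reference_group, level_col]
    if len(ref) == 0:
        raise ValueError(f"reference group {reference_group!r} is empty")
    lo, hi = np.percentile(ref.to_numpy(dtype=float), band)
    out = cells.copy()
    levels = out[level_col].to_numpy(dtype=float)
    kept = (levels >= lo) & (levels <= hi)
    out["kept"] = kept
    out["reason"] = np.where(
        kept, "", np.where(levels < lo, f"below p{band[0]:g}={lo:g}", f"above p{band[1]:g}={hi:g}")
    )
    return out


def normalize_to_control(
    values: pd.DataFrame,
    control_condition: str,
    value_col: str = "value",
    culture_col: str = "culture",
    condition_col: str = "condition",
) -> pd.DataFrame:
    """Per-culture normalization to the control condition's mean.

    Each value is divided by the mean of the control-condition values from
    the same culture, so the control group's normalized mean is 1 within
    every culture by construction.  Cultures missing the control condition
    are flagged (``normalized`` left NaN), not dropped.
    """
    out = values.copy()
    out["normalized"] = np.nan
    out["control_missing"] = False
    for culture, grp in out.groupby(culture_col, sort=False):
        ctrl = grp.loc[grp[condition_col] == control_condition, value_col]
        if len(ctrl) == 0:
            out.loc[grp.index, "control_missing"] = True
            continue
        out.loc[grp.index, "normalized"] = grp[value_col] / ctrl.mean()
    return out


# ---------------------------------------------------------------------------
# field morphology

@dataclass
class MorphologyMeasures:
    """Per-field axon/dendrite morphology summary."""

    n_nuclei: int
    tau_area: int
    map2_area: int
    tau_area_per_nucleus: float | None
    map2_area_per_nucleus: float | None
    tau_map2_ratio: float | None


def count_nuclei(dapi: np.ndarray, threshold: float, min_area_px: int = 30) -> int:
    """Nuclei as connected components of the thresholded DAPI mask above a
    minimum size (suppresses noise specks)."""
    mask = threshold_mask(dapi, threshold).pixels
    labels, n = ndimage.label(mask)
    if n == 0:
        return 0
    sizes = ndimage.sum_labels(np.ones_like(labels), labels, index=np.arange(1, n + 1))
    return int((sizes >= min_area_px).sum())


def morphology_measures(
    channels: Mapping[str, np.ndarray],
    thresholds: Mapping[str, float],
    min_nucleus_area_px: int = 30,
) -> MorphologyMeasures:
    """Tau/MAP2 area per nucleus and the Tau:MAP2 area ratio for one field.

    Per-nucleus measures are undefined (``None``) at zero nuclei; the ratio
    is undefined at zero MAP2 area and 0 when only Tau is absent.
    """
    n_nuclei = count_nuclei(channels["dapi"], thresholds["dapi"], min_nucleus_area_px)
    tau_area = threshold_mask(channels["tau"], thresholds["tau"]).area
    map2_area = threshold_mask(channels["map2"], thresholds["map2"]).area
    return MorphologyMeasures(
        n_nuclei=n_nuclei,
        tau_area=tau_area,
        map2_area=map2_area,
        tau_area_per_nucleus=tau_area / n_nuclei if n_nuclei else None,
        map2_area_per_nucleus=map2_area / n_nuclei if n_nuclei else None,
        tau_map2_ratio=tau_area / map2_area if map2_area else None,
    )
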