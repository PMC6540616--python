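"""Interaction scoring for the split-DHFR protein-complementation assay.

Pipeline, per experiment (plate):

1.  Estimate the plate blank from dedicated blank wells (first hour of
    reads), subtract it, and log2-transform each well.
2.  QC: flag wells with abrupt OD drops (reader/condensation artifacts);
    flags are reported and excluded downstream, never silently applied.
3.  Fit an ordinary least-squares slope to each well over the log-linear
    range, the points whose log2(OD600) lies in [-3, -2] (an alternative
    [-3, -2.2] window is selectable).
4.  For each MTX well, divide its slope by the mean slope of the same
    strain's DMSO wells from the same experiment (``ratio_x``).
5.  Normalize against on-plate controls:

        score = (ratio_x - ratio_NC) / (ratio_PC - ratio_NC)

    so 1 means growth equivalent to the positive control (two wild-type
    interacting fusions) and 0 means growth equivalent to the negative
    control (one fusion replaced by an inert protein).
6.  Pool per-well scores across experiments per strain; report mean +/- SEM.

Raw scores are kept unclipped; clipping to [0, 1] and the 5-bin palette are
display transforms applied only when rendering heatmaps.
"""

from __future__ import annotations

import bisect
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import (
    ControlsDegenerateError,
    EmptySeriesError,
    InsufficientWindowError,
    RatioUndefinedError,
)
from .growth import (
    MEDIA_DMSO,
    MEDIA_MTX,
    ROLE_BLANK,
    ROLE_NEGATIVE_CONTROL,
    ROLE_POSITIVE_CONTROL,
    GrowthCurve,
)

__all__ = [
    "ScoreConfig",
    "SlopeEstimate",
    "InteractionScore",
    "SpecificityCall",
    "HEATMAP_BINS",
    "estimate_blank",
    "blank_and_log",
    "qc_wells",
    "fit_linear_slope",
    "mtx_dmso_ratio",
    "interaction_score",
    "clip_score",
    "aggregate_scores",
    "classify_specificity",
    "bin_for_heatmap",
    "score_plate",
    "score_experiments",
]


@dataclass(frozen=True)
class ScoreConfig:
    """Tunable parameters of the scoring pipeline.

    ``window`` is the log2-OD fit range; the study used (-3, -2) with a
    (-3, -2.2) variant in one experiment.  ``nc_strain``/``pc_strain`` pick
    which control strains anchor 0 and 1 when a plate carries several;
    ``None`` means the first strain with the matching role, which for the
    negative side corresponds to the prey-replaced control the heatmap's 0
    is anchored to.
    """

    window: tuple[float, float] = (-3.0, -2.0)
    min_points: int = 3
    drop_threshold: float = 0.2
    degeneracy_tol: float = 1e-6
    nc_strain: str | None = None
    pc_strain: str | None = None

    def __post_init__(self) -> None:
        if not self.window[0] < self.window[1]:
            raise ValueError("window must satisfy lo < hi")
        if self.min_points < 2:
            raise ValueError("min_points must be >= 2")
        if not 0.0 < self.drop_threshold < 1.0:
            raise ValueError("drop_threshold must be in (0, 1)")


@dataclass
class SlopeEstimate:
    """OLS slope of one well's blanked log2 growth curve in the fit window."""

    well_id: str
    slope: float
    window_lo: float
    window_hi: float
    n_points: int
    fit_residual: float  # RMS residual, log2-OD units


@dataclass
class InteractionScore:
    """Per-strain interaction score with its ratio components.

    ``per_replicate_scores`` holds one score per unflagged MTX well pooled
    across experiments; ``mean``/``sem`` summarize them (SEM is the sample
    SD over sqrt(n), undefined for n = 1).  ``ratio_x``, ``ratio_nc`` and
    ``ratio_pc`` are the across-experiment means of the respective MTX/DMSO
    slope ratios, kept for audit.
    """

    strain_id: str
    ratio_x: float
    ratio_nc: float
    ratio_pc: float
    score: float
    score_clipped: float
    per_replicate_scores: np.ndarray
    mean: float
    sem: float | None


@dataclass
class SpecificityCall:
    """Nonspecific-disruption call for one mutant across its ligand panel.

    A mutant that loses most of its interactions likely mis-folds or fails
    to express rather than losing one binding site; the screen calls a
    mutant nonspecific when at least ``min_ligands`` ligands score strictly
    below ``threshold``.
    """

    mutant_id: str
    ligand_scores: dict[str, float]
    nonspecific: bool
    threshold: float = 0.3
    min_ligands: int = 3


# ---------------------------------------------------------------------------
# blanking / transform

def estimate_blank(curves: Sequence[GrowthCurve], first_hours: float = 1.0) -> float:
    """Plate blank: mean of blank-well readings within the first hour.

    Falls back to the minimum reading across the plate when no blank wells
    are present.
    """
    vals = []
    for c in curves:
        if c.role == ROLE_BLANK:
            sel = c.times_h <= c.times_h[0] + first_hours
            vals.append(c.od600[sel])
    if vals:
        return float(np.mean(np.concatenate(vals)))
    return float(min(c.od600.min() for c in curves))


def blank_and_log(
    curve: GrowthCurve, blank: float
) -> tuple[np.ndarray, np.ndarray]:
    """Blank-subtract and log2-transform one well.

    Points at or below the blank have no defined log and are dropped;
    returns (times_h, log2_od) over the surviving points.
    """
    if blank < 0:
        raise ValueError("blank must be >= 0")
    keep = curve.od600 > blank
    if not np.any(keep):
        raise EmptySeriesError(
            f"well {curve.well_id}: no readings above blank {blank:g}"
        )
    return curve.times_h[keep], np.log2(curve.od600[keep] - blank)


# ---------------------------------------------------------------------------
# QC

def qc_wells(
    curves: Sequence[GrowthCurve], drop_threshold: float = 0.2
) -> pd.DataFrame:
    """Flag wells showing abrupt drops in raw OD600.

    A well is flagged when any consecutive-reading decrease exceeds
    ``drop_threshold`` of the prior reading.  This automates the study's
    visual screen for abrupt-drop abnormalities; flags are advisory — the
    report says why, and the scorer excludes flagged wells but can be
    handed a pre-filtered set instead.
    """
    if not 0.0 < drop_threshold < 1.0:
        raise ValueError("drop_threshold must be in (0, 1)")
    rows = []
    for c in curves:
        od = c.od600
        prev = od[:-1]
        with np.errstate(divide="ignore", invalid="ignore"):
            rel_drop = np.where(prev > 0, (prev - od[1:]) / prev, 0.0)
        worst = float(rel_drop.max(initial=0.0))
        flagged = worst > drop_threshold
        rows.append(
            {
                "well": c.well_id,
                "strain": c.strain_id,
                "media": c.media,
                "flagged": flagged,
                "max_relative_drop": worst,
                "reason": f"drop of {worst:.1%} exceeds {drop_threshold:.0%}"
                if flagged
                else "",
            }
        )
    return pd.DataFrame(
        rows, columns=["well", "strain", "media", "flagged", "max_relative_drop", "reason"]
    )


# ---------------------------------------------------------------------------
# slope fitting

def fit_linear_slope(
    times_h: np.ndarray,
    log2_od: np.ndarray,
    window: tuple[float, float] = (-3.0, -2.0),
    min_points: int = 3,
    well_id: str = "",
) -> SlopeEstimate:
    """OLS slope over the points whose log2-OD lies in the closed window.

    The bounds are inclusive; wells whose curve never brings ``min_points``
    readings into the window raise :class:`InsufficientWindowError` naming
    the well, so a silently meaningless slope is never produced.
    """
    lo, hi = window
    if not lo < hi:
        raise ValueError("window must satisfy lo < hi")
    times_h = np.asarray(times_h, dtype=float)
    log2_od = np.asarray(log2_od, dtype=float)
    sel = (log2_od >= lo) & (log2_od <= hi)
    n = int(sel.sum())
    if n < min_points:
        raise InsufficientWindowError(
            f"well {well_id or '?'}: {n} points in log2-OD window "
            f"[{lo}, {hi}], need {min_points}"
        )
    t, y = times_h[sel], log2_od[sel]
    slope, intercept = np.polyfit(t, y, 1)
    resid = y - (slope * t + intercept)
    return SlopeEstimate(
        well_id=well_id,
        slope=float(slope),
        window_lo=lo,
        window_hi=hi,
        n_points=n,
        fit_residual=float(np.sqrt(np.mean(resid**2))),
    )


# ---------------------------------------------------------------------------
# ratios and scores

def mtx_dmso_ratio(
    strain_id: str,
    experiment_id: str,
    slopes: pd.DataFrame,
) -> pd.DataFrame:
    """Per-MTX-well slope ratios for one strain within one experiment.

    ``slopes`` needs columns (experiment, strain, well, media, slope); the
    pairing is strictly within the same experiment and strain: each MTX
    well's slope is divided by the mean slope of that strain's DMSO wells
    on the same plate.
    """
    sub = slopes[(slopes["strain"] == strain_id) & (slopes["experiment"] == experiment_id)]
    dmso = sub.loc[sub["media"] == MEDIA_DMSO, "slope"]
    mtx = sub[sub["media"] == MEDIA_MTX]
    if len(dmso) == 0:
        raise RatioUndefinedError(
            f"{strain_id} / {experiment_id}: no DMSO wells to normalize against"
        )
    if len(mtx) == 0:
        raise RatioUndefinedError(f"{strain_id} / {experiment_id}: no MTX wells")
    dmso_mean = float(dmso.mean())
    if dmso_mean <= 0:
        raise RatioUndefinedError(
            f"{strain_id} / {experiment_id}: non-positive DMSO mean slope {dmso_mean:g}"
        )
    out = mtx[["experiment", "strain", "well"]].copy()
    out["ratio"] = mtx["slope"].to_numpy() / dmso_mean
    return out.reset_index(drop=True)


def interaction_score(
    ratio_x: float,
    ratio_nc: float,
    ratio_pc: float,
    degeneracy_tol: float = 1e-6,
) -> float:
    """Control-normalized interaction score.

    score = (ratio_x - ratio_NC) / (ratio_PC - ratio_NC); 1 means the
    strain's MTX/DMSO growth ratio matches the positive control, 0 the
    negative control.  The raw value is returned unclipped (scores slightly
    outside [0, 1] are meaningful and reported).
    """
    denom = ratio_pc - ratio_nc
    if abs(denom) < degeneracy_tol:
        raise ControlsDegenerateError(
            f"ratio_PC ({ratio_pc:g}) and ratio_NC ({ratio_nc:g}) are degenerate"
        )
    return (ratio_x - ratio_nc) / denom


def clip_score(score: float) -> float:
    """Clip a raw score to [0, 1] for display; raw scores stay unclipped."""
    return min(1.0, max(0.0, float(score)))


HEATMAP_BINS = ("<0.2", "0.2–0.4", "0.4–0.6", "0.6–0.8", ">0.8")


def bin_for_heatmap(score_clipped: float) -> str:
    """Assign a clipped score to one of the five display bins.

    Bins are lower-inclusive half-open: [0,0.2), [0.2,0.4), [0.4,0.6),
    [0.6,0.8), [0.8,1].  Inputs must already be clipped.
    """
    s = float(score_clipped)
    if not 0.0 <= s <= 1.0:
        raise ValueError("bin_for_heatmap expects a clipped score in [0, 1]")
    # bisect keeps the boundaries exact (0.6 / 0.2 is 2.999... in floats)
    idx = bisect.bisect_right((0.2, 0.4, 0.6, 0.8), s)
    return HEATMAP_BINS[idx]


def aggregate_scores(per_well: pd.DataFrame) -> dict[str, InteractionScore]:
    """Pool per-well scores per strain across experiments.

    ``per_well`` needs columns (experiment, strain, well, ratio, score).
    Mean and SEM (sample SD / sqrt(n)) summarize all unflagged replicate
    scores; SEM is ``None`` for a single replicate rather than a fake zero.
    """
    out: dict[str, InteractionScore] = {}
    for strain, grp in per_well.groupby("strain", sort=False):
        scores = grp["score"].to_numpy(dtype=float)
        n = len(scores)
        mean = float(np.mean(scores))
        sem = float(np.std(scores, ddof=1) / math.sqrt(n)) if n > 1 else None
        out[str(strain)] = InteractionScore(
            strain_id=str(strain),
            ratio_x=float(grp["ratio"].mean()),
            ratio_nc=float(grp["ratio_nc"].mean()) if "ratio_nc" in grp else float("nan"),
            ratio_pc=float(grp["ratio_pc"].mean()) if "ratio_pc" in grp else float("nan"),
            score=mean,
            score_clipped=clip_score(mean),
            per_replicate_scores=scores,
            mean=mean,
            sem=sem,
        )
    return out


def classify_specificity(
    mutant_id: str,
    ligand_scores: Mapping[str, float],
    threshold: float = 0.3,
    min_ligands: int = 3,
) -> SpecificityCall:
    """Call a mutant nonspecific when >= ``min_ligands`` ligands score
    strictly below ``threshold`` (default: < 0.3 for at least 3 ligands)."""
    if not ligand_scores:
        raise ValueError("ligand_scores must be nonempty")
    n_low = sum(1 for s in ligand_scores.values() if s < threshold)
    return SpecificityCall(
        mutant_id=mutant_id,
        ligand_scores=dict(ligand_scores),
        nonspecific=n_low >= min_ligands,
        threshold=threshold,
        min_ligands=min_ligands,
    )


# ---------------------------------------------------------------------------
# plate / experiment drivers

def score_plate(
    curves: Sequence[GrowthCurve],
    experiment_id: str = "exp1",
    config: ScoreConfig = ScoreConfig(),
) -> dict:
    """Run the full scoring pipeline on one plate.

    Returns a dict with the QC report (``qc``), per-well slope table
    (``slopes``), per-MTX-well scores (``scores``), the experiment's
    control ratios, and the estimated blank.  Wells flagged by QC or with
    too few window points are excluded from scoring and listed under
    ``excluded``.
    """
    curves = list(curves)
    blank = estimate_blank(curves)
    qc = qc_wells(curves, config.drop_threshold)
    flagged = set(qc.loc[qc["flagged"], "well"])

    slope_rows = []
    excluded: list[dict] = []
    for c in curves:
        if c.role == ROLE_BLANK:
            continue
        if c.well_id in flagged:
            excluded.append({"well": c.well_id, "reason": "qc_flagged"})
            continue
        try:
            t, y = blank_and_log(c, blank)
            est = fit_linear_slope(
                t, y, window=config.window, min_points=config.min_points, well_id=c.well_id
            )
        except (EmptySeriesError, InsufficientWindowError) as exc:
            excluded.append({"well": c.well_id, "reason": str(exc)})
            continue
        slope_rows.append(
            {
                "experiment": experiment_id,
                "strain": c.strain_id,
                "well": c.well_id,
                "media": c.media,
                "role": c.role,
                "slope": est.slope,
                "n_points": est.n_points,
                "fit_residual": est.fit_residual,
            }
        )
    slopes = pd.DataFrame(slope_rows)
    if slopes.empty:
        raise EmptySeriesError("no wells survived QC and window selection")

    # per-strain MTX/DMSO ratios
    ratio_frames = []
    for strain in slopes["strain"].unique():
        try:
            ratio_frames.append(mtx_dmso_ratio(strain, experiment_id, slopes))
        except RatioUndefinedError as exc:
            excluded.append({"well": f"strain:{strain}", "reason": str(exc)})
    ratios = pd.concat(ratio_frames, ignore_index=True)

    roles = slopes.drop_duplicates("strain").set_index("strain")["role"]
    nc_strain = config.nc_strain or next(
        s for s in roles.index if roles[s] == ROLE_NEGATIVE_CONTROL
    )
    pc_strain = config.pc_strain or next(
        s for s in roles.index if roles[s] == ROLE_POSITIVE_CONTROL
    )
    ratio_nc = float(ratios.loc[ratios["strain"] == nc_strain, "ratio"].mean())
    ratio_pc = float(ratios.loc[ratios["strain"] == pc_strain, "ratio"].mean())
    if np.isnan(ratio_nc) or np.isnan(ratio_pc):
        raise RatioUndefinedError("control strain ratios unavailable on this plate")

    scores = ratios.copy()
    scores["ratio_nc"] = ratio_nc
    scores["ratio_pc"] = ratio_pc
    scores["score"] = [
        interaction_score(r, ratio_nc, ratio_pc, config.degeneracy_tol)
        for r in scores["ratio"]
    ]
    return {
        "experiment": experiment_id,
        "blank": blank,
        "qc": qc,
        "slopes": slopes,
        "scores": scores,
        "ratio_nc": ratio_nc,
        "ratio_pc": ratio_pc,
        "nc_strain": nc_strain,
        "pc_strain": pc_strain,
        "excluded": excluded,
    }


def score_experiments(
    plates: Mapping[str, Sequence[GrowthCurve]],
    config: ScoreConfig = ScoreConfig(),
) -> dict:
    """Score several plates (experiments) and pool per-strain results.

    Controls are matched strictly within each plate; per-well scores are
    then pooled across plates per strain (the study design: two experiments
    of three replicates gives n = 6 per strain).
    """
    per_plate = {
        exp_id: score_plate(curves, exp_id, config) for exp_id, curves in plates.items()
    }
    pooled = pd.concat([r["scores"] for r in per_plate.values()], ignore_index=True)
    return {
        "per_plate": per_plate,
        "scores": pooled,
        "summary": aggregate_scores(pooled),
    }
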