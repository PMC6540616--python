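"""Synthetic microplate growth data for the split-DHFR interaction assay.

The assay couples yeast growth in methotrexate (MTX) to the binding of two
DHFR-fragment fusion proteins: strains whose fusions interact reconstitute an
MTX-insensitive DHFR and grow, strains whose fusions do not interact grow
poorly.  A plate holds, for every strain, replicate wells in plain DMSO media
and in DMSO + MTX, read as OD600 every few minutes for a day or so.  The
scorer (:mod:`synscreen.scoring`) works from those kinetic reads alone, so a
generator with known per-strain growth rates gives it exact ground truth.

Growth is modelled as logistic in linear OD space with an initial lag, which
is the minimal standard microplate shape producing the log-linear window the
scorer fits.  The ``rate`` parameter is the specific growth rate expressed in
log2-OD units per hour (doublings per hour), so a noiseless curve in its
near-exponential range gains ``rate`` per hour in log2(OD - blank).
Reader noise is additive Gaussian on OD, truncated at zero, independent per
well.  The plate-level blank offset is added to every well and also emitted
as dedicated blank wells so that downstream blank estimation is exercised.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "MEDIA_MTX",
    "MEDIA_DMSO",
    "ROLE_SAMPLE",
    "ROLE_POSITIVE_CONTROL",
    "ROLE_NEGATIVE_CONTROL",
    "ROLE_BLANK",
    "GrowthParams",
    "GrowthCurve",
    "StrainSpec",
    "PlateSpec",
    "logistic_od",
    "simulate_growth_curve",
    "simulate_plate",
    "inject_artifact",
    "plate_to_frame",
    "frame_to_curves",
    "write_plate",
    "read_plate",
]

MEDIA_MTX = "MTX"
MEDIA_DMSO = "DMSO"
ROLE_SAMPLE = "sample"
ROLE_POSITIVE_CONTROL = "positive_control"
ROLE_NEGATIVE_CONTROL = "negative_control"
ROLE_BLANK = "blank"

_MEDIA = (MEDIA_MTX, MEDIA_DMSO)
_ROLES = (ROLE_SAMPLE, ROLE_POSITIVE_CONTROL, ROLE_NEGATIVE_CONTROL, ROLE_BLANK)


@dataclass(frozen=True)
class GrowthParams:
    """Parameters of one well's logistic growth curve.

    Attributes
    ----------
    initial_od : float
        Blank-subtracted OD at inoculation (> 0).
    carrying_capacity : float
        Blank-subtracted OD plateau.
    rate : float
        Specific growth rate in log2-OD units per hour (doublings/h), >= 0.
    lag_h : float
        Lag before growth starts; OD is held at ``initial_od`` until then.
    noise_sd : float
        SD of additive Gaussian reader noise, in OD units, >= 0.
    blank_od : float
        Media + plate background OD added to every reading.
    """

    initial_od: float = 0.05
    carrying_capacity: float = 1.8
    rate: float = 0.35
    lag_h: float = 1.0
    noise_sd: float = 0.0
    blank_od: float = 0.09

    def __post_init__(self) -> None:
        if not self.initial_od > 0:
            raise ValueError("initial_od must be > 0")
        if not self.initial_od < self.carrying_capacity:
            raise ValueError("initial_od must be < carrying_capacity")
        if self.rate < 0:
            raise ValueError("rate must be >= 0")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.blank_od < 0:
            raise ValueError("blank_od must be >= 0")


@dataclass
class GrowthCurve:
    """One well's raw OD600 time series with its plate annotations."""

    well_id: str
    strain_id: str
    media: str
    role: str
    times_h: np.ndarray
    od600: np.ndarray

    def __post_init__(self) -> None:
        self.times_h = np.asarray(self.times_h, dtype=float)
        self.od600 = np.asarray(self.od600, dtype=float)
        if self.media not in _MEDIA:
            raise ValueError(f"media must be one of {_MEDIA}, got {self.media!r}")
        if self.role not in _ROLES:
            raise ValueError(f"role must be one of {_ROLES}, got {self.role!r}")
        if self.times_h.ndim != 1 or self.times_h.size == 0:
            raise ValueError("times_h must be a nonempty 1-D series")
        if self.times_h.shape != self.od600.shape:
            raise ValueError("times_h and od600 must have the same length")
        if not np.all(np.diff(self.times_h) > 0):
            raise ValueError("times_h must be strictly increasing")
        if np.any(self.od600 < 0):
            raise ValueError("od600 values must be >= 0")


@dataclass(frozen=True)
class StrainSpec:
    """One strain on the plate, with its media-dependent growth rates."""

    strain_id: str
    role: str
    dmso_rate: float
    mtx_rate: float

    def __post_init__(self) -> None:
        if self.role not in (ROLE_SAMPLE, ROLE_POSITIVE_CONTROL, ROLE_NEGATIVE_CONTROL):
            raise ValueError(f"invalid strain role {self.role!r}")
        if self.dmso_rate < 0 or self.mtx_rate < 0:
            raise ValueError("growth rates must be >= 0")


@dataclass(frozen=True)
class PlateSpec:
    """Layout and conditions of one simulated assay plate.

    Every strain gets ``replicates_per_condition`` wells in each of the two
    media (DMSO alone and DMSO + MTX), matching the study design of three
    replicate wells per media per strain; dedicated blank wells carry media
    only.  The plate must contain at least one positive-control and one
    negative-control strain, since the score is anchored to both.
    """

    strains: tuple[StrainSpec, ...]
    replicates_per_condition: int = 3
    read_interval_min: float = 10.0
    duration_h: float = 30.0
    seed: int = 0
    n_blank_wells: int = 4
    growth: GrowthParams = field(default_factory=GrowthParams)

    def __post_init__(self) -> None:
        object.__setattr__(self, "strains", tuple(self.strains))
        if self.replicates_per_condition < 1:
            raise ValueError("replicates_per_condition must be >= 1")
        if self.read_interval_min <= 0 or self.duration_h <= 0:
            raise ValueError("read interval and duration must be > 0")
        if self.n_blank_wells < 0:
            raise ValueError("n_blank_wells must be >= 0")
        roles = {s.role for s in self.strains}
        if ROLE_POSITIVE_CONTROL not in roles:
            raise ValueError("plate must contain a positive_control strain")
        if ROLE_NEGATIVE_CONTROL not in roles:
            raise ValueError("plate must contain a negative_control strain")
        ids = [s.strain_id for s in self.strains]
        if len(ids) != len(set(ids)):
            raise ValueError("strain_ids must be unique")

    def times_h(self) -> np.ndarray:
        """Read times: every ``read_interval_min`` from 0 through ``duration_h``."""
        n = int(round(self.duration_h * 60.0 / self.read_interval_min))
        return np.arange(n + 1) * (self.read_interval_min / 60.0)


def logistic_od(params: GrowthParams, times_h: np.ndarray) -> np.ndarray:
    """Noise-free blank-subtracted logistic OD at the given times.

    OD is held at ``initial_od`` through the lag, then follows the logistic
    solution N(t) = K A e^{rt} / (K + A (e^{rt} - 1)) with r = rate * ln 2.
    """
    t = np.maximum(np.asarray(times_h, dtype=float) - params.lag_h, 0.0)
    a, k = params.initial_od, params.carrying_capacity
    r = params.rate * np.log(2.0)
    e = np.exp(r * t)
    return k * a * e / (k + a * (e - 1.0))


def simulate_growth_curve(
    params: GrowthParams,
    times_h: Sequence[float],
    seed,
    *,
    well_id: str = "A01",
    strain_id: str = "strain",
    media: str = MEDIA_DMSO,
    role: str = ROLE_SAMPLE,
) -> GrowthCurve:
    """Simulate one well: blank + logistic + truncated Gaussian reader noise.

    ``seed`` may be an int or a :class:`numpy.random.SeedSequence`; identical
    seeds give identical curves.  Blank wells are produced by the plate
    simulator with ``rate = 0`` and ``initial_od`` ~ 0 rather than here.
    """
    times_h = np.asarray(times_h, dtype=float)
    if times_h.size == 0 or not np.all(np.diff(times_h) > 0):
        raise ValueError("times_h must be nonempty and strictly increasing")
    od = params.blank_od + logistic_od(params, times_h)
    if params.noise_sd > 0:
        rng = np.random.default_rng(seed)
        od = od + rng.normal(0.0, params.noise_sd, size=od.shape)
    od = np.maximum(od, 0.0)
    return GrowthCurve(well_id, strain_id, media, role, times_h, od)


def _well_name(index: int, n_cols: int = 12) -> str:
    return f"{chr(ord('A') + index // n_cols)}{index % n_cols + 1:02d}"


def simulate_plate(spec: PlateSpec) -> list[GrowthCurve]:
    """Simulate a full plate: strain x media x replicate wells plus blanks.

    Each strain's MTX wells grow at its ``mtx_rate`` and DMSO wells at its
    ``dmso_rate``; all other growth parameters are shared plate-wide.  Wells
    draw independent noise streams spawned from ``spec.seed``, so the whole
    plate is reproducible from the spec alone.
    """
    times = spec.times_h()
    n_wells = 2 * spec.replicates_per_condition * len(spec.strains) + spec.n_blank_wells
    children = np.random.SeedSequence(spec.seed).spawn(n_wells)
    curves: list[GrowthCurve] = []
    idx = 0
    for strain in spec.strains:
        for media, rate in ((MEDIA_DMSO, strain.dmso_rate), (MEDIA_MTX, strain.mtx_rate)):
            for _rep in range(spec.replicates_per_condition):
                params = replace(spec.growth, rate=rate)
                curves.append(
                    simulate_growth_curve(
                        params,
                        times,
                        children[idx],
                        well_id=_well_name(idx),
                        strain_id=strain.strain_id,
                        media=media,
                        role=strain.role,
                    )
                )
                idx += 1
    for _ in range(spec.n_blank_wells):
        od = np.full_like(times, spec.growth.blank_od)
        if spec.growth.noise_sd > 0:
            rng = np.random.default_rng(children[idx])
            od = od + rng.normal(0.0, spec.growth.noise_sd, size=od.shape)
        od = np.maximum(od, 0.0)
        curves.append(
            GrowthCurve(_well_name(idx), "blank", MEDIA_DMSO, ROLE_BLANK, times, od)
        )
        idx += 1
    return curves


def inject_artifact(curve: GrowthCurve, at_h: float, drop_fraction: float) -> GrowthCurve:
    """Inject an abrupt-drop artifact: readings at t >= ``at_h`` are scaled
    by (1 - drop_fraction).

    Emulates the well failures (condensation, bubbles) that the QC step is
    meant to flag.  Returns a new curve; the input is untouched.
    """
    if not 0.0 <= drop_fraction <= 1.0:
        raise ValueError("drop_fraction must be in [0, 1]")
    if not curve.times_h[0] <= at_h <= curve.times_h[-1]:
        raise ValueError(f"at_h={at_h} outside curve time range")
    od = curve.od600.copy()
    od[curve.times_h >= at_h] *= 1.0 - drop_fraction
    return GrowthCurve(
        curve.well_id, curve.strain_id, curve.media, curve.role, curve.times_h.copy(), od
    )


# ---------------------------------------------------------------------------
# long-format I/O (well, strain, media, role, time_h, od600)

def plate_to_frame(curves: Sequence[GrowthCurve]) -> pd.DataFrame:
    frames = [
        pd.DataFrame(
            {
                "well": c.well_id,
                "strain": c.strain_id,
                "media": c.media,
                "role": c.role,
                "time_h": c.times_h,
                "od600": c.od600,
            }
        )
        for c in curves
    ]
    return pd.concat(frames, ignore_index=True)


def frame_to_curves(frame: pd.DataFrame) -> list[GrowthCurve]:
    curves = []
    for well, grp in frame.groupby("well", sort=False):
        grp = grp.sort_values("time_h")
        curves.append(
            GrowthCurve(
                well_id=str(well),
                strain_id=str(grp["strain"].iloc[0]),
                media=str(grp["media"].iloc[0]),
                role=str(grp["role"].iloc[0]),
                times_h=grp["time_h"].to_numpy(),
                od600=grp["od600"].to_numpy(),
            )
        )
    return curves


def write_plate(curves: Sequence[GrowthCurve], path) -> None:
    plate_to_frame(curves).to_csv(path, index=False)


def read_plate(path) -> list[GrowthCurve]:
    return frame_to_curves(pd.read_csv(path))
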