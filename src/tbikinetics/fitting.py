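"""Inverse problem: estimate the released amount D0 from sparse timed levels.

The model is linear in D0: Cp(t) = D0 * s(t), where the unit-release
shape s(t) collects the kinetic constants and the blood volume.  Ordinary
least squares over a subject's measured levels y_i at times t_i therefore
has the closed form

    D0_hat = sum_i s(t_i) * y_i / sum_i s(t_i)^2,

optionally clamped at zero (negative release is unphysical).  Cohort
fitting consumes the long-format measurement table produced by the
synthetic-cohort generator (or any CSV with the same columns), maps the
study's date-stamp labels to nominal hours, and regenerates a predicted
concentration curve per subject from the fitted D0.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .model import (
    ConcentrationCurve,
    InjuryScenario,
    KineticParameters,
    curve_over_grid,
    plasma_concentration,
)
from .presets import BiomarkerPreset

__all__ = [
    "DEFAULT_SCHEDULE",
    "TimedMeasurement",
    "FitResult",
    "shape_at",
    "estimate_D0",
    "fit_cohort",
    "predicted_vs_measured",
]

logger = logging.getLogger(__name__)

#: Nominal hours post-injury assigned to the study's date-stamp labels.
#: The source data are date- but not time-stamped, so these are plausible
#: midpoints: <6 h -> 6 h, the 24-48 h window -> 36 h, asymptomatic
#: (about a week) -> 168 h, and 7 days after return to play -> 336 h.
DEFAULT_SCHEDULE: dict[str, float] = {
    "lt6h": 6.0,
    "24-48h": 36.0,
    "asymptomatic": 168.0,
    "rtp7d": 336.0,
}


@dataclass(frozen=True)
class TimedMeasurement:
    """One timed plasma level of one biomarker for one subject."""

    subject_id: str
    biomarker: str
    t: float  # hours post-injury
    level: float  # pg/ml
    label: str = "other"  # timepoint label: lt6h / 24-48h / asymptomatic / rtp7d / other

    def __post_init__(self) -> None:
        if self.t < 0:
            raise ValueError("measurement time must be nonnegative")
        if self.level < 0:
            raise ValueError("measured level must be nonnegative")


@dataclass(frozen=True)
class FitResult:
    """Least-squares release estimate for one subject and biomarker."""

    subject_id: str
    biomarker: str
    D0_hat: float  # pg (clamped at 0 when nonnegative=True)
    D0_raw: float  # pg, unclamped least-squares estimate
    rss: float  # residual sum of squares, (pg/ml)^2
    n_points: int
    times: np.ndarray  # hr, measurements used
    predicted: np.ndarray  # model levels at `times` from D0_hat, pg/ml


def shape_at(params: KineticParameters, Vd: float, t):
    """Unit-release response s(t) in pg/ml per pg: Cp = D0 * s(t)."""
    return plasma_concentration(params, InjuryScenario(D0=1.0, Vd=Vd), t)


def estimate_D0(
    measurements,
    params: KineticParameters,
    Vd: float = 5000.0,
    nonnegative: bool = True,
    weights=None,
) -> FitResult:
    """Closed-form least-squares estimate of the released amount.

    ``measurements`` is a sequence of :class:`TimedMeasurement` (one
    subject, one biomarker).  With optional positive ``weights`` the
    weighted normal equation is used instead of plain OLS.  Raises when
    every shape value is zero (all measurements at t = 0), since D0 is
    then unidentifiable.
    """
    ms = list(measurements)
    if not ms:
        raise ValueError("at least one measurement is required")
    subject = ms[0].subject_id
    biomarker = ms[0].biomarker
    t = np.array([m.t for m in ms], dtype=float)
    y = np.array([m.level for m in ms], dtype=float)
    s = np.array([shape_at(params, Vd, ti) for ti in t])
    if not np.any(s > 0):
        raise ValueError(
            "D0 is unidentifiable: the model response is zero at every measured time"
        )
    w = np.ones_like(y) if weights is None else np.asarray(weights, dtype=float)
    if np.any(w <= 0) or w.shape != y.shape:
        raise ValueError("weights must be positive and match the measurements")
    raw = float(np.sum(w * s * y) / np.sum(w * s**2))
    d0 = max(raw, 0.0) if nonnegative else raw
    predicted = d0 * s
    rss = float(np.sum(w * (y - predicted) ** 2))
    return FitResult(
        subject_id=subject,
        biomarker=biomarker,
        D0_hat=d0,
        D0_raw=raw,
        rss=rss,
        n_points=len(ms),
        times=t,
        predicted=predicted,
    )


def _resolve_times(df: pd.DataFrame, schedule: dict[str, float]) -> pd.Series:
    """Measurement hours: explicit time_hr column wins, else mapped label."""
    if "time_hr" in df.columns:
        t = pd.to_numeric(df["time_hr"], errors="coerce")
    else:
        t = pd.Series(np.nan, index=df.index)
    mapped = df["timepoint_label"].map(schedule) if "timepoint_label" in df.columns else np.nan
    return t.fillna(mapped)


def fit_cohort(
    table: pd.DataFrame,
    preset: BiomarkerPreset,
    Vd: float | None = None,
    schedule: dict[str, float] | None = None,
    nonnegative: bool = True,
    curve_grid=None,
) -> tuple[pd.DataFrame, dict[str, ConcentrationCurve]]:
    """Fit D0 for every subject of one biomarker in a long-format table.

    Expects columns ``subject_id``, ``biomarker``, ``level_pg_ml`` and
    either ``time_hr`` or ``timepoint_label`` (mapped through
    ``schedule``, default :data:`DEFAULT_SCHEDULE`).  Rows whose time
    cannot be resolved are skipped with a logged warning; subjects left
    with no usable rows are excluded.  A per-subject ``Vd`` column is
    honoured when present, otherwise ``Vd`` (default 5,000 ml) applies.

    Returns a fits table (subject_id, biomarker, D0_hat_pg, D0_raw_pg,
    rss, n_points) and a dict of predicted per-subject curves on
    ``curve_grid`` (default 0..2*last measured hour, 200 points).
    """
    if table.empty:
        raise ValueError("measurement table is empty")
    schedule = DEFAULT_SCHEDULE if schedule is None else schedule
    df = table[table["biomarker"] == preset.name].copy()
    if df.empty:
        raise ValueError(f"no rows for biomarker {preset.name!r}")
    df["_t"] = _resolve_times(df, schedule)
    bad = df["_t"].isna() | df["level_pg_ml"].isna()
    if bad.any():
        logger.warning(
            "skipping %d rows with unresolvable timepoints for %s",
            int(bad.sum()),
            preset.name,
        )
        df = df[~bad]
    if df.empty:
        raise ValueError("no usable rows after excluding missing timepoints")

    params = preset.kinetics()
    rows = []
    curves: dict[str, ConcentrationCurve] = {}
    t_end = 2.0 * float(df["_t"].max())
    grid = np.linspace(0.0, t_end, 200) if curve_grid is None else np.asarray(curve_grid)
    for subject, grp in df.groupby("subject_id", sort=True):
        vd = float(grp["Vd"].iloc[0]) if "Vd" in grp.columns else (Vd or 5000.0)
        ms = [
            TimedMeasurement(str(subject), preset.name, float(r["_t"]), float(r["level_pg_ml"]),
                             str(r.get("timepoint_label", "other")))
            for _, r in grp.iterrows()
        ]
        fit = estimate_D0(ms, params, Vd=vd, nonnegative=nonnegative)
        rows.append(
            {
                "subject_id": str(subject),
                "biomarker": preset.name,
                "D0_hat_pg": fit.D0_hat,
                "D0_raw_pg": fit.D0_raw,
                "rss": fit.rss,
                "n_points": fit.n_points,
            }
        )
        curves[str(subject)] = curve_over_grid(
            params, InjuryScenario(D0=fit.D0_hat, Vd=vd), grid
        )
    return pd.DataFrame(rows), curves


def predicted_vs_measured(
    fits: pd.DataFrame,
    table: pd.DataFrame,
    preset: BiomarkerPreset,
    at_label: str,
    Vd: float = 5000.0,
    schedule: dict[str, float] | None = None,
) -> pd.DataFrame:
    """Pair model-estimated with measured levels at one timepoint label.

    Returns a frame with columns ``subject_id``, ``estimated_pg_ml`` and
    ``measured_pg_ml`` for every fitted subject having the label, plus a
    ``signed_error_pg_ml`` column (estimated - measured); its mean
    quantifies systematic under- or over-prediction.
    """
    schedule = DEFAULT_SCHEDULE if schedule is None else schedule
    df = table[(table["biomarker"] == preset.name)]
    if "timepoint_label" not in df.columns or not (df["timepoint_label"] == at_label).any():
        raise ValueError(f"label {at_label!r} not present for biomarker {preset.name!r}")
    df = df[df["timepoint_label"] == at_label].copy()
    df["_t"] = _resolve_times(df, schedule)
    df = df[df["_t"].notna()]
    params = preset.kinetics()
    fit_by_subject = fits.set_index("subject_id")["D0_hat_pg"]
    rows = []
    for _, r in df.iterrows():
        sid = str(r["subject_id"])
        if sid not in fit_by_subject.index:
            continue
        vd = float(r["Vd"]) if "Vd" in df.columns else Vd
        est = float(fit_by_subject[sid]) * shape_at(params, vd, float(r["_t"]))
        rows.append(
            {
                "subject_id": sid,
                "estimated_pg_ml": est,
                "measured_pg_ml": float(r["level_pg_ml"]),
                "signed_error_pg_ml": est - float(r["level_pg_ml"]),
            }
        )
    return pd.DataFrame(rows)
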