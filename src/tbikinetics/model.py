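"""One-compartment kinetic model for blood biomarker levels after concussion.

A mild traumatic brain injury releases a fixed amount ``D0`` (pg) of a
protein biomarker into the brain compartment at the moment of impact.  A
fraction ``F`` of it is absorbed into the blood with first-order rate
constant ``ka`` (hr^-1) and eliminated from the blood with first-order rate
constant ``ke`` (hr^-1).  The blood compartment is well mixed with volume of
distribution ``Vd`` (ml), approximated by total blood volume.  The plasma
concentration is the classic bi-exponential (Bateman) solution

    Cp(t) = F * D0 * ka / (Vd * (ka - ke)) * (exp(-ke*t) - exp(-ka*t))

with the analytic limit ``F * D0 * ka * t * exp(-ka*t) / Vd`` when the two
rate constants coincide.  Units are fixed throughout the package: hours, pg,
ml, and pg/ml; no unit-conversion layer exists.

The module also provides the textbook parameter relations: half-life
``t1/2 = 0.693 / ke`` and time of peak ``Tmax = ln(ka/ke) / (ka - ke)``,
plus the numerical inversion of the latter used to derive ``ka`` from a
published ``Tmax``.  That inversion is two-valued ("flip-flop" kinetics: the
relation is symmetric in ka and ke); the absorption-faster branch (ka > ke)
is the default because every published parameterisation here satisfies it.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import brentq

__all__ = [
    "HALF_LIFE_CONSTANT",
    "KineticParameters",
    "InjuryScenario",
    "ModelState",
    "ConcentrationCurve",
    "PeakSummary",
    "plasma_concentration",
    "plasma_concentration_arrays",
    "amounts_at",
    "ke_from_half_life",
    "half_life_from_ke",
    "time_of_peak",
    "ka_from_tmax",
    "curve_over_grid",
]

#: Half-life constant as conventionally printed in the pharmacokinetic
#: literature (3 significant figures of ln 2).  Functions accept
#: ``exact=True`` to use ``math.log(2)`` instead.
HALF_LIFE_CONSTANT = 0.693

# Relative ka/ke difference below which the degenerate (ka == ke) limit of
# the bi-exponential is used instead of the singular closed form.
_DEGENERACY_RTOL = 1e-8


@dataclass(frozen=True)
class KineticParameters:
    """Biomarker-specific rate constants and bioavailability.

    Parameters
    ----------
    ka : float
        First-order absorption rate constant, brain -> blood, hr^-1.
    ke : float
        First-order elimination rate constant, blood -> out, hr^-1.
    F : float
        Bioavailability: fraction of released biomarker reaching the
        blood; unitless, in (0, 1].
    """

    ka: float
    ke: float
    F: float = 0.8

    def __post_init__(self) -> None:
        if not (self.ka > 0):
            raise ValueError(f"ka must be positive, got {self.ka}")
        if not (self.ke > 0):
            raise ValueError(f"ke must be positive, got {self.ke}")
        if not (0 < self.F <= 1):
            raise ValueError(f"F must lie in (0, 1], got {self.F}")


@dataclass(frozen=True)
class InjuryScenario:
    """Subject-specific model inputs.

    Parameters
    ----------
    D0 : float
        Amount of biomarker released into the brain at impact, pg.
    Vd : float
        Volume of distribution (total blood volume), ml.
    t0 : float
        Injury time origin in hours; measurement times are absolute and
        shifted by ``t0`` internally.  Default 0.
    """

    D0: float
    Vd: float = 5000.0
    t0: float = 0.0

    def __post_init__(self) -> None:
        if self.D0 < 0:
            raise ValueError(f"D0 must be nonnegative, got {self.D0}")
        if not (self.Vd > 0):
            raise ValueError(f"Vd must be positive, got {self.Vd}")


#: Nominal study scenario: 400,000 pg released, 5,000 ml blood volume.
NOMINAL_SCENARIO = InjuryScenario(D0=400_000.0, Vd=5000.0)


@dataclass(frozen=True)
class ModelState:
    """Mass-balance state of the two compartments at one time point."""

    t: float
    D_br: float  # amount remaining in brain compartment, pg
    D_bl: float  # amount in blood compartment, pg
    Cp: float  # plasma concentration, pg/ml


@dataclass(frozen=True)
class PeakSummary:
    """Peak of the concentration-time curve and elimination half-life."""

    Tmax: float  # hr
    Cmax: float  # pg/ml
    t_half: float  # hr


@dataclass(frozen=True)
class ConcentrationCurve:
    """Plasma concentration evaluated on a time grid.

    ``times`` is a strictly increasing sequence of hours >= 0 and
    ``levels`` the matching concentrations in pg/ml.
    """

    times: np.ndarray
    levels: np.ndarray

    def __post_init__(self) -> None:
        times = np.asarray(self.times, dtype=float)
        levels = np.asarray(self.levels, dtype=float)
        if times.shape != levels.shape or times.ndim != 1:
            raise ValueError("times and levels must be 1-d arrays of equal length")
        if times.size and (np.any(np.diff(times) <= 0) or times[0] < 0):
            raise ValueError("times must be strictly increasing and nonnegative")
        object.__setattr__(self, "times", times)
        object.__setattr__(self, "levels", levels)

    def __len__(self) -> int:
        return self.times.size

    def auc(self) -> float:
        """Area under the curve by the trapezoid rule, pg*hr/ml."""
        if len(self) < 2:
            return 0.0
        return float(np.trapezoid(self.levels, self.times))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"time_hr": self.times, "level_pg_ml": self.levels})

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False, float_format="%.6g")

    @classmethod
    def from_csv(cls, path) -> "ConcentrationCurve":
        df = pd.read_csv(path)
        return cls(df["time_hr"].to_numpy(), df["level_pg_ml"].to_numpy())


def _shifted_times(scenario: InjuryScenario, t) -> np.ndarray:
    tt = np.asarray(t, dtype=float) - scenario.t0
    if np.any(tt < 0):
        raise ValueError("t must not precede the injury time origin")
    return tt


def plasma_concentration(params: KineticParameters, scenario: InjuryScenario, t):
    """Plasma concentration Cp(t) in pg/ml.

    Accepts a scalar or array of hours since ``scenario.t0``; negative
    effective times raise ``ValueError``.  Near the ka == ke degeneracy
    (relative difference below 1e-8) the analytic limit is used.
    """
    tt = _shifted_times(scenario, t)
    ka, ke, F = params.ka, params.ke, params.F
    amp = F * scenario.D0 * ka / scenario.Vd
    if abs(ka - ke) <= _DEGENERACY_RTOL * ke:
        cp = amp * tt * np.exp(-ka * tt)
    else:
        cp = amp / (ka - ke) * (np.exp(-ke * tt) - np.exp(-ka * tt))
    cp = np.maximum(cp, 0.0)
    return float(cp) if np.isscalar(t) or np.ndim(t) == 0 else cp


def plasma_concentration_arrays(D0, Vd, ka, ke, F, t):
    """Vectorised Cp for per-sample parameter arrays at a common time.

    Used by the Monte Carlo machinery: each argument may be an array of
    per-draw values (broadcastable against the others); ``t`` is a scalar
    or array of hours.  Handles near-degenerate ka/ke rows elementwise.
    """
    D0, Vd, ka, ke, F, t = np.broadcast_arrays(
        *(np.asarray(a, dtype=float) for a in (D0, Vd, ka, ke, F, t))
    )
    if np.any(t < 0):
        raise ValueError("t must be nonnegative")
    if np.any(ka <= 0) or np.any(ke <= 0) or np.any(Vd <= 0):
        raise ValueError("ka, ke and Vd must be positive")
    amp = F * D0 * ka / Vd
    diff = ka - ke
    degenerate = np.abs(diff) <= _DEGENERACY_RTOL * ke
    with np.errstate(divide="ignore", invalid="ignore"):
        cp = amp / diff * (np.exp(-ke * t) - np.exp(-ka * t))
    limit = amp * t * np.exp(-ka * t)
    cp = np.where(degenerate, limit, cp)
    return np.maximum(cp, 0.0)


def amounts_at(params: KineticParameters, scenario: InjuryScenario, t: float) -> ModelState:
    """Compartment amounts and concentration at one time point.

    The brain compartment drains exponentially, ``D_br = D0 * exp(-ka*t)``;
    the blood amount is ``Vd * Cp(t)``; together they satisfy the
    mass-balance ODE ``dD_bl/dt = F*ka*D_br - ke*D_bl``.
    """
    tt = float(_shifted_times(scenario, t))
    d_br = scenario.D0 * math.exp(-params.ka * tt)
    cp = plasma_concentration(params, scenario, t)
    return ModelState(t=float(t), D_br=d_br, D_bl=scenario.Vd * cp, Cp=cp)


def ke_from_half_life(t_half: float, *, exact: bool = False) -> float:
    """Elimination rate constant from half-life: ke = 0.693 / t1/2.

    ``exact=True`` uses ln 2 instead of the printed constant 0.693.
    """
    if not (t_half > 0):
        raise ValueError(f"t_half must be positive, got {t_half}")
    return (math.log(2) if exact else HALF_LIFE_CONSTANT) / t_half


def half_life_from_ke(ke: float, *, exact: bool = False) -> float:
    """Elimination half-life from the rate constant: t1/2 = 0.693 / ke."""
    if not (ke > 0):
        raise ValueError(f"ke must be positive, got {ke}")
    return (math.log(2) if exact else HALF_LIFE_CONSTANT) / ke


def time_of_peak(
    params: KineticParameters, scenario: InjuryScenario | None = None
) -> PeakSummary:
    """Closed-form peak: Tmax = ln(ka/ke)/(ka-ke), with limit 1/ka at ka=ke.

    ``Cmax`` is the concentration at ``Tmax`` for ``scenario`` (nominal
    400,000 pg / 5,000 ml when omitted).
    """
    ka, ke = params.ka, params.ke
    if abs(ka - ke) <= _DEGENERACY_RTOL * ke:
        tmax = 1.0 / ka
    else:
        tmax = math.log(ka / ke) / (ka - ke)
    scenario = NOMINAL_SCENARIO if scenario is None else scenario
    cmax = plasma_concentration(params, scenario, tmax + scenario.t0)
    return PeakSummary(Tmax=tmax, Cmax=cmax, t_half=half_life_from_ke(ke))


def _tmax_of(ka: float, ke: float) -> float:
    return math.log(ka / ke) / (ka - ke)


def ka_from_tmax(
    tmax: float,
    ke: float,
    branch: str = "absorption-faster",
    *,
    rtol: float = 1e-12,
) -> float:
    """Invert the Tmax relation for ka at fixed ke.

    The relation ``Tmax = ln(ka/ke)/(ka-ke)`` is symmetric under exchange
    of the two rates, so two roots exist (flip-flop kinetics).  ``branch``
    selects ``"absorption-faster"`` (ka > ke, the default: all published
    presets here satisfy it) or ``"absorption-slower"`` (ka < ke).

    Tmax is a strictly decreasing function of ka with value 1/ke at
    ka = ke, so the faster branch requires ``Tmax < 1/ke`` and the slower
    branch ``Tmax > 1/ke``; at equality the unique solution ka = ke is
    returned with a warning.  Root-finding is bracketed Brent iteration,
    converged to relative tolerance ``rtol``.
    """
    if not (tmax > 0):
        raise ValueError(f"Tmax must be positive, got {tmax}")
    if not (ke > 0):
        raise ValueError(f"ke must be positive, got {ke}")
    if branch not in ("absorption-faster", "absorption-slower"):
        raise ValueError(f"unknown branch {branch!r}")

    if abs(tmax * ke - 1.0) < 1e-12:
        warnings.warn(
            "Tmax*ke == 1: degenerate case, returning ka = ke", RuntimeWarning
        )
        return ke

    def f(ka: float) -> float:
        return _tmax_of(ka, ke) - tmax

    if branch == "absorption-faster":
        if tmax >= 1.0 / ke:
            raise ValueError(
                f"no absorption-faster root: Tmax={tmax} >= 1/ke={1.0 / ke:.6g}"
            )
        lo = ke * (1.0 + 1e-9)
        hi = max(10.0, 100.0 * ke)
        for _ in range(60):
            if f(hi) < 0:
                break
            hi *= 10.0
        else:  # pragma: no cover - unreachable for valid inputs
            raise RuntimeError("failed to bracket the absorption-faster root")
    else:
        if tmax <= 1.0 / ke:
            raise ValueError(
                f"no absorption-slower root: Tmax={tmax} <= 1/ke={1.0 / ke:.6g}"
            )
        hi = ke * (1.0 - 1e-9)
        lo = ke * 1e-6
        for _ in range(60):
            if f(lo) > 0:
                break
            lo /= 10.0
        else:  # pragma: no cover
            raise RuntimeError("failed to bracket the absorption-slower root")

    return float(brentq(f, lo, hi, rtol=max(rtol, 4 * np.finfo(float).eps)))


def curve_over_grid(
    params: KineticParameters, scenario: InjuryScenario, times
) -> ConcentrationCurve:
    """Evaluate the model on a strictly increasing, nonnegative time grid."""
    times = np.asarray(times, dtype=float)
    if times.size == 0:
        return ConcentrationCurve(times=times, levels=np.empty(0))
    if np.any(np.diff(times) <= 0):
        raise ValueError("time grid must be strictly increasing")
    levels = plasma_concentration(params, scenario, times)
    return ConcentrationCurve(times=times, levels=levels)
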