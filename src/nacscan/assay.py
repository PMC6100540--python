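"""In vitro reactivation arithmetic for Ellman-style cholinesterase assays.

The experimental readout is enzyme activity (slope of an absorbance trace,
ΔA/min) under four conditions: intact enzyme (a0), organophosphate-inhibited
enzyme (ai), oxime-treated inhibited enzyme (ar, after subtracting the
oximolysis control — the non-enzymatic substrate hydrolysis caused by the
oxime itself), and the oximolysis control.  Percent reactivation is

    %R = [1 − (a0 − ar) / (a0 − ai)] × 100

computed per replicate and summarized as mean ± sample SD over (typically
three) independent determinations.  Inhibition timing uses pseudo-first-order
kinetics: the enzyme↔organophosphate reaction half-life T_1/2 is fitted from
a log-linear decay and the incubation time is an integer number of
half-lives (seven by default, leaving 2⁻⁷ ≈ 0.8 % residual activity).

Units are minutes for time and mol/L for concentration throughout.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "ActivityMeasurement",
    "ReactivationResult",
    "InhibitionKinetics",
    "activity_from_trace",
    "percent_reactivation",
    "summarize_reactivation",
    "fit_half_life",
    "inhibition_time",
    "reactivation_from_activities",
]

CONDITIONS = ("intact", "inhibited", "reactivated", "oximolysis_control")


@dataclass(frozen=True)
class ActivityMeasurement:
    """One activity value (rate units, e.g. ΔA/min) for one condition."""

    condition: str
    replicate_id: int
    activity: float

    def __post_init__(self) -> None:
        if self.condition not in CONDITIONS:
            raise ValueError(f"unknown condition {self.condition!r}")
        if not np.isfinite(self.activity):
            raise ValueError("activity must be finite")


@dataclass(frozen=True)
class ReactivationResult:
    """Mean ± SD percent reactivation for one oxime × enzyme × concentration."""

    oxime: str
    enzyme: str
    concentration: float  # mol/L
    pct_R_mean: float
    pct_R_sd: float
    n_replicates: int
    out_of_range: bool = False  # any replicate %R outside [0, 100] (never clamped)

    def __post_init__(self) -> None:
        if self.n_replicates < 1:
            raise ValueError("need at least one replicate")
        if self.pct_R_sd < 0:
            raise ValueError("SD must be ≥ 0")


@dataclass(frozen=True)
class InhibitionKinetics:
    """Pseudo-first-order inhibition rate and derived half-life."""

    k_obs: float  # 1/min
    half_life: float  # min
    r_squared: float

    def __post_init__(self) -> None:
        if not self.k_obs > 0:
            raise ValueError("k_obs must be positive")
        if not math.isclose(self.half_life, math.log(2) / self.k_obs, rel_tol=1e-9):
            raise ValueError("half_life must equal ln(2)/k_obs")


def activity_from_trace(
    times: Sequence[float],
    absorbance: Sequence[float],
    window: Optional[Tuple[float, float]] = None,
) -> float:
    """Enzyme activity as the OLS slope of an absorbance trace (ΔA/min).

    ``window`` restricts the fit to a fixed time interval (inclusive); the
    default is the full trace.  Needs ≥ 3 points with strictly increasing
    times.  A negative slope is allowed but warned about.
    """
    t = np.asarray(times, dtype=float)
    a = np.asarray(absorbance, dtype=float)
    if t.size != a.size:
        raise ValueError("times and absorbance must have equal length")
    if t.size < 3:
        raise ValueError("need at least 3 trace points")
    if not np.all(np.diff(t) > 0):
        raise ValueError("times must be strictly increasing")
    if window is not None:
        mask = (t >= window[0]) & (t <= window[1])
        if mask.sum() < 3:
            raise ValueError("fewer than 3 points in the linear window")
        t, a = t[mask], a[mask]
    slope = stats.linregress(t, a).slope
    if slope < 0:
        warnings.warn(f"negative activity slope {slope:.3g}", stacklevel=2)
    return float(slope)


def percent_reactivation(
    a0: float,
    ai: float,
    ar_raw: float,
    oximolysis: float = 0.0,
) -> float:
    """Percent reactivation %R = [1 − (a0 − ar)/(a0 − ai)] × 100.

    ``ar = ar_raw − oximolysis`` is applied before the formula, subtracting
    the oxime-driven non-enzymatic substrate hydrolysis.  The value is never
    clamped: noise can push it below 0 or above 100 and unbiased replicate
    averaging requires keeping it.
    """
    if not a0 > ai:
        raise ValueError(f"no inhibition window: a0={a0} ≤ ai={ai}")
    ar = ar_raw - oximolysis
    return float((1.0 - (a0 - ar) / (a0 - ai)) * 100.0)


def summarize_reactivation(
    pct_values: Sequence[float],
    oxime: str = "",
    enzyme: str = "",
    concentration: float = float("nan"),
) -> ReactivationResult:
    """Arithmetic mean and sample SD (n−1) of per-replicate %R values.

    With a single replicate the SD is reported as 0 (n=1 carries no spread
    information; ``n_replicates`` flags it).
    """
    values = np.asarray(list(pct_values), dtype=float)
    if values.size < 1:
        raise ValueError("need at least one %R value")
    sd = float(np.std(values, ddof=1)) if values.size > 1 else 0.0
    return ReactivationResult(
        oxime=oxime,
        enzyme=enzyme,
        concentration=concentration,
        pct_R_mean=float(np.mean(values)),
        pct_R_sd=sd,
        n_replicates=int(values.size),
        out_of_range=bool(np.any((values < 0) | (values > 100))),
    )


def reactivation_from_activities(
    measurements: Sequence[ActivityMeasurement],
    oxime: str = "",
    enzyme: str = "",
    concentration: float = float("nan"),
) -> ReactivationResult:
    """%R per replicate from condition-labelled activities, then mean ± SD.

    Replicates are matched by ``replicate_id``; each needs intact, inhibited
    and reactivated activities.  The oximolysis control may be present per
    replicate or shared (a single control applied to every replicate);
    absent controls default to zero correction.
    """
    by_cond: dict = {c: {} for c in CONDITIONS}
    for m in measurements:
        by_cond[m.condition][m.replicate_id] = m.activity
    reps = sorted(by_cond["reactivated"])
    if not reps:
        raise ValueError("no reactivated-condition measurements")
    oxi = by_cond["oximolysis_control"]
    shared_oxi = next(iter(oxi.values())) if len(oxi) == 1 else None
    pct = []
    for r in reps:
        try:
            a0 = by_cond["intact"][r]
            ai = by_cond["inhibited"][r]
        except KeyError as exc:
            raise ValueError(f"replicate {r}: missing condition {exc}") from exc
        correction = oxi.get(r, shared_oxi if shared_oxi is not None else 0.0)
        pct.append(percent_reactivation(a0, ai, by_cond["reactivated"][r], correction))
    return summarize_reactivation(pct, oxime=oxime, enzyme=enzyme, concentration=concentration)


def fit_half_life(
    times: Sequence[float],
    residual_activities: Sequence[float],
) -> InhibitionKinetics:
    """Fit pseudo-first-order inhibition kinetics from a decay time-course.

    The observed rate constant comes from an OLS fit of ln(a(t)/a(0))
    against time; ``half_life = ln 2 / k_obs``.  All activities must be
    positive and the fitted decay must actually decay.
    """
    t = np.asarray(times, dtype=float)
    a = np.asarray(residual_activities, dtype=float)
    if t.size != a.size:
        raise ValueError("times and activities must have equal length")
    if t.size < 3:
        raise ValueError("need at least 3 points")
    if np.any(a <= 0):
        raise ValueError("all activities must be positive for a log-linear fit")
    fit = stats.linregress(t, np.log(a / a[0]))
    k_obs = -fit.slope
    if k_obs <= 0:
        raise ValueError(f"no decay: fitted k_obs = {k_obs:.3g} ≤ 0")
    return InhibitionKinetics(
        k_obs=float(k_obs),
        half_life=float(math.log(2) / k_obs),
        r_squared=float(fit.rvalue**2),
    )


def inhibition_time(kinetics: InhibitionKinetics, n_halflives: float = 7.0) -> dict:
    """Incubation time for a target depth of inhibition.

    Returns ``n_halflives × T_1/2`` minutes together with the residual
    activity fraction 2^(−n_halflives); seven half-lives (the default)
    leave under 1 % residual activity.
    """
    if not kinetics.half_life > 0:
        raise ValueError("half_life must be positive")
    return {
        "minutes": float(n_halflives * kinetics.half_life),
        "residual_fraction": float(2.0 ** (-n_halflives)),
        "n_halflives": float(n_halflives),
    }
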