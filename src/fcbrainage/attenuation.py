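"""Brain-age attenuation: the longitudinal primary outcome.

At baseline, predicted brain age is regressed on chronological age; the
fitted line is the cohort's expected aging trajectory.  Each subject's
expected follow-up brain age advances their baseline prediction along that
trajectory by their own inter-scan interval:

    expected_t18 = predicted_t0 + slope * dt_years

Brain-age attenuation is expected minus observed follow-up brain age;
positive values mean slowed brain aging.  A bias-corrected brain-age-gap
variant (residual of predicted-minus-chronological on chronological age)
is provided; the difference of corrected gaps is nearly identical to the
primary measure whenever inter-scan intervals are similar across subjects.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = [
    "TrajectoryFit",
    "AttenuationRecord",
    "BiasCorrection",
    "SlopeEstimate",
    "fit_trajectory",
    "expected_age_t18",
    "brain_age_attenuation",
    "fit_bias_correction",
    "bias_corrected_gap",
    "attenuation_from_gaps",
    "months_per_percent",
    "attenuation_records",
]

MONTHS_PER_YEAR = 12.0


@dataclass(frozen=True)
class TrajectoryFit:
    """OLS of predicted brain age on chronological age at baseline."""

    intercept: float
    slope: float
    n: int
    residual_sd: float


@dataclass(frozen=True)
class BiasCorrection:
    """OLS of the brain-age gap on chronological age (bias regression)."""

    intercept: float
    slope: float
    n: int


@dataclass(frozen=True)
class AttenuationRecord:
    subject_id: str
    predicted_t0: float
    predicted_t18: float
    chronological_t0: float
    dt_months: float
    expected_t18: float
    attenuation_years: float
    gap_corrected_t0: float | None = None
    gap_corrected_t18: float | None = None

    @property
    def attenuation_months(self) -> float:
        return MONTHS_PER_YEAR * self.attenuation_years


@dataclass(frozen=True)
class SlopeEstimate:
    """OLS slope with a two-sided confidence interval."""

    slope: float
    stderr: float
    ci_low: float
    ci_high: float
    r: float
    p: float
    n: int


def fit_trajectory(chronological_t0, predicted_t0) -> TrajectoryFit:
    """Expected aging trajectory: OLS of predicted on chronological age."""
    x = np.asarray(chronological_t0, dtype=float).ravel()
    y = np.asarray(predicted_t0, dtype=float).ravel()
    if len(x) != len(y):
        raise ValueError("chronological and predicted lengths differ")
    if len(x) < 3:
        raise ValueError("need at least 3 subjects")
    if np.ptp(x) == 0:
        raise ValueError("chronological ages are constant")
    res = stats.linregress(x, y)
    resid = y - (res.intercept + res.slope * x)
    dof = max(len(x) - 2, 1)
    return TrajectoryFit(
        intercept=float(res.intercept),
        slope=float(res.slope),
        n=len(x),
        residual_sd=float(np.sqrt(np.sum(resid**2) / dof)),
    )


def expected_age_t18(
    predicted_t0,
    dt_months,
    fit: TrajectoryFit,
    method: str = "advance",
    chronological_t0=None,
) -> np.ndarray:
    """Expected brain age at follow-up.

    ``method="advance"`` (default): the subject advances along the cohort
    trajectory from their own baseline prediction,
    ``predicted_t0 + slope * dt_years``.  ``method="regress"`` is a
    sensitivity variant that projects chronological age through the full
    regression, ``intercept + slope * (chronological_t0 + dt_years)``.
    """
    p0 = np.asarray(predicted_t0, dtype=float)
    dt = np.asarray(dt_months, dtype=float)
    if np.any(dt <= 0):
        raise ValueError("dt_months must be positive")
    dt_years = dt / MONTHS_PER_YEAR
    if method == "advance":
        return p0 + fit.slope * dt_years
    if method == "regress":
        if chronological_t0 is None:
            raise ValueError("method='regress' requires chronological_t0")
        a0 = np.asarray(chronological_t0, dtype=float)
        return fit.intercept + fit.slope * (a0 + dt_years)
    raise ValueError("method must be 'advance' or 'regress'")


def brain_age_attenuation(expected_t18, observed_t18) -> dict[str, np.ndarray]:
    """Attenuation = expected minus observed follow-up brain age.

    Positive = slowed aging (observed younger than expected); negative =
    acceleration.  Returned in both years and months (months = 12 x years).
    """
    e = np.asarray(expected_t18, dtype=float)
    o = np.asarray(observed_t18, dtype=float)
    if not (np.all(np.isfinite(e)) and np.all(np.isfinite(o))):
        raise ValueError("expected/observed ages must be finite")
    years = e - o
    return {"years": years, "months": MONTHS_PER_YEAR * years}


def fit_bias_correction(predicted, chronological) -> BiasCorrection:
    """Fit the bias regression of the gap (predicted - chronological) on
    chronological age."""
    p = np.asarray(predicted, dtype=float).ravel()
    a = np.asarray(chronological, dtype=float).ravel()
    if len(p) != len(a):
        raise ValueError("length mismatch")
    if len(p) < 3:
        raise ValueError("need at least 3 subjects")
    if np.ptp(a) == 0:
        raise ValueError("chronological ages are constant")
    res = stats.linregress(a, p - a)
    return BiasCorrection(
        intercept=float(res.intercept), slope=float(res.slope), n=len(a)
    )


def bias_corrected_gap(
    predicted,
    chronological,
    correction: BiasCorrection | None = None,
) -> np.ndarray:
    """Bias-corrected brain-age gap.

    gap = predicted - chronological, minus the linear age trend.  When
    ``correction`` is None the trend is fit on the data supplied (the
    output then has mean 0 and exactly zero correlation with age); pass a
    baseline-fitted :class:`BiasCorrection` to apply the same correction
    to a later timepoint.
    """
    p = np.asarray(predicted, dtype=float).ravel()
    a = np.asarray(chronological, dtype=float).ravel()
    if len(p) != len(a):
        raise ValueError("length mismatch")
    if correction is None:
        correction = fit_bias_correction(p, a)
    return (p - a) - (correction.intercept + correction.slope * a)


def attenuation_from_gaps(gap_corrected_t0, gap_corrected_t18) -> np.ndarray:
    """Corrected-gap difference, signed to match the primary measure:
    a shrinking corrected gap (T0 minus T18) is attenuation."""
    g0 = np.asarray(gap_corrected_t0, dtype=float).ravel()
    g18 = np.asarray(gap_corrected_t18, dtype=float).ravel()
    if len(g0) != len(g18):
        raise ValueError("length mismatch")
    return g0 - g18


def months_per_percent(
    attenuation_months,
    weight_change_pct,
    conf_level: float = 0.95,
) -> SlopeEstimate:
    """OLS slope of attenuation (months) on percent weight LOST.

    ``weight_change_pct`` is signed (negative = loss); the regression uses
    -weight_change_pct so that loss sits on the positive x-axis and the
    slope reads as months of attenuation per 1% of body weight lost.
    """
    y = np.asarray(attenuation_months, dtype=float).ravel()
    x = -np.asarray(weight_change_pct, dtype=float).ravel()
    if len(x) != len(y):
        raise ValueError("length mismatch")
    if len(x) < 3:
        raise ValueError("need at least 3 subjects")
    if np.ptp(x) == 0:
        raise ValueError("weight change is constant")
    res = stats.linregress(x, y)
    dof = len(x) - 2
    tcrit = stats.t.ppf(0.5 + conf_level / 2.0, dof)
    half = tcrit * res.stderr
    return SlopeEstimate(
        slope=float(res.slope),
        stderr=float(res.stderr),
        ci_low=float(res.slope - half),
        ci_high=float(res.slope + half),
        r=float(res.rvalue),
        p=float(res.pvalue),
        n=len(x),
    )


def attenuation_records(
    subject_ids,
    chronological_t0,
    predicted_t0,
    predicted_t18,
    dt_months,
    fit: TrajectoryFit | None = None,
    reuse_t0_bias: bool = True,
) -> list[AttenuationRecord]:
    """Full per-subject attenuation table.

    The bias-corrected gaps are computed with the T0-fitted bias
    regression reused at T18 by default (``reuse_t0_bias=False`` refits
    the bias regression at each timepoint).
    """
    a0 = np.asarray(chronological_t0, dtype=float).ravel()
    p0 = np.asarray(predicted_t0, dtype=float).ravel()
    p18 = np.asarray(predicted_t18, dtype=float).ravel()
    dt = np.asarray(dt_months, dtype=float).ravel()
    n = len(a0)
    if not (len(p0) == len(p18) == len(dt) == len(subject_ids) == n):
        raise ValueError("all per-subject arrays must share one length")
    if fit is None:
        fit = fit_trajectory(a0, p0)
    expected = expected_age_t18(p0, dt, fit)
    att = brain_age_attenuation(expected, p18)["years"]
    corr0 = fit_bias_correction(p0, a0)
    g0 = bias_corrected_gap(p0, a0, corr0)
    a18 = a0 + dt / MONTHS_PER_YEAR
    g18 = bias_corrected_gap(
        p18, a18, corr0 if reuse_t0_bias else None
    )
    return [
        AttenuationRecord(
            subject_id=str(sid),
            predicted_t0=float(p0[i]),
            predicted_t18=float(p18[i]),
            chronological_t0=float(a0[i]),
            dt_months=float(dt[i]),
            expected_t18=float(expected[i]),
            attenuation_years=float(att[i]),
            gap_corrected_t0=float(g0[i]),
            gap_corrected_t18=float(g18[i]),
        )
        for i, sid in enumerate(subject_ids)
    ]
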