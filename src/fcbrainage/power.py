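"""Effect-size conversions and power arithmetic for correlation tests.

The chain implemented here converts a published two-sample t statistic to
Cohen's d and the effect-size correlation r, then carries r through the
Fisher-z approximation to statistical power, minimal sample size, and the
minimal detectable effect at a given n:

    d = 2 t / sqrt(df)            r = sign(t) sqrt(t^2 / (t^2 + df))
    r = d / sqrt(d^2 + 4)         d = 2 r / sqrt(1 - r^2)
    power = Phi(|atanh r| sqrt(n - 3) - z_{1 - alpha/2})

Two-sided tests throughout.  The tiny wrong-tail probability and the
small-sample bias term atanh(r) + r / (2 (n - 1)) are omitted by default
and available by flag.
"""

from __future__ import annotations

import math

from scipy import stats

__all__ = [
    "t_to_d",
    "t_to_r",
    "d_to_r",
    "r_to_d",
    "corr_power",
    "corr_sample_size",
    "required_effect_d",
]


def t_to_d(t: float, df: float) -> float:
    """Cohen's d from an independent-samples t statistic: d = 2t/sqrt(df)."""
    if df < 1:
        raise ValueError("df must be >= 1")
    return 2.0 * t / math.sqrt(df)


def t_to_r(t: float, df: float) -> float:
    """Effect-size correlation from t: r = sqrt(t^2/(t^2+df)), signed by t."""
    if df < 1:
        raise ValueError("df must be >= 1")
    return math.copysign(math.sqrt(t * t / (t * t + df)), t)


def d_to_r(d: float) -> float:
    """r = d / sqrt(d^2 + 4)."""
    return d / math.sqrt(d * d + 4.0)


def r_to_d(r: float) -> float:
    """d = 2 r / sqrt(1 - r^2)."""
    if abs(r) >= 1:
        raise ValueError("|r| must be < 1")
    return 2.0 * r / math.sqrt(1.0 - r * r)


def _atanh_effect(r: float, n: int, bias_correction: bool) -> float:
    z = math.atanh(abs(r))
    if bias_correction:
        z += abs(r) / (2.0 * (n - 1))
    return z


def corr_power(
    r: float,
    n: int,
    alpha: float = 0.05,
    bias_correction: bool = False,
    include_other_tail: bool = False,
) -> float:
    """Power of the two-sided test that a Pearson correlation is zero,
    via the Fisher-z approximation."""
    if n < 4:
        raise ValueError("n must be >= 4")
    if not 0 < abs(r) < 1:
        raise ValueError("need 0 < |r| < 1")
    if not 0 < alpha < 1:
        raise ValueError("alpha must lie in (0, 1)")
    za = stats.norm.ppf(1.0 - alpha / 2.0)
    shift = _atanh_effect(r, n, bias_correction) * math.sqrt(n - 3)
    power = stats.norm.cdf(shift - za)
    if include_other_tail:
        power += stats.norm.cdf(-shift - za)
    return float(power)


def corr_sample_size(
    r: float,
    alpha: float = 0.05,
    power: float = 0.95,
    **power_kwargs,
) -> int:
    """Smallest n with corr_power(r, n, alpha) >= power.

    Seeded by the closed form ceil(((z_{1-alpha/2} + z_power)/atanh r)^2
    + 3) and then verified/adjusted by direct power evaluation, so the
    returned n is the exact integer inverse of :func:`corr_power`.
    """
    if not 0 < abs(r) < 1:
        raise ValueError("need 0 < |r| < 1")
    if not 0 < power < 1:
        raise ValueError("power must lie in (0, 1)")
    za = stats.norm.ppf(1.0 - alpha / 2.0)
    zb = stats.norm.ppf(power)
    n = max(4, math.ceil(((za + zb) / math.atanh(abs(r))) ** 2 + 3))
    while n > 4 and corr_power(r, n - 1, alpha, **power_kwargs) >= power:
        n -= 1
    while corr_power(r, n, alpha, **power_kwargs) < power:
        n += 1
    return n


def required_effect_d(
    n: int,
    alpha: float = 0.05,
    power: float = 0.90,
    tol: float = 1e-10,
    **power_kwargs,
) -> float:
    """Minimal Cohen's d detectable with the given n, alpha and power.

    Solves corr_power(r, n, alpha) = power for r by monotone bisection
    (power is strictly increasing in |r|), then converts r to d.
    """
    if n < 4:
        raise ValueError("n must be >= 4")
    if not 0 < power < 1:
        raise ValueError("power must lie in (0, 1)")
    hi = 1.0 - 1e-12
    if corr_power(hi, n, alpha, **power_kwargs) < power:
        raise ValueError("requested power unattainable at this n")
    lo = 1e-12
    if corr_power(lo, n, alpha, **power_kwargs) >= power:
        return 0.0
    while hi - lo > tol:
        mid = 0.5 * (lo + hi)
        if corr_power(mid, n, alpha, **power_kwargs) >= power:
            hi = mid
        else:
            lo = mid
    return r_to_d(0.5 * (lo + hi))
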