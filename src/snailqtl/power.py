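"""Power to detect a trait locus inside a candidate marker interval.

Noncentral chi-square power calculation in the Hu & Xu style: the likelihood
ratio test of a single-locus effect has, under the alternative, a noncentral
chi-square distribution whose noncentrality grows with sample size and the
proportion of trait variance the locus explains, attenuated by the
information loss from testing at markers rather than at the locus itself.
With the locus in the worst case centred in an interval of width w cM, the
nearest flanking marker sits w/2 away, contributing a squared-correlation
attenuation (1 - 2 r)^2 with r the Haldane fraction of w/2:

    lambda = n (1 - 2 r)^2 h^2 / (1 - h^2),
    power  = P[ chi^2_1(lambda) > chi^2_{1, 1 - alpha} ].

One degree of freedom corresponds to the single transmission contrast of a
fully penetrant dominant locus in this cross. Power is monotone increasing
in n and h^2 and decreasing in interval width and alpha stringency; h^2 = 1
is the fully deterministic limit (power 1), h^2 = 0 recovers the test size.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

from scipy import stats

from .sim import haldane_r

__all__ = ["PowerSpec", "qtl_power", "power_threshold_h2"]

_DF = 1


@dataclass(frozen=True)
class PowerSpec:
    n: int = 75
    h2: float = 1.0
    interval_cm: float = 5.0
    alpha: float = 0.01

    def __post_init__(self):
        if self.n < 2:
            raise ValueError("n must be >= 2")
        if not 0.0 <= self.h2 <= 1.0:
            raise ValueError("h2 must lie in [0, 1]")
        if not 0.0 < self.alpha < 1.0:
            raise ValueError("alpha must lie in (0, 1)")
        if self.interval_cm < 0:
            raise ValueError("interval_cm must be non-negative")


def qtl_power(spec: PowerSpec) -> float:
    """Probability of detecting the locus at significance level alpha."""
    if spec.h2 >= 1.0:
        return 1.0  # noncentrality diverges: detection is certain
    crit = stats.chi2.ppf(1.0 - spec.alpha, _DF)
    if spec.h2 <= 0.0:
        return float(stats.chi2.sf(crit, _DF))  # central case: the test size
    atten = (1.0 - 2.0 * haldane_r(spec.interval_cm / 2.0)) ** 2
    lam = spec.n * atten * spec.h2 / (1.0 - spec.h2)
    return float(stats.ncx2.sf(crit, _DF, lam))


def power_threshold_h2(n: int, interval_cm: float, alpha: float,
                       power_target: float, grid_step: float = 0.01) -> float | None:
    """Smallest trait variance (as a percentage, scanned on a 1% grid) at
    which power, rounded to the nearest percent, reaches ``power_target``.

    Returns the threshold in percent, or None (with a warning) if no h^2 on
    the grid attains the target.
    """
    if not 0.0 <= power_target <= 1.0:
        raise ValueError("power_target must lie in [0, 1]")
    target_pct = round(100.0 * power_target)
    steps = int(round(1.0 / grid_step))
    for i in range(0, steps + 1):
        h2 = i / steps
        p = qtl_power(PowerSpec(n=n, h2=h2, interval_cm=interval_cm, alpha=alpha))
        if round(100.0 * p) >= target_pct:
            return 100.0 * i / steps
    warnings.warn(f"power target {power_target:.2f} unattainable at n={n}, "
                  f"interval={interval_cm} cM, alpha={alpha}")
    return None
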