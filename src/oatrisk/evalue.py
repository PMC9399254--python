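"""E-value quantitative bias analysis for unmeasured confounding.

The E-value is the minimum strength of association, on the risk-ratio
scale, that an unmeasured confounder would need with both treatment and
outcome — above and beyond the measured covariates — to fully explain an
observed ratio.  For an estimate RR (inverted first if protective, so
RR* >= 1):

    E = RR* + sqrt(RR* (RR* - 1))

The companion E-value for the confidence limit closer to the null is 1
when the interval crosses the null.  Rate ratios are assessed on the
risk-ratio scale directly.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


@dataclass(frozen=True)
class EValueResult:
    rr: float
    ci_low: float | None
    ci_high: float | None
    e_value: float
    e_value_ci: float | None


def _point_e(rr: float) -> float:
    star = rr if rr >= 1.0 else 1.0 / rr
    return float(star + np.sqrt(star * (star - 1.0)))


def e_value(
    rr: float, ci_low: float | None = None, ci_high: float | None = None
) -> EValueResult:
    """E-values for a ratio estimate and (optionally) its 95% CI.

    ``rr`` must be positive and, when given, ``ci_low <= rr <= ci_high``.
    The CI E-value is computed on whichever limit lies nearer the null
    (RR = 1) and equals 1 when the interval contains the null.
    """
    if rr <= 0:
        raise ValueError("rr must be positive")
    if ci_low is not None and ci_high is not None:
        if ci_low <= 0 or ci_high <= 0:
            raise ValueError("confidence limits must be positive")
        if not (ci_low <= rr <= ci_high):
            raise ValueError("rr must lie inside [ci_low, ci_high]")
    e_point = _point_e(rr)
    e_ci = None
    if ci_low is not None and ci_high is not None:
        if ci_low <= 1.0 <= ci_high:
            e_ci = 1.0
        else:
            limit = ci_low if rr >= 1.0 else ci_high
            e_ci = _point_e(limit)
    return EValueResult(rr, ci_low, ci_high, e_point, e_ci)
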