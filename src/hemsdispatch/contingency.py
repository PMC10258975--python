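"""2x2 contingency-table odds ratio with Woolf confidence interval.

This closed form is the oracle primitive behind the logistic screens:
for a single binary group indicator the logistic MLE of the odds ratio
equals the cross-product ratio, and the Wald CI equals the Woolf CI
exp(ln OR +/- 1.96 * sqrt(1/a + 1/b + 1/c + 1/d)).
"""

from __future__ import annotations

import math

__all__ = ["odds_ratio_2x2"]


def odds_ratio_2x2(
    a: float, b: float, c: float, d: float
) -> tuple[float, tuple[float, float]]:
    """Odds ratio and Woolf 95% CI for the table [[a, b], [c, d]].

    ``a``/``b`` are group-1 successes/failures, ``c``/``d`` group-2
    (reference) successes/failures, so OR = (a*d)/(b*c).  When any cell
    is zero the Haldane-Anscombe +0.5 correction is applied to every
    cell before both the estimate and the CI.

    Raises
    ------
    ValueError
        If any count is negative, or both cells of one margin are zero
        (the odds ratio is then undefined even after correction).
    """
    cells = (a, b, c, d)
    if any(x < 0 for x in cells):
        raise ValueError("counts must be non-negative")
    if a + b == 0 or c + d == 0 or a + c == 0 or b + d == 0:
        raise ValueError("a zero margin leaves the odds ratio undefined")
    if any(x == 0 for x in cells):
        a, b, c, d = (x + 0.5 for x in cells)
    orr = (a * d) / (b * c)
    se = math.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    z = 1.959963984540054  # Phi^-1(0.975)
    log_or = math.log(orr)
    return orr, (math.exp(log_or - z * se), math.exp(log_or + z * se))
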