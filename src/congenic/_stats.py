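"""Empirical-Bayes variance shrinkage for the moderated two-sample t-test.

Per-probe-set sample variances s_g^2 (pooled across the two groups, d degrees
of freedom each) are modelled as draws from a scaled-inverse-chi-square prior
with d0 degrees of freedom and scale s0^2.  The prior parameters are estimated
by moment matching on z_g = log(s_g^2): under the model z_g follows a shifted
log-F distribution whose first two moments have digamma/trigamma closed forms,

    E[z_g]   = log(s0^2) + psi(d0/2) - log(d0/2) - (psi(d/2) - log(d/2))
    Var[z_g] = psi'(d/2) + psi'(d0/2)

so d0 solves psi'(d0/2) = Var(z) - psi'(d/2) (inverted by Newton iteration)
and s0^2 follows from the mean equation.  The posterior variance

    s~_g^2 = (d0 * s0^2 + d * s_g^2) / (d0 + d)

replaces s_g^2 in the t statistic, which then has d0 + d degrees of freedom.
When the moment equations have no finite solution (sample log-variance spread
no larger than its pure-sampling expectation, Var(z) <= psi'(d/2)), shrinkage
is degenerate and the caller is told to fall back to the ordinary pooled test.
"""

from __future__ import annotations

from typing import NamedTuple

import numpy as np
from scipy import special

__all__ = ["VariancePrior", "estimate_variance_prior", "trigamma_inverse"]


def trigamma_inverse(x: float, tol: float = 1e-10, max_iter: int = 100) -> float:
    """Solve psi'(y) = x for y > 0 by Newton iteration on 1/y.

    psi'(y) ~ 1/y for large y and ~ 1/y^2 as y -> 0, so iterating
    y <- y * (1 + y * (psi'(y) - x) / (y^2 * psi''(y))) converges quickly from
    the large-y start y0 = 0.5 + 1/x.
    """
    if x <= 0:
        raise ValueError(f"trigamma_inverse requires x > 0, got {x}")
    if x > 1e7:  # psi'(y) ~ 1/y^2 near zero
        return 1.0 / np.sqrt(x)
    if x < 1e-6:  # psi'(y) ~ 1/y for large y
        return 1.0 / x
    y = 0.5 + 1.0 / x
    for _ in range(max_iter):
        tri = special.polygamma(1, y)
        dif = tri * (1.0 - tri / x) / special.polygamma(2, y)
        y += dif
        if abs(dif) < tol * y:
            break
    return float(y)


class VariancePrior(NamedTuple):
    d0: float          # prior degrees of freedom (inf if not estimable)
    s0_squared: float  # prior variance scale
    finite: bool       # True iff the moment equations had a finite solution


def estimate_variance_prior(s2: np.ndarray, df: float) -> VariancePrior:
    """Moment-match the scaled-inverse-chi-square prior on sample variances.

    Parameters
    ----------
    s2
        Per-probe-set pooled sample variances (zero/non-finite entries are
        excluded from the moment estimation but may still be shrunk later).
    df
        Residual degrees of freedom of each sample variance (n1 + n2 - 2).
    """
    s2 = np.asarray(s2, dtype=float)
    ok = np.isfinite(s2) & (s2 > 0)
    if ok.sum() < 2:
        return VariancePrior(np.inf, float(np.nanmean(s2)) if s2.size else np.nan, False)
    z = np.log(s2[ok])
    e = z - special.digamma(df / 2.0) + np.log(df / 2.0)
    e_mean = float(np.mean(e))
    e_var = float(np.var(e, ddof=1))
    excess = e_var - float(special.polygamma(1, df / 2.0))
    if excess <= 0:
        # Observed spread of log-variances is within pure sampling noise:
        # no finite-d0 solution exists.
        return VariancePrior(np.inf, float(np.exp(e_mean)), False)
    d0 = 2.0 * trigamma_inverse(excess)
    s0_sq = float(np.exp(e_mean + special.digamma(d0 / 2.0) - np.log(d0 / 2.0)))
    return VariancePrior(d0, s0_sq, True)
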