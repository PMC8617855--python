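"""Power and sample-size formulas for concordance trials.

Both objectives share one structure: the per-subject difference of mean
concordance scores is asymptotically normal, its variance under the design
alternative is an explicit function of the marginal concordance rate, the
number of readers m, and the component correlations, and the power
function inverts in closed form.

Objective 1 (device non-inferior to the radiologist panel, margin delta1,
designed at the alternative ps = pr):

    sigma1^2 = var(s_i) + var(r_i) - 2 rho1 sqrt(var(s_i) var(r_i))
    var(s_i) = pr(1-pr) [1/m + (m-1) rho_ss / m]
    var(r_i) = pr(1-pr) [2/(m(m-1)) + 4(m-2) rho_r1/(m(m-1))
                          + (m-2)(m-3) rho_r2/(m(m-1))]
    power(n) = Phi_bar( [z_{1-a} sqrt(sigma1^2 + delta1^2)
                         - sqrt(n) delta1] / sigma1 )
    n = ceil( (z_{1-a} sqrt(sigma1^2+delta1^2) + z_{1-b} sigma1)^2
              / delta1^2 )

Objective 2 (device--senior rate px exceeds device--junior rate py = px -
delta2; two-sided level alpha) is identical with sigma2^2 built from
var(x_i), var(y_i), rho2 and z_{1-a/2} in place of z_{1-a}.  The power
expression uses only the near-tail rejection region, as is standard for a
two-sided test at realistic effect sizes.

Normal quantiles are computed to machine precision and sample sizes are
rounded up; this reproduces the trial-size tables of the numerical studies
exactly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from scipy.stats import norm

from .correlations import (
    ComponentCorrelations1,
    ComponentCorrelations2,
    _rfac,
    _sfac,
    rho1_from_components,
    rho2_from_components,
    solve_components_obj1,
    solve_components_obj2,
)

__all__ = [
    "Design1Spec",
    "Design2Spec",
    "sigma1_sq",
    "power_objective1",
    "samplesize_objective1",
    "sigma2_sq",
    "power_objective2",
    "samplesize_objective2",
]


def _check_common(alpha: float, power: float) -> None:
    if not 0.0 < alpha < 0.5:
        raise ValueError(f"alpha must be in (0, 0.5), got {alpha}")
    if not 0.5 < power < 1.0:
        raise ValueError(f"target power must be in (0.5, 1), got {power}")


@dataclass(frozen=True)
class Design1Spec:
    """Design parameters for the device-vs-panel non-inferiority trial.

    Component correlations may be given explicitly; otherwise they are
    solved from ``rho1_target`` under the standard offset constraints
    (see :func:`concord.correlations.solve_components_obj1`).  When both
    are given the explicit components win and the implied rho1 is used.
    """

    pr: float
    delta1: float
    m: int = 10
    alpha: float = 0.05
    power: float = 0.8
    components: ComponentCorrelations1 | None = None
    rho1_target: float | None = None

    def __post_init__(self) -> None:
        _check_common(self.alpha, self.power)
        if not 0.0 < self.pr < 1.0:
            raise ValueError(f"pr must be in (0, 1), got {self.pr}")
        if not 0.0 < self.delta1 < self.pr:
            raise ValueError(
                f"similarity margin delta1 must satisfy 0 < delta1 < pr, "
                f"got delta1={self.delta1}, pr={self.pr}"
            )
        if self.components is None and self.rho1_target is None:
            raise ValueError("give either components or rho1_target")
        if self.components is not None and self.components.m != self.m:
            raise ValueError(
                f"components solved for m={self.components.m}, design has m={self.m}"
            )

    def resolved_components(self) -> ComponentCorrelations1:
        if self.components is not None:
            return self.components
        return solve_components_obj1(self.rho1_target, self.m)

    @property
    def rho1(self) -> float:
        return rho1_from_components(self.resolved_components())


@dataclass(frozen=True)
class Design2Spec:
    """Design parameters for the senior-vs-junior comparison trial.

    ``delta2`` is the design difference px - py > 0; the variance is
    evaluated at the alternative (py = px - delta2).
    """

    px: float
    delta2: float
    m: int = 5
    alpha: float = 0.05
    power: float = 0.8
    components: ComponentCorrelations2 | None = None
    rho2_target: float | None = None

    def __post_init__(self) -> None:
        _check_common(self.alpha, self.power)
        if not 0.0 < self.delta2 < self.px < 1.0:
            raise ValueError(
                f"need 0 < delta2 < px < 1, got delta2={self.delta2}, px={self.px}"
            )
        if self.components is None and self.rho2_target is None:
            raise ValueError("give either components or rho2_target")
        if self.components is not None and self.components.m != self.m:
            raise ValueError(
                f"components solved for m={self.components.m}, design has m={self.m}"
            )

    def resolved_components(self) -> ComponentCorrelations2:
        if self.components is not None:
            return self.components
        return solve_components_obj2(self.rho2_target, self.m)

    @property
    def rho2(self) -> float:
        return rho2_from_components(self.resolved_components())


def sigma1_sq(spec: Design1Spec) -> float:
    """Asymptotic variance of sqrt(n)(p̂s - p̂r) at the alternative ps = pr."""
    c = spec.resolved_components()
    pq = spec.pr * (1.0 - spec.pr)
    var_s = pq * _sfac(spec.m, c.rho_ss)
    var_r = pq * _rfac(spec.m, c.rho_r1, c.rho_r2)
    rho1 = rho1_from_components(c)
    out = var_s + var_r - 2.0 * rho1 * math.sqrt(var_s * var_r)
    if out <= 0.0:
        raise ValueError(f"infeasible design: sigma1^2 = {out:.6g} <= 0")
    return out


def sigma2_sq(spec: Design2Spec) -> float:
    """Asymptotic variance of sqrt(n)(p̂x - p̂y) at the alternative py = px - delta2."""
    c = spec.resolved_components()
    var_x = spec.px * (1.0 - spec.px) * _sfac(spec.m, c.rho_xx)
    py = spec.px - spec.delta2
    var_y = py * (1.0 - py) * _sfac(spec.m, c.rho_yy)
    rho2 = rho2_from_components(c)
    out = var_x + var_y - 2.0 * rho2 * math.sqrt(var_x * var_y)
    if out <= 0.0:
        raise ValueError(f"infeasible design: sigma2^2 = {out:.6g} <= 0")
    return out


def _power(n: float, sigma_sq: float, delta: float, z_alpha: float) -> float:
    sigma = math.sqrt(sigma_sq)
    arg = (z_alpha * math.sqrt(sigma_sq + delta * delta) - math.sqrt(n) * delta) / sigma
    return float(norm.sf(arg))


def _samplesize_raw(sigma_sq: float, delta: float, z_alpha: float, z_beta: float) -> float:
    sigma = math.sqrt(sigma_sq)
    return (z_alpha * math.sqrt(sigma_sq + delta * delta) + z_beta * sigma) ** 2 / (
        delta * delta
    )


def power_objective1(n: int | float, spec: Design1Spec) -> float:
    """Power of the one-sided Z1 test with n subjects at ps = pr."""
    if n < 1:
        raise ValueError(f"n must be >= 1, got {n}")
    return _power(n, sigma1_sq(spec), spec.delta1, norm.ppf(1.0 - spec.alpha))


def samplesize_objective1(spec: Design1Spec, return_unrounded: bool = False):
    """Smallest subject count reaching the target power for objective 1."""
    raw = _samplesize_raw(
        sigma1_sq(spec),
        spec.delta1,
        norm.ppf(1.0 - spec.alpha),
        norm.ppf(spec.power),
    )
    return raw if return_unrounded else math.ceil(raw)


def power_objective2(n: int | float, spec: Design2Spec) -> float:
    """Power of the two-sided Z2 test with n subjects at px - py = delta2."""
    if n < 1:
        raise ValueError(f"n must be >= 1, got {n}")
    return _power(n, sigma2_sq(spec), spec.delta2, norm.ppf(1.0 - spec.alpha / 2.0))


def samplesize_objective2(spec: Design2Spec, return_unrounded: bool = False):
    """Smallest subject count reaching the target power for objective 2."""
    raw = _samplesize_raw(
        sigma2_sq(spec),
        spec.delta2,
        norm.ppf(1.0 - spec.alpha / 2.0),
        norm.ppf(spec.power),
    )
    return raw if return_unrounded else math.ceil(raw)
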