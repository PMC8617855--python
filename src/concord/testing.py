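"""Z-tests on concordance rates.

Objective 1 tests non-inferiority of the device--radiologist concordance
rate ps against the radiologist--radiologist rate pr with a similarity
margin delta1 > 0:

    H1: ps <= pr - delta1   vs   H̄1: ps > pr - delta1
    Z1 = sqrt(n) (p̂s - p̂r + delta1) / σ̂1,  reject if Z1 > z_{1-α}

with the null-anchored variance σ̂1² = n⁻¹ Σ (s_i - r_i + delta1)² or the
GEE robust (working-independence sandwich) variant
σ̃1² = n⁻¹ Σ (s_i - r_i - (p̂s - p̂r))², the empirical variance of the
per-subject differences; the two are asymptotically identical under H1
because p̂s - p̂r is consistent for ps - pr = -delta1 there.

Objective 2 compares the device's concordance with senior vs junior
radiologists by a standard two-sided test of H2: px = py using
Z2 = sqrt(n) (p̂x - p̂y) / σ̂2 with σ̂2² = n⁻¹ Σ (x_i - y_i)².

Variance divisors are 1/n throughout (not 1/(n-1)), matching the
large-sample estimators the power formulas in :mod:`concord.design`
invert.  A degenerate variance estimate (σ̂ = 0) raises, never returns an
infinite statistic.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass

import numpy as np
from scipy.stats import norm

from .indicators import ConcordanceData1, ConcordanceData2

__all__ = [
    "TestResult",
    "variance_components_obj1",
    "test_objective1",
    "test_objective2",
]

VARIANCE_FLAVORS = ("null_anchored", "gee_robust")

# variance below this is floating-point residue of an exactly-degenerate
# configuration (all per-subject differences identical); real indicator
# data is bounded away from it by orders of magnitude
_DEGENERATE_VAR = 1e-24


@dataclass(frozen=True)
class TestResult:
    """Outcome of a concordance-rate Z-test."""

    objective: int
    statistic: float
    p_value: float
    alpha: float
    critical_value: float
    sidedness: str  # "one_sided_upper" | "two_sided"
    reject: bool
    estimates: dict
    variance_estimate: float
    variance_flavor: str
    n: int

    def to_json(self, **kwargs) -> str:
        return json.dumps(
            {
                "objective": self.objective,
                "statistic": self.statistic,
                "p_value": self.p_value,
                "alpha": self.alpha,
                "critical_value": self.critical_value,
                "sidedness": self.sidedness,
                "reject": self.reject,
                "estimates": self.estimates,
                "variance_estimate": self.variance_estimate,
                "variance_flavor": self.variance_flavor,
                "n": self.n,
            },
            **kwargs,
        )

    def summary(self) -> str:
        """Plain-text summary table of the test."""
        title = (
            "Device vs radiologist-panel concordance (one-sided margin test)"
            if self.objective == 1
            else "Device concordance: senior vs junior radiologists (two-sided)"
        )
        lines = [title, "=" * len(title)]
        for k, v in self.estimates.items():
            lines.append(f"{k:<24s} {v: .6f}")
        lines += [
            f"{'n subjects':<24s} {self.n:d}",
            f"{'Z statistic':<24s} {self.statistic: .6f}",
            f"{'p-value':<24s} {self.p_value: .6g}",
            f"{'critical value':<24s} {self.critical_value: .6f}"
            f"  ({self.sidedness}, alpha={self.alpha})",
            f"{'variance estimate':<24s} {self.variance_estimate: .6g}"
            f"  ({self.variance_flavor})",
            f"{'reject null':<24s} {self.reject}",
        ]
        return "\n".join(lines)


def _check_alpha(alpha: float) -> None:
    if not 0.0 < alpha < 0.5:
        raise ValueError(f"alpha must be in (0, 0.5), got {alpha}")


def variance_components_obj1(data: ConcordanceData1) -> tuple[float, float]:
    """Empirical (divide-by-n) variances of r_i and s_i: (σ̂r², σ̂s²)."""
    if data.n < 2:
        raise ValueError(f"need n >= 2 subjects, got n={data.n}")
    r_i, s_i = data.r_i, data.s_i
    return (
        float(np.mean((r_i - r_i.mean()) ** 2)),
        float(np.mean((s_i - s_i.mean()) ** 2)),
    )


def test_objective1(
    data: ConcordanceData1,
    delta1: float,
    alpha: float = 0.05,
    variance_flavor: str = "null_anchored",
) -> TestResult:
    """One-sided upper Z-test of H1: ps <= pr - delta1."""
    _check_alpha(alpha)
    if delta1 <= 0:
        raise ValueError(f"similarity margin delta1 must be positive, got {delta1}")
    if variance_flavor not in VARIANCE_FLAVORS:
        raise ValueError(
            f"variance_flavor must be one of {VARIANCE_FLAVORS}, got {variance_flavor!r}"
        )
    if data.n < 2:
        raise ValueError(f"need n >= 2 subjects, got n={data.n}")
    r_i, s_i = data.r_i, data.s_i
    pr_hat, ps_hat = float(r_i.mean()), float(s_i.mean())
    d = s_i - r_i + delta1
    if variance_flavor == "null_anchored":
        var = float(np.mean(d**2))
    else:
        var = float(np.mean((s_i - r_i - (ps_hat - pr_hat)) ** 2))
    if var <= _DEGENERATE_VAR:
        raise ValueError(
            "degenerate variance: all per-subject differences s_i - r_i are "
            f"identical ({float((s_i - r_i)[0]):g}); Z1 is undefined"
        )
    z1 = math.sqrt(data.n) * float(d.mean()) / math.sqrt(var)
    crit = float(norm.ppf(1.0 - alpha))
    return TestResult(
        objective=1,
        statistic=z1,
        p_value=float(norm.sf(z1)),
        alpha=alpha,
        critical_value=crit,
        sidedness="one_sided_upper",
        reject=bool(z1 > crit),
        estimates={"ps_hat": ps_hat, "pr_hat": pr_hat, "delta1": delta1},
        variance_estimate=var,
        variance_flavor=variance_flavor,
        n=data.n,
    )


def test_objective2(data: ConcordanceData2, alpha: float = 0.05) -> TestResult:
    """Two-sided Z-test of H2: px = py."""
    _check_alpha(alpha)
    if data.n < 2:
        raise ValueError(f"need n >= 2 subjects, got n={data.n}")
    x_i, y_i = data.x_i, data.y_i
    px_hat, py_hat = float(x_i.mean()), float(y_i.mean())
    d = x_i - y_i
    var = float(np.mean(d**2))
    if var <= _DEGENERATE_VAR:
        raise ValueError(
            "degenerate variance: x_i and y_i coincide on every subject; "
            "Z2 is undefined"
        )
    z2 = math.sqrt(data.n) * float(d.mean()) / math.sqrt(var)
    crit = float(norm.ppf(1.0 - alpha / 2.0))
    return TestResult(
        objective=2,
        statistic=z2,
        p_value=float(2.0 * norm.sf(abs(z2))),
        alpha=alpha,
        critical_value=crit,
        sidedness="two_sided",
        reject=bool(abs(z2) > crit),
        estimates={"px_hat": px_hat, "py_hat": py_hat},
        variance_estimate=var,
        variance_flavor="null_anchored",
        n=data.n,
    )
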