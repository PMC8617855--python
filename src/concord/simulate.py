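"""Correlated binary concordance data via latent-Gaussian dichotomisation.

The Monte-Carlo studies need vectors of binary concordance indicators with
prescribed marginal success probabilities and prescribed pairwise
correlations (the component correlations of :mod:`concord.correlations`).
They are generated by thresholding a multivariate standard normal vector:
indicator k equals 1 iff Z_k > tau_k where tau_k is the upper-tail normal
quantile of its marginal.  For each indicator pair the latent normal
correlation is solved exactly (Emrich & Piedmonte style) so that the
induced *binary* correlation hits its target:

    Phi2(tau_j, tau_k; rho*) = rho_b sqrt(p_j q_j p_k q_k) + p_j p_k

where Phi2 is the bivariate standard normal upper-orthant probability.
Pairwise targets are matched essentially exactly; joint higher-order
structure is whatever the Gaussian copula implies and is not asserted.

The pairwise-solved latent matrix can be marginally non-positive-definite;
it is repaired by clipping eigenvalues at 1e-10 and re-normalising to unit
diagonal.  The largest entry perturbation is recorded on the model and a
warning is raised when it exceeds 0.01.

Note that concordance indicators generated this way need not be logically
transitive (r_12 = r_13 = 1 does not force r_23 = 1); the indicators are
simulated directly, which is exactly what the asymptotic theory consumes.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
from scipy.optimize import brentq
from scipy.stats import multivariate_normal, norm

from .correlations import ComponentCorrelations1, ComponentCorrelations2
from .indicators import ConcordanceData1, ConcordanceData2, reader_pairs

__all__ = [
    "IndicatorLayout",
    "LatentModel",
    "binary_corr_bounds",
    "solve_latent_correlation",
    "assemble_layout",
    "simulate_dataset",
    "simulate_readings",
]


def binary_corr_bounds(p_j: float, p_k: float) -> tuple[float, float]:
    """Feasible range of the correlation of two Bernoulli(p_j), Bernoulli(p_k).

    The bounds come from the Frechet limits on the joint success
    probability.
    """
    q_j, q_k = 1.0 - p_j, 1.0 - p_k
    lo = max(-math.sqrt(p_j * p_k / (q_j * q_k)), -math.sqrt(q_j * q_k / (p_j * p_k)))
    hi = min(math.sqrt(p_j * q_k / (p_k * q_j)), math.sqrt(p_k * q_j / (p_j * q_k)))
    return lo, hi


def solve_latent_correlation(p_j: float, p_k: float, rho_b: float) -> float:
    """Latent normal correlation inducing binary correlation rho_b.

    Solves the upper-orthant equation by bracketed Brent root finding; the
    induced binary correlation matches ``rho_b`` to ~1e-8 or better.
    """
    for p in (p_j, p_k):
        if not 0.0 < p < 1.0:
            raise ValueError(f"marginal {p} outside (0, 1)")
    if rho_b == 0.0:
        return 0.0
    lo, hi = binary_corr_bounds(p_j, p_k)
    if not lo < rho_b < hi:
        raise ValueError(
            f"binary correlation {rho_b} infeasible for marginals "
            f"({p_j}, {p_k}); feasible range is ({lo:.6f}, {hi:.6f})"
        )
    t_j, t_k = norm.isf(p_j), norm.isf(p_k)
    target = rho_b * math.sqrt(p_j * (1 - p_j) * p_k * (1 - p_k)) + p_j * p_k
    edge = 1.0 - 1e-8

    def f(rho: float) -> float:
        # P(Z_j > t_j, Z_k > t_k) = Phi2(-t_j, -t_k; rho); comonotone /
        # antithetic limits (Frechet bounds) near rho = +/-1 where the
        # bivariate CDF is numerically singular
        if rho >= edge:
            orthant = min(p_j, p_k)
        elif rho <= -edge:
            orthant = max(0.0, p_j + p_k - 1.0)
        else:
            orthant = multivariate_normal.cdf(
                [-t_j, -t_k], mean=[0.0, 0.0], cov=[[1.0, rho], [rho, 1.0]]
            )
        return orthant - target

    return brentq(f, -1.0, 1.0, xtol=1e-12)


@dataclass(frozen=True)
class IndicatorLayout:
    """Target marginals and binary correlation matrix for one indicator vector.

    Objective 1 orders the m(m-1)/2 radiologist-pair indicators (pairs
    lexicographic, j < j') before the m device indicators; objective 2
    orders the m device--senior indicators before the m device--junior
    indicators.
    """

    objective: int
    m: int
    labels: tuple[str, ...]
    marginals: np.ndarray
    binary_corr: np.ndarray

    @property
    def dimension(self) -> int:
        return len(self.labels)

    @property
    def n_pair_indicators(self) -> int:
        """Number of leading r-pair columns (objective 1 only)."""
        return self.m * (self.m - 1) // 2 if self.objective == 1 else 0


def assemble_layout(
    objective: int,
    m: int,
    marginals: tuple[float, float],
    components: ComponentCorrelations1 | ComponentCorrelations2,
) -> IndicatorLayout:
    """Build the full target correlation matrix from the component classes.

    Objective 1 (marginals = (pr, ps)): entries are rho_r1 / rho_r2 for
    r-pair columns sharing one / no reader, rho_s1 / rho_s2 for an r-pair
    against a device indicator inside / outside the pair, rho_ss between
    device indicators.  Objective 2 (marginals = (px, py)): rho_xx within
    seniors, rho_yy within juniors, rho_xy across.

    Every entry is checked against the binary feasibility bounds of its
    marginal pair.
    """
    if objective not in (1, 2):
        raise ValueError(f"objective must be 1 or 2, got {objective}")
    if components.m != m:
        raise ValueError(f"components have m={components.m}, layout asks m={m}")

    if objective == 1:
        pr, ps = marginals
        pairs = reader_pairs(m)
        npair = len(pairs)
        labels = tuple(f"r_{j + 1}_{k + 1}" for j, k in pairs) + tuple(
            f"s_{j + 1}" for j in range(m)
        )
        marg = np.array([pr] * npair + [ps] * m, dtype=float)
        d = npair + m
        corr = np.eye(d)
        for a in range(d):
            for b in range(a + 1, d):
                if a < npair and b < npair:
                    shared = len(set(pairs[a]) & set(pairs[b]))
                    rho = components.rho_r1 if shared == 1 else components.rho_r2
                elif a < npair:
                    j = b - npair
                    rho = (
                        components.rho_s1 if j in pairs[a] else components.rho_s2
                    )
                else:
                    rho = components.rho_ss
                corr[a, b] = corr[b, a] = rho
    else:
        px, py = marginals
        labels = tuple(f"x_{j + 1}" for j in range(m)) + tuple(
            f"y_{j + 1}" for j in range(m)
        )
        marg = np.array([px] * m + [py] * m, dtype=float)
        d = 2 * m
        corr = np.eye(d)
        for a in range(d):
            for b in range(a + 1, d):
                if b < m:
                    rho = components.rho_xx
                elif a >= m:
                    rho = components.rho_yy
                else:
                    rho = components.rho_xy
                corr[a, b] = corr[b, a] = rho

    for p in marg:
        if not 0.0 < p < 1.0:
            raise ValueError(f"marginal {p} outside (0, 1)")
    for a in range(d):
        for b in range(a + 1, d):
            lo, hi = binary_corr_bounds(marg[a], marg[b])
            if not lo <= corr[a, b] <= hi:
                raise ValueError(
                    f"target correlation {corr[a, b]:.6f} for "
                    f"({labels[a]}, {labels[b]}) outside feasible range "
                    f"({lo:.6f}, {hi:.6f})"
                )
    return IndicatorLayout(
        objective=objective, m=m, labels=labels, marginals=marg, binary_corr=corr
    )


@dataclass
class LatentModel:
    """Solved latent-Gaussian generator for an :class:`IndicatorLayout`."""

    layout: IndicatorLayout
    thresholds: np.ndarray
    latent_corr: np.ndarray
    cholesky: np.ndarray
    max_repair_perturbation: float

    @classmethod
    def from_layout(cls, layout: IndicatorLayout) -> "LatentModel":
        d = layout.dimension
        marg = layout.marginals
        latent = np.eye(d)
        cache: dict[tuple[float, float, float], float] = {}
        for a in range(d):
            for b in range(a + 1, d):
                key = (marg[a], marg[b], layout.binary_corr[a, b])
                if key not in cache:
                    cache[key] = solve_latent_correlation(*key)
                latent[a, b] = latent[b, a] = cache[key]
        # eigenvalue-clipping PSD repair
        w, v = np.linalg.eigh(latent)
        repaired = latent
        perturb = 0.0
        if w.min() < 1e-10:
            w = np.clip(w, 1e-10, None)
            repaired = (v * w) @ v.T
            s = np.sqrt(np.diag(repaired))
            repaired = repaired / np.outer(s, s)
            np.fill_diagonal(repaired, 1.0)
            perturb = float(np.abs(repaired - latent).max())
            if perturb > 0.01:
                warnings.warn(
                    f"PSD repair perturbed a latent correlation by {perturb:.4f} "
                    f"(> 0.01); induced binary correlations may drift",
                    stacklevel=2,
                )
        try:
            chol = np.linalg.cholesky(
                repaired + 1e-12 * np.eye(d)
            )
        except np.linalg.LinAlgError as exc:
            raise ValueError(
                "latent correlation matrix is not positive definite even "
                "after eigenvalue-clipping repair"
            ) from exc
        return cls(
            layout=layout,
            thresholds=norm.isf(marg),
            latent_corr=repaired,
            cholesky=chol,
            max_repair_perturbation=perturb,
        )

    def sample(self, n: int, rng: np.random.Generator) -> np.ndarray:
        """(n, dimension) 0/1 indicator array."""
        z = rng.standard_normal((n, self.layout.dimension)) @ self.cholesky.T
        return (z > self.thresholds).astype(np.int8)


def _wrap(layout: IndicatorLayout, x: np.ndarray):
    if layout.objective == 1:
        npair = layout.n_pair_indicators
        return ConcordanceData1(r_indicators=x[:, :npair], s_indicators=x[:, npair:])
    m = layout.m
    return ConcordanceData2(x_indicators=x[:, :m], y_indicators=x[:, m:])


def simulate_dataset(
    layout: IndicatorLayout, n: int, seed: int | np.random.Generator
) -> ConcordanceData1 | ConcordanceData2:
    """Simulate n subjects of correlated binary indicators.

    Deterministic given a seed; per-subject summaries (r_i, s_i or x_i,
    y_i) come from the same reductions used on real data.
    """
    if n < 1:
        raise ValueError(f"n must be >= 1, got {n}")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    model = LatentModel.from_layout(layout)
    return _wrap(layout, model.sample(n, rng))


def simulate_readings(
    n: int,
    m: int,
    categories: tuple[str, ...] = ("oval", "round", "irregular"),
    objective: int = 1,
    classification: str = "Shape",
    seed: int | np.random.Generator = 0,
):
    """Simple i.i.d. categorical reading-table generator (I/O fixture).

    Every reader (device included) draws a label uniformly and
    independently; this exercises the reading-table plumbing but carries
    none of the correlation structure of a real trial, so it is not used
    for operating-characteristic studies.
    """
    import pandas as pd

    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if objective == 1:
        roles = [("device", "AI")] + [
            ("radiologist", f"R{j + 1:02d}") for j in range(m)
        ]
    elif objective == 2:
        roles = (
            [("device", "AI")]
            + [("senior", f"S{j + 1:02d}") for j in range(m)]
            + [("junior", f"J{j + 1:02d}") for j in range(m)]
        )
    else:
        raise ValueError(f"objective must be 1 or 2, got {objective}")
    rows = []
    for i in range(n):
        for role, rid in roles:
            rows.append(
                {
                    "subject_id": f"P{i + 1:04d}",
                    "reader_id": rid,
                    "reader_role": role,
                    "classification": classification,
                    "value": categories[rng.integers(len(categories))],
                }
            )
    return pd.DataFrame(rows)
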