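"""Compound correlation algebra for concordance scores.

Sample-size planning for concordance trials needs the correlation between
the two per-subject mean concordance scores (radiologist--radiologist mean
``r_i`` versus device--radiologist mean ``s_i``, or device--senior ``x_i``
versus device--junior ``y_i``).  That compound correlation is induced by
the pairwise correlations among the underlying binary indicators, which
fall into a small number of structural classes depending on which readers
the two indicators share.

This module provides the forward maps (components -> compound correlation),
the inverse solvers under the offset constraints used in the numerical
studies, and pooled empirical estimation of the components from pilot data.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, fields

import numpy as np
from scipy.optimize import brentq

__all__ = [
    "ComponentCorrelations1",
    "ComponentCorrelations2",
    "rho1_from_components",
    "rho2_from_components",
    "solve_components_obj1",
    "solve_components_obj2",
    "estimate_components_from_pilot",
]


@dataclass(frozen=True)
class ComponentCorrelations1:
    """Pairwise indicator correlations for the device-vs-panel objective.

    Parameters
    ----------
    m : int
        Number of radiologists reading each image (>= 2).
    rho_r1 : float
        corr(r_i12, r_i13): two radiologist-pair indicators sharing one reader.
    rho_r2 : float
        corr(r_i12, r_i34): two radiologist-pair indicators with no shared
        reader (only defined when m >= 4; unused otherwise).
    rho_s1 : float
        corr(r_i12, s_i1): pair indicator and a device indicator whose
        radiologist belongs to the pair.
    rho_s2 : float
        corr(r_i12, s_i3): pair indicator and a device indicator whose
        radiologist is outside the pair (m >= 3).
    rho_ss : float
        corr(s_i1, s_i2): two device--radiologist indicators.
    """

    m: int
    rho_r1: float
    rho_r2: float
    rho_s1: float
    rho_s2: float
    rho_ss: float

    def __post_init__(self) -> None:
        if self.m < 2:
            raise ValueError(f"need m >= 2 radiologists, got m={self.m}")
        for f in fields(self):
            if f.name == "m":
                continue
            v = getattr(self, f.name)
            if not -1.0 < v < 1.0:
                raise ValueError(f"{f.name}={v} outside (-1, 1)")

    def to_dict(self) -> dict:
        return {
            "m": self.m,
            "rho_r1": self.rho_r1,
            "rho_r2": self.rho_r2,
            "rho_s1": self.rho_s1,
            "rho_s2": self.rho_s2,
            "rho_ss": self.rho_ss,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ComponentCorrelations1":
        return cls(**{f.name: d[f.name] for f in fields(cls)})


@dataclass(frozen=True)
class ComponentCorrelations2:
    """Pairwise indicator correlations for the senior-vs-junior objective.

    ``rho_xx`` = corr(x_i1, x_i2) within the senior group, ``rho_yy`` =
    corr(y_i1, y_i2) within the junior group, and ``rho_xy`` =
    corr(x_ij, y_ij') across groups; ``m`` is the number of radiologists
    per experience group.
    """

    m: int
    rho_xx: float
    rho_yy: float
    rho_xy: float

    def __post_init__(self) -> None:
        if self.m < 2:
            raise ValueError(f"need m >= 2 per group, got m={self.m}")
        for name in ("rho_xx", "rho_yy", "rho_xy"):
            v = getattr(self, name)
            if not -1.0 < v < 1.0:
                raise ValueError(f"{name}={v} outside (-1, 1)")

    def to_dict(self) -> dict:
        return {
            "m": self.m,
            "rho_xx": self.rho_xx,
            "rho_yy": self.rho_yy,
            "rho_xy": self.rho_xy,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ComponentCorrelations2":
        return cls(**{f.name: d[f.name] for f in fields(cls)})


def _rfac(m: int, rho_r1: float, rho_r2: float) -> float:
    """Variance inflation factor of the pair-mean r_i: var(r_i)/[p(1-p)]."""
    mm = m * (m - 1)
    return 2.0 / mm + 4.0 * (m - 2) * rho_r1 / mm + (m - 2) * (m - 3) * rho_r2 / mm


def _sfac(m: int, rho_ss: float) -> float:
    """Variance inflation factor of the device-mean s_i: var(s_i)/[p(1-p)]."""
    return 1.0 / m + (m - 1) * rho_ss / m


def rho1_from_components(c: ComponentCorrelations1) -> float:
    """Compound correlation rho1 = corr(r_i, s_i) implied by the components.

    rho1 = [(2/m) rho_s1 + ((m-2)/m) rho_s2]
           / sqrt(_rfac(m, rho_r1, rho_r2) * _sfac(m, rho_ss))

    The marginal concordance rates cancel, so rho1 depends on the component
    correlations and m only.
    """
    m = c.m
    num = (2.0 / m) * c.rho_s1 + ((m - 2.0) / m) * c.rho_s2
    fr = _rfac(m, c.rho_r1, c.rho_r2)
    fs = _sfac(m, c.rho_ss)
    if fr <= 0 or fs <= 0:
        raise ValueError(
            f"infeasible components: variance factors must be positive "
            f"(got r-factor {fr:.6g}, s-factor {fs:.6g})"
        )
    return num / math.sqrt(fr * fs)


def rho2_from_components(c: ComponentCorrelations2) -> float:
    """Compound correlation rho2 = corr(x_i, y_i) implied by the components.

    Every one of the m^2 cross covariances equals
    rho_xy * sqrt(px qx py qy), so cov(x_i, y_i) = rho_xy sqrt(px qx py qy)
    and the marginal-rate factors cancel in the ratio:

    rho2 = rho_xy / sqrt(_sfac(m, rho_xx) * _sfac(m, rho_yy))
    """
    m = c.m
    fx = _sfac(m, c.rho_xx)
    fy = _sfac(m, c.rho_yy)
    if fx <= 0 or fy <= 0:
        raise ValueError(
            f"infeasible components: variance factors must be positive "
            f"(got x-factor {fx:.6g}, y-factor {fy:.6g})"
        )
    return c.rho_xy / math.sqrt(fx * fy)


def solve_components_obj1(
    rho1_target: float,
    m: int,
    offsets: tuple[float, float, float] = (0.1, 0.1, 0.1),
) -> ComponentCorrelations1:
    """Solve the five component correlations that yield a given rho1.

    The five components are under-determined by one scalar target, so the
    solver uses the offset constraints of the numerical studies:

        rho_s1 = rho_s2 + offsets[0]
        rho_r1 = rho_r2 + offsets[1]
        rho_ss = rho_r1 = rho_s1 + offsets[2]

    leaving rho_s2 as the single free parameter, found by Brent root
    finding so that :func:`rho1_from_components` equals ``rho1_target``
    to 1e-10.
    """
    a, b, cc = offsets

    def build(rs2: float) -> ComponentCorrelations1:
        rs1 = rs2 + a
        rss = rs1 + cc
        rr1 = rss
        rr2 = rr1 - b
        return ComponentCorrelations1(
            m=m, rho_r1=rr1, rho_r2=rr2, rho_s1=rs1, rho_s2=rs2, rho_ss=rss
        )

    # Components are rs2 + {0, a, a+cc, a+cc-b}; keep each in (-1, 1) and
    # both variance factors positive.  All constraints are linear in rs2
    # with known sign, so the feasible set is an open interval.
    eps = 1e-9
    shifts = (0.0, a, a + cc, a + cc - b)
    lo = -1.0 + eps - min(shifts)
    hi = 1.0 - eps - max(shifts)
    # _sfac > 0: rs2 + a + cc > -1/(m-1)
    lo = max(lo, -1.0 / (m - 1) - a - cc + eps)
    if m >= 3:
        # _rfac > 0, linear increasing in rs2 for m >= 3
        coef = 4.0 * (m - 2) + (m - 2) * (m - 3)
        const = 2.0 + 4.0 * (m - 2) * (a + cc) + (m - 2) * (m - 3) * (a + cc - b)
        lo = max(lo, -const / coef + eps)
    if lo >= hi:
        raise ValueError(f"offsets {offsets} leave no feasible components at m={m}")

    def f(rs2: float) -> float:
        return rho1_from_components(build(rs2)) - rho1_target

    flo, fhi = f(lo), f(hi)
    if flo * fhi > 0:
        lo_v, hi_v = sorted((flo + rho1_target, fhi + rho1_target))
        raise ValueError(
            f"rho1 target {rho1_target} not attainable under the offset "
            f"constraints at m={m}; attainable range is "
            f"({lo_v:.4f}, {hi_v:.4f})"
        )
    rs2 = brentq(f, lo, hi, xtol=1e-12, rtol=8.9e-16)
    return build(rs2)


def solve_components_obj2(
    rho2_target: float, m: int, offset: float = 0.1
) -> ComponentCorrelations2:
    """Solve (rho_xx, rho_yy, rho_xy) for a given rho2 under rho_xx = rho_yy
    = rho_xy + offset.

    With that constraint the compound formula inverts in closed form:

        rho_xy = rho2 (1/m + offset (m-1)/m) / (1 - rho2 (m-1)/m)
    """
    denom = 1.0 - rho2_target * (m - 1) / m
    if denom <= 0:
        raise ValueError(
            f"rho2 target {rho2_target} too large for m={m}: no solution"
        )
    rho_xy = rho2_target * (1.0 / m + offset * (m - 1) / m) / denom
    rho_xx = rho_xy + offset
    if not (-1.0 < rho_xy < 1.0 and -1.0 < rho_xx < 1.0):
        raise ValueError(
            f"solved components (rho_xx={rho_xx:.4f}, rho_xy={rho_xy:.4f}) "
            f"outside (-1, 1)"
        )
    return ComponentCorrelations2(m=m, rho_xx=rho_xx, rho_yy=rho_xx, rho_xy=rho_xy)


def _pooled_corr(cols: np.ndarray, pairs: list[tuple[int, int]], what: str) -> float:
    """Pearson correlation pooled over index pairs of indicator columns."""
    sd = cols.std(axis=0)
    const = np.flatnonzero(sd == 0)
    if const.size:
        raise ValueError(
            f"cannot estimate {what}: indicator column(s) {const.tolist()} "
            f"are constant"
        )
    corr = np.corrcoef(cols, rowvar=False)
    if corr.ndim == 0:  # single column, no pairs (guarded by callers)
        raise ValueError(f"no indicator pairs available for {what}")
    return float(np.mean([corr[a, b] for a, b in pairs]))


def estimate_components_from_pilot(data):
    """Estimate the component correlations from pilot concordance data.

    For each structural class of indicator pairs the empirical Pearson
    correlation is pooled (averaged) across all index pairs in the class.
    Accepts :class:`~concord.indicators.ConcordanceData1` (returns
    :class:`ComponentCorrelations1`) or
    :class:`~concord.indicators.ConcordanceData2` (returns
    :class:`ComponentCorrelations2`).

    Raises ``ValueError`` if any indicator column is constant (that class's
    correlation is undefined).  Estimates are noisy below n ~ 10 subjects;
    a warning is emitted there.
    """
    import warnings

    from .indicators import ConcordanceData1, ConcordanceData2

    if data.n < 10:
        warnings.warn(
            f"pilot estimation with n={data.n} < 10 subjects is unreliable",
            stacklevel=2,
        )
    if isinstance(data, ConcordanceData1):
        m = data.m
        pairs = data.reader_pairs
        npair = len(pairs)
        r = data.r_indicators.astype(float)
        s = data.s_indicators.astype(float)
        rr_shared, rr_disjoint = [], []
        for a in range(npair):
            for b in range(a + 1, npair):
                if set(pairs[a]) & set(pairs[b]):
                    rr_shared.append((a, b))
                else:
                    rr_disjoint.append((a, b))
        rs_shared, rs_out = [], []
        for a in range(npair):
            for j in range(m):
                (rs_shared if j in pairs[a] else rs_out).append((a, npair + j))
        ss = [(npair + a, npair + b) for a in range(m) for b in range(a + 1, m)]
        cols = np.hstack([r, s])
        kw = dict(m=m)
        kw["rho_r1"] = _pooled_corr(cols, rr_shared, "rho_r1")
        kw["rho_r2"] = (
            _pooled_corr(cols, rr_disjoint, "rho_r2") if rr_disjoint else 0.0
        )
        kw["rho_s1"] = _pooled_corr(cols, rs_shared, "rho_s1")
        kw["rho_s2"] = _pooled_corr(cols, rs_out, "rho_s2") if rs_out else 0.0
        kw["rho_ss"] = _pooled_corr(cols, ss, "rho_ss")
        return ComponentCorrelations1(**kw)
    if isinstance(data, ConcordanceData2):
        m = data.m
        cols = np.hstack(
            [data.x_indicators.astype(float), data.y_indicators.astype(float)]
        )
        xx = [(a, b) for a in range(m) for b in range(a + 1, m)]
        yy = [(m + a, m + b) for a, b in xx]
        xy = [(a, m + b) for a in range(m) for b in range(m)]
        return ComponentCorrelations2(
            m=m,
            rho_xx=_pooled_corr(cols, xx, "rho_xx"),
            rho_yy=_pooled_corr(cols, yy, "rho_yy"),
            rho_xy=_pooled_corr(cols, xy, "rho_xy"),
        )
    raise TypeError(f"unsupported pilot data type: {type(data).__name__}")
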