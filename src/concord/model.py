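"""Model-style front end over the concordance estimators and tests.

Two model classes mirror the two trial objectives.  Each is constructed
from data (raw readings, a wide indicator frame, or indicator arrays),
exposes the point estimates, and ``fit()`` returns a results object with
the test statistic, variance estimate, p-value, reject decision and a
``summary()`` table.

>>> model = DeviceRadiologistConcordance.from_readings(df, "Shape")
>>> res = model.fit(delta1=0.05)
>>> print(res.summary())
"""

from __future__ import annotations

import pandas as pd

from . import testing
from .correlations import estimate_components_from_pilot
from .indicators import (
    ConcordanceData1,
    ConcordanceData2,
    estimate_pr,
    estimate_ps,
    estimate_px_py,
    indicators_from_readings,
    read_indicators_csv,
)

__all__ = ["DeviceRadiologistConcordance", "SeniorJuniorConcordance"]


class _ConcordanceModelBase:
    _objective: int

    def __init__(self, data):
        expected = ConcordanceData1 if self._objective == 1 else ConcordanceData2
        if not isinstance(data, expected):
            raise TypeError(
                f"expected {expected.__name__}, got {type(data).__name__}"
            )
        self.data = data

    @classmethod
    def from_readings(cls, readings: pd.DataFrame, classification: str):
        """Build from a long-format reading table for one classification."""
        return cls(indicators_from_readings(readings, classification, cls._objective))

    # statsmodels-flavoured alias
    from_dataframe = from_readings

    @classmethod
    def from_indicators_csv(cls, path):
        return cls(read_indicators_csv(path))

    @property
    def n(self) -> int:
        return self.data.n

    @property
    def m(self) -> int:
        return self.data.m

    def estimate_components(self):
        """Pilot estimate of the component correlations (for re-design)."""
        return estimate_components_from_pilot(self.data)


class DeviceRadiologistConcordance(_ConcordanceModelBase):
    """Device-vs-panel concordance model (non-inferiority objective).

    Wraps per-subject radiologist--radiologist means r_i and
    device--radiologist means s_i; ``fit`` runs the one-sided margin test.
    """

    _objective = 1

    @property
    def pr_hat(self) -> float:
        return estimate_pr(self.data)

    @property
    def ps_hat(self) -> float:
        return estimate_ps(self.data)

    def fit(
        self,
        delta1: float,
        alpha: float = 0.05,
        variance_flavor: str = "null_anchored",
    ) -> testing.TestResult:
        """One-sided test of H1: ps <= pr - delta1 at level alpha."""
        return testing.test_objective1(
            self.data, delta1=delta1, alpha=alpha, variance_flavor=variance_flavor
        )

    @classmethod
    def simulate(
        cls, n: int, m: int, pr: float, ps: float, components, seed=0
    ) -> "DeviceRadiologistConcordance":
        """Model on data simulated from the latent-Gaussian generator."""
        from .simulate import assemble_layout, simulate_dataset

        layout = assemble_layout(1, m, (pr, ps), components)
        return cls(simulate_dataset(layout, n, seed))


class SeniorJuniorConcordance(_ConcordanceModelBase):
    """Senior-vs-junior device concordance model (two-sided comparison)."""

    _objective = 2

    @property
    def px_hat(self) -> float:
        return estimate_px_py(self.data)[0]

    @property
    def py_hat(self) -> float:
        return estimate_px_py(self.data)[1]

    def fit(self, alpha: float = 0.05) -> testing.TestResult:
        """Two-sided test of H2: px = py at level alpha."""
        return testing.test_objective2(self.data, alpha=alpha)

    @classmethod
    def simulate(
        cls, n: int, m: int, px: float, py: float, components, seed=0
    ) -> "SeniorJuniorConcordance":
        from .simulate import assemble_layout, simulate_dataset

        layout = assemble_layout(2, m, (px, py), components)
        return cls(simulate_dataset(layout, n, seed))
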