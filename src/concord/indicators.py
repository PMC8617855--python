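"""Concordance indicators and rate estimators.

A concordance trial collects, for each subject's image, one categorical
reading per reader (the AI device plus a panel of radiologists) under one
or more lexicon classifications (e.g. the BI-RADS ultrasound "Shape"
category).  Two readers concur on an image when they assign the identical
category label.  This module turns a long-format reading table into binary
concordance indicators and the per-subject / overall concordance-rate
estimators:

* Objective 1 (device vs panel): ``r_ijj'`` = 1 iff radiologists j and j'
  concur (m(m-1)/2 informative pairs per subject), ``s_ij`` = 1 iff
  radiologist j and the device concur; per-subject means ``r_i``, ``s_i``
  and overall rates ``p̂r = mean(r_i)``, ``p̂s = mean(s_i)``.
* Objective 2 (senior vs junior panels): ``x_ij`` (device vs senior j),
  ``y_ij`` (device vs junior j); means ``x_i``, ``y_i`` and rates
  ``p̂x``, ``p̂y``.

Concordance is exact label equality after whitespace stripping and case
folding; there is no partial credit for adjacent categories.  Reading
tables must be complete blocks (every subject read by the same readers);
a missing cell is an error, never imputed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "READINGS_COLUMNS",
    "ConcordanceData1",
    "ConcordanceData2",
    "read_readings_csv",
    "indicators_from_readings",
    "estimate_pr",
    "estimate_ps",
    "estimate_px_py",
    "write_indicators_csv",
    "read_indicators_csv",
]

READINGS_COLUMNS = ["subject_id", "reader_id", "reader_role", "classification", "value"]

ROLES_OBJ1 = {"device", "radiologist"}
ROLES_OBJ2 = {"device", "senior", "junior"}


def reader_pairs(m: int) -> list[tuple[int, int]]:
    """Lexicographic (j, j') pairs over j < j' for m readers (0-based)."""
    return [(j, k) for j in range(m) for k in range(j + 1, m)]


@dataclass(frozen=True)
class ConcordanceData1:
    """Per-subject concordance indicators for the device-vs-panel objective.

    ``r_indicators`` has one column per radiologist pair in the order of
    :func:`reader_pairs` over the sorted radiologist ids; ``s_indicators``
    one column per radiologist in sorted-id order.
    """

    r_indicators: np.ndarray  # (n, m(m-1)/2) in {0,1}
    s_indicators: np.ndarray  # (n, m) in {0,1}
    subject_ids: tuple = ()
    reader_ids: tuple = ()

    def __post_init__(self) -> None:
        r = np.asarray(self.r_indicators)
        s = np.asarray(self.s_indicators)
        if r.ndim != 2 or s.ndim != 2 or r.shape[0] != s.shape[0]:
            raise ValueError("indicator arrays must be 2-D with matching rows")
        m = s.shape[1]
        if r.shape[1] != m * (m - 1) // 2:
            raise ValueError(
                f"r_indicators has {r.shape[1]} columns, expected "
                f"m(m-1)/2 = {m * (m - 1) // 2} for m={m}"
            )
        for arr, name in ((r, "r_indicators"), (s, "s_indicators")):
            if not np.isin(arr, (0, 1)).all():
                raise ValueError(f"{name} entries must be 0/1")

    @property
    def n(self) -> int:
        return self.s_indicators.shape[0]

    @property
    def m(self) -> int:
        return self.s_indicators.shape[1]

    @property
    def reader_pairs(self) -> list[tuple[int, int]]:
        return reader_pairs(self.m)

    @property
    def r_i(self) -> np.ndarray:
        """Per-subject radiologist--radiologist concordance mean."""
        return self.r_indicators.mean(axis=1)

    @property
    def s_i(self) -> np.ndarray:
        """Per-subject device--radiologist concordance mean."""
        return self.s_indicators.mean(axis=1)


@dataclass(frozen=True)
class ConcordanceData2:
    """Per-subject concordance indicators for the senior-vs-junior objective."""

    x_indicators: np.ndarray  # (n, m) device vs senior readers
    y_indicators: np.ndarray  # (n, m) device vs junior readers
    subject_ids: tuple = ()
    senior_ids: tuple = ()
    junior_ids: tuple = ()

    def __post_init__(self) -> None:
        x = np.asarray(self.x_indicators)
        y = np.asarray(self.y_indicators)
        if x.shape != y.shape or x.ndim != 2:
            raise ValueError("x and y indicator arrays must share an (n, m) shape")
        for arr, name in ((x, "x_indicators"), (y, "y_indicators")):
            if not np.isin(arr, (0, 1)).all():
                raise ValueError(f"{name} entries must be 0/1")

    @property
    def n(self) -> int:
        return self.x_indicators.shape[0]

    @property
    def m(self) -> int:
        return self.x_indicators.shape[1]

    @property
    def x_i(self) -> np.ndarray:
        return self.x_indicators.mean(axis=1)

    @property
    def y_i(self) -> np.ndarray:
        return self.y_indicators.mean(axis=1)


def _canon(v) -> str:
    return str(v).strip().casefold()


def read_readings_csv(path) -> pd.DataFrame:
    """Read a long-format readings CSV (columns: subject_id, reader_id,
    reader_role, classification, value)."""
    df = pd.read_csv(path, dtype=str)
    if df.empty:
        raise ValueError(f"no readings found in {path}")
    missing = [c for c in READINGS_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required column(s) {missing}")
    return df


def _label_matrix(
    sub: pd.DataFrame, subjects: list, readers: list, classification: str
) -> np.ndarray:
    """(n_subjects, n_readers) matrix of canonical labels; errors on gaps."""
    piv = sub.pivot_table(
        index="subject_id", columns="reader_id", values="value", aggfunc="count"
    ).reindex(index=subjects, columns=readers)
    dup = piv.stack(future_stack=True)
    bad = dup[dup != 1]
    if not bad.empty:
        subj, rdr = bad.index[0]
        what = "missing" if np.isnan(bad.iloc[0]) else "duplicated"
        raise ValueError(
            f"{what} reading for subject {subj!r}, reader {rdr!r}, "
            f"classification {classification!r}"
        )
    lab = sub.pivot(index="subject_id", columns="reader_id", values="value")
    lab = lab.reindex(index=subjects, columns=readers)
    return lab.map(_canon).to_numpy()


def indicators_from_readings(
    readings: pd.DataFrame, classification: str, objective: int
) -> ConcordanceData1 | ConcordanceData2:
    """Compute binary concordance indicators for one lexicon classification.

    Two readings concur iff their canonicalised category labels are equal.
    Radiologist pair columns are ordered lexicographically over sorted
    reader ids, so indicator arrays are reproducible.

    Parameters
    ----------
    readings : DataFrame
        Long-format reading table (see :data:`READINGS_COLUMNS`).  Roles
        must be device+radiologist (objective 1) or device+senior+junior
        (objective 2).
    classification : str
        Which lexicon classification to analyse.
    objective : {1, 2}
        Which trial objective's indicator set to build.
    """
    if objective not in (1, 2):
        raise ValueError(f"objective must be 1 or 2, got {objective}")
    sub = readings[readings["classification"] == classification]
    if sub.empty:
        avail = sorted(readings["classification"].unique())
        raise ValueError(
            f"classification {classification!r} not present; available: {avail}"
        )
    roles = set(sub["reader_role"].unique())
    allowed = ROLES_OBJ1 if objective == 1 else ROLES_OBJ2
    if not roles <= allowed:
        raise ValueError(
            f"objective {objective} expects roles {sorted(allowed)}, "
            f"found {sorted(roles)}"
        )
    subjects = sorted(sub["subject_id"].unique())

    def ids_for(role: str) -> list:
        return sorted(sub.loc[sub["reader_role"] == role, "reader_id"].unique())

    dev_ids = ids_for("device")
    if len(dev_ids) != 1:
        raise ValueError(f"expected exactly one device reader, found {dev_ids}")
    dev = _label_matrix(
        sub[sub["reader_role"] == "device"], subjects, dev_ids, classification
    )[:, 0]

    if objective == 1:
        rad_ids = ids_for("radiologist")
        if len(rad_ids) < 2:
            raise ValueError(f"need >= 2 radiologists, found {len(rad_ids)}")
        lab = _label_matrix(
            sub[sub["reader_role"] == "radiologist"], subjects, rad_ids, classification
        )
        pairs = reader_pairs(len(rad_ids))
        r = np.column_stack(
            [(lab[:, j] == lab[:, k]).astype(np.int8) for j, k in pairs]
        )
        s = (lab == dev[:, None]).astype(np.int8)
        return ConcordanceData1(
            r_indicators=r,
            s_indicators=s,
            subject_ids=tuple(subjects),
            reader_ids=tuple(rad_ids),
        )

    sen_ids, jun_ids = ids_for("senior"), ids_for("junior")
    if len(sen_ids) < 2 or len(sen_ids) != len(jun_ids):
        raise ValueError(
            f"need equal groups of >= 2 senior and junior radiologists, "
            f"found {len(sen_ids)} senior / {len(jun_ids)} junior"
        )
    sen = _label_matrix(
        sub[sub["reader_role"] == "senior"], subjects, sen_ids, classification
    )
    jun = _label_matrix(
        sub[sub["reader_role"] == "junior"], subjects, jun_ids, classification
    )
    return ConcordanceData2(
        x_indicators=(sen == dev[:, None]).astype(np.int8),
        y_indicators=(jun == dev[:, None]).astype(np.int8),
        subject_ids=tuple(subjects),
        senior_ids=tuple(sen_ids),
        junior_ids=tuple(jun_ids),
    )


def estimate_pr(data: ConcordanceData1) -> float:
    """Overall radiologist--radiologist concordance rate, mean of r_i."""
    if data.n < 1:
        raise ValueError("empty concordance data")
    return float(data.r_i.mean())


def estimate_ps(data: ConcordanceData1) -> float:
    """Overall device--radiologist concordance rate, mean of s_i."""
    if data.n < 1:
        raise ValueError("empty concordance data")
    return float(data.s_i.mean())


def estimate_px_py(data: ConcordanceData2) -> tuple[float, float]:
    """Overall device--senior and device--junior concordance rates."""
    if data.n < 1:
        raise ValueError("empty concordance data")
    return float(data.x_i.mean()), float(data.y_i.mean())


# -- wide indicator CSV (one row per subject), for audit and round-trips ----

def _frame1(data: ConcordanceData1) -> pd.DataFrame:
    cols = {}
    ids = data.reader_ids or tuple(range(1, data.m + 1))
    for c, (j, k) in enumerate(data.reader_pairs):
        cols[f"r_{ids[j]}_{ids[k]}"] = data.r_indicators[:, c]
    for j in range(data.m):
        cols[f"s_{ids[j]}"] = data.s_indicators[:, j]
    idx = data.subject_ids or tuple(range(1, data.n + 1))
    return pd.DataFrame(cols, index=pd.Index(idx, name="subject_id"))


def _frame2(data: ConcordanceData2) -> pd.DataFrame:
    cols = {}
    sids = data.senior_ids or tuple(range(1, data.m + 1))
    jids = data.junior_ids or tuple(range(1, data.m + 1))
    for j in range(data.m):
        cols[f"x_{sids[j]}"] = data.x_indicators[:, j]
    for j in range(data.m):
        cols[f"y_{jids[j]}"] = data.y_indicators[:, j]
    idx = data.subject_ids or tuple(range(1, data.n + 1))
    return pd.DataFrame(cols, index=pd.Index(idx, name="subject_id"))


def write_indicators_csv(data: ConcordanceData1 | ConcordanceData2, path) -> None:
    """Write indicators as a wide CSV: subject_id then r_*/s_* or x_*/y_*."""
    frame = _frame1(data) if isinstance(data, ConcordanceData1) else _frame2(data)
    frame.to_csv(path)


def read_indicators_csv(path) -> ConcordanceData1 | ConcordanceData2:
    """Read a wide indicator CSV written by :func:`write_indicators_csv`.

    The objective is inferred from the column prefixes (r_/s_ vs x_/y_).
    """
    df = pd.read_csv(path, index_col="subject_id")
    if df.empty:
        raise ValueError(f"no indicator rows found in {path}")
    rcols = [c for c in df.columns if c.startswith("r_")]
    scols = [c for c in df.columns if c.startswith("s_")]
    xcols = [c for c in df.columns if c.startswith("x_")]
    ycols = [c for c in df.columns if c.startswith("y_")]
    subjects = tuple(df.index)
    if rcols and scols and not (xcols or ycols):
        return ConcordanceData1(
            r_indicators=df[rcols].to_numpy(dtype=np.int8),
            s_indicators=df[scols].to_numpy(dtype=np.int8),
            subject_ids=subjects,
            reader_ids=tuple(c[2:] for c in scols),
        )
    if xcols and ycols and not (rcols or scols):
        return ConcordanceData2(
            x_indicators=df[xcols].to_numpy(dtype=np.int8),
            y_indicators=df[ycols].to_numpy(dtype=np.int8),
            subject_ids=subjects,
            senior_ids=tuple(c[2:] for c in xcols),
            junior_ids=tuple(c[2:] for c in ycols),
        )
    raise ValueError(
        f"{path}: cannot infer indicator layout from columns {list(df.columns)}; "
        f"expected r_*/s_* (objective 1) or x_*/y_* (objective 2)"
    )
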