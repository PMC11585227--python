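"""Containers for incompletely observed factorial repeated-measures data.

The design has ``a`` independent groups of subjects, each subject measured at
``d`` time points; any single measurement may be missing.  Data are held
group-wise as rectangular ``(n_i, d)`` value arrays together with a boolean
observation mask (``observed[i][k, j]`` is True iff subject ``k`` of group
``i`` was measured at time ``j``).  Values at unobserved positions are
immaterial and ignored by every downstream computation.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "IncompleteFactorialData",
    "DesignMeta",
    "design_meta",
    "read_long_format",
    "write_long_format",
]

LONG_COLUMNS = ("subject", "group", "time", "value")


@dataclass
class IncompleteFactorialData:
    """Incomplete factorial repeated-measures data.

    Parameters
    ----------
    values : list of ndarray
        One ``(n_i, d)`` float array per group.  Entries at unobserved
        positions may be anything (conventionally NaN).
    observed : list of ndarray
        Boolean masks of the same shapes; True = observed.
    group_labels, time_labels : list of str, optional
        Display labels; defaults are ``g1..ga`` and ``t1..td``.
    subject_labels : list of list, optional
        Per-group subject identifiers (round-trip support for the long
        format reader/writer).
    """

    values: list
    observed: list
    group_labels: list = None
    time_labels: list = None
    subject_labels: list = None

    def __post_init__(self):
        self.values = [np.asarray(v, dtype=float) for v in self.values]
        if self.observed is None:
            self.observed = [~np.isnan(v) for v in self.values]
        self.observed = [np.asarray(m, dtype=bool) for m in self.observed]
        if len(self.values) == 0:
            raise ValueError("no groups")
        d = self.values[0].shape[1] if self.values[0].ndim == 2 else None
        for v, m in zip(self.values, self.observed):
            if v.ndim != 2 or m.shape != v.shape:
                raise ValueError("values and observed must be matching (n_i, d) arrays")
            if v.shape[1] != d:
                raise ValueError("all groups must share the same number of time points")
            if v.shape[0] < 1:
                raise ValueError("every group needs at least one subject")
            if np.isnan(v[m]).any():
                raise ValueError("NaN marked as observed")
        if self.group_labels is None:
            self.group_labels = [f"g{i + 1}" for i in range(self.a)]
        if self.time_labels is None:
            self.time_labels = [f"t{j + 1}" for j in range(self.d)]
        for i, m in enumerate(self.observed):
            empty = ~m.any(axis=1)
            if empty.any():
                warnings.warn(
                    f"group {self.group_labels[i]}: {int(empty.sum())} subject(s) "
                    "with no observation at any time point; kept but contribute "
                    "nothing to any statistic",
                    stacklevel=2,
                )

    # -- design dimensions -------------------------------------------------
    @property
    def a(self) -> int:
        return len(self.values)

    @property
    def d(self) -> int:
        return self.values[0].shape[1]

    @property
    def n(self) -> np.ndarray:
        """Group sizes ``n_i`` (subjects, observed or not)."""
        return np.array([v.shape[0] for v in self.values])

    @property
    def n_total(self) -> int:
        return int(self.n.sum())

    def lambda_dot(self) -> np.ndarray:
        """(a, d) table of per-cell observed counts lambda_ij."""
        return np.array([m.sum(axis=0) for m in self.observed])

    def require_complete_cells(self, min_count: int = 2) -> None:
        """Refuse designs with under-observed cells.

        Every cell (group, time) must have at least ``min_count`` observed
        subjects: 1 for the effect estimators to exist, 2 for the covariance
        estimator (and hence for any of the tests) to exist.
        """
        lam = self.lambda_dot()
        bad = np.argwhere(lam < min_count)
        if len(bad):
            cells = ", ".join(
                f"(group={self.group_labels[i]}, time={self.time_labels[j]}, "
                f"observed={int(lam[i, j])})"
                for i, j in bad
            )
            raise ValueError(
                f"cells with fewer than {min_count} observed subjects: {cells}"
            )


@dataclass
class DesignMeta:
    """Observation-count summaries of an incomplete design.

    N is the total number of observed measurements; ``lambda_dot[i, j]``
    counts subjects of group i observed at time j; ``delta[i][j, j2]``
    counts subjects of group i observed at both times j and j2 (so its
    diagonal equals ``lambda_dot[i]``).
    """

    N: int
    n_total: int
    n: np.ndarray
    lambda_dot: np.ndarray
    delta: list = field(default_factory=list)

    def to_json(self) -> str:
        return json.dumps(
            {
                "N": int(self.N),
                "n_total": int(self.n_total),
                "n": [int(x) for x in self.n],
                "lambda_dot": self.lambda_dot.astype(int).tolist(),
                "delta": [d.astype(int).tolist() for d in self.delta],
            }
        )


def design_meta(data: IncompleteFactorialData) -> DesignMeta:
    """Compute N, lambda_ij. and the pairwise-complete counts Delta_i."""
    lam = data.lambda_dot()
    delta = [m.astype(float).T @ m.astype(float) for m in data.observed]
    return DesignMeta(
        N=int(lam.sum()),
        n_total=data.n_total,
        n=data.n,
        lambda_dot=lam,
        delta=[d.astype(int) for d in delta],
    )


def _read_table(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep=None, engine="python")
    df.columns = [str(c).strip().lower() for c in df.columns]
    missing = [c for c in LONG_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"long-format file lacks required column(s): {missing}")
    return df


def read_long_format(path, sort: bool = False) -> IncompleteFactorialData:
    """Read long-format (subject, group, time, value) CSV/TSV data.

    A missing measurement may be encoded either as an empty/NA value cell or
    by simply omitting the (subject, time) row; both are equivalent.  Groups
    and time points are ordered by first appearance unless ``sort`` is set.
    """
    df = _read_table(path)
    if len(df) == 0:
        raise ValueError("no records")
    dup = df.duplicated(subset=["subject", "group", "time"])
    if dup.any():
        rows = df.loc[dup, ["subject", "group", "time"]].iloc[0].tolist()
        raise ValueError(f"duplicate (subject, group, time) triple, e.g. {rows}")
    per_subj = df.groupby("subject")["group"].nunique()
    multi = per_subj[per_subj > 1]
    if len(multi):
        raise ValueError(
            f"subject(s) appearing in more than one group: {list(multi.index)}"
        )

    def order(col):
        vals = list(dict.fromkeys(df[col]))
        return sorted(vals) if sort else vals

    groups, times = order("group"), order("time")
    g_index = {g: i for i, g in enumerate(groups)}
    t_index = {t: j for j, t in enumerate(times)}

    values, observed, subject_labels = [], [], []
    for g in groups:
        sub = df[df["group"] == g]
        subjects = list(dict.fromkeys(sub["subject"]))
        if sort:
            subjects = sorted(subjects)
        s_index = {s: k for k, s in enumerate(subjects)}
        vals = np.full((len(subjects), len(times)), np.nan)
        for _, row in sub.iterrows():
            vals[s_index[row["subject"]], t_index[row["time"]]] = row["value"]
        values.append(vals)
        observed.append(~np.isnan(vals))
        subject_labels.append(subjects)
    return IncompleteFactorialData(
        values=values,
        observed=observed,
        group_labels=[str(g) for g in groups],
        time_labels=[str(t) for t in times],
        subject_labels=subject_labels,
    )


def write_long_format(data: IncompleteFactorialData, path) -> None:
    """Write long-format CSV; unobserved cells become empty value fields."""
    rows = []
    for i in range(data.a):
        labels = (
            data.subject_labels[i]
            if data.subject_labels is not None
            else [f"{data.group_labels[i]}_s{k + 1}" for k in range(data.n[i])]
        )
        for k in range(data.values[i].shape[0]):
            for j in range(data.d):
                rows.append(
                    {
                        "subject": labels[k],
                        "group": data.group_labels[i],
                        "time": data.time_labels[j],
                        "value": data.values[i][k, j]
                        if data.observed[i][k, j]
                        else np.nan,
                    }
                )
    pd.DataFrame(rows, columns=list(LONG_COLUMNS)).to_csv(path, index=False)
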