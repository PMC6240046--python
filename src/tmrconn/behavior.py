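"""Behavioral outcomes and brain-behavior statistics.

Object-placement accuracy is the Euclidean error (cm) between the true and
placed location. Overnight forgetting is the Test 2 - Test 1 change in mean
error (positive = forgetting), summarised overall and split by cueing
status. Brain-behavior associations use Kendall's tau-b; two dependent
correlations sharing one variable are compared with the Williams-Hotelling
t-test (df = n - 3).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "ForgettingSummary",
    "placement_error",
    "forgetting_summary",
    "kendall_tau",
    "williams_hotelling",
]


def placement_error(true_xy, placed_xy) -> float:
    """Euclidean distance (cm) between the correct and placed location."""
    t = np.asarray(true_xy, dtype=float)
    p = np.asarray(placed_xy, dtype=float)
    if not (np.all(np.isfinite(t)) and np.all(np.isfinite(p))):
        raise ValueError("coordinates must be finite")
    return float(np.hypot(*(p - t)))


@dataclass
class ForgettingSummary:
    """Per-subject overnight error change and its group-level tests."""

    per_subject: pd.DataFrame  # subject, delta_overall, delta_cued, delta_uncued
    group: dict  # mean/sem/t/p for overall, cued, uncued, cued_vs_uncued

    @property
    def n_subjects(self) -> int:
        return len(self.per_subject)


def _paired_stats(deltas: np.ndarray) -> dict:
    n = len(deltas)
    mean = float(deltas.mean())
    sem = float(deltas.std(ddof=1) / np.sqrt(n)) if n > 1 else np.nan
    if sem == 0:
        warnings.warn("zero variance in per-subject deltas; t undefined", stacklevel=3)
        return dict(mean=mean, sem=0.0, t=np.nan, p=np.nan, df=n - 1)
    t, p = stats.ttest_1samp(deltas, 0.0)
    return dict(mean=mean, sem=sem, t=float(t), p=float(p), df=n - 1)


def forgetting_summary(table: pd.DataFrame) -> ForgettingSummary:
    """Summarise overnight forgetting from an item-level behavioral table.

    ``table`` needs columns ``subject``, ``cued``, ``error_test1``,
    ``error_test2``. Delta = Test2 - Test1 mean error per subject, overall
    and by cueing status; group tests are two-sided paired t-tests (the
    cued-vs-uncued contrast is a paired t on delta_cued - delta_uncued,
    the two-level equivalent of the repeated-measures F with F = t^2).
    """
    required = {"subject", "cued", "error_test1", "error_test2"}
    if not required.issubset(table.columns):
        raise ValueError(f"table must have columns {sorted(required)}")
    if table[["error_test1", "error_test2"]].isna().any().any():
        raise ValueError("both tests must be present for every item")

    rows = []
    for subject, grp in table.groupby("subject"):
        d = grp["error_test2"] - grp["error_test1"]
        cued = grp["cued"].astype(bool)
        if cued.all() or (~cued).all():
            warnings.warn(
                f"subject {subject} has no items in one condition; excluded",
                stacklevel=2,
            )
            continue
        rows.append(
            dict(
                subject=subject,
                delta_overall=float(d.mean()),
                delta_cued=float(d[cued].mean()),
                delta_uncued=float(d[~cued].mean()),
            )
        )
    per_subject = pd.DataFrame(rows)
    group = {
        "overall": _paired_stats(per_subject["delta_overall"].to_numpy()),
        "cued": _paired_stats(per_subject["delta_cued"].to_numpy()),
        "uncued": _paired_stats(per_subject["delta_uncued"].to_numpy()),
        "cued_vs_uncued": _paired_stats(
            (per_subject["delta_cued"] - per_subject["delta_uncued"]).to_numpy()
        ),
    }
    return ForgettingSummary(per_subject=per_subject, group=group)


def kendall_tau(x, y) -> tuple[float, float]:
    """Kendall's tau-b with a normal-approximation two-sided p.

    Tie correction follows the tau-b definition; the p-value uses the
    tie-corrected variance of the concordance score S with a continuity
    correction of 1.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(x)
    if n != len(y):
        raise ValueError("x and y must have equal length")
    if n < 4:
        raise ValueError("need at least 4 observations")
    if np.all(x == x[0]) or np.all(y == y[0]):
        raise ValueError("constant input vector")

    dx = np.sign(x[:, None] - x[None, :])
    dy = np.sign(y[:, None] - y[None, :])
    iu = np.triu_indices(n, k=1)
    s = float(np.sum(dx[iu] * dy[iu]))

    n0 = n * (n - 1) / 2.0
    tx = np.array([c for c in pd.Series(x).value_counts() if c > 1], dtype=float)
    ty = np.array([c for c in pd.Series(y).value_counts() if c > 1], dtype=float)
    n1 = float(np.sum(tx * (tx - 1) / 2))
    n2 = float(np.sum(ty * (ty - 1) / 2))
    tau = s / np.sqrt((n0 - n1) * (n0 - n2))

    v0 = n * (n - 1) * (2 * n + 5)
    vt = np.sum(tx * (tx - 1) * (2 * tx + 5))
    vu = np.sum(ty * (ty - 1) * (2 * ty + 5))
    v1 = np.sum(tx * (tx - 1)) * np.sum(ty * (ty - 1)) / (2.0 * n * (n - 1))
    v2 = (
        np.sum(tx * (tx - 1) * (tx - 2))
        * np.sum(ty * (ty - 1) * (ty - 2))
        / (9.0 * n * (n - 1) * (n - 2))
    )
    var_s = (v0 - vt - vu) / 18.0 + v1 + v2
    if var_s <= 0:
        return float(tau), 1.0
    z = (s - np.sign(s)) / np.sqrt(var_s)  # continuity correction
    p = 2.0 * stats.norm.sf(abs(z))
    return float(tau), float(min(p, 1.0))


def williams_hotelling(
    r12: float, r13: float, r23: float, n: int
) -> tuple[float, float]:
    """Williams' t for two dependent correlations sharing variable 1.

    Tests r12 = r13 given the correlation r23 between variables 2 and 3,
    with df = n - 3:

        t = (r12 - r13) * sqrt( (n-1)(1+r23) /
              ( 2 (n-1)/(n-3) |R| + rbar^2 (1-r23)^3 ) )

    where rbar = (r12 + r13)/2 and |R| is the determinant of the 3x3
    correlation matrix.
    """
    if n < 4:
        raise ValueError("need n >= 4")
    for r in (r12, r13, r23):
        if abs(r) > 1:
            raise ValueError("correlations must lie in [-1, 1]")
    R = np.array([[1.0, r12, r13], [r12, 1.0, r23], [r13, r23, 1.0]])
    if np.linalg.eigvalsh(R).min() < -1e-10:
        raise ValueError("correlation triple is not positive semidefinite")
    det = float(np.linalg.det(R))
    rbar = (r12 + r13) / 2.0
    denom = 2.0 * (n - 1) / (n - 3) * det + rbar**2 * (1.0 - r23) ** 3
    if denom <= 0:
        raise ValueError("degenerate correlation structure")
    t = (r12 - r13) * np.sqrt((n - 1) * (1.0 + r23) / denom)
    p = 2.0 * stats.t.sf(abs(t), n - 3)
    return float(t), float(p)
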