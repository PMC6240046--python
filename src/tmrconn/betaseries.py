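"""Trial-wise GLM estimation of beta time-series.

Each sound presentation gets its own regressor (a boxcar convolved with the
canonical double-gamma HRF), all trials are fit in a single GLM
("least-squares-all"), and the trial coefficients are concatenated into a
node x trial beta time-series. Prewhitening is a single Cochrane-Orcutt
iteration with a per-node AR(1) coefficient estimated from OLS residuals.
High-pass filtering uses the standard discrete-cosine basis (default cutoff
128 s), applied by residualizing both data and design against the basis,
which is equivalent to including the DCT columns as regressors.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import linalg, stats

__all__ = [
    "DesignMatrix",
    "BetaSeries",
    "spm_hrf",
    "dct_highpass_basis",
    "build_design",
    "fit_betas",
    "split_by_condition",
]

#: canonical double-gamma HRF parameters (seconds): response delay, undershoot
#: delay, response dispersion, undershoot dispersion, response/undershoot
#: ratio, total kernel length
HRF_PARAMS = dict(
    peak_delay=6.0,
    undershoot_delay=16.0,
    peak_disp=1.0,
    undershoot_disp=1.0,
    ratio=6.0,
    length=32.0,
)

CONDITIONS = ("cue", "control")


def spm_hrf(dt: float, **params) -> np.ndarray:
    """Canonical double-gamma haemodynamic response sampled every ``dt`` s.

    The kernel is the difference of two gamma densities (peak at ~6 s,
    undershoot at ~16 s, ratio 1:6) normalised to unit sum.
    """
    p = {**HRF_PARAMS, **params}
    t = np.arange(0, p["length"] + dt, dt)
    peak = stats.gamma.pdf(t, p["peak_delay"] / p["peak_disp"], scale=p["peak_disp"])
    under = stats.gamma.pdf(
        t, p["undershoot_delay"] / p["undershoot_disp"], scale=p["undershoot_disp"]
    )
    h = peak - under / p["ratio"]
    return h / h.sum()


def dct_highpass_basis(n_scans: int, tr: float, cutoff: float) -> np.ndarray:
    """Discrete-cosine high-pass basis (constant term excluded).

    The number of regressors is ``floor(2 T / cutoff)`` for run length
    ``T = n_scans * tr``, i.e. all cosines with period longer than the
    cutoff.
    """
    T = n_scans * tr
    n_dct = int(np.floor(2.0 * T / cutoff))
    n_dct = max(n_dct, 0)
    t = np.arange(n_scans)
    basis = np.empty((n_scans, n_dct))
    for j in range(1, n_dct + 1):
        basis[:, j - 1] = np.sqrt(2.0 / n_scans) * np.cos(
            np.pi * (2 * t + 1) * j / (2 * n_scans)
        )
    return basis


@dataclass
class DesignMatrix:
    """Trial-wise design: one column per event plus nuisance and DCT columns."""

    matrix: np.ndarray  # n_scans x n_regressors
    columns: list[str]
    tr: float
    cutoff: float
    hrf: dict = field(default_factory=lambda: dict(HRF_PARAMS))

    @property
    def n_scans(self) -> int:
        return self.matrix.shape[0]

    @property
    def trial_indices(self) -> np.ndarray:
        return np.array(
            [i for i, c in enumerate(self.columns) if c.startswith("trial_")]
        )

    @property
    def dct_indices(self) -> np.ndarray:
        return np.array(
            [i for i, c in enumerate(self.columns) if c.startswith("dct_")], dtype=int
        )

    @property
    def n_trials(self) -> int:
        return len(self.trial_indices)


@dataclass
class BetaSeries:
    """Node x trial matrix of trial-specific GLM amplitudes."""

    data: np.ndarray  # n_nodes x n_trials
    trial_types: np.ndarray  # condition label per trial, in trial order
    node_ids: np.ndarray | None = None

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=float)
        self.trial_types = np.asarray(self.trial_types)
        if self.data.ndim != 2:
            raise ValueError("beta series data must be 2-D (nodes x trials)")
        if self.data.shape[1] != len(self.trial_types):
            raise ValueError(
                f"{self.data.shape[1]} trials in data but "
                f"{len(self.trial_types)} trial labels"
            )

    @property
    def n_nodes(self) -> int:
        return self.data.shape[0]

    @property
    def n_trials(self) -> int:
        return self.data.shape[1]


def _trial_regressor(onset, duration, tr, n_scans, hrf_kernel, dt):
    """Boxcar at `onset` convolved with the HRF, sampled at scan times."""
    n_fine = int(np.ceil(n_scans * tr / dt)) + len(hrf_kernel)
    box = np.zeros(n_fine)
    i0 = int(round(onset / dt))
    i1 = max(i0 + 1, int(round((onset + duration) / dt)))
    box[i0:i1] = 1.0
    conv = np.convolve(box, hrf_kernel)[:n_fine]
    scan_idx = np.round(np.arange(n_scans) * tr / dt).astype(int)
    return conv[scan_idx]


def build_design(
    events: pd.DataFrame,
    tr: float,
    n_scans: int,
    nuisance: pd.DataFrame | None = None,
    cutoff: float = 128.0,
    dt: float = 0.1,
) -> DesignMatrix:
    """Build a least-squares-all design matrix from an event table.

    Parameters
    ----------
    events
        BIDS-style event table with columns ``onset``, ``duration``,
        ``trial_type`` (and optionally ``sound_id``); one regressor is built
        per row, in row order.
    tr, n_scans
        Sampling grid of the run.
    nuisance
        Table of nuisance series appended unchanged (e.g. six motion and
        three compartment regressors).
    cutoff
        High-pass cutoff period in seconds; must exceed ``2 * tr``.
    """
    if cutoff <= 2 * tr:
        raise ValueError(f"high-pass cutoff {cutoff}s must exceed 2*TR = {2 * tr}s")
    onsets = np.asarray(events["onset"], dtype=float)
    durations = np.asarray(events["duration"], dtype=float)
    if len(onsets) == 0:
        raise ValueError("event table is empty")
    if np.any(np.diff(np.sort(onsets)) == 0):
        raise ValueError("overlapping identical onsets make the design rank deficient")
    run_end = n_scans * tr
    if np.any(onsets + durations > run_end):
        raise ValueError(
            f"events extend past the run end ({run_end:.1f}s with {n_scans} scans)"
        )

    hrf_kernel = spm_hrf(dt)
    cols = [
        _trial_regressor(on, du, tr, n_scans, hrf_kernel, dt)
        for on, du in zip(onsets, durations)
    ]
    names = [f"trial_{k:03d}" for k in range(len(cols))]

    if nuisance is not None:
        for name in nuisance.columns:
            cols.append(np.asarray(nuisance[name], dtype=float))
            names.append(str(name))
        if len(nuisance) != n_scans:
            raise ValueError("nuisance table length does not match n_scans")

    dct = dct_highpass_basis(n_scans, tr, cutoff)
    for j in range(dct.shape[1]):
        cols.append(dct[:, j])
        names.append(f"dct_{j + 1:02d}")

    return DesignMatrix(matrix=np.column_stack(cols), columns=names, tr=tr, cutoff=cutoff)


def _highpass_projector(design: DesignMatrix) -> np.ndarray:
    """Residual-forming projector onto the complement of constant + DCT."""
    n = design.n_scans
    basis = [np.ones((n, 1))]
    di = design.dct_indices
    if di.size:
        basis.append(design.matrix[:, di])
    D = np.hstack(basis)
    Q, _ = np.linalg.qr(D)
    return np.eye(n) - Q @ Q.T


def _check_rank(X: np.ndarray, names: list[str]) -> None:
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        # QR with column pivoting: the trailing pivots index dependent columns
        _, _, piv = linalg.qr(X, pivoting=True, mode="economic")
        bad = [names[i] for i in piv[rank:]]
        raise ValueError(f"design is rank deficient; collinear columns: {bad}")


def _ar1_rho(resid: np.ndarray) -> np.ndarray:
    """Lag-1 autocorrelation of residuals, rows = nodes."""
    num = np.sum(resid[:, 1:] * resid[:, :-1], axis=1)
    den = np.sum(resid[:, :-1] ** 2, axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        rho = np.where(den > 0, num / den, 0.0)
    return rho


def _prewhiten(y: np.ndarray, X: np.ndarray, rho: float):
    """AR(1) whitening transform of a series and design."""
    c = np.sqrt(1.0 - rho**2)
    yw = np.empty_like(y)
    yw[0] = c * y[0]
    yw[1:] = y[1:] - rho * y[:-1]
    Xw = np.empty_like(X)
    Xw[0] = c * X[0]
    Xw[1:] = X[1:] - rho * X[:-1]
    return yw, Xw


def fit_betas(
    series: np.ndarray,
    design: DesignMatrix,
    trial_types: np.ndarray | list | None = None,
    ar1: str = "estimate",
) -> BetaSeries:
    """Fit the trial-wise GLM and return the trial coefficients per node.

    Parameters
    ----------
    series
        node x scan data matrix.
    design
        Output of :func:`build_design`.
    trial_types
        Condition label per trial (propagated into the result); defaults to
        a placeholder label.
    ar1
        ``"none"`` for plain OLS, ``"estimate"`` for one Cochrane-Orcutt
        iteration: OLS, lag-1 residual autocorrelation per node, AR(1)
        whitening of data and design, refit.
    """
    if ar1 not in ("none", "estimate"):
        raise ValueError(f"unknown ar1 mode {ar1!r}")
    Y = np.atleast_2d(np.asarray(series, dtype=float))
    if Y.shape[1] != design.n_scans:
        raise ValueError(
            f"series has {Y.shape[1]} scans but design has {design.n_scans}"
        )

    P = _highpass_projector(design)
    keep = np.array(
        [i for i, c in enumerate(design.columns) if not c.startswith("dct_")]
    )
    names = [design.columns[i] for i in keep]
    X = P @ design.matrix[:, keep]
    Yr = Y @ P.T  # P is symmetric
    _check_rank(X, names)

    beta, *_ = np.linalg.lstsq(X, Yr.T, rcond=None)
    beta = beta.T  # nodes x regressors

    if ar1 == "estimate":
        resid = Yr - beta @ X.T
        rho = _ar1_rho(resid)
        if np.any(np.abs(rho) >= 1.0):
            warnings.warn(
                "AR(1) estimate at or beyond |rho|=1 clipped to 0.99", stacklevel=2
            )
            rho = np.clip(rho, -0.99, 0.99)
        for i in range(Y.shape[0]):
            yw, Xw = _prewhiten(Yr[i], X, rho[i])
            beta[i], *_ = np.linalg.lstsq(Xw, yw, rcond=None)

    ti = design.trial_indices
    if trial_types is None:
        trial_types = np.array(["trial"] * len(ti))
    return BetaSeries(data=beta[:, ti], trial_types=np.asarray(trial_types))


def split_by_condition(
    betas: BetaSeries, events: pd.DataFrame
) -> dict[str, BetaSeries]:
    """Partition a beta series into per-condition beta series.

    Within-condition trial order is preserved; every trial lands in exactly
    one split. Under the default protocol the cue split has 50 columns and
    the control split 25.
    """
    labels = np.asarray(events["trial_type"])
    if len(labels) != betas.n_trials:
        raise ValueError(
            f"{len(labels)} events but beta series has {betas.n_trials} trials"
        )
    unknown = set(labels) - set(CONDITIONS)
    if unknown:
        raise ValueError(f"unknown condition labels: {sorted(unknown)}")
    out = {}
    for cond in CONDITIONS:
        sel = labels == cond
        if not sel.any():
            warnings.warn(f"condition {cond!r} has no trials", stacklevel=2)
        out[cond] = BetaSeries(
            data=betas.data[:, sel],
            trial_types=labels[sel],
            node_ids=betas.node_ids,
        )
    return out
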