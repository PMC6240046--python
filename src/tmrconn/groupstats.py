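"""Group-level inference on node maps.

Covers the second-level analyses: paired t-tests of participation-
coefficient maps (cue vs control), seed-based connectivity contrasts
(Fisher-z correlation maps contrasted between conditions), covariate maps
(simple second-level regression), cluster-extent correction at a
cluster-forming threshold of Z > 2.33, small-volume correction within ROI
masks, and Benjamini-Hochberg correction across ROIs.

The primary cluster correction is a sign-flipping permutation test on the
maximum cluster extent. A Gaussian-Random-Field approximation in the style
of SPM's cluster-level correction is provided as an alternative
(`method="grf"`); it uses a residual-smoothness estimate and the standard
expected-cluster-size formula and is approximate by construction.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage, special, stats

__all__ = [
    "StatMap",
    "ClusterResult",
    "RoiCorrection",
    "SeedContrast",
    "paired_t_map",
    "seed_contrast_map",
    "covariate_map",
    "cluster_inference",
    "small_volume_correct",
    "bh_critical_p",
    "fisher_z",
]

Z_CAP = 37.0  # probit of the smallest representable two-sided p
R_CLIP = 0.999999  # Fisher-z clipping bound for |r| -> 1


@dataclass
class StatMap:
    """Node-wise statistic map with its z-transform."""

    values: np.ndarray  # t statistics, flat node order
    z: np.ndarray  # signed probit transform of the two-sided p
    df: int
    kind: str = "t"
    shape: tuple | None = None  # 3-D grid shape when nodes are voxels
    undefined: np.ndarray | None = None  # mask of nodes excluded from clustering
    capped: np.ndarray | None = None  # nodes where |t| overflowed
    description: str = ""

    @property
    def n_nodes(self) -> int:
        return len(self.values)


@dataclass
class ClusterResult:
    """One suprathreshold cluster with its extent-corrected p-value."""

    nodes: np.ndarray  # flat indices of member nodes
    extent: int
    peak_stat: float
    peak_index: tuple | int
    corrected_p: float


@dataclass
class RoiCorrection:
    """Per-ROI minimum cluster p-values with BH correction across ROIs."""

    roi_p: dict  # name -> min corrected cluster p within the mask
    critical_p: float
    significant: dict  # name -> bool
    q: float = 0.05


def _t_to_z(t: np.ndarray, df: int) -> np.ndarray:
    """Signed probit transform: z with the same two-sided p as t."""
    p = 2.0 * stats.t.sf(np.abs(t), df)
    z = stats.norm.isf(np.clip(p, 1e-300, 1.0) / 2.0)
    return np.clip(np.sign(t) * z, -Z_CAP, Z_CAP)


def paired_t_map(maps_a: np.ndarray, maps_b: np.ndarray, shape=None) -> StatMap:
    """Node-wise paired t-test across subjects (one-sample t on differences).

    Nodes with zero difference variance are flagged undefined and excluded
    from clustering.
    """
    A, B = np.asarray(maps_a, float), np.asarray(maps_b, float)
    if A.shape != B.shape:
        raise ValueError("subject x node maps must have matching shapes")
    n = A.shape[0]
    if n < 3:
        raise ValueError("need at least 3 subjects")
    D = A - B
    mean = D.mean(axis=0)
    sd = D.std(axis=0, ddof=1)
    undefined = sd == 0
    if undefined.any():
        warnings.warn(
            f"{int(undefined.sum())} node(s) with zero difference variance "
            "excluded from inference",
            stacklevel=2,
        )
    t = np.zeros(D.shape[1])
    ok = ~undefined
    t[ok] = mean[ok] / (sd[ok] / np.sqrt(n))
    t[undefined] = np.nan
    z = np.full_like(t, np.nan)
    z[ok] = _t_to_z(t[ok], n - 1)
    return StatMap(
        values=t, z=z, df=n - 1, shape=shape, undefined=undefined,
        description="paired t",
    )


def fisher_z(r: np.ndarray) -> np.ndarray:
    """Fisher z-transform with clipping so r = +/-1 does not overflow."""
    return np.arctanh(np.clip(r, -R_CLIP, R_CLIP))


def _seed_correlation(betas, seed_mask: np.ndarray) -> np.ndarray:
    """Correlate the mean seed beta series with every node's series."""
    data = betas.data
    seed_series = data[seed_mask].mean(axis=0)
    ss = seed_series - seed_series.mean()
    denom_s = np.sqrt((ss**2).sum())
    dc = data - data.mean(axis=1, keepdims=True)
    denom_n = np.sqrt((dc**2).sum(axis=1))
    with np.errstate(invalid="ignore", divide="ignore"):
        r = (dc @ ss) / (denom_n * denom_s)
    return np.nan_to_num(r)


@dataclass
class SeedContrast:
    """Group seed-connectivity contrast plus subject-level maps for permutation."""

    stat_map: StatMap
    subject_contrasts: np.ndarray  # subject x node, z_cue - z_control
    excluded_nodes: np.ndarray = field(default_factory=lambda: np.array([], int))


def seed_contrast_map(
    seed_mask: np.ndarray, betas_by_subject: list[dict], shape=None
) -> SeedContrast:
    """Seed-based connectivity contrast (cue vs control) across subjects.

    Per subject the seed series is the mean beta series over seed nodes;
    node-wise Pearson correlations are computed per condition, Fisher
    z-transformed and contrasted (cue - control); the group map is the
    paired t-test of the per-condition z maps across subjects. Seed nodes
    are excluded from the target set and recorded.
    """
    seed_mask = np.asarray(seed_mask, dtype=bool).reshape(-1)
    if not seed_mask.any():
        raise ValueError("seed mask is empty")
    z_cue, z_ctl = [], []
    for subj in betas_by_subject:
        z_cue.append(fisher_z(_seed_correlation(subj["cue"], seed_mask)))
        z_ctl.append(fisher_z(_seed_correlation(subj["control"], seed_mask)))
    z_cue, z_ctl = np.array(z_cue), np.array(z_ctl)
    excluded = np.flatnonzero(seed_mask)
    z_cue[:, excluded] = 0.0
    z_ctl[:, excluded] = 0.0
    stat_map = paired_t_map(z_cue, z_ctl, shape=shape)
    und = stat_map.undefined.copy() if stat_map.undefined is not None else np.zeros(
        z_cue.shape[1], bool
    )
    und[excluded] = True
    stat_map.undefined = und
    stat_map.values[excluded] = np.nan
    stat_map.z[excluded] = np.nan
    stat_map.description = "seed contrast (Fisher z, cue - control)"
    return SeedContrast(
        stat_map=stat_map,
        subject_contrasts=z_cue - z_ctl,
        excluded_nodes=excluded,
    )


def covariate_map(
    contrast_maps: np.ndarray, covariate: np.ndarray, shape=None
) -> StatMap:
    """Second-level slope map: regress node contrasts on a subject covariate.

    The covariate is mean-centred; per node the slope t-statistic has
    ``n_subjects - 2`` degrees of freedom. Nodes fitted exactly (zero
    residual variance, nonzero slope) are flagged ``capped``.
    """
    Y = np.asarray(contrast_maps, float)
    x = np.asarray(covariate, float)
    n = len(x)
    if Y.shape[0] != n:
        raise ValueError("covariate length must match number of subjects")
    if n < 4:
        raise ValueError("need at least 4 subjects")
    xc = x - x.mean()
    sxx = (xc**2).sum()
    if sxx == 0:
        raise ValueError("covariate is constant")
    slope = (xc @ Y) / sxx
    fitted = np.outer(xc, slope) + Y.mean(axis=0)
    rss = ((Y - fitted) ** 2).sum(axis=0)
    df = n - 2
    with np.errstate(invalid="ignore", divide="ignore"):
        se = np.sqrt(rss / df / sxx)
        t = slope / se
    capped = (se == 0) & (slope != 0)
    t[capped] = np.sign(slope[capped]) * np.inf
    t[(se == 0) & (slope == 0)] = 0.0
    z = np.where(np.isinf(t), np.sign(t) * Z_CAP, 0.0)
    finite = np.isfinite(t)
    z[finite] = _t_to_z(t[finite], df)
    return StatMap(
        values=t, z=z, df=df, shape=shape, capped=capped,
        description="covariate slope t",
    )


def _connectivity_structure(connectivity: int) -> np.ndarray:
    rank = {6: 1, 18: 2, 26: 3}.get(connectivity)
    if rank is None:
        raise ValueError("connectivity must be 6, 18 or 26")
    return ndimage.generate_binary_structure(3, rank)


def _label_clusters(above: np.ndarray, shape, structure):
    lab, n = ndimage.label(above.reshape(shape), structure=structure)
    return lab.reshape(-1), n


def _max_null_extents(
    subject_maps: np.ndarray,
    t_thresh: float,
    shape,
    structure,
    mask: np.ndarray,
    n_perm: int,
    rng: np.random.Generator,
) -> np.ndarray:
    """Max cluster extent per sign-flipping permutation under the null."""
    S, V = subject_maps.shape
    msq = (subject_maps**2).mean(axis=0)  # invariant under sign flips
    out = np.empty(n_perm, dtype=int)
    signs = rng.choice([-1.0, 1.0], size=(n_perm, S))
    for p in range(n_perm):
        mean = (signs[p] @ subject_maps) / S
        var = (msq - mean**2) * S / (S - 1)
        with np.errstate(invalid="ignore", divide="ignore"):
            t = mean / np.sqrt(var / S)
        above = (t > t_thresh) & mask & np.isfinite(t)
        if not above.any():
            out[p] = 0
            continue
        lab, n = _label_clusters(above, shape, structure)
        out[p] = np.bincount(lab[lab > 0]).max() if n else 0
    return out


def _smoothness_fwhm(subject_maps: np.ndarray, shape) -> np.ndarray:
    """Per-axis FWHM (voxels) from normalised residual spatial derivatives."""
    resid = subject_maps - subject_maps.mean(axis=0, keepdims=True)
    sd = resid.std(axis=0, ddof=1)
    sd[sd == 0] = 1.0
    e = (resid / sd).reshape(subject_maps.shape[0], *shape)
    fwhm = np.empty(3)
    for ax in range(3):
        d = np.diff(e, axis=ax + 1)
        v = d.var()
        fwhm[ax] = np.sqrt(4 * np.log(2) / v) if v > 0 else np.inf
    return fwhm


def _grf_cluster_p(extent, z_thresh, n_vox, fwhm):
    """Approximate GRF cluster-level p (expected-cluster-size formula)."""
    resel_per_vox = 1.0 / np.prod(np.clip(fwhm, 1e-3, None))
    resels = n_vox * resel_per_vox
    u = z_thresh
    # 3-D Euler-characteristic density and expected suprathreshold volume
    rho3 = (4 * np.log(2)) ** 1.5 / (2 * np.pi) ** 2 * (u**2 - 1) * np.exp(-(u**2) / 2)
    e_m = max(resels * rho3, 1e-12)
    e_n = n_vox * stats.norm.sf(u)
    beta = (special.gamma(2.5) * e_m / max(e_n, 1e-12)) ** (2 / 3)
    p_ge = np.exp(-beta * extent ** (2 / 3))
    return float(1.0 - np.exp(-e_m * p_ge))


def cluster_inference(
    stat_map: StatMap,
    z_threshold: float = 2.33,
    method: str = "permutation",
    n_perm: int = 1000,
    rng_seed: int = 0,
    mask: np.ndarray | None = None,
    subject_maps: np.ndarray | None = None,
    connectivity: int = 6,
) -> list[ClusterResult]:
    """Cluster-extent inference at a cluster-forming threshold.

    Clusters are maximal face-connected (6-neighbour by default) components
    of the one-sided suprathreshold map ``z > z_threshold``. With
    ``method="permutation"`` the null distribution of the maximum cluster
    extent is built by sign-flipping the subject-level difference/contrast
    maps; corrected p = (1 + #{null >= observed}) / (1 + n_perm). With
    ``method="grf"`` the corrected p comes from the approximate
    Gaussian-Random-Field expected-cluster-size formula.
    """
    if stat_map.shape is None:
        raise ValueError("cluster inference needs a map on a 3-D grid")
    shape = stat_map.shape
    structure = _connectivity_structure(connectivity)
    valid = np.isfinite(stat_map.z)
    if stat_map.undefined is not None:
        valid &= ~stat_map.undefined
    if mask is not None:
        valid &= np.asarray(mask, bool).reshape(-1)
    above = valid & (stat_map.z > z_threshold)
    if not above.any():
        return []
    lab, n_clust = _label_clusters(above, shape, structure)

    clusters = []
    for c in range(1, n_clust + 1):
        nodes = np.flatnonzero(lab == c)
        peak_local = nodes[np.nanargmax(stat_map.z[nodes])]
        clusters.append(
            dict(
                nodes=nodes,
                extent=len(nodes),
                peak_stat=float(stat_map.z[peak_local]),
                peak_index=np.unravel_index(peak_local, shape),
            )
        )

    if method == "permutation":
        if subject_maps is None:
            raise ValueError("permutation inference needs subject-level maps")
        if n_perm < 100:
            raise ValueError("use at least 100 permutations")
        rng = np.random.default_rng(rng_seed)
        t_thresh = float(stats.t.isf(stats.norm.sf(z_threshold), stat_map.df))
        null_max = _max_null_extents(
            np.asarray(subject_maps, float), t_thresh, shape, structure,
            valid, n_perm, rng,
        )
        for c in clusters:
            c["corrected_p"] = float(
                (1 + np.sum(null_max >= c["extent"])) / (1 + n_perm)
            )
    elif method == "grf":
        if subject_maps is not None:
            fwhm = _smoothness_fwhm(np.asarray(subject_maps, float), shape)
        else:
            fwhm = np.full(3, 2.0)
        n_search = int(valid.sum())
        for c in clusters:
            c["corrected_p"] = _grf_cluster_p(c["extent"], z_threshold, n_search, fwhm)
    else:
        raise ValueError(f"unknown method {method!r}")

    return [ClusterResult(**c) for c in sorted(clusters, key=lambda d: -d["extent"])]


def bh_critical_p(pvals, q: float = 0.05) -> float:
    """Benjamini-Hochberg critical p: the largest sorted p(i) <= i*q/m.

    Returns 0.0 when no p-value passes its step-up threshold.
    """
    p = np.sort(np.asarray(pvals, dtype=float))
    m = len(p)
    passed = p <= q * np.arange(1, m + 1) / m
    if not passed.any():
        return 0.0
    return float(p[np.max(np.flatnonzero(passed))])


def small_volume_correct(
    stat_map: StatMap,
    roi_masks: dict[str, np.ndarray],
    z_threshold: float = 2.33,
    q: float = 0.05,
    method: str = "permutation",
    n_perm: int = 1000,
    rng_seed: int = 0,
    subject_maps: np.ndarray | None = None,
    connectivity: int = 6,
) -> RoiCorrection:
    """Small-volume cluster inference per ROI, then BH across ROIs.

    Each named mask restricts cluster inference to the ROI; the ROI's
    p-value is its minimum corrected cluster p (1.0 when no suprathreshold
    cluster exists). The Benjamini-Hochberg critical p is computed over the
    ROI p-values and ROIs at or below it are flagged significant.
    """
    roi_p = {}
    for name, m in roi_masks.items():
        m = np.asarray(m, bool).reshape(-1)
        if not m.any():
            raise ValueError(f"ROI mask {name!r} is empty")
        clusters = cluster_inference(
            stat_map, z_threshold=z_threshold, method=method, n_perm=n_perm,
            rng_seed=rng_seed, mask=m, subject_maps=subject_maps,
            connectivity=connectivity,
        )
        roi_p[name] = min((c.corrected_p for c in clusters), default=1.0)
    crit = bh_critical_p(list(roi_p.values()), q)
    significant = {k: bool(crit > 0 and v <= crit) for k, v in roi_p.items()}
    return RoiCorrection(roi_p=roi_p, critical_p=crit, significant=significant, q=q)
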