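"""Seed-based resting-state FC of the bilateral clusters and the directional
group contrasts between them.

Per subject and merged cluster: the cluster's mean BOLD time series is
correlated (Pearson) with every brain voxel and Fisher z-transformed.  For
each ordered cluster pair (X > Y) a paired one-tailed t-test on the
per-subject Fisher-z difference maps is corrected with Benjamini-Hochberg
FDR per contrast, and the corrected q-values are converted to z-scores,
thresholded at 1.645 (one-tailed p = 0.05).
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import permutations

import numpy as np
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .bold import BoldSeries
from .parcellation import Parcellation

__all__ = [
    "SeedFCMap",
    "ContrastResult",
    "Z_THRESHOLD",
    "FISHER_CAP",
    "cluster_timeseries",
    "seed_fc",
    "contrast",
    "run_all_contrasts",
]

#: one-tailed standard normal quantile at p = 0.05
Z_THRESHOLD = 1.6448536269514722
#: |r| is clipped to 1 - 1e-7 before atanh so Fisher z stays finite
FISHER_CAP = 1e-7
#: cap on |z| after q -> z conversion (keeps maps finite at q ~ 0)
Z_CAP = 8.2


@dataclass
class SeedFCMap:
    """One subject x cluster seed-FC result over the brain mask."""

    r: np.ndarray           # (n_mask_voxels,)
    fisher_z: np.ndarray    # (n_mask_voxels,)
    n_timepoints: int
    zero_variance: np.ndarray  # bool flags, r set to 0 there


@dataclass
class ContrastResult:
    """Voxel-wise directional contrast X > Y over a brain mask."""

    contrast: tuple[str, str]
    t_map: np.ndarray
    p_map: np.ndarray
    q_map: np.ndarray
    z_map: np.ndarray
    df: int
    threshold: float = Z_THRESHOLD

    @property
    def suprathreshold(self) -> np.ndarray:
        return self.z_map >= self.threshold


def cluster_timeseries(b: BoldSeries, p: Parcellation, merged_id: str) -> np.ndarray:
    """Unweighted mean BOLD series over all voxels of one merged cluster."""
    merged = p.merged_labels()
    letters = p.merged_ids()
    if merged_id not in letters:
        raise ValueError(f"unknown merged cluster {merged_id!r}")
    code = letters.index(merged_id) + 1
    mask = merged == code
    if not mask.any():
        raise ValueError(f"merged cluster {merged_id!r} is empty")
    return b.data[mask, :].mean(axis=0)


def seed_fc(b: BoldSeries, series: np.ndarray, brain_mask: np.ndarray) -> SeedFCMap:
    """Voxel-wise Pearson correlation of every in-mask voxel with a seed
    series, plus its Fisher z transform (|r| clipped to 1 - 1e-7).

    Zero-variance voxels get r = 0 and are flagged.
    """
    series = np.asarray(series, dtype=float)
    T = b.n_timepoints
    if series.shape != (T,):
        raise ValueError("seed series length must match the BOLD series")
    if series.std() == 0:
        raise ValueError("seed series is constant")
    mask = np.asarray(brain_mask).astype(bool)
    X = b.data[mask, :]  # (v, T)
    sc = series - series.mean()
    Xc = X - X.mean(axis=1, keepdims=True)
    sx = np.sqrt((Xc**2).sum(axis=1))
    ss = np.sqrt((sc**2).sum())
    zero_var = sx < 1e-12
    denom = np.where(zero_var, 1.0, sx * ss)
    r = np.clip((Xc @ sc) / denom, -1.0, 1.0)
    r[zero_var] = 0.0
    z = np.arctanh(np.clip(r, -1.0 + FISHER_CAP, 1.0 - FISHER_CAP))
    return SeedFCMap(r=r, fisher_z=z, n_timepoints=T, zero_variance=zero_var)


def contrast(
    fc_x: list[np.ndarray] | np.ndarray,
    fc_y: list[np.ndarray] | np.ndarray,
    names: tuple[str, str] = ("X", "Y"),
    threshold: float = Z_THRESHOLD,
) -> ContrastResult:
    """Paired one-tailed t-test (X > Y) on per-subject Fisher-z maps.

    Per voxel, with d_i = z_Xi - z_Yi over n subjects: t = mean(d) /
    (sd(d)/sqrt(n)), one-tailed p = 1 - CDF_t(t; n-1); BH-FDR across voxels
    gives q, and z = Phi^-1(1 - q) capped at +/-8.2.  Voxels with sd(d) = 0
    get p = 0.5.
    """
    X = np.asarray(fc_x, dtype=float)
    Y = np.asarray(fc_y, dtype=float)
    if X.shape != Y.shape:
        raise ValueError("subject map stacks must have identical shape")
    n = X.shape[0]
    if n < 3:
        raise ValueError("need at least 3 subjects")
    d = X - Y
    mean = d.mean(axis=0)
    sd = d.std(axis=0, ddof=1)
    flat_sd = sd == 0
    t = np.where(flat_sd, 0.0, mean / np.where(flat_sd, 1.0, sd / np.sqrt(n)))
    df = n - 1
    p = stats.t.sf(t, df)
    p[flat_sd] = 0.5
    _, q, _, _ = multipletests(p.ravel(), method="fdr_bh")
    q = q.reshape(p.shape)
    z = np.clip(stats.norm.isf(q), -Z_CAP, Z_CAP)
    return ContrastResult(
        contrast=names, t_map=t, p_map=p, q_map=q, z_map=z, df=df,
        threshold=threshold,
    )


def run_all_contrasts(
    fc_by_cluster: dict[str, list[np.ndarray]],
    threshold: float = Z_THRESHOLD,
) -> dict[tuple[str, str], ContrastResult]:
    """All ordered pairwise contrasts between the clusters' subject z-maps.

    Three clusters yield six directional contrasts (A>B, B>A, A>C, C>A,
    B>C, C>B), each carrying its own FDR family.
    """
    names = sorted(fc_by_cluster)
    if len(names) < 2:
        raise ValueError("need at least 2 clusters to contrast")
    n_subj = {k: len(v) for k, v in fc_by_cluster.items()}
    if len(set(n_subj.values())) != 1:
        raise ValueError(f"subject counts differ across clusters: {n_subj}")
    out = {}
    for a, b in permutations(names, 2):
        out[(a, b)] = contrast(
            fc_by_cluster[a], fc_by_cluster[b], names=(a, b), threshold=threshold
        )
    return out
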