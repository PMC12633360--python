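"""Connectivity-based parcellation of the seed region from TW-dFC maps.

Pipeline: temporally concatenate subjects' 4D TW-dFC maps over an analysis
mask -> PCA-reduce and run fixed-point (FastICA) spatial ICA, retaining
enough components to explain a target fraction of variance (default 0.98)
-> threshold each component's spatial z-map (Gaussian-mixture posterior by
default) -> stack the thresholded z-scores at each seed voxel into a feature
vector -> k-means cluster the seed voxels -> merge hemispherically
symmetric clusters across the midline into lettered bilateral clusters
(A, B, C, ...).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import linear_sum_assignment
from sklearn.cluster import KMeans
from sklearn.decomposition import PCA, FastICA
from sklearn.exceptions import ConvergenceWarning

from .grid import VolumeGrid, voxel_centers
from .twdfc_map import TWdFCMap

__all__ = [
    "ComponentSet",
    "FeatureMatrix",
    "Parcellation",
    "concatenate_maps",
    "decompose",
    "threshold_zmaps",
    "build_features",
    "kmeans_parcellate",
    "merge_bilateral",
]

logger = logging.getLogger(__name__)


@dataclass
class ComponentSet:
    """Spatial ICA result: z-scored maps, mixing matrix, variance bookkeeping."""

    spatial_maps: np.ndarray       # (n_components, n_voxels) z-scored
    mixing: np.ndarray             # (n_frames, n_components)
    variance_explained: float      # cumulative PCA variance fraction retained
    analysis_voxels: np.ndarray    # (n_voxels, 3) int indices into the grid
    grid: VolumeGrid

    @property
    def n_components(self) -> int:
        return self.spatial_maps.shape[0]


@dataclass
class FeatureMatrix:
    """(seed voxels x components) feature array plus the voxel index list."""

    features: np.ndarray
    voxels: np.ndarray  # (n_seed_voxels, 3), lexicographic order
    n_outside_analysis: int = 0


@dataclass
class Parcellation:
    """Integer label volume over the seed mask (0 background, 1..k inside),
    optionally with a bilateral cluster-id -> letter merge mapping."""

    labels: np.ndarray
    k: int
    grid: VolumeGrid
    centroids: np.ndarray                     # (k, 3) world mm, row c = label c+1
    bilateral_map: dict[int, str] = field(default_factory=dict)
    inertia: float = float("nan")

    def merged_labels(self) -> np.ndarray:
        """Label volume re-coded to merged ids (1=A, 2=B, ...); 0 background."""
        if not self.bilateral_map:
            raise ValueError("no bilateral merge has been applied")
        letters = sorted(set(self.bilateral_map.values()))
        code = {let: i + 1 for i, let in enumerate(letters)}
        out = np.zeros_like(self.labels)
        for lab, let in self.bilateral_map.items():
            out[self.labels == lab] = code[let]
        return out

    def merged_ids(self) -> list[str]:
        return sorted(set(self.bilateral_map.values()))


def concatenate_maps(maps: list[TWdFCMap], analysis_mask: np.ndarray | None = None):
    """Temporally concatenate subjects' TW-dFC maps into (frames x voxels).

    The analysis mask defaults to voxels finite in at least one frame of at
    least one subject.  Each subject block is demeaned per voxel (nan-aware)
    and remaining NaNs are imputed as 0, so every subject block has exactly
    zero column means.  Returns (data, analysis_voxels, subject_slices).
    """
    if not maps:
        raise ValueError("no maps given")
    grid = maps[0].grid
    for m in maps[1:]:
        if m.grid.dims != grid.dims or not np.allclose(m.grid.affine, grid.affine):
            raise ValueError("all maps must share the same grid")
    if analysis_mask is None:
        analysis_mask = np.zeros(grid.dims, dtype=bool)
        for m in maps:
            analysis_mask |= np.any(np.isfinite(m.data), axis=3)
    else:
        analysis_mask = np.asarray(analysis_mask).astype(bool)
    vox = np.argwhere(analysis_mask)  # lexicographic C-order
    blocks, slices, start = [], [], 0
    for m in maps:
        block = m.data[analysis_mask, :].T.astype(float)  # (frames, voxels)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN columns
            mean = np.nanmean(block, axis=0)
        block = block - np.where(np.isfinite(mean), mean, 0.0)
        block[~np.isfinite(block)] = 0.0
        blocks.append(block)
        slices.append(slice(start, start + block.shape[0]))
        start += block.shape[0]
    return np.vstack(blocks), vox, slices


def decompose(
    data: np.ndarray,
    n_components: int | str = "auto",
    var_threshold: float = 0.98,
    seed: int = 0,
    max_iter: int = 2000,
    grid: VolumeGrid | None = None,
    analysis_voxels: np.ndarray | None = None,
) -> ComponentSet:
    """PCA-reduce then fixed-point spatial ICA on (frames x voxels) data.

    In auto mode the component count is the smallest n whose cumulative PCA
    eigenvalue fraction reaches ``var_threshold``.  Spatial maps are
    standardised to z-scores per component.  Deterministic given ``seed``;
    if the fixed-point iteration fails to converge the decomposition is
    retried with a reseeded rotation before raising.
    """
    data = np.asarray(data, dtype=float)
    frames, voxels = data.shape
    max_rank = min(frames, voxels)
    pca = PCA(n_components=max_rank, svd_solver="full", random_state=seed)
    pca.fit(data)
    cum = np.cumsum(pca.explained_variance_ratio_)
    if n_components == "auto":
        n = int(np.searchsorted(cum, var_threshold - 1e-12) + 1)
        n = min(n, max_rank)
    else:
        n = int(n_components)
        if n > max_rank:
            raise ValueError(f"n_components={n} exceeds data rank bound {max_rank}")
    variance_explained = float(cum[n - 1])
    last_err = None
    for attempt in range(3):
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("error", ConvergenceWarning)
                ica = FastICA(
                    n_components=n,
                    whiten="unit-variance",
                    fun="logcosh",
                    max_iter=max_iter,
                    tol=1e-4,
                    random_state=seed + attempt,
                )
                # spatial ICA: voxels are samples, frames are features
                sources = ica.fit_transform(data.T)  # (voxels, n)
            break
        except ConvergenceWarning as e:  # retry once with a new rotation
            last_err = e
            logger.warning("FastICA did not converge (attempt %d), retrying", attempt)
    else:
        raise RuntimeError(f"ICA failed to converge after retries: {last_err}")
    maps = sources.T  # (n, voxels)
    mixing = ica.mixing_  # (frames, n)
    mu = maps.mean(axis=1, keepdims=True)
    sd = maps.std(axis=1, keepdims=True)
    sd[sd == 0] = 1.0
    zmaps = (maps - mu) / sd
    return ComponentSet(
        spatial_maps=zmaps,
        mixing=mixing,
        variance_explained=variance_explained,
        analysis_voxels=(
            analysis_voxels if analysis_voxels is not None else np.empty((0, 3), int)
        ),
        grid=grid if grid is not None else VolumeGrid.isotropic((1, 1, 1)),
    )


def _em_two_gaussians(z: np.ndarray, n_iter: int = 200, tol: float = 1e-8):
    """2-class Gaussian EM initialised as a robust null plus a broad signal
    class.  Returns (means, sds, weights, posterior_of_signal) or None when
    the fit degenerates."""
    med = np.median(z)
    mad = np.median(np.abs(z - med))
    scale = max(1.4826 * mad, 1e-3)
    mu = np.array([med, med])
    sd = np.array([scale, 3.0 * scale])
    w = np.array([0.9, 0.1])
    ll_old = -np.inf
    for _ in range(n_iter):
        log_pdf = (
            -0.5 * ((z[:, None] - mu[None, :]) / sd[None, :]) ** 2
            - np.log(sd[None, :])
            - 0.5 * np.log(2 * np.pi)
            + np.log(w[None, :])
        )
        m = log_pdf.max(axis=1, keepdims=True)
        p = np.exp(log_pdf - m)
        norm = p.sum(axis=1, keepdims=True)
        resp = p / norm
        ll = float(np.sum(np.log(norm) + m))
        nk = resp.sum(axis=0)
        if np.any(nk < 2):
            return None
        w = nk / z.size
        mu = (resp * z[:, None]).sum(axis=0) / nk
        var = (resp * (z[:, None] - mu[None, :]) ** 2).sum(axis=0) / nk
        if np.any(var < 1e-12):
            return None
        sd = np.sqrt(var)
        if abs(ll - ll_old) < tol * (1 + abs(ll)):
            break
        ll_old = ll
    # signal = the class with the larger second moment about the null centre,
    # so both heavy tails and mean-shifted populations count as signal
    # on a pure-noise map the classes converge to near-identical Gaussians
    # with a small-weight "signal" class whose posterior never exceeds 0.5,
    # so nothing is kept — no special-casing needed
    moment = (mu - med) ** 2 + sd**2
    sig = int(np.argmax(moment))
    return mu, sd, w, resp[:, sig]


def threshold_zmaps(
    c: ComponentSet, mode: str = "mixture", z_cut: float = 1.645
) -> np.ndarray:
    """Sparsify each component's spatial z-map.

    mode="mixture" (default): per component, fit a 2-class Gaussian mixture
    to the z values and keep voxels whose posterior probability of the
    signal class exceeds 0.5; falls back to the |z| rule with a warning when
    the mixture fit degenerates.  mode="zabs": keep |z| > z_cut.  Kept
    voxels retain their z value, all others are set exactly to 0.
    """
    if mode not in ("mixture", "zabs"):
        raise ValueError('mode must be "mixture" or "zabs"')
    out = np.zeros_like(c.spatial_maps)
    for i, z in enumerate(c.spatial_maps):
        if mode == "mixture":
            fit = _em_two_gaussians(z)
            if fit is None:
                warnings.warn(
                    f"mixture fit degenerate for component {i}; "
                    f"falling back to |z| > {z_cut}"
                )
                keep = np.abs(z) > z_cut
            else:
                keep = fit[3] > 0.5
        else:
            keep = np.abs(z) > z_cut
        out[i, keep] = z[keep]
    return out


def build_features(
    thresholded: np.ndarray,
    analysis_voxels: np.ndarray,
    seed_mask: np.ndarray,
) -> FeatureMatrix:
    """Per seed voxel, stack the component z-scores into a feature vector.

    Rows follow lexicographic voxel-index order.  Seed voxels absent from
    the analysis domain get an all-zero row (counted and warned about).
    """
    seed_mask = np.asarray(seed_mask).astype(bool)
    seed_vox = np.argwhere(seed_mask)
    lut = {tuple(v): i for i, v in enumerate(np.asarray(analysis_voxels))}
    n_comp = thresholded.shape[0]
    feats = np.zeros((seed_vox.shape[0], n_comp), dtype=float)
    missing = 0
    for r, v in enumerate(seed_vox):
        col = lut.get(tuple(v))
        if col is None:
            missing += 1
            continue
        feats[r] = thresholded[:, col]
    if missing:
        warnings.warn(f"{missing} seed voxels outside the analysis mask (zero rows)")
    return FeatureMatrix(features=feats, voxels=seed_vox, n_outside_analysis=missing)


def kmeans_parcellate(
    f: FeatureMatrix,
    k: int,
    grid: VolumeGrid,
    seed: int = 0,
    n_init: int = 10,
) -> Parcellation:
    """k-means++ clustering of seed-voxel feature vectors into k clusters.

    Labels are re-numbered 1..k by descending cluster size (ties broken by
    smaller lexicographic centroid).  Deterministic given ``seed``.
    """
    if k < 2:
        raise ValueError("k must be >= 2")
    X = f.features
    if X.shape[0] < k:
        raise ValueError("fewer rows than clusters")
    if np.unique(X, axis=0).shape[0] < k:
        raise ValueError("fewer distinct feature rows than clusters")
    km = KMeans(n_clusters=k, init="k-means++", n_init=n_init, random_state=seed)
    raw = km.fit_predict(X)
    sizes = np.bincount(raw, minlength=k)
    order = sorted(
        range(k), key=lambda c: (-sizes[c], tuple(km.cluster_centers_[c]))
    )
    relabel = {old: new + 1 for new, old in enumerate(order)}
    labels_vol = np.zeros(grid.dims, dtype=np.int32)
    for row, v in enumerate(f.voxels):
        labels_vol[tuple(v)] = relabel[raw[row]]
    centroids = np.zeros((k, 3), dtype=float)
    for lab in range(1, k + 1):
        vox = f.voxels[np.array([relabel[r] for r in raw]) == lab]
        centroids[lab - 1] = voxel_centers(vox, grid).mean(axis=0)
    return Parcellation(
        labels=labels_vol,
        k=k,
        grid=grid,
        centroids=centroids,
        inertia=float(km.inertia_),
    )


def merge_bilateral(
    p: Parcellation,
    midline_x: float = 0.0,
    override: dict[int, str] | None = None,
) -> Parcellation:
    """Pair mirror-symmetric left/right clusters into lettered bilateral ones.

    Clusters are split by centroid side of the midline plane x = midline_x;
    left/right pairs are matched by optimal one-to-one assignment between
    each left centroid and the mirror image (x -> 2 midline_x - x) of the
    right centroids.  Merged ids are lettered A, B, C... from anterior to
    posterior (descending mean centroid y).  An explicit ``override``
    mapping {cluster label -> letter} bypasses matching entirely.
    """
    if override is not None:
        bmap = dict(override)
        missing = set(range(1, p.k + 1)) - set(bmap)
        if missing:
            raise ValueError(f"override lacks labels {sorted(missing)}")
        return Parcellation(
            labels=p.labels,
            k=p.k,
            grid=p.grid,
            centroids=p.centroids,
            bilateral_map=bmap,
            inertia=p.inertia,
        )
    x = p.centroids[:, 0]
    left = np.flatnonzero(x < midline_x)
    right = np.flatnonzero(x >= midline_x)
    if len(left) != len(right):
        raise ValueError(
            f"{len(left)} left vs {len(right)} right clusters; supply an "
            "explicit override mapping to merge asymmetric solutions"
        )
    mirrored = p.centroids[right].copy()
    mirrored[:, 0] = 2.0 * midline_x - mirrored[:, 0]
    cost = np.linalg.norm(
        p.centroids[left][:, None, :] - mirrored[None, :, :], axis=2
    )
    li, ri = linear_sum_assignment(cost)
    pairs = [(int(left[a]) + 1, int(right[b]) + 1) for a, b in zip(li, ri)]
    # letter pairs anterior (larger y) to posterior
    mean_y = [
        0.5 * (p.centroids[a - 1, 1] + p.centroids[b - 1, 1]) for a, b in pairs
    ]
    bmap: dict[int, str] = {}
    for rank, pi in enumerate(np.argsort(mean_y)[::-1]):
        letter = chr(ord("A") + rank)
        a, b = pairs[pi]
        bmap[a] = letter
        bmap[b] = letter
    return Parcellation(
        labels=p.labels,
        k=p.k,
        grid=p.grid,
        centroids=p.centroids,
        bilateral_map=bmap,
        inertia=p.inertia,
    )
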