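"""End-to-end convenience drivers composing the library stages.

These mirror the two studies the toolkit is built for: (1) per-subject
TW-dFC maps -> group spatial ICA -> k-means parcellation of the seed with
bilateral merging; (2) per-subject seed-based FC of each merged cluster ->
directional group contrasts.
"""

from __future__ import annotations

import numpy as np

from .bold import BoldSeries, bandpass, gaussian_smooth
from .groupfc import ContrastResult, run_all_contrasts, cluster_timeseries, seed_fc
from .parcellation import (
    Parcellation,
    build_features,
    concatenate_maps,
    decompose,
    kmeans_parcellate,
    merge_bilateral,
    threshold_zmaps,
)
from .seed import classify_endpoints, extract_seed_tractogram
from .tck import Tractogram
from .twdfc_map import TWdFCMap, WindowSpec, compute_twdfc

__all__ = [
    "preprocess",
    "subject_twdfc",
    "parcellate_cohort",
    "cohort_contrasts",
    "phantom_group_study",
]


def preprocess(
    b: BoldSeries,
    fwhm_mm: float = 6.0,
    band_hz: tuple[float, float] = (0.01, 0.1),
    mask: np.ndarray | None = None,
) -> BoldSeries:
    """Standard pre-processing: Gaussian smoothing then temporal bandpass."""
    out = gaussian_smooth(b, fwhm_mm, mask=mask)
    if band_hz is not None:
        out = bandpass(out, *band_hz)
    return out


def subject_twdfc(
    bold: BoldSeries,
    tractogram: Tractogram,
    seed_mask: np.ndarray,
    spec: WindowSpec | None = None,
    policy: str = "one",
    use_weights: bool = False,
) -> TWdFCMap:
    """Seed-restrict the tractogram and compute one subject's TW-dFC map."""
    cats = classify_endpoints(tractogram, seed_mask, bold.grid)
    sub, table = extract_seed_tractogram(
        tractogram, cats, bold.grid, seed_mask, policy=policy
    )
    return compute_twdfc(bold, sub, table, spec=spec, use_weights=use_weights)


def parcellate_cohort(
    maps: list[TWdFCMap],
    seed_mask: np.ndarray,
    k: int = 6,
    n_components: int | str = "auto",
    var_threshold: float = 0.98,
    threshold_mode: str = "mixture",
    rng_seed: int = 0,
    midline_x: float = 0.0,
    strict_merge: bool = True,
) -> tuple[Parcellation, float]:
    """Concatenate maps, decompose, threshold, cluster and merge bilaterally.

    Returns (merged parcellation, variance explained by retained components).
    With ``strict_merge=False`` an asymmetric solution (unequal cluster
    counts per hemisphere) is returned unmerged with a warning instead of
    raising.
    """
    data, vox, _ = concatenate_maps(maps)
    comps = decompose(
        data,
        n_components=n_components,
        var_threshold=var_threshold,
        seed=rng_seed,
        grid=maps[0].grid,
        analysis_voxels=vox,
    )
    thr = threshold_zmaps(comps, mode=threshold_mode)
    feats = build_features(thr, vox, seed_mask)
    parc = kmeans_parcellate(feats, k=k, grid=maps[0].grid, seed=rng_seed)
    try:
        merged = merge_bilateral(parc, midline_x=midline_x)
    except ValueError:
        if strict_merge:
            raise
        import warnings

        warnings.warn("bilateral merge failed; returning unmerged parcellation")
        merged = parc
    return merged, comps.variance_explained


def phantom_group_study(cfg, n_subjects: int, master_seed: int):
    """Seed-FC group study on a phantom cohort with the planted cluster atlas.

    Smoothing is mask-renormalised over the phantom's tissue (seed + target
    regions); the FC family is the tissue voxels outside the seed (a
    cluster's correlation with its own voxels is trivially positive and is
    not part of the contrast question).  Returns (phantom, fc_mask,
    {cluster letter -> per-subject Fisher-z maps}).
    """
    from .groupfc import seed_fc as _seed_fc
    from .phantom import make_cohort

    phantom, cohort = make_cohort(cfg, n_subjects, master_seed)
    labels = phantom.bilateral_labels()
    n_clusters = int(labels.max())
    tissue = phantom.region_map >= 0
    fc_mask = tissue & ~phantom.seed_mask
    letters = [chr(ord("A") + i) for i in range(n_clusters)]
    fc: dict[str, list[np.ndarray]] = {c: [] for c in letters}
    for subj in cohort:
        b = preprocess(subj["bold"], mask=tissue)
        for ci, c in enumerate(letters):
            series = b.data[labels == ci + 1, :].mean(axis=0)
            fc[c].append(_seed_fc(b, series, fc_mask).fisher_z)
    return phantom, fc_mask, fc


def cohort_contrasts(
    bolds: list[BoldSeries],
    parcellation: Parcellation,
    brain_mask: np.ndarray,
) -> dict[tuple[str, str], ContrastResult]:
    """Per-subject seed FC of every merged cluster, then all directional
    group contrasts (paired, one-tailed, per-contrast BH-FDR)."""
    fc: dict[str, list[np.ndarray]] = {m: [] for m in parcellation.merged_ids()}
    for b in bolds:
        for m in parcellation.merged_ids():
            series = cluster_timeseries(b, parcellation, m)
            fc[m].append(seed_fc(b, series, brain_mask).fisher_z)
    return run_all_contrasts(fc)
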