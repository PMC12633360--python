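"""Synthetic phantoms with the statistical structure the pipeline assumes.

The phantom emulates, at desk scale, the ingredients of a seed-restricted
structure-function study: a bilateral seed region (two mirrored ellipsoids,
standing in for the left and right hippocampus) split into contiguous
subregions along its long (anterior-posterior) axis; distal grey-matter
target blocks; streamlines wired subregion -> target according to a
connectivity matrix; and BOLD series whose inter-regional coupling switches
between latent states over time, which is exactly the signal a sliding-window
track-weighted analysis is built to detect.

Signals are generated at region level (multivariate normal per latent state,
AR(1)-smoothed) and copied to each region's voxels with independent additive
voxel noise; this keeps the coupling structure exactly controllable.  Every
generator is a pure function of its configuration and seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .bold import BoldSeries
from .grid import VolumeGrid, voxel_centers
from .tck import Tractogram

__all__ = [
    "PhantomConfig",
    "Phantom",
    "GroundTruth",
    "default_couplings",
    "equicorrelated_couplings",
    "add_coupling_effect",
    "make_phantom",
    "simulate_states",
    "simulate_streamlines",
    "simulate_bold",
    "make_cohort",
    "null_config",
    "effect_config",
]

#: per-bilateral-subregion coupling to its primary target in each latent
#: state: subregion 1 is state-1-coupled, subregion 2 state-2-coupled,
#: subregion 3 statically coupled — three distinct temporal profiles
DEFAULT_STATE_PROFILES = ((0.8, 0.1), (0.1, 0.8), (0.45, 0.45))


def default_couplings(
    n_subregions: int = 3,
    n_targets: int = 6,
    profiles=DEFAULT_STATE_PROFILES,
) -> list[np.ndarray]:
    """State-wise region correlation matrices for the default phantom.

    Region order: subregions left 0..n-1, right n..2n-1, then targets.
    Left subregion i couples to target i, right subregion i to target
    i + n_subregions (mirror wiring); the strength per state follows
    ``profiles[i % len(profiles)]``.  Block-2x2 structure keeps every matrix
    positive definite for |rho| < 1.
    """
    n_states = len(profiles[0])
    n_regions = 2 * n_subregions + n_targets
    out = []
    for s in range(n_states):
        C = np.eye(n_regions)
        for side in range(2):
            for i in range(n_subregions):
                region = side * n_subregions + i
                target = 2 * n_subregions + (side * n_subregions + i) % n_targets
                rho = profiles[i % len(profiles)][s]
                C[region, target] = C[target, region] = rho
        out.append(C)
    return out


def equicorrelated_couplings(
    n_regions: int, rho: float, n_states: int = 1
) -> list[np.ndarray]:
    """All region pairs share correlation rho in every state (a null world:
    every cluster sees the same FC everywhere)."""
    C = np.full((n_regions, n_regions), rho)
    np.fill_diagonal(C, 1.0)
    return [C.copy() for _ in range(n_states)]


def add_coupling_effect(
    couplings: list[np.ndarray], pairs: list[tuple[int, int]], delta: float
) -> list[np.ndarray]:
    """Add ``delta`` to the given region-pair correlations in every state."""
    out = []
    for C in couplings:
        C = C.copy()
        for a, b in pairs:
            C[a, b] += delta
            C[b, a] += delta
        out.append(C)
    return out


@dataclass(frozen=True)
class PhantomConfig:
    """Geometry, wiring and signal parameters of the synthetic study."""

    dims: tuple[int, int, int] = (32, 32, 24)
    voxel_mm: float = 2.0
    n_subregions: int = 3           # per side
    n_targets: int = 6
    streamlines_per_subregion: int = 200
    connectivity: np.ndarray | None = None   # (2*n_subregions, n_targets)
    T: int = 300
    tr: float = 0.72
    n_states: int = 2
    dwell_mean: float = 100.0       # volumes
    couplings: list | None = None   # per-state region correlation matrices
    noise_sd: float = 1.0           # voxel noise, signal variance is 1
    ar_phi: float = 0.3
    midpoint_jitter_mm: float = 6.0
    seed_semiaxes_vox: tuple[float, float, float] = (2.6, 8.2, 2.6)
    target_size_vox: int = 3

    @property
    def n_regions(self) -> int:
        return 2 * self.n_subregions + self.n_targets

    def resolved_connectivity(self) -> np.ndarray:
        """Subregion -> target probabilities; default: 0.8 on the mirror-wired
        primary target, the rest spread uniformly."""
        if self.connectivity is not None:
            C = np.asarray(self.connectivity, dtype=float)
            if C.shape != (2 * self.n_subregions, self.n_targets):
                raise ValueError("connectivity must be (2*n_subregions, n_targets)")
            if not np.allclose(C.sum(axis=1), 1.0):
                raise ValueError("connectivity rows must sum to 1")
            if np.any(C < 0):
                raise ValueError("connectivity entries must be non-negative")
            return C
        C = np.full(
            (2 * self.n_subregions, self.n_targets),
            0.2 / max(self.n_targets - 1, 1),
        )
        for row in range(2 * self.n_subregions):
            C[row, row % self.n_targets] = 0.8
        return C

    def resolved_couplings(self) -> list[np.ndarray]:
        cs = (
            self.couplings
            if self.couplings is not None
            else default_couplings(self.n_subregions, self.n_targets)[: self.n_states]
        )
        if len(cs) != self.n_states:
            raise ValueError(f"need {self.n_states} coupling matrices, got {len(cs)}")
        for C in cs:
            C = np.asarray(C, dtype=float)
            if C.shape != (self.n_regions, self.n_regions):
                raise ValueError("coupling matrix has wrong shape")
            if not np.allclose(C, C.T):
                raise ValueError("coupling matrix must be symmetric")
            if not np.allclose(np.diag(C), 1.0):
                raise ValueError("coupling matrix must have unit diagonal")
            if np.linalg.eigvalsh(C).min() < -1e-10:
                raise ValueError("coupling matrix is not positive semidefinite")
        return [np.asarray(C, dtype=float) for C in cs]

    def validate(self) -> None:
        if self.n_subregions < 1 or self.n_targets < 2 * self.n_subregions:
            raise ValueError("need at least one target per subregion per side")
        if self.dwell_mean < 1:
            raise ValueError("dwell_mean must be >= 1 volume")
        self.resolved_connectivity()
        self.resolved_couplings()


@dataclass
class Phantom:
    grid: VolumeGrid
    seed_mask: np.ndarray          # bool
    subregion_labels: np.ndarray   # int, 1..2n (left 1..n, right n+1..2n)
    target_masks: list[np.ndarray]
    region_map: np.ndarray         # int, region index per voxel, -1 outside

    def bilateral_labels(self) -> np.ndarray:
        """Planted labels mirrored left/right: left i and right i share id i."""
        out = np.zeros_like(self.subregion_labels)
        n = (int(self.subregion_labels.max())) // 2
        for lab in range(1, 2 * n + 1):
            out[self.subregion_labels == lab] = (lab - 1) % n + 1
        return out


@dataclass
class GroundTruth:
    assignments: np.ndarray | None = None   # (n_streamlines, 2): subregion row, target
    states: np.ndarray | None = None        # (T,) latent state sequence
    couplings: list | None = None
    labels: np.ndarray | None = None        # bilateral subregion label volume


def make_phantom(cfg: PhantomConfig) -> Phantom:
    """Build the deterministic phantom geometry.

    Two mirrored ellipsoids (long axis = y) are split into ``n_subregions``
    contiguous slabs along y; cuboid targets sit laterally of each seed body
    at the y-level of their wired subregion.  Raises if any regions overlap.
    """
    cfg.validate()
    dims = cfg.dims
    v = cfg.voxel_mm
    origin = (
        -(dims[0] / 2.0 - 0.5) * v,   # midline x = 0 between the two centre columns
        -(dims[1] - 1) / 2.0 * v,
        -(dims[2] - 1) / 2.0 * v,
    )
    grid = VolumeGrid.isotropic(dims, v, origin)
    i, j, k = np.indices(dims)
    a, b, c = cfg.seed_semiaxes_vox
    cx_left = dims[0] / 2.0 - 1 - a - 2.0   # keep a gap to the midline/targets
    cx_right = dims[0] - 1 - cx_left
    cy, cz = (dims[1] - 1) / 2.0, (dims[2] - 1) / 2.0
    left = ((i - cx_left) / a) ** 2 + ((j - cy) / b) ** 2 + ((k - cz) / c) ** 2 <= 1.0
    right = ((i - cx_right) / a) ** 2 + ((j - cy) / b) ** 2 + ((k - cz) / c) ** 2 <= 1.0
    if (left & right).any():
        raise ValueError("seed bodies overlap; shrink seed_semiaxes_vox")
    seed = left | right
    labels = np.zeros(dims, dtype=np.int32)
    n = cfg.n_subregions
    ys = np.flatnonzero(seed.any(axis=(0, 2)))
    edges = np.linspace(ys.min(), ys.max() + 1, n + 1)
    for s, body in enumerate((left, right)):
        for sub in range(n):
            slab = body & (j >= edges[sub]) & (j < edges[sub + 1])
            labels[slab] = s * n + sub + 1
    # targets: lateral blocks at the y-level of their wired subregion
    tsz = cfg.target_size_vox
    target_masks = []
    sub_y_centers = 0.5 * (edges[:-1] + edges[1:])
    for t in range(cfg.n_targets):
        side = 0 if t < n else 1
        sub = t % n
        x0 = 1 if side == 0 else dims[0] - 1 - tsz
        y0 = int(round(sub_y_centers[sub])) - tsz // 2
        z0 = (dims[2] - tsz) // 2 + (4 if sub % 2 else -4)
        m = np.zeros(dims, dtype=bool)
        m[x0 : x0 + tsz, y0 : y0 + tsz, z0 : z0 + tsz] = True
        if not m.any() or m.sum() != tsz**3:
            raise ValueError("target block falls outside the grid; enlarge dims")
        target_masks.append(m)
    all_t = np.zeros(dims, dtype=int)
    for m in target_masks:
        all_t += m
    if all_t.max() > 1 or (seed & (all_t > 0)).any():
        raise ValueError("regions overlap; adjust geometry parameters")
    region_map = np.full(dims, -1, dtype=np.int32)
    region_map[labels > 0] = labels[labels > 0] - 1
    for t, m in enumerate(target_masks):
        region_map[m] = 2 * n + t
    return Phantom(
        grid=grid,
        seed_mask=seed,
        subregion_labels=labels,
        target_masks=target_masks,
        region_map=region_map,
    )


def simulate_states(
    T: int, n_states: int, dwell_mean: float, rng: np.random.Generator
) -> np.ndarray:
    """Latent Markov chain with geometric dwell times (mean ``dwell_mean``)."""
    p_switch = 1.0 / dwell_mean
    states = np.empty(T, dtype=np.int64)
    s = int(rng.integers(n_states))
    for t in range(T):
        states[t] = s
        if n_states > 1 and rng.random() < p_switch:
            others = [x for x in range(n_states) if x != s]
            s = others[int(rng.integers(len(others)))]
    return states


def _resample_1mm(points: np.ndarray, step_mm: float = 1.0) -> np.ndarray:
    seg = np.linalg.norm(np.diff(points, axis=0), axis=1)
    arc = np.concatenate([[0.0], np.cumsum(seg)])
    total = arc[-1]
    targets = np.concatenate([np.arange(0.0, total, step_mm), [total]])
    return np.column_stack([np.interp(targets, arc, points[:, d]) for d in range(3)])


def simulate_streamlines(
    phantom: Phantom, cfg: PhantomConfig, rng: np.random.Generator
) -> tuple[Tractogram, GroundTruth]:
    """Draw streamlines subregion -> target following the connectivity matrix.

    Each streamline is a quadratic Bezier from a subregion voxel centre to a
    target voxel centre with a jittered midpoint, resampled at 1 mm.  Start
    voxels cycle through a shuffled list of the subregion's voxels so every
    seed voxel is traversed.  Exactly one endpoint lies in the seed mask by
    construction.
    """
    C = cfg.resolved_connectivity()
    n = cfg.n_subregions
    streamlines, rows = [], []
    for row in range(2 * n):
        sub_vox = np.argwhere(phantom.subregion_labels == row + 1)
        perm = rng.permutation(len(sub_vox))
        t_draws = rng.choice(cfg.n_targets, size=cfg.streamlines_per_subregion, p=C[row])
        for s_i in range(cfg.streamlines_per_subregion):
            start_vox = sub_vox[perm[s_i % len(sub_vox)]]
            tmask = phantom.target_masks[t_draws[s_i]]
            t_vox_all = np.argwhere(tmask)
            end_vox = t_vox_all[int(rng.integers(len(t_vox_all)))]
            p0 = voxel_centers(start_vox, phantom.grid)[0]
            p1 = voxel_centers(end_vox, phantom.grid)[0]
            mid = 0.5 * (p0 + p1) + rng.normal(0.0, cfg.midpoint_jitter_mm, 3)
            u = np.linspace(0.0, 1.0, 40)[:, None]
            bez = (1 - u) ** 2 * p0 + 2 * u * (1 - u) * mid + u**2 * p1
            streamlines.append(_resample_1mm(bez))
            rows.append((row, int(t_draws[s_i])))
    truth = GroundTruth(
        assignments=np.asarray(rows, dtype=np.int64),
        labels=phantom.bilateral_labels(),
    )
    tract = Tractogram(streamlines=streamlines, header={"count": str(len(streamlines))})
    return tract, truth


def simulate_bold(
    phantom: Phantom, cfg: PhantomConfig, rng: np.random.Generator
) -> tuple[BoldSeries, GroundTruth]:
    """Region-level state-switching multivariate normal signals, AR(1)
    smoothed, copied to region voxels with iid voxel noise on top."""
    couplings = cfg.resolved_couplings()
    chols = [np.linalg.cholesky(C + 1e-10 * np.eye(cfg.n_regions)) for C in couplings]
    states = simulate_states(cfg.T, cfg.n_states, cfg.dwell_mean, rng)
    sig = np.empty((cfg.T, cfg.n_regions))
    innov = rng.standard_normal((cfg.T, cfg.n_regions))
    phi = cfg.ar_phi
    prev = chols[states[0]] @ innov[0]
    sig[0] = prev
    scale = np.sqrt(1.0 - phi**2)  # keeps unit marginal variance
    for t in range(1, cfg.T):
        e = chols[states[t]] @ innov[t]
        prev = phi * prev + scale * e
        sig[t] = prev
    data = rng.normal(0.0, cfg.noise_sd, size=(*cfg.dims, cfg.T))
    rm = phantom.region_map
    for r in range(cfg.n_regions):
        data[rm == r, :] += sig[:, r]
    bold = BoldSeries(data, cfg.tr, phantom.grid)
    truth = GroundTruth(
        states=states, couplings=couplings, labels=phantom.bilateral_labels()
    )
    return bold, truth


def make_cohort(
    cfg: PhantomConfig, n_subjects: int, master_seed: int
) -> tuple[Phantom, list[dict]]:
    """Subject-wise phantom data with independent RNG streams.

    The geometry is shared; streamline draws, state sequences and noise are
    per subject.  Returns (phantom, subjects) where each subject is a dict
    with keys ``tractogram``, ``bold``, ``truth``.
    """
    if n_subjects < 1:
        raise ValueError("n_subjects must be >= 1")
    phantom = make_phantom(cfg)
    subjects = []
    for child in np.random.SeedSequence(master_seed).spawn(n_subjects):
        rng = np.random.default_rng(child)
        tract, truth_t = simulate_streamlines(phantom, cfg, rng)
        bold, truth_b = simulate_bold(phantom, cfg, rng)
        truth = GroundTruth(
            assignments=truth_t.assignments,
            states=truth_b.states,
            couplings=truth_b.couplings,
            labels=phantom.bilateral_labels(),
        )
        subjects.append({"tractogram": tract, "bold": bold, "truth": truth})
    return phantom, subjects


def null_config(rho: float = 0.3, **kwargs) -> PhantomConfig:
    """A cohort config where every cluster sees identical coupling (used for
    type-I-error checks): all region pairs equicorrelated, single state."""
    base = PhantomConfig(**kwargs)
    return replace(
        base,
        n_states=1,
        couplings=equicorrelated_couplings(base.n_regions, rho, n_states=1),
    )


def effect_config(
    rho: float = 0.3, delta: float = 0.35, subregion: int = 0, **kwargs
) -> PhantomConfig:
    """The null config plus a planted coupling increase between one bilateral
    subregion (default: the first) and its mirror-wired targets.

    The default ``delta`` of 0.35 realises a subject-level effect size of
    about d = 1 on the Fisher-z difference maps once voxel noise has
    attenuated the observed correlations.
    """
    base = PhantomConfig(**kwargs)
    n = base.n_subregions
    pairs = [
        (subregion, 2 * n + subregion % base.n_targets),
        (n + subregion, 2 * n + (n + subregion) % base.n_targets),
    ]
    couplings = add_coupling_effect(
        equicorrelated_couplings(base.n_regions, rho, n_states=1), pairs, delta
    )
    return replace(base, n_states=1, couplings=couplings)
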