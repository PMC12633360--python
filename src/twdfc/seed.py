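"""Seed-restricted tractogram extraction and endpoint mapping.

Given a whole-brain tractogram and a binary seed mask (e.g. a manually
segmented hippocampus), keep only streamlines terminating in the seed, build
a table of (seed endpoint voxel, distal endpoint voxel, weight) per kept
streamline, and produce endpoint-density maps.  The table row is oriented so
``seed_voxel`` is always the in-seed endpoint, regardless of the streamline's
stored vertex order.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from enum import Enum

import numpy as np
import pandas as pd

from .grid import VolumeGrid, world_to_voxel
from .tck import Tractogram

__all__ = [
    "EndpointCategory",
    "EndpointTable",
    "classify_endpoints",
    "extract_seed_tractogram",
    "endpoint_density_map",
]

logger = logging.getLogger(__name__)


class EndpointCategory(Enum):
    NONE_IN_SEED = "none_in_seed"
    ONE_IN_SEED = "one_in_seed"
    BOTH_IN_SEED = "both_in_seed"
    ENDPOINT_OUT_OF_FOV = "endpoint_out_of_fov"


@dataclass
class EndpointTable:
    """Per kept streamline: index into the parent tractogram, the seed-side
    and distal-side endpoint voxels (0-based), and its streamline weight."""

    streamline_id: np.ndarray  # (n,) int
    seed_voxel: np.ndarray     # (n, 3) int
    distal_voxel: np.ndarray   # (n, 3) int
    weight: np.ndarray         # (n,) float

    def __post_init__(self) -> None:
        n = len(self.streamline_id)
        self.streamline_id = np.asarray(self.streamline_id, dtype=np.int64)
        self.seed_voxel = np.asarray(self.seed_voxel, dtype=np.int64).reshape(n, 3)
        self.distal_voxel = np.asarray(self.distal_voxel, dtype=np.int64).reshape(n, 3)
        self.weight = np.asarray(self.weight, dtype=float).reshape(n)
        if np.unique(self.streamline_id).size != n:
            raise ValueError("streamline_ids must be unique")
        if np.any(self.weight < 0):
            raise ValueError("weights must be non-negative")

    def __len__(self) -> int:
        return len(self.streamline_id)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "streamline_id": self.streamline_id,
                "seed_i": self.seed_voxel[:, 0],
                "seed_j": self.seed_voxel[:, 1],
                "seed_k": self.seed_voxel[:, 2],
                "distal_i": self.distal_voxel[:, 0],
                "distal_j": self.distal_voxel[:, 1],
                "distal_k": self.distal_voxel[:, 2],
                "weight": self.weight,
            }
        )

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path) -> "EndpointTable":
        df = pd.read_csv(path, sep="\t")
        return cls(
            streamline_id=df["streamline_id"].to_numpy(),
            seed_voxel=df[["seed_i", "seed_j", "seed_k"]].to_numpy(),
            distal_voxel=df[["distal_i", "distal_j", "distal_k"]].to_numpy(),
            weight=df["weight"].to_numpy(),
        )


def classify_endpoints(
    t: Tractogram, seed: np.ndarray, grid: VolumeGrid
) -> list[EndpointCategory]:
    """Label each streamline by where its two terminal vertices fall.

    Categories: both endpoints outside the seed, exactly one inside, both
    inside, or at least one endpoint off the grid entirely (no BOLD signal
    exists there, so such streamlines are unusable downstream).
    """
    seed = np.asarray(seed).astype(bool)
    if seed.shape != grid.dims:
        raise ValueError("seed mask shape does not match grid")
    if len(t) == 0:
        return []
    ends = t.endpoints()  # (n, 2, 3)
    idx, in_fov = world_to_voxel(ends.reshape(-1, 3), grid)
    idx = idx.reshape(-1, 2, 3)
    in_fov = in_fov.reshape(-1, 2)
    cats: list[EndpointCategory] = []
    for i in range(len(t)):
        if not in_fov[i].all():
            cats.append(EndpointCategory.ENDPOINT_OUT_OF_FOV)
            continue
        hits = sum(bool(seed[tuple(idx[i, e])]) for e in (0, 1))
        cats.append(
            (
                EndpointCategory.NONE_IN_SEED,
                EndpointCategory.ONE_IN_SEED,
                EndpointCategory.BOTH_IN_SEED,
            )[hits]
        )
    return cats


def extract_seed_tractogram(
    t: Tractogram,
    categories: list[EndpointCategory],
    grid: VolumeGrid,
    seed: np.ndarray,
    policy: str = "one",
) -> tuple[Tractogram, EndpointTable]:
    """Keep streamlines terminating in the seed and build the endpoint table.

    policy="one" (default) keeps only streamlines with exactly one endpoint
    in the seed — the retained connections run between the seed and a distal
    grey-matter target.  policy="both" additionally keeps intra-seed
    streamlines (both endpoints inside); for those the first vertex is taken
    as the seed side.  Out-of-FOV streamlines are always dropped (their count
    is logged).
    """
    if policy not in ("one", "both"):
        raise ValueError('policy must be "one" or "both"')
    if len(categories) != len(t):
        raise ValueError("categories length does not match tractogram")
    seed = np.asarray(seed).astype(bool)
    wanted = {EndpointCategory.ONE_IN_SEED}
    if policy == "both":
        wanted.add(EndpointCategory.BOTH_IN_SEED)
    n_oof = sum(c is EndpointCategory.ENDPOINT_OUT_OF_FOV for c in categories)
    if n_oof:
        logger.info("dropping %d streamlines with out-of-FOV endpoints", n_oof)
    keep = [i for i, c in enumerate(categories) if c in wanted]
    streamlines = [t.streamlines[i] for i in keep]
    weights = t.weights[keep] if t.weights is not None else np.ones(len(keep))
    ids, seed_vox, distal_vox = [], [], []
    for row, i in enumerate(keep):
        ends = streamlines[row][[0, -1]]
        idx, _ = world_to_voxel(ends, grid)
        first_in_seed = bool(seed[tuple(idx[0])])
        s_end, d_end = (0, 1) if first_in_seed else (1, 0)
        ids.append(i)
        seed_vox.append(idx[s_end])
        distal_vox.append(idx[d_end])
    if not keep:
        warnings.warn("no streamlines matched the seed policy; result is empty")
        table = EndpointTable(
            np.empty(0, int), np.empty((0, 3), int), np.empty((0, 3), int), np.empty(0)
        )
    else:
        table = EndpointTable(np.array(ids), np.array(seed_vox), np.array(distal_vox), weights)
    out = Tractogram(
        streamlines=streamlines,
        weights=weights if t.weights is not None else None,
        header={"count": str(len(streamlines))},
    )
    return out, table


def endpoint_density_map(
    tab: EndpointTable, grid: VolumeGrid, which: str = "seed", weighted: bool = False
) -> np.ndarray:
    """Per-voxel count (or weight sum) of streamline termination points.

    The map total equals the number of table rows (or the total weight)
    exactly — endpoints are counted, never smeared.
    """
    if which not in ("seed", "distal"):
        raise ValueError('which must be "seed" or "distal"')
    vox = tab.seed_voxel if which == "seed" else tab.distal_voxel
    vals = tab.weight if weighted else np.ones(len(tab))
    out = np.zeros(grid.dims, dtype=float)
    np.add.at(out, (vox[:, 0], vox[:, 1], vox[:, 2]), vals)
    return out
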