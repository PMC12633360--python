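"""TCK tractogram I/O and per-streamline weight files.

The TCK dialect: an ASCII header opened by the magic line ``mrtrix tracks``,
``key: value`` lines including ``file: . <offset>``, closed by ``END``; then a
binary stream of vertex triplets (float32 little-endian by default), with a
``(NaN, NaN, NaN)`` triplet separating streamlines and an ``(Inf, Inf, Inf)``
triplet terminating the stream.  Vertices are world-mm scanner coordinates.

Weight files (e.g. SIFT2 output) are plain text: one non-negative float per
streamline, whitespace/newline separated, no header; length is always
validated against the tractogram.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "Tractogram",
    "TckFormatError",
    "TckIntegrityError",
    "read_tck",
    "write_tck",
    "read_weights",
    "concatenate_tractograms",
]

MAGIC = "mrtrix tracks"

_DTYPES = {
    "Float32LE": np.dtype("<f4"),
    "Float32BE": np.dtype(">f4"),
    "Float64LE": np.dtype("<f8"),
    "Float64BE": np.dtype(">f8"),
}


class TckFormatError(ValueError):
    """File does not follow the TCK layout (magic/header/END)."""


class TckIntegrityError(ValueError):
    """Header and body disagree (count mismatch, truncation)."""


@dataclass
class Tractogram:
    """Streamline polylines in world mm with optional per-streamline weights."""

    streamlines: list[np.ndarray]
    weights: np.ndarray | None = None
    header: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        sls = []
        for s in self.streamlines:
            a = np.asarray(s, dtype=np.float32)
            if a.ndim != 2 or a.shape[1] != 3 or a.shape[0] < 2:
                raise ValueError("each streamline must be an (n>=2, 3) array")
            if not np.all(np.isfinite(a)):
                raise ValueError("streamline contains non-finite vertex")
            sls.append(a)
        self.streamlines = sls
        if self.weights is not None:
            w = np.asarray(self.weights, dtype=float)
            if w.shape != (len(sls),):
                raise ValueError(
                    f"{w.size} weights for {len(sls)} streamlines"
                )
            if np.any(~np.isfinite(w)) or np.any(w < 0):
                raise ValueError("weights must be finite and non-negative")
            self.weights = w

    def __len__(self) -> int:
        return len(self.streamlines)

    def endpoints(self) -> np.ndarray:
        """(n, 2, 3) array of first/last vertices per streamline."""
        if not self.streamlines:
            return np.empty((0, 2, 3), dtype=np.float32)
        return np.stack([s[[0, -1]] for s in self.streamlines])


def _parse_header(raw: bytes):
    try:
        text = raw.decode("ascii", errors="strict")
    except UnicodeDecodeError as e:
        raise TckFormatError("header is not ASCII") from e
    lines = text.split("\n")
    if not lines or lines[0].strip() != MAGIC:
        raise TckFormatError(f'missing magic line "{MAGIC}"')
    header: dict[str, str] = {}
    offset = None
    for line in lines[1:]:
        if line.strip() == "END":
            break
        if ":" not in line:
            continue
        key, val = line.split(":", 1)
        key, val = key.strip(), val.strip()
        header[key] = val
        if key == "file":
            parts = val.split()
            if len(parts) != 2 or parts[0] != ".":
                raise TckFormatError(f'unsupported file field "{val}"')
            offset = int(parts[1])
    else:
        raise TckFormatError('header not terminated by "END"')
    if offset is None:
        raise TckFormatError('header lacks "file: . <offset>"')
    return header, offset


def read_tck(path) -> Tractogram:
    """Read a TCK tractogram; vertices are returned in world mm, order kept.

    Raises
    ------
    TckFormatError
        Missing magic line, missing END, malformed file field.
    TckIntegrityError
        Truncated body, missing terminator, or a body streamline count that
        contradicts the header ``count`` field.
    """
    with open(path, "rb") as f:
        raw = f.read()
    end = raw.find(b"END")
    if end < 0:
        raise TckFormatError('header not terminated by "END"')
    header, offset = _parse_header(raw[: end + 4])
    dtype = _DTYPES.get(header.get("datatype", "Float32LE"))
    if dtype is None:
        raise TckFormatError(f'unsupported datatype "{header.get("datatype")}"')
    body = np.frombuffer(raw[offset:], dtype=dtype)
    if body.size % 3 != 0:
        raise TckIntegrityError("body size is not a multiple of 3 values")
    trip = body.reshape(-1, 3).astype(np.float32)
    if trip.shape[0] == 0 or not np.all(np.isinf(trip[-1])):
        raise TckIntegrityError("body lacks the Inf-triplet terminator")
    trip = trip[:-1]
    is_sep = np.all(np.isnan(trip), axis=1)
    streamlines: list[np.ndarray] = []
    start = 0
    for sep in np.flatnonzero(is_sep):
        if sep > start:
            streamlines.append(np.ascontiguousarray(trip[start:sep]))
        start = sep + 1
    if start < trip.shape[0]:  # final streamline without trailing separator
        streamlines.append(np.ascontiguousarray(trip[start:]))
    if "count" in header:
        declared = int(header["count"])
        if declared != len(streamlines):
            raise TckIntegrityError(
                f"header declares count={declared} but body holds {len(streamlines)}"
            )
    for s in streamlines:
        if not np.all(np.isfinite(s)):
            raise TckIntegrityError("streamline contains non-finite vertex")
    return Tractogram(streamlines=streamlines, header=header)


def write_tck(t: Tractogram, path) -> None:
    """Write float32-LE TCK; ``read_tck`` round-trips it bit-exactly."""
    header = dict(t.header)
    header["datatype"] = "Float32LE"
    header["count"] = str(len(t))
    header.pop("file", None)
    lines = [MAGIC] + [f"{k}: {v}" for k, v in header.items()]
    # the file field states its own byte offset, so fix it iteratively
    for pad in range(8):
        offset_guess = len("\n".join(lines + ["file: . 0", "END"])) + 1 + pad
        candidate = "\n".join(lines + [f"file: . {offset_guess}", "END"]) + "\n"
        if len(candidate) == offset_guess:
            break
    else:  # pragma: no cover - 8 digits of slack always suffice
        raise RuntimeError("could not settle header offset")
    chunks = [candidate.encode("ascii")]
    sep = np.full((1, 3), np.nan, dtype="<f4")
    for s in t.streamlines:
        chunks.append(np.asarray(s, dtype="<f4").tobytes())
        chunks.append(sep.tobytes())
    chunks.append(np.full((1, 3), np.inf, dtype="<f4").tobytes())
    with open(path, "wb") as f:
        f.write(b"".join(chunks))


def read_weights(path, n: int) -> np.ndarray:
    """Read exactly ``n`` non-negative per-streamline weights from text.

    Raises :class:`TckIntegrityError` on a count mismatch and ``ValueError``
    on negative or non-finite entries.
    """
    with open(path) as f:
        tokens = f.read().split()
    try:
        w = np.array([float(tok) for tok in tokens], dtype=float)
    except ValueError as e:
        raise ValueError(f"non-numeric weight entry in {path}") from e
    if w.size != n:
        raise TckIntegrityError(f"expected {n} weights, file holds {w.size}")
    if np.any(~np.isfinite(w)):
        raise ValueError("non-finite weight entry")
    if np.any(w < 0):
        raise ValueError("negative weight entry")
    return w


def concatenate_tractograms(*tractograms: Tractogram) -> Tractogram:
    """Combine tractograms; the streamline count is the sum of the parts.

    Weights are concatenated when every input carries them; if only some do,
    they are dropped with a warning (a partial weight vector is meaningless).
    """
    if not tractograms:
        return Tractogram(streamlines=[])
    streamlines = [s for t in tractograms for s in t.streamlines]
    have_w = [t.weights is not None for t in tractograms]
    weights = None
    if all(have_w):
        weights = np.concatenate([t.weights for t in tractograms])
    elif any(have_w):
        warnings.warn("some inputs lack weights; combined tractogram is unweighted")
    header = {"count": str(len(streamlines))}
    return Tractogram(streamlines=streamlines, weights=weights, header=header)
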