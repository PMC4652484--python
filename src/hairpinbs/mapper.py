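"""Minimal seed-and-extend read mapper with a three-letter bisulfite mode.

Bisulfite conversion makes reads mismatch the reference wherever an
unmethylated C was read as T.  Three-letter mapping removes those mismatches
by collapsing C to T (and, for the complementary PCR strands, G to A) in
both the read and the reference before comparison.  In ``bisulfite`` mode
this mapper searches all four strand/conversion combinations of a
non-directional library: {Watson, Crick} x {C->T, G->A}.  In ``plain`` mode
it searches both strands unconverted.

Candidate locations come from exact k-mer seed hits (k = 16 by default, the
classic hash-window size); each candidate is scored by Hamming mismatch
count between the converted read and the converted reference window, with no
indels.  A read is *unique* when exactly one location attains the best score
within the mismatch threshold, *ambiguous* when several tie, and *unmapped*
otherwise.  ``brute_force_map`` applies the identical scoring rules at every
position of the genome and serves as the mapper's testing oracle.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from .simulate import ReferenceGenome, revcomp

__all__ = [
    "UNIQUE",
    "AMBIGUOUS",
    "UNMAPPED",
    "Location",
    "MappingResult",
    "MapperIndex",
    "build_index",
    "map_read",
    "brute_force_map",
    "map_batch",
    "summarize_categories",
]

UNIQUE = "unique"
AMBIGUOUS = "ambiguous"
UNMAPPED = "unmapped"

_CODE = np.full(256, 255, dtype=np.uint8)
for _i, _b in enumerate(b"ACGTN"):
    _CODE[_b] = _i
_A, _C, _G, _T, _N = range(5)


def _encode(seq: str) -> np.ndarray:
    arr = _CODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]
    if arr.max(initial=0) == 255:
        raise ValueError("sequence contains characters outside {A,C,G,T,N}")
    return arr


def _convert(arr: np.ndarray, conversion: str) -> np.ndarray:
    if conversion == "CT":
        out = arr.copy()
        out[out == _C] = _T
        return out
    if conversion == "GA":
        out = arr.copy()
        out[out == _G] = _A
        return out
    if conversion == "none":
        return arr
    raise ValueError(f"unknown conversion {conversion!r}")


@dataclass(frozen=True)
class Location:
    """A candidate placement: 0-based Watson start, reference strand, and the
    letter-collapse view under which the read matched."""

    name: str
    pos: int
    strand: str  # watson / crick
    conversion: str  # CT / GA / none

    def sort_key(self):
        return (self.name, self.pos, self.strand)


@dataclass(frozen=True)
class MappingResult:
    read_id: str
    category: str
    best_score: int | None
    best_locations: tuple[Location, ...]
    n_best: int


@dataclass(frozen=True)
class _View:
    name: str
    strand: str
    conversion: str
    arr: np.ndarray
    ref_len: int


class MapperIndex:
    """Exact k-mer hash over the converted genome views."""

    def __init__(self, ref: ReferenceGenome, k: int = 16, mode: str = "bisulfite") -> None:
        if mode not in ("bisulfite", "plain"):
            raise ValueError("mode must be 'bisulfite' or 'plain'")
        if k < 1:
            raise ValueError("seed length k must be positive")
        if k > ref.shortest():
            raise ValueError(f"seed length {k} exceeds the shortest reference record")
        self.k = k
        self.mode = mode
        self.conversions: tuple[str, ...] = ("CT", "GA") if mode == "bisulfite" else ("none",)
        self.views: list[_View] = _build_views(ref, self.conversions)
        self.seeds: dict[bytes, list[tuple[int, int]]] = {}
        for vi, view in enumerate(self.views):
            arr = view.arr
            for pos in range(len(arr) - k + 1):
                self.seeds.setdefault(arr[pos : pos + k].tobytes(), []).append((vi, pos))


def _build_views(ref: ReferenceGenome, conversions: tuple[str, ...]) -> list[_View]:
    views = []
    for name, seq in ref.records.items():
        watson = _encode(seq)
        crick = _encode(revcomp(seq))
        for conv in conversions:
            views.append(_View(name, "watson", conv, _convert(watson, conv), len(seq)))
            views.append(_View(name, "crick", conv, _convert(crick, conv), len(seq)))
    return views


def build_index(ref: ReferenceGenome, k: int = 16, mode: str = "bisulfite") -> MapperIndex:
    """Index every k-mer of the converted genome views (both strands)."""
    return MapperIndex(ref, k=k, mode=mode)


def _seed_offsets(read_len: int, k: int, seed_span: int | None) -> list[int]:
    """Seed start offsets within the read.

    Default: non-overlapping k-mers across the whole read plus a final
    k-mer flush with the 3' end (full pigeonhole sensitivity).  With
    ``seed_span`` set, seeds are restricted to the first ``seed_span`` bases,
    emulating mappers that anchor on a 5' seed region.
    """
    span = read_len if seed_span is None else min(seed_span, read_len)
    if span < k:
        span = k
    offsets = list(range(0, span - k + 1, k))
    if offsets[-1] != span - k:
        offsets.append(span - k)
    return offsets


def _finalize(
    read_id: str,
    scored: dict[tuple[str, int, str], tuple[int, int, str]],
    threshold: int,
    tie_cap: int,
) -> MappingResult:
    """Shared category logic: dedupe is already done; pick best <= threshold."""
    within = {loc: s for loc, s in scored.items() if s[0] <= threshold}
    if not within:
        return MappingResult(read_id, UNMAPPED, None, (), 0)
    best = min(s[0] for s in within.values())
    best_locs = [
        Location(name, pos, strand, s[2])
        for (name, pos, strand), s in within.items()
        if s[0] == best
    ]
    best_locs.sort(key=Location.sort_key)
    n_best = len(best_locs)
    category = UNIQUE if n_best == 1 else AMBIGUOUS
    return MappingResult(read_id, category, best, tuple(best_locs[:tie_cap]), n_best)


def map_read(
    index: MapperIndex,
    read: str,
    max_mismatch_fraction: float = 0.1,
    read_id: str = "read",
    seed_span: int | None = None,
    tie_cap: int = 100,
) -> MappingResult:
    """Map one read against the index.

    The mismatch threshold is floor(max_mismatch_fraction * length); N bases
    in the read mismatch everything.  Locations reached under both letter
    collapses count once (deduplicated by (name, pos, strand), best score
    kept).  At most ``tie_cap`` tied best locations are reported; ``n_best``
    always records the true count.
    """
    L = len(read)
    if L < index.k:
        raise ValueError(f"read length {L} is shorter than seed length {index.k}")
    threshold = math.floor(max_mismatch_fraction * L)
    read_arr = _encode(read)
    conv_reads = {c: _convert(read_arr, c) for c in index.conversions}
    offsets = _seed_offsets(L, index.k, seed_span)

    candidates: set[tuple[int, int]] = set()
    for conv in index.conversions:
        r = conv_reads[conv]
        for o in offsets:
            key = r[o : o + index.k].tobytes()
            for vi, pos in index.seeds.get(key, ()):
                if index.views[vi].conversion != conv:
                    continue
                start = pos - o
                if 0 <= start <= len(index.views[vi].arr) - L:
                    candidates.add((vi, start))

    scored: dict[tuple[str, int, str], tuple[int, int, str]] = {}
    for vi, start in candidates:
        view = index.views[vi]
        score = int(np.count_nonzero(view.arr[start : start + L] != conv_reads[view.conversion]))
        pos = start if view.strand == "watson" else view.ref_len - start - L
        key = (view.name, pos, view.strand)
        entry = (score, index.conversions.index(view.conversion), view.conversion)
        if key not in scored or entry[:2] < scored[key][:2]:
            scored[key] = entry
    return _finalize(read_id, scored, threshold, tie_cap)


def brute_force_map(
    ref: ReferenceGenome,
    read: str,
    mode: str = "bisulfite",
    max_mismatch_fraction: float = 0.1,
    read_id: str = "read",
    tie_cap: int = 100,
) -> MappingResult:
    """Exhaustive oracle: score every position, both strands, both letter
    collapses, with exactly the scoring and category rules of map_read."""
    if all(len(seq) < len(read) for seq in ref.records.values()):
        raise ValueError("read is longer than every reference record")
    conversions: tuple[str, ...] = ("CT", "GA") if mode == "bisulfite" else ("none",)
    L = len(read)
    threshold = math.floor(max_mismatch_fraction * L)
    read_arr = _encode(read)
    conv_reads = {c: _convert(read_arr, c) for c in conversions}

    scored: dict[tuple[str, int, str], tuple[int, int, str]] = {}
    for view in _build_views(ref, conversions):
        if len(view.arr) < L:
            continue
        windows = sliding_window_view(view.arr, L)
        scores = np.count_nonzero(windows != conv_reads[view.conversion], axis=1)
        for start in np.flatnonzero(scores <= threshold):
            start = int(start)
            pos = start if view.strand == "watson" else view.ref_len - start - L
            key = (view.name, pos, view.strand)
            entry = (int(scores[start]), conversions.index(view.conversion), view.conversion)
            if key not in scored or entry[:2] < scored[key][:2]:
                scored[key] = entry
    return _finalize(read_id, scored, threshold, tie_cap)


def map_batch(
    index: MapperIndex,
    reads: Iterable[tuple[str, str]] | Mapping[str, str],
    **map_kwargs,
) -> tuple[list[MappingResult], dict]:
    """Map reads in order; return per-read results plus a category summary."""
    items = reads.items() if isinstance(reads, Mapping) else reads
    results = [map_read(index, seq, read_id=rid, **map_kwargs) for rid, seq in items]
    return results, summarize_categories(results)


def summarize_categories(results: Sequence[MappingResult]) -> dict:
    """Percent unique/ambiguous/unmapped; all zeros (with n=0) when empty."""
    n = len(results)
    if n == 0:
        return {"n": 0, "unique_pct": 0.0, "ambiguous_pct": 0.0, "unmapped_pct": 0.0}
    counts = {UNIQUE: 0, AMBIGUOUS: 0, UNMAPPED: 0}
    for r in results:
        counts[r.category] += 1
    return {
        "n": n,
        "unique_pct": 100.0 * counts[UNIQUE] / n,
        "ambiguous_pct": 100.0 * counts[AMBIGUOUS] / n,
        "unmapped_pct": 100.0 * counts[UNMAPPED] / n,
    }
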