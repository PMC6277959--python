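"""Partition an acquired image series into per-well z-stacks.

The camera writes sequentially numbered JPEGs with no well metadata, and
very occasionally skips a frame, so stacks cannot be cut every
``n_z + 1`` images blindly.  Instead the scan protocol appends one
deliberately out-of-focus sentinel image to each well; JPEG compression
makes that defocused frame markedly smaller on disk than the focused
frames flanking it.  Segmentation therefore needs only file sizes — no
pixel decoding: unusually small files are flagged as sentinel
candidates, and a dynamic alignment reconciles the candidates with the
expected stack period, tolerating missing data images.

The recovered stacks are then assigned to wells by replaying the scan
order the planner used (the k-th stack belongs to the k-th well
visited).
"""

from __future__ import annotations

import json
import re
import statistics
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

from platescan.plate_geometry import PlateSpec
from platescan.scan_planner import well_order

__all__ = [
    "ImageRecord",
    "WellStack",
    "SeriesManifest",
    "load_series",
    "detect_sentinels",
    "reconcile_sentinels",
    "assign_wells",
    "segment_series",
]

IMAGE_SUFFIXES = {".jpg", ".jpeg", ".png"}
DEFAULT_SEQ_PATTERN = r"(\d+)(?!.*\d)"  # last integer group in the basename


@dataclass(frozen=True)
class ImageRecord:
    """One acquired image: path, on-disk size, and sequence index."""

    path: str
    size: int
    seq: int

    def __post_init__(self) -> None:
        if self.size <= 0:
            raise ValueError(f"{self.path}: image size must be positive")


@dataclass
class WellStack:
    """One well's share of the series: data images plus its sentinel."""

    well: str
    images: list[ImageRecord]
    sentinel: ImageRecord | None
    complete: bool

    @property
    def n_data(self) -> int:
        return len(self.images)


@dataclass
class SeriesManifest:
    """Ordered per-well stacks covering the whole series.

    ``well_count_matches`` is False when the series yielded a different
    number of stacks than the plate has wells (aborted scan, wrong
    plate argument, ...); stacks are then labeled from the start of the
    scan order only.
    """

    stacks: list[WellStack]
    n_z: int
    order: str
    plate: str
    well_count_matches: bool = True

    def to_json(self, path: str | Path | None = None) -> str:
        doc = {
            "plate": self.plate,
            "n_z": self.n_z,
            "order": self.order,
            "well_count_matches": self.well_count_matches,
            "stacks": [
                {
                    "well": s.well,
                    "images": [r.path for r in s.images],
                    "sentinel": s.sentinel.path if s.sentinel else None,
                    "complete": s.complete,
                }
                for s in self.stacks
            ],
        }
        text = json.dumps(doc, indent=2)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_json(cls, path: str | Path) -> "SeriesManifest":
        doc = json.loads(Path(path).read_text())

        def rec(p: str) -> ImageRecord:
            return ImageRecord(path=p, size=max(Path(p).stat().st_size, 1), seq=_parse_seq(Path(p).name))

        stacks = [
            WellStack(
                well=s["well"],
                images=[rec(p) for p in s["images"]],
                sentinel=rec(s["sentinel"]) if s.get("sentinel") else None,
                complete=s["complete"],
            )
            for s in doc["stacks"]
        ]
        return cls(
            stacks=stacks,
            n_z=doc["n_z"],
            order=doc["order"],
            plate=doc["plate"],
            well_count_matches=doc.get("well_count_matches", True),
        )

    def to_csv(self, path: str | Path) -> None:
        """Flat table: well, z_index (or 'sentinel'), filename."""
        rows = []
        for s in self.stacks:
            for i, r in enumerate(s.images):
                rows.append({"well": s.well, "z_index": str(i), "filename": r.path})
            if s.sentinel is not None:
                rows.append({"well": s.well, "z_index": "sentinel", "filename": s.sentinel.path})
        pd.DataFrame(rows, columns=["well", "z_index", "filename"]).to_csv(path, index=False)


def _parse_seq(name: str, pattern: str = DEFAULT_SEQ_PATTERN) -> int:
    m = re.search(pattern, Path(name).stem)
    if m is None:
        raise ValueError(f"no sequence number in filename {name!r}")
    return int(m.group(1))


def load_series(
    source: str | Path | Iterable[tuple[str, int]],
    seq_pattern: str = DEFAULT_SEQ_PATTERN,
) -> list[ImageRecord]:
    """Build sorted ImageRecords from a directory or (name, size) listing.

    Non-image files (by suffix) and files without a parseable sequence
    number are ignored; records are sorted by sequence index.  An empty
    result or a duplicated sequence index is an error.
    """
    entries: list[tuple[str, int]]
    if isinstance(source, (str, Path)):
        directory = Path(source)
        entries = [
            (str(p), p.stat().st_size)
            for p in sorted(directory.iterdir())
            if p.is_file()
        ]
    else:
        entries = [(str(n), int(s)) for n, s in source]

    records = []
    for name, size in entries:
        if Path(name).suffix.lower() not in IMAGE_SUFFIXES:
            continue
        try:
            seq = _parse_seq(Path(name).name, seq_pattern)
        except ValueError:
            continue
        records.append(ImageRecord(path=name, size=size, seq=seq))

    if not records:
        raise ValueError("no images with parseable sequence numbers found")
    seen: dict[int, str] = {}
    for r in records:
        if r.seq in seen:
            raise ValueError(f"duplicate sequence index {r.seq}: {seen[r.seq]} and {r.path}")
        seen[r.seq] = r.path
    records.sort(key=lambda r: r.seq)
    return records


def detect_sentinels(
    records: Sequence[ImageRecord],
    expected_period: int,
    rel_threshold: float = 0.75,
) -> set[int]:
    """Indices of sentinel candidates: files much smaller than their flank.

    An index is a candidate iff its size is below ``rel_threshold``
    times the median size of its (up to ``expected_period``) nearest
    neighbors, neighbors that are themselves candidates excluded.  The
    exclusion is reached by fixpoint iteration starting from the empty
    candidate set, so a run of small files (adjacent sentinels around a
    lost stack) does not drag the local median down.  Raising the
    threshold can only grow the candidate set.
    """
    if len(records) < 2:
        raise ValueError("need at least 2 records to detect sentinels")
    if expected_period < 2:
        raise ValueError("expected_period must be at least 2 (n_z + 1)")
    sizes = [r.size for r in records]
    n = len(sizes)
    candidates: set[int] = set()
    for _ in range(n + 1):
        new = set()
        for i in range(n):
            neighbors = _nearest_non_candidates(i, n, expected_period, candidates | {i})
            if not neighbors:
                continue
            med = statistics.median(sizes[j] for j in neighbors)
            if sizes[i] < rel_threshold * med:
                new.add(i)
        if new <= candidates:
            break
        # growing only: monotone iteration converges and keeps
        # rel_threshold-monotonicity
        candidates |= new
    if not candidates:
        raise ValueError(
            "no sentinel candidates found: sentinel images may be disabled "
            "for this acquisition, or rel_threshold is too low"
        )
    return candidates


def _nearest_non_candidates(i: int, n: int, k: int, excluded: set[int]) -> list[int]:
    """Up to k indices nearest to i (by distance, ties to the left) not excluded."""
    out: list[int] = []
    for dist in range(1, n):
        for j in (i - dist, i + dist):
            if 0 <= j < n and j not in excluded:
                out.append(j)
                if len(out) == k:
                    return out
    return out


def reconcile_sentinels(
    records: Sequence[ImageRecord],
    candidates: set[int],
    n_z: int,
) -> list[tuple[list[int], int | None]]:
    """Cut the series into stacks using the candidate sentinels.

    Chooses the subset of candidates, in order, such that every segment
    between consecutive sentinels holds between 1 and ``n_z`` data
    images.  Among valid cuttings the best explanation, lexicographically:

    1. fewest sentinel-less stacks (sentinel frames are rarely lost);
    2. smallest total byte size of the chosen sentinels (true sentinels
       are the most defocused, hence the smallest files — this keeps a
       merely blurry data frame from being mistaken for a sentinel);
    3. most stacks with exactly ``n_z`` data images;
    4. most balanced stack sizes.

    A segment of ``n_z + 1 .. 2*n_z`` data images — the signature of a
    lost sentinel frame — is split into two stacks at its interior size
    minimum.  The trailing portion after the last sentinel, if any,
    becomes a final stack without a sentinel.

    Returns ``[(data_indices, sentinel_index_or_None), ...]`` covering
    every record exactly once.
    """
    n = len(records)
    sizes = [r.size for r in records]
    cand = sorted(candidates)
    if any(not (0 <= c < n) for c in cand):
        raise ValueError("candidate index out of range")

    # Dynamic program over record positions. state = first uncovered index.
    # From position p we either end a stack at the next chosen sentinel s
    # (1..n_z data in between), or absorb a merged double segment
    # (n_z+1..2*n_z data) split at its size minimum, or finish with a
    # trailing sentinel-less stack.
    from functools import lru_cache

    cand_set = set(cand)

    def seg_score(n_data: int) -> int:
        return 1 if n_data == n_z else 0

    ZERO = (0, 0, 0, 0)

    def add(a: tuple, b: tuple) -> tuple:
        return tuple(x + y for x, y in zip(a, b))

    @lru_cache(maxsize=None)
    def best(p: int) -> tuple[tuple, tuple]:
        """Best (-n_sentinel_less, -sentinel_bytes, n_exact, -imbalance)
        and cut plan from record index p."""
        if p == n:
            return ZERO, ()
        options: list[tuple[tuple, tuple]] = []
        # end the next stack at a candidate sentinel s
        for s in range(p, min(p + 2 * n_z + 1, n)):
            if s not in cand_set:
                continue
            n_data = s - p
            if n_data < 1:
                continue  # empty stack: sentinel adjacent to previous cut
            tail_sc, tail_plan = best(s + 1)
            if n_data <= n_z:
                sc = add(tail_sc, (0, -sizes[s], seg_score(n_data), 0))
                options.append((sc, ((p, s, s),) + tail_plan))
            else:
                # merged segment: a sentinel frame was lost; split in two
                split = _merge_split(sizes, p, s, n_z)
                a, b = split - p, s - split
                sc = add(
                    tail_sc,
                    (-1, -sizes[s], seg_score(a) + seg_score(b), -abs(a - b)),
                )
                options.append((sc, ((p, split, None), (split, s, s)) + tail_plan))
        # trailing sentinel-less stack (series cut off before its sentinel)
        remaining = n - p
        if 1 <= remaining <= n_z:
            sc = (-1, 0, seg_score(remaining), 0)
            options.append((sc, ((p, n, None),)))
        if not options:
            raise ValueError(
                f"sentinel spacing incompatible with n_z={n_z} near record "
                f"index {p} (candidates: {cand})"
            )
        return max(options, key=lambda o: o[0])

    _, plan = best(0)
    stacks: list[tuple[list[int], int | None]] = []
    for start, stop, sent in plan:
        stacks.append((list(range(start, stop)), sent))
    return stacks


def _merge_split(sizes: Sequence[int], start: int, stop: int, n_z: int) -> int:
    """Split point of a merged (sentinel-lost) segment [start, stop).

    The lost sentinel sat somewhere inside; its neighborhood is the
    interior size minimum.  Among valid splits (each half 1..n_z data
    images) pick the boundary after the smallest interior image, ties
    toward equal halves.
    """
    lo = max(start + 1, stop - n_z)
    hi = min(stop - 1, start + n_z)
    mid = (start + stop) / 2

    def key(split: int) -> tuple[int, float]:
        # boundary after the smaller of the two adjacent images
        return (min(sizes[split - 1], sizes[split]), abs(split - mid))

    return min(range(lo, hi + 1), key=key)


def assign_wells(
    stacks: list[tuple[list[int], int | None]],
    records: Sequence[ImageRecord],
    spec: PlateSpec,
    order: str = "row-serpentine",
    n_z: int = 5,
) -> SeriesManifest:
    """Label stacks with well names by replaying the scan order."""
    if len(stacks) > spec.n_wells:
        raise ValueError(
            f"{len(stacks)} stacks found but the {spec.name}-well plate has "
            f"only {spec.n_wells} wells"
        )
    wells = well_order(spec, order)
    out = []
    for (data_idx, sent_idx), (row, col) in zip(stacks, wells):
        out.append(
            WellStack(
                well=spec.well_label(row, col),
                images=[records[i] for i in data_idx],
                sentinel=records[sent_idx] if sent_idx is not None else None,
                complete=len(data_idx) == n_z,
            )
        )
    return SeriesManifest(
        stacks=out,
        n_z=n_z,
        order=order,
        plate=spec.name,
        well_count_matches=len(stacks) == spec.n_wells,
    )


def segment_series(
    source: str | Path | Iterable[tuple[str, int]],
    spec: PlateSpec,
    n_z: int = 5,
    order: str = "row-serpentine",
    rel_threshold: float = 0.75,
    seq_pattern: str = DEFAULT_SEQ_PATTERN,
) -> SeriesManifest:
    """Load, detect, reconcile and assign in one call."""
    records = load_series(source, seq_pattern)
    candidates = detect_sentinels(records, expected_period=n_z + 1, rel_threshold=rel_threshold)
    stacks = reconcile_sentinels(records, candidates, n_z=n_z)
    return assign_wells(stacks, records, spec, order=order, n_z=n_z)
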