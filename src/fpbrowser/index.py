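"""Sum-keyed hash index and exact city-block nearest-neighbor search.

The library is organized into one hash table per fingerprint space, keyed
by the fingerprint's total sum. Because |Δ total sum| lower-bounds the
city-block distance, a query with total sum ``s`` and distance bound ``d``
only needs the buckets with keys in ``[s - d, s + d]`` — e.g. total sum 100
with CBD <= 10 scans keys 90..110 — and the retrieval is exact, not
approximate.

Two search modes mirror the browser: ``MAX_DISTANCE`` returns every
filter-passing molecule within a CBD bound; ``MAX_COUNT`` returns the k
provably nearest filter-passing molecules by expanding rings of buckets in
order of increasing |Δ total sum| until no unexplored ring can still hold a
closer hit. Both modes cap results at 1000 hits.
"""

from __future__ import annotations

import heapq
import logging
from collections import Counter
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path

import numpy as np

from .fingerprints import FingerprintVector, Space, fingerprint
from .standardize import VENDOR_MASK_MAX, MoleculeRecord

logger = logging.getLogger(__name__)

#: Hard ceiling on the number of hits any search returns.
MAX_HITS = 1000


class SearchMode(str, Enum):
    MAX_COUNT = "count"
    MAX_DISTANCE = "distance"


@dataclass(frozen=True)
class QueryFilters:
    """Optional property constraints on hits, relative to the query molecule.

    Locks require equality with the query's own annotation; the optional
    oxygen/nitrogen counts require an exact element count.
    """

    lock_formula: bool = False
    lock_hba: bool = False
    lock_hbd: bool = False
    required_oxygen: int | None = None
    required_nitrogen: int | None = None

    def __post_init__(self) -> None:
        for name in ("required_oxygen", "required_nitrogen"):
            value = getattr(self, name)
            if value is not None and value < 0:
                raise ValueError(f"{name} must be >= 0, got {value}")


@dataclass(frozen=True)
class SearchQuery:
    query_record: MoleculeRecord
    space: Space
    mode: SearchMode
    limit: int
    wanted_vendor_mask: int = VENDOR_MASK_MAX
    filters: QueryFilters = field(default_factory=QueryFilters)

    def __post_init__(self) -> None:
        if self.mode is SearchMode.MAX_COUNT and self.limit <= 0:
            raise ValueError(f"Max Count must be positive, got {self.limit}")
        if self.mode is SearchMode.MAX_DISTANCE and self.limit < 0:
            raise ValueError(f"Max Distance must be >= 0, got {self.limit}")
        if not 1 <= self.wanted_vendor_mask <= VENDOR_MASK_MAX:
            raise ValueError(
                f"wanted_vendor_mask must be in [1, {VENDOR_MASK_MAX}]"
            )
        if self.mode is SearchMode.MAX_COUNT and self.limit > MAX_HITS:
            logger.warning(
                "Max Count %d exceeds the %d-hit ceiling; clamped", self.limit, MAX_HITS
            )
            object.__setattr__(self, "limit", MAX_HITS)


@dataclass
class SearchResult:
    """Hits sorted by increasing CBD (ties by id) plus a CBD histogram."""

    hits: list[tuple[MoleculeRecord, int]]
    histogram: dict[int, int]

    @property
    def records(self) -> list[MoleculeRecord]:
        return [record for record, _ in self.hits]

    def __len__(self) -> int:
        return len(self.hits)


@dataclass
class SumKeyIndex:
    """One fingerprint space's hash table: total-sum key -> bucket."""

    space: Space
    buckets: dict[int, list[tuple[MoleculeRecord, FingerprintVector]]]

    @property
    def size(self) -> int:
        return sum(len(bucket) for bucket in self.buckets.values())


def build_index(
    records: list[MoleculeRecord],
    space: Space | str,
    fingerprints: list[FingerprintVector] | None = None,
) -> SumKeyIndex:
    """Fingerprint every record and bucket it under its total sum.

    Precomputed fingerprints (one per record, same space) may be passed to
    avoid re-encoding a library that is indexed in several spaces.
    """
    space = Space(space)
    if not records:
        raise ValueError("cannot build an index from an empty record list")
    if fingerprints is None:
        fingerprints = [fingerprint(record, space) for record in records]
    if len(fingerprints) != len(records):
        raise ValueError("records and fingerprints must have equal length")
    buckets: dict[int, list[tuple[MoleculeRecord, FingerprintVector]]] = {}
    for record, fp in zip(records, fingerprints):
        if fp.space != space:
            raise ValueError(f"fingerprint space {fp.space.value} != {space.value}")
        buckets.setdefault(fp.total_sum, []).append((record, fp))
    return SumKeyIndex(space=space, buckets=buckets)


def bucket_range(query_sum: int, max_cbd: int) -> tuple[int, int]:
    """Inclusive total-sum key range that can hold hits within ``max_cbd``.

    A query fingerprint with total sum 100 and CBD bound 10 needs only the
    keys 90..110; keys are clamped at zero from below.
    """
    if query_sum < 0 or max_cbd < 0:
        raise ValueError("query_sum and max_cbd must be non-negative")
    return (max(0, query_sum - max_cbd), query_sum + max_cbd)


def passes_filters(record: MoleculeRecord, query: SearchQuery) -> bool:
    """Vendor-mask intersection plus the enabled property locks."""
    if record.vendor_mask & query.wanted_vendor_mask == 0:
        return False
    q, f = query.query_record, query.filters
    if f.lock_formula and record.formula != q.formula:
        return False
    if f.lock_hba and record.hba != q.hba:
        return False
    if f.lock_hbd and record.hbd != q.hbd:
        return False
    if f.required_oxygen is not None and record.n_oxygen != f.required_oxygen:
        return False
    if f.required_nitrogen is not None and record.n_nitrogen != f.required_nitrogen:
        return False
    return True


def _scan_bucket(
    index: SumKeyIndex, key: int, query: SearchQuery, query_fp: FingerprintVector
) -> list[tuple[int, str, MoleculeRecord]]:
    out = []
    for record, fp in index.buckets.get(key, ()):
        if passes_filters(record, query):
            dist = int(np.abs(fp.values - query_fp.values).sum())
            out.append((dist, record.id, record))
    return out


def _finalize(candidates: list[tuple[int, str, MoleculeRecord]], cap: int) -> SearchResult:
    candidates.sort(key=lambda c: (c[0], c[1]))
    if len(candidates) > cap:
        logger.warning("result truncated to the %d nearest hits", cap)
        candidates = candidates[:cap]
    hits = [(record, dist) for dist, _, record in candidates]
    return SearchResult(hits=hits, histogram=dict(Counter(d for _, d in hits)))


def search(index: SumKeyIndex, query: SearchQuery) -> SearchResult:
    """Exact nearest-neighbor retrieval in the query's fingerprint space.

    ``MAX_DISTANCE``: all filter-passing records with CBD <= limit (the
    1000 nearest if more qualify). ``MAX_COUNT``: the ``limit`` filter-
    passing records with provably smallest CBD; buckets are visited in
    rings of increasing |Δ total sum| and the expansion stops only when the
    running k-th smallest CBD is strictly below the next ring's lower
    bound, which makes the hit set identical to a full linear scan.
    """
    if index.space != query.space:
        raise ValueError(
            f"index space {index.space.value} != query space {query.space.value}"
        )
    query_fp = fingerprint(query.query_record, query.space)
    qsum = query_fp.total_sum

    if query.mode is SearchMode.MAX_DISTANCE:
        low, high = bucket_range(qsum, query.limit)
        candidates = []
        for key in range(low, high + 1):
            candidates.extend(
                c for c in _scan_bucket(index, key, query, query_fp)
                if c[0] <= query.limit
            )
        return _finalize(candidates, MAX_HITS)

    # MAX_COUNT: ring expansion over |Δ total sum| = 0, 1, 2, ...
    k = query.limit
    max_key = max(index.buckets) if index.buckets else 0
    candidates: list[tuple[int, str, MoleculeRecord]] = []
    kth_heap: list[int] = []  # max-heap (negated) of the k smallest CBDs
    delta = 0
    while True:
        keys = {qsum + delta, qsum - delta}
        for key in keys:
            if key < 0:
                continue
            for cand in _scan_bucket(index, key, query, query_fp):
                candidates.append(cand)
                if len(kth_heap) < k:
                    heapq.heappush(kth_heap, -cand[0])
                elif cand[0] < -kth_heap[0]:
                    heapq.heapreplace(kth_heap, -cand[0])
        delta += 1
        ring_exhausted = qsum - delta < 0 and qsum + delta > max_key
        if len(kth_heap) == k and -kth_heap[0] < delta:
            break  # no unexplored bucket can hold a closer (or tied) hit
        if ring_exhausted:
            break
    candidates = [c for c in candidates if len(kth_heap) < k or c[0] <= -kth_heap[0]]
    result = _finalize(candidates, MAX_HITS)
    result.hits = result.hits[:k]
    result.histogram = dict(Counter(d for _, d in result.hits))
    return result


def cbd_histogram(result: SearchResult) -> dict[int, int]:
    """Count of hits at each CBD; values sum to the number of hits."""
    return dict(Counter(dist for _, dist in result.hits))


# --------------------------------------------------------------------------
# Persistence: one self-contained TSV per space, buckets in ascending key
# order. Count-space fingerprints are comma-separated; binary spaces are
# serialized as 1024-character 0/1 strings.

_COLUMNS = (
    "id", "smiles", "formula", "hba", "hbd", "n_oxygen", "n_nitrogen",
    "vendor_mask", "total_sum", "values",
)


def _serialize_values(fp: FingerprintVector) -> str:
    if fp.space.is_binary:
        return "".join("1" if v else "0" for v in fp.values)
    return ",".join(str(v) for v in fp.values)


def _parse_values(space: Space, text: str) -> np.ndarray:
    if space.is_binary:
        return np.frombuffer(text.encode(), dtype=np.uint8).astype(np.int64) - ord("0")
    return np.array([int(v) for v in text.split(",")], dtype=np.int64)


def save_index(index: SumKeyIndex, directory: str | Path) -> Path:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    path = directory / f"{index.space.value}.index.tsv"
    with path.open("w") as fh:
        fh.write("\t".join(_COLUMNS) + "\n")
        for key in sorted(index.buckets):
            for record, fp in index.buckets[key]:
                row = (
                    record.id, record.smiles, record.formula, record.hba,
                    record.hbd, record.n_oxygen, record.n_nitrogen,
                    record.vendor_mask, fp.total_sum, _serialize_values(fp),
                )
                fh.write("\t".join(str(v) for v in row) + "\n")
    return path


def load_index(directory: str | Path, space: Space | str) -> SumKeyIndex:
    space = Space(space)
    path = Path(directory) / f"{space.value}.index.tsv"
    buckets: dict[int, list[tuple[MoleculeRecord, FingerprintVector]]] = {}
    with path.open() as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if tuple(header) != _COLUMNS:
            raise ValueError(f"unexpected index header in {path}")
        for line in fh:
            f = line.rstrip("\n").split("\t")
            record = MoleculeRecord(
                id=f[0], smiles=f[1], formula=f[2], hba=int(f[3]), hbd=int(f[4]),
                n_oxygen=int(f[5]), n_nitrogen=int(f[6]), vendor_mask=int(f[7]),
            )
            fp = FingerprintVector(space, _parse_values(space, f[9]))
            if fp.total_sum != int(f[8]):
                raise ValueError(f"total_sum mismatch for {record.id} in {path}")
            buckets.setdefault(fp.total_sum, []).append((record, fp))
    if not buckets:
        raise ValueError(f"empty index file {path}")
    return SumKeyIndex(space=space, buckets=buckets)
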