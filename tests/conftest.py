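"""Shared fixtures: seeded synthetic libraries and their fingerprints.

The large library (5000 molecules) and its four fingerprint encodings are
session-scoped because encoding dominates test runtime; every consumer
treats them as read-only.
"""

from __future__ import annotations

import numpy as np
import pytest

import fpbrowser as fb

LIBRARY_SEED = 7
LIBRARY_SIZE = 5000


@pytest.fixture(scope="session")
def library5000() -> list[fb.MoleculeRecord]:
    return fb.generate_library(fb.GeneratorConfig(n=LIBRARY_SIZE, seed=LIBRARY_SEED))


@pytest.fixture(scope="session")
def fingerprints5000(library5000) -> dict[fb.Space, list[fb.FingerprintVector]]:
    return {
        space: [fb.fingerprint(record, space) for record in library5000]
        for space in fb.Space
    }


@pytest.fixture(scope="session")
def indexes5000(library5000, fingerprints5000) -> dict[fb.Space, fb.SumKeyIndex]:
    return {
        space: fb.build_index(library5000, space, fingerprints=fingerprints5000[space])
        for space in fb.Space
    }


@pytest.fixture(scope="session")
def library300() -> list[fb.MoleculeRecord]:
    return fb.generate_library(fb.GeneratorConfig(n=300, seed=11))


def linear_scan(
    records: list[fb.MoleculeRecord],
    fingerprints: list[fb.FingerprintVector],
    query: fb.SearchQuery,
) -> list[tuple[str, int]]:
    """Brute-force oracle for search(): (id, cbd) sorted by (cbd, id).

    Applies the same contract as the index — filters, mode semantics, the
    1000-hit ceiling — but by scanning every record, with no pruning.
    """
    query_fp = fb.fingerprint(query.query_record, query.space)
    matrix = np.vstack([fp.values for fp in fingerprints])
    dists = np.abs(matrix - query_fp.values[np.newaxis, :]).sum(axis=1)
    passing = [
        (int(dists[i]), record.id)
        for i, record in enumerate(records)
        if fb.passes_filters(record, query)
    ]
    passing.sort()
    if query.mode is fb.SearchMode.MAX_DISTANCE:
        passing = [p for p in passing if p[0] <= query.limit]
        passing = passing[: fb.MAX_HITS]
    else:
        passing = passing[: min(query.limit, fb.MAX_HITS)]
    return [(mol_id, dist) for dist, mol_id in passing]
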