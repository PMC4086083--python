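"""Similarity measures between fingerprint vectors.

Two measures are provided: the city-block (Manhattan, L1) distance used to
rank nearest neighbors, and the Tanimoto similarity coefficient in its
generalized count-vector form, which reduces to the familiar bit formula on
binary fingerprints.

The key property exploited by the sum-keyed index is the pruning bound

    |sum(A) - sum(B)|  <=  CBD(A, B)

which holds because the difference of sums is a signed telescoping of the
per-component differences.
"""

from __future__ import annotations

import logging

import numpy as np

from .fingerprints import FingerprintVector

logger = logging.getLogger(__name__)


def _check_spaces(a: FingerprintVector, b: FingerprintVector) -> None:
    if a.space != b.space:
        raise ValueError(
            f"fingerprint space mismatch: {a.space.value} vs {b.space.value}"
        )


def cbd(a: FingerprintVector, b: FingerprintVector) -> int:
    """City-block distance sum_j |A_j - B_j|; smaller means more similar."""
    _check_spaces(a, b)
    return int(np.abs(a.values - b.values).sum())


def tanimoto(a: FingerprintVector, b: FingerprintVector) -> float:
    """Generalized Tanimoto coefficient in [0, 1].

    ``sum(A.B) / (sum(A^2) + sum(B^2) - sum(A.B))``. Two all-zero vectors
    (degenerate molecules) return 0 with a logged warning rather than 0/0.
    """
    _check_spaces(a, b)
    dot = int(a.values @ b.values)
    denom = int(a.values @ a.values) + int(b.values @ b.values) - dot
    if denom == 0:
        logger.warning("Tanimoto of two all-zero fingerprints; returning 0.0")
        return 0.0
    return dot / denom


def cbd_matrix(query_values: np.ndarray, matrix: np.ndarray) -> np.ndarray:
    """City-block distances from one vector to every row of a matrix."""
    return np.abs(matrix - query_values[np.newaxis, :]).sum(axis=1)
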