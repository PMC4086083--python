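"""Seeded synthetic library generation.

Everything in the package is testable without downloading any compound
catalog: a fragment grammar (drug-like scaffold templates crossed with
substituent fragments) deterministically enumerates valid, standardizable
molecules, and a seeded generator samples unique records with random
9-bit vendor masks. The grammar guarantees chemical validity; it makes no
attempt to emulate any real catalog's property distributions.

Also provided: a handful of named real drug molecules used as reference
queries in docs and tests, and well-separated integer-vector "blobs" for
exercising the clustering module.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np

from .fingerprints import FingerprintVector, Space
from .standardize import (
    VENDOR_MASK_MAX,
    MoleculeRecord,
    annotate,
    standardize_smiles,
    strip_counter_ions,
)

# Scaffold templates with two substitution slots. Substituents are written
# so they stay valid SMILES both inside a branch "(...)" and appended to a
# chain tail.
TEMPLATES: tuple[str, ...] = (
    "c1ccc({a})cc1{b}",
    "c1ccc({a})c({b})c1",
    "c1cc({a})cc({b})c1",
    "c1ccc(CC({a}){b})cc1",
    "c1ccc(N({a})C(=O){b})cc1",
    "c1ccc(OC({a}){b})cc1",
    "c1ccnc({a})c1{b}",
    "c1ccc2c(c1)cc({a})n2{b}",
    "C1CCN(C(=O){a})CC1{b}",
    "C1CCC(N({a}){b})CC1",
    "c1csc({a})c1{b}",
    "c1cnc(N({a}){b})nc1",
    "O=C(N{a})c1ccc({b})cc1",
    "c1ccc(S(=O)(=O)N({a}){b})cc1",
)

SUBSTITUENTS: tuple[str, ...] = (
    "C", "CC", "CCC", "C(C)C", "CCCC", "C(C)(C)C",
    "O", "OC", "OCC", "N", "NC", "N(C)C",
    "F", "Cl", "Br", "C#N", "C(F)(F)F",
    "C(=O)O", "C(=O)N", "C(=O)OC", "C(=O)C",
    "CO", "CN", "CCO", "CCN", "S(C)(=O)=O", "SC",
    "C=C", "CC=C", "Cc1ccccc1",
)


@dataclass(frozen=True)
class GeneratorConfig:
    n: int
    seed: int
    templates: tuple[str, ...] = TEMPLATES
    substituents: tuple[str, ...] = SUBSTITUENTS
    vendor_bit_count: int = 9

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValueError(f"n must be >= 1, got {self.n}")


def generate_library(config: GeneratorConfig) -> list[MoleculeRecord]:
    """Sample ``n`` unique standardized records, deterministically per seed.

    The template x substituent x substituent grammar is enumerated in a
    seeded random order; each candidate is standardized and deduplicated on
    its canonical SMILES. Ids are ``SYN000001`` ... in acceptance order and
    vendor masks are drawn uniformly from [1, 511].
    """
    rng = np.random.default_rng(config.seed)
    combos = list(
        itertools.product(
            range(len(config.templates)),
            range(len(config.substituents)),
            range(len(config.substituents)),
        )
    )
    order = rng.permutation(len(combos))
    records: list[MoleculeRecord] = []
    seen: set[str] = set()
    for pos in order:
        t, a, b = combos[pos]
        raw = config.templates[t].format(
            a=config.substituents[a], b=config.substituents[b]
        )
        try:
            smiles = standardize_smiles(raw)
        except ValueError:  # grammar corner case; skip silently
            continue
        if smiles in seen:
            continue
        seen.add(smiles)
        mask = int(rng.integers(1, VENDOR_MASK_MAX + 1))
        records.append(annotate(smiles, f"SYN{len(records) + 1:06d}", mask))
        if len(records) == config.n:
            return records
    raise ValueError(
        f"fragment grammar exhausted after {len(records)} unique molecules "
        f"(requested {config.n}); provide a larger template/substituent set"
    )


#: Named query molecules (as drawn; counter ions stripped but no pH rules —
#: queries enter the browser as sketched, the library is standardized).
REFERENCE_SMILES: dict[str, str] = {
    "adrenaline": "CNC[C@H](O)c1ccc(O)c(O)c1",
    "aspirin": "CC(=O)Oc1ccccc1C(=O)O",
    "caffeine": "Cn1cnc2c1c(=O)n(C)c(=O)n2C",
    "ibuprofen": "CC(C)Cc1ccc(C(C)C(=O)O)cc1",
    "paracetamol": "CC(=O)Nc1ccc(O)cc1",
}


def reference_queries() -> dict[str, MoleculeRecord]:
    """Bundled named query molecules, annotated as drawn."""
    return {
        name: annotate(strip_counter_ions(smi), name)
        for name, smi in REFERENCE_SMILES.items()
    }


def make_blobs(
    space: Space | str,
    k: int,
    per_blob: int,
    seed: int,
    spread: int = 2,
    separation: int = 200,
) -> tuple[list[FingerprintVector], np.ndarray]:
    """Well-separated integer-vector blobs in a count space (MQN / SMIfp).

    Each blob's points deviate from its center by at most ``spread`` per
    perturbed component (intra-blob CBD <= 3 * 2 * spread), while centers
    differ by ``separation`` on three components (inter-blob CBD >=
    ``separation``); with the defaults the margin exceeds the spread by
    more than an order of magnitude. Returns the vectors and the true blob
    labels.
    """
    space = Space(space)
    if space.is_binary:
        raise ValueError("make_blobs supports the count spaces (MQN, SMIfp) only")
    rng = np.random.default_rng(seed)
    dims = space.n_dims
    vectors: list[FingerprintVector] = []
    labels = []
    for blob in range(k):
        center = np.full(dims, 10, dtype=np.int64)
        center[(3 * blob) % dims] += separation * (blob + 1)
        for _ in range(per_blob):
            point = center.copy()
            where = rng.choice(dims, size=3, replace=False)
            point[where] += rng.integers(0, spread + 1, size=3)
            vectors.append(FingerprintVector(space, point))
            labels.append(blob)
    return vectors, np.array(labels)
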