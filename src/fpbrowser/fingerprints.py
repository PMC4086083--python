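"""The four fingerprint spaces.

Two binary substructure fingerprints and two scalar count fingerprints,
all encoded as non-negative integer vectors with a cached total sum (the
hash key of the sum-keyed index):

- ``SFP``   — daylight-type substructure fingerprint: every linear
  atom-bond path of length 0-7 bonds, hashed to 1024 bits.
- ``ECFP4`` — extended-connectivity fingerprint of bond diameter 4
  (circular environments of radius 0-2), folded to 1024 bits.
- ``MQN``   — molecular quantum numbers: 42 integer counts of atoms,
  bonds, polar groups and topological features.
- ``SMIFP`` — SMILES fingerprint: counts of 34 defined symbols in the
  canonical SMILES string.

All four encoders are pure functions of the canonical structure: any
SMILES ordering of the same molecule yields the same vector.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from enum import Enum

import numpy as np
from rdkit import Chem
from rdkit.Chem import rdFingerprintGenerator, rdMolDescriptors

from .standardize import MoleculeRecord, _mol_from_smiles

#: Maximum linear path length, in bonds, enumerated by the substructure
#: fingerprint.
SFP_MAX_PATH_LENGTH = 7
#: Bond diameter of the extended-connectivity fingerprint (radius 2).
ECFP_BOND_DIAMETER = 4
#: Folded length of both binary fingerprints.
N_BITS = 1024


class Space(str, Enum):
    """Fingerprint space identifiers."""

    SFP = "sfp"
    ECFP4 = "ecfp4"
    MQN = "mqn"
    SMIFP = "smifp"

    @property
    def n_dims(self) -> int:
        return _DIMS[self]

    @property
    def is_binary(self) -> bool:
        return self in (Space.SFP, Space.ECFP4)


_DIMS = {Space.SFP: N_BITS, Space.ECFP4: N_BITS, Space.MQN: 42, Space.SMIFP: 34}


@dataclass(frozen=True)
class FingerprintVector:
    """A fingerprint with its total sum (the index hash key)."""

    space: Space
    values: np.ndarray
    total_sum: int = field(init=False)

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=np.int64)
        if values.shape != (self.space.n_dims,):
            raise ValueError(
                f"{self.space.value} fingerprint must have length "
                f"{self.space.n_dims}, got shape {values.shape}"
            )
        if (values < 0).any():
            raise ValueError("fingerprint values must be non-negative")
        if self.space.is_binary and (values > 1).any():
            raise ValueError(f"{self.space.value} fingerprint must be binary")
        values.setflags(write=False)
        object.__setattr__(self, "values", values)
        object.__setattr__(self, "total_sum", int(values.sum()))


# --------------------------------------------------------------------------
# MQN — 42 integer descriptors: 12 atom counts, 7 bond counts (aromatic
# systems kekulized first; rotatable bonds), 6 polarity counts and 17
# topology counts. RDKit implements the canonical definition.

def mqn(record: MoleculeRecord) -> FingerprintVector:
    mol = _mol_from_smiles(record.smiles, context=record.id)
    return FingerprintVector(Space.MQN, np.array(rdMolDescriptors.MQNs_(mol)))


# --------------------------------------------------------------------------
# SMIfp — literal symbol counts on the canonical SMILES. Two-character
# element symbols (Cl, Br) count as one symbol; anything outside the table
# (stereo bond slashes, '%nn' ring closures) is ignored.

SMIFP_SYMBOLS: tuple[str, ...] = (
    "C", "c", "N", "n", "O", "o", "S", "s", "P", "F", "Cl", "Br", "I", "B",
    "=", "#", "(", ")", "[", "]", "+", "-", "@", "H",
    "1", "2", "3", "4", "5", "6", "7", "8", "9", ".",
)
_SMIFP_INDEX = {sym: i for i, sym in enumerate(SMIFP_SYMBOLS)}


def smifp(record: MoleculeRecord) -> FingerprintVector:
    canonical = Chem.MolToSmiles(_mol_from_smiles(record.smiles, context=record.id))
    counts = np.zeros(len(SMIFP_SYMBOLS), dtype=np.int64)
    i = 0
    while i < len(canonical):
        two = canonical[i : i + 2]
        if two in ("Cl", "Br"):
            counts[_SMIFP_INDEX[two]] += 1
            i += 2
            continue
        idx = _SMIFP_INDEX.get(canonical[i])
        if idx is not None:
            counts[idx] += 1
        i += 1
    return FingerprintVector(Space.SMIFP, counts)


# --------------------------------------------------------------------------
# sFP — all linear paths of 0..7 bonds. Each path is rendered as a token
# string (atom symbol + aromaticity + formal charge, joined by bond-order
# symbols), read in whichever direction is lexicographically smaller, and
# hashed with SHA-1 to one of 1024 bit positions. The hash is stable across
# runs and platforms; bit-exact parity with any other toolkit's path
# fingerprint is not a goal.

_BOND_SYMBOL = {
    Chem.BondType.SINGLE: "-",
    Chem.BondType.DOUBLE: "=",
    Chem.BondType.TRIPLE: "#",
    Chem.BondType.AROMATIC: ":",
}


def _atom_token(atom: Chem.Atom) -> str:
    token = atom.GetSymbol()
    if atom.GetIsAromatic():
        token = token.lower()
    charge = atom.GetFormalCharge()
    if charge:
        token += f"{charge:+d}"
    return token


def _path_token(mol: Chem.Mol, bond_path: tuple[int, ...]) -> str:
    bonds = [mol.GetBondWithIdx(i) for i in bond_path]
    # Reconstruct the atom sequence from the bond sequence.
    if len(bonds) == 1:
        atoms = [bonds[0].GetBeginAtomIdx(), bonds[0].GetEndAtomIdx()]
    else:
        first, second = bonds[0], bonds[1]
        shared = {first.GetBeginAtomIdx(), first.GetEndAtomIdx()} & {
            second.GetBeginAtomIdx(), second.GetEndAtomIdx()
        }
        start = ({first.GetBeginAtomIdx(), first.GetEndAtomIdx()} - shared).pop()
        atoms = [start]
        for bond in bonds:
            atoms.append(bond.GetOtherAtomIdx(atoms[-1]))
    pieces = [_atom_token(mol.GetAtomWithIdx(atoms[0]))]
    for bond, atom_idx in zip(bonds, atoms[1:]):
        pieces.append(_BOND_SYMBOL[bond.GetBondType()])
        pieces.append(_atom_token(mol.GetAtomWithIdx(atom_idx)))
    forward = "".join(pieces)
    backward = "".join(reversed(pieces))
    return min(forward, backward)


def _stable_bit(token: str) -> int:
    digest = hashlib.sha1(token.encode()).digest()
    return int.from_bytes(digest[:4], "big") % N_BITS


def sfp(record: MoleculeRecord) -> FingerprintVector:
    mol = _mol_from_smiles(record.smiles, context=record.id)
    bits = np.zeros(N_BITS, dtype=np.int64)
    for atom in mol.GetAtoms():  # length-0 paths: single atoms
        bits[_stable_bit(_atom_token(atom))] = 1
    for length in range(1, SFP_MAX_PATH_LENGTH + 1):
        for path in Chem.FindAllPathsOfLengthN(mol, length, useBonds=True):
            bits[_stable_bit(_path_token(mol, tuple(path)))] = 1
    return FingerprintVector(Space.SFP, bits)


# --------------------------------------------------------------------------
# ECFP4 — Morgan circular environments of radius 0..2, duplicate
# environment identifiers emitted once, folded to 1024 bits.

_MORGAN = rdFingerprintGenerator.GetMorganGenerator(
    radius=ECFP_BOND_DIAMETER // 2, fpSize=N_BITS
)


def ecfp4(record: MoleculeRecord) -> FingerprintVector:
    mol = _mol_from_smiles(record.smiles, context=record.id)
    fp = _MORGAN.GetFingerprintAsNumPy(mol)
    return FingerprintVector(Space.ECFP4, fp.astype(np.int64))


_ENCODERS = {Space.SFP: sfp, Space.ECFP4: ecfp4, Space.MQN: mqn, Space.SMIFP: smifp}


def fingerprint(record: MoleculeRecord, space: Space | str) -> FingerprintVector:
    """Encode ``record`` in the requested space."""
    return _ENCODERS[Space(space)](record)


def fingerprint_matrix(
    records: list[MoleculeRecord], space: Space | str
) -> np.ndarray:
    """Stack fingerprints of many records into an (n, dims) int64 matrix."""
    space = Space(space)
    return np.vstack([_ENCODERS[space](r).values for r in records])
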